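"""Domain-rotation geometry: superposition, Euler-Rodrigues axis, rotation/tilt
decomposition, per-residue average spatial deviation and free energy vs tilt.

The rotation of a mobile domain relative to a fixed body is described by
active Z-Y-Z Euler angles in a reference frame whose Z axis is the
Euler-Rodrigues (E-R) axis relating two end-state orientations of the domain.
In this convention gamma = phi + psi measures rotation about the E-R axis and
the polar angle theta ("tilt") measures rotation orthogonal to it.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .structure import Structure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------------

@dataclasses.dataclass
class RigidTransform:
    """y ~ rotation @ x + translation, least-squares over the fitted atoms."""

    rotation: np.ndarray     # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, A
    rmsd: float              # A over fitted atoms

    def apply(self, coord: np.ndarray) -> np.ndarray:
        return coord @ self.rotation.T + self.translation


def kabsch_fit(
    reference: np.ndarray,
    mobile: np.ndarray,
    selection: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal proper rotation + translation mapping mobile onto reference.

    Uses the SVD solution of the orthogonal Procrustes problem with the
    determinant correction that excludes reflections.  Requires at least
    three non-collinear selected atoms.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref = ref[sel]
        mob = mob[sel]
    if ref.shape != mob.shape:
        raise ValueError("reference/mobile selections differ in length")
    if len(ref) < 3:
        raise ValueError("need at least 3 atoms to superpose")

    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = ref - ref_c
    q = mob - mob_c
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    # collinearity: rank of the centered point cloud < 2
    if np.linalg.matrix_rank(p, tol=1e-8 * max(1.0, np.abs(p).max())) < 2:
        raise ValueError("degenerate (collinear) selection for superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mob_c
    fitted = q @ rot.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


# ---------------------------------------------------------------------------------
# Euler-Rodrigues axis/angle and Z-Y-Z decomposition
# ---------------------------------------------------------------------------------

def _axis_angle(rot: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Axis (unit vector or None if undefined) and angle (deg) of a rotation."""
    tr = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(tr)
    if angle < 1e-8:
        return None, float(np.degrees(angle))
    if np.pi - angle < 1e-6:
        # near 180 deg: axis from the symmetric part's dominant eigenvector
        w, v = np.linalg.eigh((rot + rot.T) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = np.array([
            rot[2, 1] - rot[1, 2],
            rot[0, 2] - rot[2, 0],
            rot[1, 0] - rot[0, 1],
        ]) / (2.0 * np.sin(angle))
    axis = axis / np.linalg.norm(axis)
    return axis, float(np.degrees(angle))


def er_axis_angle(
    transform_a: RigidTransform | np.ndarray,
    transform_b: RigidTransform | np.ndarray,
) -> tuple[np.ndarray | None, float]:
    """Euler-Rodrigues axis and angle of the relative rotation R_b R_a^T.

    Returns (axis, angle_deg) with angle in [0, 180]; axis is None (flagged
    undefined) when the two orientations coincide.
    """
    ra = transform_a.rotation if isinstance(transform_a, RigidTransform) else np.asarray(transform_a)
    rb = transform_b.rotation if isinstance(transform_b, RigidTransform) else np.asarray(transform_b)
    for r in (ra, rb):
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("inputs must be proper orthogonal rotations")
    rel = rb @ ra.T
    axis, angle = _axis_angle(rel)
    if axis is None:
        logger.info("relative rotation ~0 degrees; E-R axis undefined")
    return axis, angle


def axis_frame(z_axis: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal basis (columns X, Y, Z) with the given Z axis."""
    z = np.asarray(z_axis, dtype=float)
    z = z / np.linalg.norm(z)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def euler_zyz(rot: np.ndarray) -> tuple[float, float, float]:
    """Decompose an active rotation as Rz(phi) Ry(theta) Rz(psi), radians.

    theta is returned in [0, pi].  In the degenerate theta ~ 0 (or pi) case
    only phi + psi (phi - psi) is defined; psi is set to 0 there.
    """
    r = np.asarray(rot, dtype=float)
    cos_t = np.clip(r[2, 2], -1.0, 1.0)
    # sin(theta) from the off-diagonal entries: more precise near the poles
    # than arccos(r22), and robust when those entries are pure round-off
    sin_t = np.sqrt(
        0.5 * (r[0, 2] ** 2 + r[1, 2] ** 2 + r[2, 0] ** 2 + r[2, 1] ** 2)
    )
    theta = np.arctan2(sin_t, cos_t)
    if sin_t > 1e-9:
        phi = np.arctan2(r[1, 2], r[0, 2])
        psi = np.arctan2(r[2, 1], -r[2, 0])
    elif cos_t > 0:  # theta ~ 0: rotation purely about z
        phi = np.arctan2(r[1, 0], r[0, 0])
        psi = 0.0
    else:            # theta ~ pi
        phi = np.arctan2(-r[1, 0], -r[0, 0])
        psi = 0.0
    return float(phi), float(theta), float(psi)


def compose_zyz(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rebuild the rotation matrix Rz(phi) Ry(theta) Rz(psi) (radians)."""
    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(phi) @ ry(theta) @ rz(psi)


@dataclasses.dataclass
class EulerDecomposition:
    """Per-frame Z-Y-Z angles (degrees) about a fixed E-R reference frame."""

    phi: float
    psi: float
    theta: float
    gamma: float  # phi + psi, wrapped to (-180, 180]
    frame_index: int


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def rotation_tilt_timeseries(
    traj,
    post_reference: Structure | np.ndarray,
    body_selection: np.ndarray,
    domain_selection: np.ndarray,
    er_axis: np.ndarray,
    frame_mask: np.ndarray | None = None,
) -> list[EulerDecomposition]:
    """Per-frame rotation (gamma) and tilt (theta) of a domain.

    For each frame: (1) superpose the frame onto the reference on the body
    selection; (2) fit the reference domain onto the frame's domain atoms;
    (3) decompose the resulting rotation with Z-Y-Z Euler angles in the frame
    whose Z axis is the E-R axis; (4) report gamma = phi + psi and tilt theta.
    An optional boolean frame mask restricts the output.
    """
    ref_coord = (
        post_reference.coord
        if isinstance(post_reference, Structure)
        else np.asarray(post_reference, dtype=float)
    )
    er = np.asarray(er_axis, dtype=float)
    if abs(np.linalg.norm(er) - 1.0) > 1e-6:
        raise ValueError("er_axis must be normalized")
    frames = traj.frames if hasattr(traj, "frames") else np.asarray(traj)
    if frames.shape[1] != len(ref_coord):
        raise ValueError("trajectory and reference atom counts differ")
    basis = axis_frame(er)
    out: list[EulerDecomposition] = []
    for fi, frame in enumerate(frames):
        if frame_mask is not None and not frame_mask[fi]:
            continue
        t_body = kabsch_fit(ref_coord, frame, body_selection)
        aligned = t_body.apply(frame)
        t_dom = kabsch_fit(aligned, ref_coord, domain_selection)
        m = basis.T @ t_dom.rotation @ basis
        phi, theta, psi = euler_zyz(m)
        out.append(
            EulerDecomposition(
                phi=float(np.degrees(phi)),
                psi=float(np.degrees(psi)),
                theta=float(np.degrees(theta)),
                gamma=_wrap_deg(float(np.degrees(phi) + np.degrees(psi))),
                frame_index=fi,
            )
        )
    return out


def decompositions_to_frame(decomps: list[EulerDecomposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.frame_index, d.phi, d.psi, d.theta, d.gamma) for d in decomps],
        columns=["frame", "phi", "psi", "theta", "gamma"],
    )


# ---------------------------------------------------------------------------------
# per-residue average spatial deviation
# ---------------------------------------------------------------------------------

@dataclasses.dataclass
class ASDProfile:
    """Per-residue average spatial deviation (A) over a trajectory."""

    table: pd.DataFrame  # columns: chain, resid, asd

    def value(self, chain: str, resid: int) -> float:
        row = self.table[(self.table.chain == chain) & (self.table.resid == resid)]
        return float(row.asd.iloc[0])


def asd_per_residue(
    traj,
    reference: Structure,
    domain_selection: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> ASDProfile:
    """Mean per-residue displacement from the reference after superposition.

    Each frame is aligned onto the reference over ``fit_selection`` (default:
    the domain selection itself, i.e. intramolecular deformation); the
    deviation of each residue's representative atom in ``domain_selection``
    is then averaged over frames.
    """
    frames = traj.frames if hasattr(traj, "frames") else np.asarray(traj)
    if len(frames) == 0:
        raise ValueError("empty frame set")
    fit_sel = domain_selection if fit_selection is None else fit_selection
    ref = reference.coord
    dom = np.asarray(domain_selection, dtype=int)
    dev_sum = np.zeros(len(dom))
    for frame in frames:
        t = kabsch_fit(ref, frame, fit_sel)
        aligned = t.apply(frame)
        dev_sum += np.linalg.norm(aligned[dom] - ref[dom], axis=1)
    asd = dev_sum / len(frames)
    table = pd.DataFrame(
        {
            "chain": reference.chain_id[dom],
            "resid": reference.res_id[dom],
            "asd": asd,
        }
    )
    return ASDProfile(table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------------
# free energy vs tilt
# ---------------------------------------------------------------------------------

@dataclasses.dataclass
class FESProfile:
    """Binned free energy F(theta) = -T ln P(theta), shifted so min F = 0.

    Bins with zero counts carry F = NaN (undefined, not zero).
    """

    table: pd.DataFrame  # columns: theta_lo, theta_hi, theta_mid, count, free_energy


def free_energy_vs_tilt(
    decomps,
    temperature: float,
    bin_width: float = 1.0,
    jacobian: bool = False,
) -> FESProfile:
    """Boltzmann inversion of the tilt-angle histogram (k_BT units).

    ``decomps`` is a list of :class:`EulerDecomposition` or an array of tilt
    angles in degrees.  With ``jacobian=True`` the probability is divided by
    sin(theta) before inversion (spherical-measure correction, off by
    default).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if isinstance(decomps, (list, tuple)) and decomps and isinstance(
        decomps[0], EulerDecomposition
    ):
        theta = np.array([d.theta for d in decomps], dtype=float)
    else:
        theta = np.asarray(decomps, dtype=float)
    if theta.size == 0:
        raise ValueError("no tilt samples")
    lo = np.floor(theta.min() / bin_width) * bin_width
    hi = np.ceil(theta.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(theta, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p = counts.astype(float) / counts.sum()
    if jacobian:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = p / np.sin(np.radians(np.clip(mids, 1e-3, None)))
    with np.errstate(divide="ignore"):
        f = np.where(counts > 0, -temperature * np.log(np.where(p > 0, p, 1.0)), np.nan)
    finite = np.isfinite(f)
    if finite.sum() == 1:
        logger.warning("all tilt samples fall in a single bin; profile is trivial")
    f = f - np.nanmin(f)
    table = pd.DataFrame(
        {
            "theta_lo": edges[:-1],
            "theta_hi": edges[1:],
            "theta_mid": mids,
            "count": counts,
            "free_energy": f,
        }
    )
    return FESProfile(table=table)
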