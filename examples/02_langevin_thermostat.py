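"""Langevin dynamics in reduced units: thermostat sanity on the toy system.

Runs BAOAB Langevin dynamics at the reduced temperature 0.5 and checks
equipartition: the mean kinetic energy per degree of freedom should settle
at T/2 = 0.25 eps.
"""
import sbmkit

structure, _ = sbmkit.make_toy_two_domain_system()
ff = sbmkit.build_force_field(structure)

config = sbmkit.SimConfig(temperature=0.5, timestep=0.002, friction=1.0,
                          n_steps=10_000, save_interval=100, seed=7)
traj = sbmkit.run_langevin(ff, sbmkit.State(structure.coord.copy()), config)

ke = traj.energies.kinetic.to_numpy()
burn = len(ke) // 4
per_dof = ke[burn:].mean() / (3 * structure.n_atoms)
print(f"{config.n_steps} steps at T = {config.temperature}, "
      f"{traj.n_frames} frames saved")
print(traj.energies[["step", "potential", "kinetic", "temperature"]].tail(3)
      .to_string(index=False))
print(f"mean kinetic energy per dof = {per_dof:.4f} eps "
      f"(equipartition predicts T/2 = {config.temperature / 2})")
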