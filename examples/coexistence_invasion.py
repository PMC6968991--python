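"""Cooperative invasion in the stable-coexistence regime.

At (c_MA, c_AM) = (0, 0) the two phenotypes do not compete with each
other: they mix, combine acid production with matrix degradation, and
advance as a single front. This script integrates the default
configuration to t = 50 (about 575 days), prints the front position and
tumour mass at each snapshot, and converts the late-time front speed to
cm/year with the printed scales (2.24 cm and 11.57 days per unit).
"""

from acidinvasion import (
    DimensionlessParams,
    Grid1D,
    InitialConditionSpec,
    SolverSettings,
    build_initial_state,
    front_position,
    integrate,
    invasion_speed,
    speed_cm_per_year,
    to_dimensional,
    tumour_mass,
)

params = DimensionlessParams()  # defaults: c_MA = c_AM = 0
grid = Grid1D()
state0 = build_initial_state(grid, InitialConditionSpec())
traj = integrate(state0, params, grid, SolverSettings(snapshot_times=(0.0, 25.0, 50.0)))

for t, state in zip(traj.times, traj.states):
    f = front_position(state, grid, "either")
    print(
        f"t = {t:4.0f} ({to_dimensional(t, 'time'):6.1f} days): "
        f"front x = {f:.4f}, tumour mass = {tumour_mass(state, grid):.4f}"
    )

v = invasion_speed(traj, "either", window=(25.0, 50.0))
print(f"\nfront speed over t in [25, 50]: {v:.5f} (dimensionless)")
print(f"  = {speed_cm_per_year(v):.3f} cm/year")
print("\nThe mixed front advances steadily — unlike either phenotype alone —")
print("at a speed set by how fast the degrader tail clears matrix ahead of it.")
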