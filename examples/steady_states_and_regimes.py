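"""Enumerate the homogeneous steady states and locate stability thresholds.

The kinetics admit closed-form equilibria (healthy tissue, monocultures,
and several coexistence states). This script classifies their linear
stability at the default parameters with symmetric competition 0.5 and
then bisects the competition values at which the coexistence state SS3
and the acid-monoculture state SS1 change stability.
"""

from acidinvasion import (
    DimensionlessParams,
    classify_regime,
    classify_stability,
    critical_competition,
    enumerate_steady_states,
)

params = DimensionlessParams(c_MA=0.5, c_AM=0.5)

print(f"regime at (c_MA, c_AM) = (0.5, 0.5): {classify_regime(0.5, 0.5)}\n")
print(f"{'state':6s} {'S':>8s} {'T_A':>8s} {'T_M':>8s} {'L':>8s} {'M':>6s}  feasible  stability")
for ss in enumerate_steady_states(params):
    classify_stability(ss, params)
    m = "free" if ss.m_free else f"{ss.M:.2f}"
    print(
        f"{ss.label:6s} {ss.S:8.4f} {ss.T_A:8.4f} {ss.T_M:8.4f} {ss.L:8.4f} {m:>6s}"
        f"  {str(ss.feasible):8s}  {ss.stability}"
        + (f" (non-matrix: {ss.nonmatrix_stability})" if ss.nonmatrix_stability else "")
    )

defaults = DimensionlessParams()
print()
print("stability thresholds (bisection on the leading non-matrix eigenvalue):")
print(f"  SS3, symmetric c_MA = c_AM:   c* = {critical_competition(defaults, 'symmetric'):.6f}")
print(f"  SS3, c_AM axis (c_MA = 0.5):  c* = {critical_competition(defaults, 'c_AM', 0.5):.6f}")
print(f"  SS3, c_MA axis (c_AM = 0.5):  c* = {critical_competition(defaults, 'c_MA', 0.5):.6f}")
print(f"  SS1, onset along c_AM:        c* = {critical_competition(defaults, 'c_AM', target_state='SS1'):.6f}")
print()
print("The coexistence state is stable only while inter-species competition")
print("stays below the intra-species level; on the c_MA axis the boundary")
print("sits slightly below 1 because the acid supply (delta * T_A*) must")
print("also remain strong enough to keep the stroma excluded.")
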