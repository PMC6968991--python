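"""Neither tumour phenotype invades on its own.

Long-horizon controls (t = 10,000, over ten years at the 11.57-day time
unit): with only acid-producers present the front stalls against the
undegraded matrix barrier near x = 0.3; with only matrix-degraders the
intact stroma suppresses growth and the front stops near x = 0.2. Any
invasion seen in the two-phenotype runs is therefore due to cooperation.
"""

from acidinvasion import SolverSettings, to_dimensional
from acidinvasion.experiments import run_single_population

settings = SolverSettings(
    rel_tol=1e-8, abs_tol=1e-8,
    snapshot_times=(0.0, 25.0, 100.0, 1000.0, 5000.0, 10_000.0),
)

for which, barrier in (("T_A", "extra-cellular matrix"), ("T_M", "stroma")):
    res = run_single_population(which, t_end=10_000.0, settings=settings)
    print(f"{which} alone (blocked by {barrier}):")
    for t, f in zip(res.front_times, res.front_positions):
        print(f"  t = {t:7.0f}  front at x = {f:.4f}")
    print(
        f"  -> stalled: {res.stalled}; final position x = {res.stall_position:.3f}"
        f" ({to_dimensional(res.stall_position, 'length'):.2f} cm from the core)\n"
    )
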