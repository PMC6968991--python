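"""Scripted in-silico experiments.

Each driver wires together the initial data, the solver and the metrics
for one of the study designs: single-population controls, the competition
sweep over (c_MA, c_AM), four-regime snapshot runs, perturbation of the
bistable front, and the matrix-degradation (kappa) sensitivity study.

Defaults reproduce the published study conditions: 200-point grid on
[0, 1], steps at sigma = 0.2 (tissue) / 0.1 (tumour) with omega = 0.1,
t_end = 50 (about 575 days) except for the long single-population controls
(t_end = 10,000). Sweep-scale drivers default to a relaxed tolerance of
1e-8; see the methods note for the measured effect (below 1e-3 on front
positions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import Grid1D, StateFields
from .initial import InitialConditionSpec, build_initial_state
from .metrics import (
    front_position,
    small_population_flag,
    species_integral,
    tumour_mass,
)
from .params import DimensionlessParams
from .solver import SolverSettings, Trajectory, integrate
from .steady_states import classify_regime

#: a species with a smaller integral than this counts as extinct
EXTINCTION_INTEGRAL = 1e-3
#: a front moving less than this over the final 10 time units is halted
HALT_DISPLACEMENT = 0.01

_SWEEP_TOLS = dict(rel_tol=1e-8, abs_tol=1e-8)


class InvalidExperimentError(ValueError):
    pass


@dataclass
class SinglePopulationResult:
    which: str
    trajectory: Trajectory
    front_times: np.ndarray
    front_positions: list
    stall_position: float | None

    @property
    def stalled(self) -> bool:
        f = [p for p in self.front_positions[-2:] if p is not None]
        return len(f) == 2 and abs(f[1] - f[0]) < HALT_DISPLACEMENT


def run_single_population(
    which: str,
    t_end: float = 10_000.0,
    params: DimensionlessParams | None = None,
    grid: Grid1D | None = None,
    ics: InitialConditionSpec | None = None,
    settings: SolverSettings | None = None,
) -> SinglePopulationResult:
    """Long-horizon control with only one tumour phenotype present.

    In isolation neither phenotype can invade: the acid-producers stall
    against undegraded matrix, the matrix-degraders against intact stroma.
    """
    if which not in ("T_A", "T_M"):
        raise InvalidExperimentError(
            f"which must be 'T_A' or 'T_M', got {which!r} (at least one population must be present)"
        )
    params = params or DimensionlessParams()
    grid = grid or Grid1D()
    ics = ics or InitialConditionSpec()
    ics = replace(ics, include_TA=which == "T_A", include_TM=which == "T_M")
    if settings is None:
        snaps = tuple(t for t in (0, 10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 7500) if t < t_end)
        settings = SolverSettings(snapshot_times=snaps + (t_end,), **_SWEEP_TOLS)
    state0 = build_initial_state(grid, ics)
    traj = integrate(state0, params, grid, settings)
    fronts = [front_position(s, grid, which) for s in traj.states]
    return SinglePopulationResult(which, traj, traj.times.copy(), fronts, fronts[-1])


@dataclass
class SweepRecord:
    """Metrics for one (c_MA, c_AM) point of the competition sweep."""

    c_MA: float
    c_AM: float
    front_either: float | None = None
    front_either_max_rate: float | None = None
    front_TA: float | None = None
    front_TM: float | None = None
    mass: float = np.nan
    integral_TA: float = np.nan
    integral_TM: float = np.nan
    keep_TA: bool = False
    keep_TM: bool = False
    regime: str = ""
    error: str | None = None


def _sweep_point(
    c_MA, c_AM, state0, params, grid, settings, t_end
) -> SweepRecord:
    rec = SweepRecord(c_MA=c_MA, c_AM=c_AM, regime=classify_regime(c_MA, c_AM))
    p = params.replace(c_MA=c_MA, c_AM=c_AM)
    try:
        traj = integrate(state0, p, grid, settings)
    except Exception as exc:  # per-record failure must not kill the sweep
        rec.error = f"{type(exc).__name__}: {exc}"
        return rec
    final = traj.state_at(t_end)
    rec.front_either = front_position(final, grid, "either")
    rec.front_either_max_rate = front_position(final, grid, "either", method="max_rate", params=p)
    rec.front_TA = front_position(final, grid, "T_A")
    rec.front_TM = front_position(final, grid, "T_M")
    rec.mass = tumour_mass(final, grid)
    rec.integral_TA = species_integral(final, grid, "T_A")
    rec.integral_TM = species_integral(final, grid, "T_M")
    rec.keep_TA = small_population_flag(final, grid, "T_A")
    rec.keep_TM = small_population_flag(final, grid, "T_M")
    return rec


def run_competition_sweep(
    c_MA_values,
    c_AM_values=None,
    t_end: float = 50.0,
    params: DimensionlessParams | None = None,
    grid: Grid1D | None = None,
    ics: InitialConditionSpec | None = None,
    settings: SolverSettings | None = None,
    progress=None,
) -> list[SweepRecord]:
    """One record per (c_MA, c_AM) combination, row-major over the grid.

    Runs are independent, so results do not depend on evaluation order.
    ``progress`` may be a callable taking the finished record (e.g. for a
    progress bar or incremental writing).
    """
    c_MA_values = np.atleast_1d(np.asarray(c_MA_values, dtype=float))
    c_AM_values = (
        c_MA_values if c_AM_values is None else np.atleast_1d(np.asarray(c_AM_values, dtype=float))
    )
    if c_MA_values.size == 0 or c_AM_values.size == 0:
        raise InvalidExperimentError("competition grid must be non-empty")
    params = params or DimensionlessParams()
    grid = grid or Grid1D()
    ics = ics or InitialConditionSpec()
    settings = settings or SolverSettings(snapshot_times=(0.0, t_end), **_SWEEP_TOLS)
    state0 = build_initial_state(grid, ics)
    records = []
    for c_MA in c_MA_values:
        for c_AM in c_AM_values:
            rec = _sweep_point(float(c_MA), float(c_AM), state0, params, grid, settings, t_end)
            records.append(rec)
            if progress is not None:
                progress(rec)
    return records


@dataclass
class SnapshotResult:
    c_MA: float
    c_AM: float
    trajectory: Trajectory
    outcome: str
    survived_TA: bool
    survived_TM: bool
    halted: bool


def run_snapshot_experiment(
    c_MA: float,
    c_AM: float,
    snapshot_times: tuple = (0.0, 25.0, 40.0, 50.0),
    params: DimensionlessParams | None = None,
    grid: Grid1D | None = None,
    ics: InitialConditionSpec | None = None,
    settings: SolverSettings | None = None,
) -> SnapshotResult:
    """Integrate one competition pair and classify the qualitative outcome.

    Outcomes: ``mixed_invasion`` (both phenotypes survive and the front
    advances), ``unstable_mixed_front`` (the same but in the bistable
    regime, where the mixed front is structurally unstable),
    ``encapsulation`` (matrix-degraders exclude acid-producers and the
    stroma pens the tumour in), ``transient_invasion`` (acid-producers
    exclude matrix-degraders; advance stops once the degrader rim dies),
    ``arrest`` (neither survives or no motion at all). Extinction means a
    species integral below 1e-3; halted means front displacement below
    0.01 over the final 10 time units.
    """
    params = (params or DimensionlessParams()).replace(c_MA=c_MA, c_AM=c_AM)
    grid = grid or Grid1D()
    ics = ics or InitialConditionSpec()
    settings = settings or SolverSettings(snapshot_times=snapshot_times, **_SWEEP_TOLS)
    traj = integrate(build_initial_state(grid, ics), params, grid, settings)
    t_end = traj.times[-1]
    final = traj.states[-1]
    surv_A = species_integral(final, grid, "T_A") >= EXTINCTION_INTEGRAL
    surv_M = species_integral(final, grid, "T_M") >= EXTINCTION_INTEGRAL
    f_end = front_position(final, grid, "either")
    times_before = traj.times[traj.times <= t_end - 10.0]
    f_before = (
        front_position(traj.state_at(times_before[-1]), grid, "either")
        if times_before.size else None
    )
    halted = not (
        f_end is not None and f_before is not None and f_end - f_before >= HALT_DISPLACEMENT
    )
    if surv_A and surv_M:
        outcome = (
            "unstable_mixed_front"
            if classify_regime(c_MA, c_AM) == "bistable"
            else "mixed_invasion"
        )
    elif surv_M and not surv_A:
        outcome = "encapsulation"
    elif surv_A and not surv_M:
        outcome = "transient_invasion"
    else:
        outcome = "arrest"
    return SnapshotResult(c_MA, c_AM, traj, outcome, surv_A, surv_M, halted)


@dataclass(frozen=True)
class PerturbationSpec:
    """How to perturb the tumour initial data in the bistable regime."""

    amplitude: float = 1e-2
    mode: str = "multiplicative-noise"
    offset: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mode not in ("multiplicative-noise", "spatial-offset"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


@dataclass
class PerturbationOutcome:
    spec: PerturbationSpec
    unperturbed: Trajectory
    perturbed: Trajectory
    separated: bool
    front_unperturbed: float | None
    front_perturbed: float | None

    @property
    def halted_relative_to_unperturbed(self) -> bool:
        if self.front_unperturbed is None or self.front_perturbed is None:
            return False
        return self.front_perturbed < self.front_unperturbed - HALT_DISPLACEMENT


def _dominance_separated(state: StateFields, occupancy: float = EXTINCTION_INTEGRAL) -> bool:
    """True when occupied space splits into strongly T_A- and T_M-dominated zones."""
    tot = state.T_A + state.T_M
    occ = tot > occupancy
    if not np.any(occ):
        return False
    dom = (state.T_A[occ] - state.T_M[occ]) / tot[occ]
    return bool(dom.max() > 0.9 and dom.min() < -0.9)


def run_perturbation_experiment(
    c_MA: float = 1.7,
    c_AM: float = 1.7,
    spec: PerturbationSpec | None = None,
    t_end: float = 50.0,
    params: DimensionlessParams | None = None,
    grid: Grid1D | None = None,
    ics: InitialConditionSpec | None = None,
    settings: SolverSettings | None = None,
) -> PerturbationOutcome:
    """Probe the structural instability of the bistable mixed front.

    Runs an unperturbed and a perturbed variant under identical solver
    settings and reports whether the two phenotypes separate spatially
    (parapatry) and whether the perturbed front falls behind.
    """
    spec = spec or PerturbationSpec()
    params = (params or DimensionlessParams()).replace(c_MA=c_MA, c_AM=c_AM)
    grid = grid or Grid1D()
    ics = ics or InitialConditionSpec()
    settings = settings or SolverSettings(snapshot_times=(0.0, t_end / 2, t_end), **_SWEEP_TOLS)

    base = build_initial_state(grid, ics)
    if spec.mode == "multiplicative-noise":
        rng = np.random.default_rng(spec.seed)
        pert = base.copy()
        pert.T_A *= 1.0 + spec.amplitude * rng.uniform(-1.0, 1.0, grid.n_points)
        pert.T_M *= 1.0 + spec.amplitude * rng.uniform(-1.0, 1.0, grid.n_points)
        np.clip(pert.T_A, 0.0, None, out=pert.T_A)
        np.clip(pert.T_M, 0.0, None, out=pert.T_M)
    else:
        # spatial-offset: the populations start "slightly apart" in disjoint
        # adjacent regions — acid-producers in the core, degraders in the
        # rim, divided at sigma_tumour - offset. A plain translation of one
        # profile ends in competitive exclusion rather than separation; the
        # side-by-side seeding is what produces persistent parapatry.
        split = ics.sigma_tumour - spec.offset
        pert = base.copy()
        pert.T_A = base.T_A * (grid.x <= split)
        pert.T_M = base.T_M * (grid.x > split)

    unpert_traj = integrate(base, params, grid, settings)
    pert_traj = integrate(pert, params, grid, settings)
    final = pert_traj.states[-1]
    return PerturbationOutcome(
        spec=spec,
        unperturbed=unpert_traj,
        perturbed=pert_traj,
        separated=_dominance_separated(final),
        front_unperturbed=front_position(unpert_traj.states[-1], grid, "either"),
        front_perturbed=front_position(final, grid, "either"),
    )


@dataclass
class KappaSweepResult:
    kappa: float
    records: list
    asymmetry: float


def front_asymmetry(records: list[SweepRecord]) -> float:
    """Mean signed front difference between mirrored sub-unit pairs.

    Averages front(c_MA=a, c_AM=b) - front(c_MA=b, c_AM=a) over all pairs
    with a < b < 1; a nonzero value means invasion depends on *which*
    phenotype is the stronger competitor, an asymmetry introduced by the
    finite matrix-degradation rate.
    """
    table = {(round(r.c_MA, 12), round(r.c_AM, 12)): r for r in records}
    diffs = []
    for (a, b), r in table.items():
        if a < b < 1.0:
            mirror = table.get((b, a))
            if mirror and r.front_either is not None and mirror.front_either is not None:
                diffs.append(r.front_either - mirror.front_either)
    return float(np.mean(diffs)) if diffs else np.nan


def run_kappa_sensitivity(
    kappas=(5.0, 10.0, 20.0),
    c_values=np.linspace(0.0, 2.0, 5),
    t_end: float = 50.0,
    params: DimensionlessParams | None = None,
    **sweep_kwargs,
) -> list[KappaSweepResult]:
    """Repeat the competition sweep for several matrix-degradation rates."""
    if np.any(np.asarray(kappas, dtype=float) < 0):
        raise InvalidExperimentError("kappa values must be >= 0")
    params = params or DimensionlessParams()
    out = []
    for k in kappas:
        recs = run_competition_sweep(
            c_values, t_end=t_end, params=params.replace(kappa=float(k)), **sweep_kwargs
        )
        out.append(KappaSweepResult(float(k), recs, front_asymmetry(recs)))
    return out
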