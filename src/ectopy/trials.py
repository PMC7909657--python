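"""Monte-Carlo repolarization-failure trials and wavefront scenarios.

The core protocol probes a heterogeneous sheet (typically 40 x 40 with a
central annulus and periodic edges) for abnormal repolarization: a brief
spatially-uniform stimulus (I = 2 for 15 ms) excites every cell, and any
cell still depolarized (V > 0) at 1000 ms post-onset has *failed to
repolarize*.  Repeating the trial over independently drawn b-fields yields
per-cell failure frequencies, which are summarized separately for cells on
the tissue boundary (4-adjacent to the annulus) and in the midfield.
Normalizing an observed rate by the density of intrinsically abnormal cells
gives the adjusted failure rate of the abnormal cells themselves.

``wavefront_scenario`` runs the narrative experiments instead: a planar wave
is launched from the left edge and the run is classified by whether any
activity persists to the end of the simulation (sustained ectopy) and which
cells failed first after the wave passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .cell import CellParams
from .heterogeneity import AnnulusGeometry, AnnulusSpec, BFieldSpec, build_annulus, default_annulus
from .medium import (
    FieldState,
    IntegrationDivergedError,
    MediumConfig,
    StimulusProtocol,
    detect_failures,
    integrate,
)

__all__ = [
    "TrialProtocol",
    "TrialSummary",
    "ScenarioResult",
    "run_trials",
    "radial_profile",
    "adjusted_rates",
    "wavefront_scenario",
]


@dataclass(frozen=True)
class TrialProtocol:
    """Specification of one Monte-Carlo repolarization-failure experiment."""

    shape: tuple[int, int] = (40, 40)
    annulus: AnnulusSpec | None = field(default_factory=default_annulus)
    bc: str = "periodic"
    b_spec: BFieldSpec = field(default_factory=BFieldSpec)
    c: float = 0.3
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    t_eval: float = 1000.0
    threshold: float = 0.0
    n_trials: int = 300
    seed: int = 0
    dt: float = 0.1
    cell: CellParams = field(default_factory=CellParams)

    def __post_init__(self) -> None:
        if self.t_eval < self.stimulus.onset + self.stimulus.duration:
            raise ValueError("evaluation time must not precede the stimulus end")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


@dataclass
class TrialSummary:
    """Aggregated failure statistics over all trials (percent units).

    ``boundary_rate``/``midfield_rate`` are means of the per-trial failure
    fractions over boundary/midfield cells; the quoted SE is the standard
    error of those per-trial fractions across trials.  ``*_se_binomial`` is
    the pooled binomial standard error, reported alongside because the two
    estimators differ when failures are spatially correlated within a trial.
    """

    failure_pct: np.ndarray
    n_trials: int
    n_diverged: int
    boundary_rate: float
    boundary_se: float
    midfield_rate: float
    midfield_se: float
    boundary_se_binomial: float
    midfield_se_binomial: float
    per_trial_boundary: np.ndarray
    per_trial_midfield: np.ndarray
    geometry: AnnulusGeometry | None
    protocol: TrialProtocol | None = None


def _rate_and_se(per_trial: np.ndarray) -> tuple[float, float]:
    rate = 100.0 * float(np.mean(per_trial))
    if len(per_trial) > 1:
        se = 100.0 * float(np.std(per_trial, ddof=1) / np.sqrt(len(per_trial)))
    else:
        se = np.nan
    return rate, se


def run_trials(protocol: TrialProtocol, progress: bool = False) -> TrialSummary:
    """Run the seeded Monte-Carlo protocol and aggregate failure statistics.

    Each trial draws an independent b-field (child seed of ``protocol.seed``)
    over fixed geometry, integrates from rest through the stimulus to the
    evaluation time, and scores per-cell failures (V > threshold).  Trials
    whose integration diverges are excluded and counted in ``n_diverged``.
    """
    geo = build_annulus(protocol.shape, protocol.annulus, protocol.bc) if protocol.annulus else None
    tissue = geo.tissue if geo is not None else np.ones(protocol.shape, dtype=bool)
    counts = np.zeros(protocol.shape)
    boundary_fracs, midfield_fracs = [], []
    n_diverged = 0
    children = np.random.SeedSequence(protocol.seed).spawn(protocol.n_trials)
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        b = protocol.b_spec.sample(protocol.shape, rng)
        cfg = MediumConfig(b_field=b, c=protocol.c, bc=protocol.bc,
                           cell=protocol.cell, annulus=geo)
        state = FieldState(np.full(protocol.shape, -1.25), np.zeros(protocol.shape), 0.0)
        try:
            final, _ = integrate(state, cfg, protocol.stimulus, protocol.t_eval, dt=protocol.dt)
        except IntegrationDivergedError:
            n_diverged += 1
            continue
        fail = detect_failures(final, cfg, protocol.threshold)
        counts += fail
        if geo is not None:
            boundary_fracs.append(fail[geo.boundary].mean())
            midfield_fracs.append(fail[geo.midfield].mean())
        else:
            boundary_fracs.append(np.nan)
            midfield_fracs.append(fail[tissue].mean())
    if n_diverged:
        warnings.warn(f"{n_diverged} of {protocol.n_trials} trials diverged and were excluded")
    n_ok = protocol.n_trials - n_diverged
    failure_pct = np.where(tissue, 100.0 * counts / max(n_ok, 1), np.nan)
    b_arr = np.asarray(boundary_fracs)
    m_arr = np.asarray(midfield_fracs)
    b_rate, b_se = _rate_and_se(b_arr)
    m_rate, m_se = _rate_and_se(m_arr)

    def binom_se(rate_pct, n_cells):
        p = rate_pct / 100.0
        return 100.0 * np.sqrt(p * (1 - p) / max(n_cells * n_ok, 1))

    nb = int(geo.boundary.sum()) if geo is not None else 0
    nm = int(geo.midfield.sum()) if geo is not None else int(tissue.sum())
    return TrialSummary(
        failure_pct=failure_pct,
        n_trials=n_ok,
        n_diverged=n_diverged,
        boundary_rate=b_rate,
        boundary_se=b_se,
        midfield_rate=m_rate,
        midfield_se=m_se,
        boundary_se_binomial=binom_se(b_rate, nb) if nb else np.nan,
        midfield_se_binomial=binom_se(m_rate, nm),
        per_trial_boundary=b_arr,
        per_trial_midfield=m_arr,
        geometry=geo,
        protocol=protocol,
    )


def radial_profile(summary: TrialSummary, bin_width: float = 1.0) -> pd.DataFrame:
    """Mean failure percentage binned by rounded distance from the annulus center.

    Annulus (absent) cells are excluded.  Returns a DataFrame with columns
    ``radius`` (bin center), ``mean_pct`` and ``n_cells``.
    """
    geo = summary.geometry
    if geo is None:
        raise ValueError("radial profile requires an annulus geometry")
    dist = geo.distance()
    tissue = geo.tissue
    bins = np.round(dist[tissue] / bin_width).astype(int)
    vals = summary.failure_pct[tissue]
    df = pd.DataFrame({"bin": bins, "pct": vals})
    g = df.groupby("bin")["pct"]
    return pd.DataFrame(
        {
            "radius": g.mean().index * bin_width,
            "mean_pct": g.mean().to_numpy(),
            "n_cells": g.size().to_numpy(),
        }
    ).reset_index(drop=True)


def adjusted_rates(observed_pct: float, bistable_density: float) -> float:
    """Failure rate of the abnormal cells themselves: observed % / density."""
    if not 0.0 < bistable_density <= 1.0:
        raise ValueError("bistable density must lie in (0, 1]")
    return observed_pct / bistable_density


# ---------------------------------------------------------------------------
# narrative wavefront scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Outcome of a single traveling-wave run.

    ``outcome`` is ``"sustained ectopy"`` if any tissue cell is depolarized
    at the end of the run, else ``"normal propagation"``.  ``genesis_mask``
    marks the first cells that failed to repolarize: the earliest cells to
    stay continuously depolarized for longer than the persistence horizon
    (several times the normal action-potential duration, so no healthy cell
    can qualify); ``genesis_time`` is when they reached that horizon.
    """

    outcome: str
    times: np.ndarray
    depolarized_counts: np.ndarray
    genesis_mask: np.ndarray | None
    genesis_time: float | None
    final_state: FieldState
    snapshots: list[FieldState]
    cfg: MediumConfig
    streak_start: np.ndarray | None = None  # onset time of the streak active at t_end
    permanent_mask: np.ndarray | None = None  # depolarized through t_end for >= horizon
    first_permanent_mask: np.ndarray | None = None  # earliest-onset permanent sources
    first_permanent_time: float | None = None


def wavefront_scenario(
    cfg: MediumConfig,
    stim: StimulusProtocol | None = None,
    t_end: float = 6000.0,
    dt: float = 0.1,
    sample_every: float = 10.0,
    threshold: float = 0.0,
    persist_horizon: float = 700.0,
    snapshot_times=None,
) -> ScenarioResult:
    """Launch a planar wave from the left edge and classify the outcome.

    The sheet is sampled every ``sample_every`` ms.  A cell counts as a
    persistent failure once it has stayed above ``threshold`` continuously
    for ``persist_horizon`` ms (default 700 ms, about four times the
    homogeneous action-potential duration, so an ordinary excursion cannot
    qualify).  The first cells to do so form the genesis set.
    """
    if stim is None:
        stim = StimulusProtocol(amplitude=2.0, onset=0.0, duration=15.0, support="left")
    wanted = sorted(set(float(t) for t in (snapshot_times or [])))
    tissue = cfg.tissue
    state = FieldState(np.full(cfg.shape, -1.25), np.zeros(cfg.shape), 0.0)
    n_need = max(1, int(round(persist_horizon / sample_every)))
    streak = np.zeros(cfg.shape, dtype=np.int64)
    streak_start = np.full(cfg.shape, np.nan)
    times, counts, keep = [], [], []
    genesis_mask = None
    genesis_time = None
    t = 0.0
    while t < t_end - 1e-9:
        t_next = min(t + sample_every, t_end)
        hit = [w for w in wanted if t < w <= t_next]
        state, snaps = integrate(state, cfg, stim, t_next, dt=dt, snapshot_times=hit)
        keep.extend(snaps)
        t = state.t
        dep = (state.V > threshold) & tissue
        fresh = dep & (streak == 0)
        streak_start = np.where(fresh, t, np.where(dep, streak_start, np.nan))
        streak = np.where(dep, streak + 1, 0)
        times.append(t)
        counts.append(int(dep.sum()))
        if genesis_mask is None and (streak >= n_need).any():
            genesis_mask = streak >= n_need
            genesis_time = t
    outcome = "sustained ectopy" if ((state.V > threshold) & tissue).any() else "normal propagation"
    # permanent sources: still inside a streak at t_end that has lasted the horizon
    permanent = (streak * sample_every) >= persist_horizon
    first_mask = None
    first_time = None
    if permanent.any():
        first_time = float(np.nanmin(np.where(permanent, streak_start, np.nan)))
        first_mask = permanent & (streak_start <= first_time + sample_every / 2)
    return ScenarioResult(outcome, np.asarray(times), np.asarray(counts),
                          genesis_mask, genesis_time, state, keep, cfg,
                          streak_start=streak_start, permanent_mask=permanent,
                          first_permanent_mask=first_mask, first_permanent_time=first_time)
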