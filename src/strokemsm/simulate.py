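"""Synthetic two-arm stroke trials with ground-truth Markov trajectories.

Subjects follow a continuous-time Markov chain on the mRS states (death
absorbing, reachable only from severe states in the default structure);
treatment multiplies chosen transition intensities by exp(log HR).  Visits
happen at jittered nominal days and record the latent state at that time;
a death between visits is recorded at its exact simulated day.  Baseline
covariates (NIHSS total and items, age, glucose, onset-to-randomization
time, early CT score) are drawn correlated with the initial state through a
shared latent severity factor.

Every subject gets an independent deterministic random substream derived
from (seed, arm, subject index), so enlarging the trial does not perturb
already-simulated subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import StateSpace, TrialPanel

_ARM_CODE = {"control": 0, "treatment": 1}


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distribution of one baseline covariate and its loading on
    the latent severity factor (correlation sign follows the loading)."""

    name: str
    mean: float
    sd: float
    loading: float = 0.0
    lo: float | None = None
    hi: float | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [-1, 1]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def default_covariate_models() -> tuple[CovariateModel, ...]:
    """Plausible NINDS-scale baseline covariates (a stand-in model: the
    marginals and loadings are configuration, not estimates)."""
    return (
        CovariateModel("nihss_total", 14.0, 6.0, 0.80, 0, 42, integer=True),
        CovariateModel("age", 67.0, 12.0, 0.25, 25, 100),
        CovariateModel("glucose", 150.0, 60.0, 0.15, 50, 500),
        CovariateModel("onset_to_rand_minutes", 110.0, 40.0, 0.0, 20, 180),
        CovariateModel("early_ct_score", 8.0, 2.0, -0.35, 0, 10, integer=True),
    )


def default_intensities() -> tuple[dict[tuple[int, int], float], ...]:
    """Baseline intensities per epoch (per day) for the reduced structure.

    The acute epoch (first 90 days) carries most of the recovery; the
    chronic epoch scales every rate down.  Values are chosen to give
    realistic 90-day outcome spreads at NINDS scale, not estimated from any
    dataset.
    """
    acute: dict[tuple[int, int], float] = {}
    for r in range(1, 6):
        acute[(r, r - 1)] = 0.020          # recovery
    for r in range(0, 5):
        acute[(r, r + 1)] = 0.006          # worsening
    acute[(4, 6)] = 0.004                  # death from severe disability
    acute[(5, 6)] = 0.012
    chronic = {k: 0.15 * v for k, v in acute.items()}
    return (acute, chronic)


@dataclass(frozen=True)
class SimulationSpec:
    """Stated world of the synthetic trial (defaults mimic NINDS scale)."""

    n_per_arm: int = 310
    state_space: StateSpace = field(default_factory=StateSpace.reduced)
    intensities: tuple[Mapping[tuple[int, int], float], ...] = \
        field(default_factory=default_intensities)
    breakpoints: tuple[float, ...] = (90.0,)
    #: either one map (r, s) -> log HR applied in every epoch, or a tuple
    #: of per-epoch maps (e.g. an effect confined to the acute phase)
    treatment_log_hr: Mapping[tuple[int, int], float] | \
        tuple[Mapping[tuple[int, int], float], ...] = \
        field(default_factory=dict)
    initial_state_dist: tuple[float, ...] = (0.0, 0.02, 0.08, 0.20, 0.35, 0.35)
    visit_days: tuple[float, ...] = (8.5, 90.0, 180.0, 360.0)
    jitter_days: tuple[float, ...] = (1.5, 10.0, 10.0, 10.0)
    dropout_rate: float = 0.0
    monotone_dropout: bool = False
    covariate_models: tuple[CovariateModel, ...] = \
        field(default_factory=default_covariate_models)
    nihss_item_weights: tuple[float, ...] = (0.40, 0.25, 0.15, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if len(self.intensities) != len(self.breakpoints) + 1:
            raise ValueError("need one intensity map per epoch")
        if abs(sum(self.initial_state_dist) - 1.0) > 1e-9:
            raise ValueError("initial_state_dist must sum to 1")
        if any(j < 0 for j in self.jitter_days):
            raise ValueError("jitter must be non-negative")
        if len(self.jitter_days) != len(self.visit_days):
            raise ValueError("one jitter half-width per visit")
        allowed = self.state_space.allowed
        for hr_map in self._log_hr_by_epoch():
            bad = set(hr_map) - set(allowed)
            if bad:
                raise ValueError(f"treatment_log_hr on disallowed "
                                 f"transitions: {sorted(bad)}")
        for ints in self.intensities:
            bad = set(ints) - set(allowed)
            if bad:
                raise ValueError(f"intensities on disallowed transitions: "
                                 f"{sorted(bad)}")

    def _log_hr_by_epoch(self) -> tuple[Mapping[tuple[int, int], float], ...]:
        if isinstance(self.treatment_log_hr, (tuple, list)):
            if len(self.treatment_log_hr) != len(self.intensities):
                raise ValueError("need one treatment_log_hr map per epoch")
            return tuple(self.treatment_log_hr)
        return tuple(self.treatment_log_hr
                     for _ in range(len(self.intensities)))

    def Q_matrices(self, arm: str) -> list[np.ndarray]:
        """Generator per epoch for one arm (treatment scales intensities)."""
        idx = {s: i for i, s in enumerate(self.state_space.states)}
        n = self.state_space.n_states
        out = []
        for ints, hr_map in zip(self.intensities, self._log_hr_by_epoch()):
            Q = np.zeros((n, n))
            for (r, s), rate in ints.items():
                q = float(rate)
                if arm == "treatment" and (r, s) in hr_map:
                    q *= math.exp(hr_map[(r, s)])
                Q[idx[r], idx[s]] = q
            np.fill_diagonal(Q, -Q.sum(axis=1))
            out.append(Q)
        return out


@dataclass
class SimulatedTrial:
    """Generated panel plus the latent ground truth behind it."""

    panel: TrialPanel
    spec: SimulationSpec
    trajectories: dict[str, dict]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sid, tr in self.trajectories.items():
            for t, s in zip(tr["jump_times"], tr["states"]):
                rows.append({"subject_id": sid, "time_days": t, "state": s})
        return pd.DataFrame(rows)


def _subject_rng(seed: int, arm: str, i: int, stream: int = 0
                 ) -> np.random.Generator:
    key = (_ARM_CODE[arm], i, stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


def simulate_trajectory(Q_by_epoch: Sequence[np.ndarray],
                        breakpoints: Sequence[float],
                        initial_state: int, horizon_days: float,
                        rng: np.random.Generator,
                        states: Sequence[int] | None = None,
                        ) -> tuple[list[float], list[int]]:
    """Sample one continuous-time path by competing exponential clocks.

    Holding time in state r is Exponential(total exit rate); the next state
    is drawn proportional to the exit intensities.  A clock that would cross
    an epoch breakpoint is truncated there and redrawn under the new
    generator (valid by memorylessness).  A zero exit rate leaves the path
    constant until the next breakpoint or the horizon.
    """
    breakpoints = list(breakpoints)
    if len(Q_by_epoch) != len(breakpoints) + 1:
        raise ValueError("need one generator per epoch")
    states = list(states) if states is not None \
        else list(range(Q_by_epoch[0].shape[0]))
    idx = {s: i for i, s in enumerate(states)}
    t, s = 0.0, initial_state
    times, path = [0.0], [initial_state]
    while t < horizon_days:
        e = int(np.searchsorted(breakpoints, t, side="right"))
        next_bp = breakpoints[e] if e < len(breakpoints) else math.inf
        row = Q_by_epoch[e][idx[s]].copy()
        row[idx[s]] = 0.0
        total = row.sum()
        if total <= 0.0:
            if math.isinf(next_bp):
                break
            t = next_bp
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= min(next_bp, horizon_days):
            t = min(next_bp, horizon_days)
            continue
        t += dt
        s = states[int(rng.choice(len(states), p=row / total))]
        times.append(t)
        path.append(s)
    return times, path


def _state_at(times: list[float], path: list[int], t: float) -> int:
    j = int(np.searchsorted(times, t, side="right")) - 1
    return path[max(j, 0)]


def simulate_baseline_covariates(spec: SimulationSpec,
                                 initial_states: Sequence[int],
                                 rng: np.random.Generator | None = None,
                                 rngs: Sequence[np.random.Generator] | None = None,
                                 ) -> pd.DataFrame:
    """Draw baseline covariates correlated with initial state.

    The shared latent severity factor is the initial state standardized by
    the *theoretical* moments of the initial distribution (so draws for one
    subject never depend on who else is in the trial); each covariate is
    mean + sd * (loading * severity + sqrt(1 - loading^2) * noise).
    """
    init = np.asarray(initial_states)
    dist = np.asarray(spec.initial_state_dist)
    support = np.arange(len(dist))
    mu = float(dist @ support)
    var = float(dist @ (support - mu) ** 2)
    sd = math.sqrt(var) if var > 0 else 1.0
    z = (init - mu) / sd
    n = len(init)
    if rngs is None:
        base = rng or np.random.default_rng(spec.seed)
        rngs = [base] * n
    cols: dict[str, np.ndarray] = {}
    for cm in spec.covariate_models:
        vals = np.empty(n)
        resid = math.sqrt(max(1.0 - cm.loading ** 2, 0.0))
        for i in range(n):
            eps = rngs[i].standard_normal()
            vals[i] = cm.mean + cm.sd * (cm.loading * z[i] + resid * eps)
        if cm.lo is not None or cm.hi is not None:
            vals = np.clip(vals, cm.lo, cm.hi)
        if cm.integer:
            vals = np.rint(vals)
        cols[cm.name] = vals
    # split the NIHSS total into item scores (shares plus rounding noise)
    if "nihss_total" in cols and spec.nihss_item_weights:
        total = cols["nihss_total"]
        for j, w in enumerate(spec.nihss_item_weights):
            item = np.empty(n)
            for i in range(n):
                item[i] = max(round(w * total[i] + rngs[i].standard_normal()), 0)
            cols[f"nihss_item{j + 1}"] = item
    return pd.DataFrame(cols)


def simulate_trial(spec: SimulationSpec) -> SimulatedTrial:
    """Generate a full two-arm trial panel with latent ground truth."""
    horizon = max(spec.visit_days) + max(spec.jitter_days)
    records = []
    trajectories: dict[str, dict] = {}
    order: list[tuple[str, str, int]] = []
    init_states: list[int] = []
    for arm in ("control", "treatment"):
        Qs = spec.Q_matrices(arm)
        transient = [s for s in spec.state_space.states
                     if s not in spec.state_space.absorbing]
        for i in range(spec.n_per_arm):
            sid = f"{arm[0]}{i:04d}"
            rng = _subject_rng(spec.seed, arm, i)
            init = int(rng.choice(transient[:len(spec.initial_state_dist)],
                                  p=spec.initial_state_dist))
            times, path = simulate_trajectory(
                Qs, spec.breakpoints, init, horizon, rng,
                states=list(spec.state_space.states))
            visits = sorted(
                float(v + rng.uniform(-j, j))
                for v, j in zip(spec.visit_days, spec.jitter_days))
            observe = [rng.uniform() >= spec.dropout_rate for _ in visits]
            if spec.monotone_dropout and not all(observe):
                first_miss = observe.index(False)
                observe = observe[:first_miss] + \
                    [False] * (len(visits) - first_miss)
            death_time = None
            for t, s in zip(times, path):
                if s in spec.state_space.absorbing:
                    death_time = t
                    break
            dead_recorded = False
            for visit, keep in zip(visits, observe):
                if death_time is not None and visit >= death_time:
                    if not dead_recorded:
                        records.append({"subject_id": sid, "arm": arm,
                                        "time_days": death_time,
                                        "state": path[-1],
                                        "death_exact": True})
                        dead_recorded = True
                    continue
                if not keep:
                    continue
                records.append({"subject_id": sid, "arm": arm,
                                "time_days": visit,
                                "state": _state_at(times, path, visit),
                                "death_exact": False})
            trajectories[sid] = {"jump_times": times, "states": path,
                                 "initial_state": init, "arm": arm}
            order.append((sid, arm, i))
            init_states.append(init)
    cov_rngs = [_subject_rng(spec.seed, arm, i, stream=1)
                for (_, arm, i) in order]
    baseline = simulate_baseline_covariates(spec, init_states, rngs=cov_rngs)
    baseline.index = pd.Index([sid for sid, _, _ in order], name="subject_id")
    data = pd.DataFrame(records,
                        columns=["subject_id", "arm", "time_days", "state",
                                 "death_exact"])
    panel = TrialPanel(data, baseline=baseline, state_space=spec.state_space)
    return SimulatedTrial(panel=panel, spec=spec, trajectories=trajectories)
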