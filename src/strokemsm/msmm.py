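"""Continuous-time multistate Markov models for panel-observed ordinal data.

The disease process is a continuous-time Markov chain on the mRS states:
a generator matrix Q holds transition intensities q_rs (instantaneous risk
of moving from state r to state s), covariates act multiplicatively on the
intensities (per-transition hazard ratios exp(beta)), and intensities may be
piecewise-constant across epochs separated by breakpoints.  Panel data —
the chain observed only at visit times — contribute likelihood terms
P_{y_j, y_{j+1}}(t_{j+1} - t_j) with P(t) = expm(Q t); an interval that
crosses a breakpoint uses the ordered product of epoch-wise probability
matrices.  Death times are typically known exactly in trials, so by default
a transition into the absorbing state contributes the density
sum_k P_{y_j,k}(dt) q_{k,death} instead of a panel term.

The public surface follows the statsmodels convention:
``MultistateMarkovModel(panel, spec).fit()`` returns :class:`MsmmResults`
with parameter estimates, observed-information standard errors, a
per-transition hazard-ratio table and a text summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .panel import StateSpace, TrialPanel

logger = logging.getLogger("strokemsm")

_TINY = 1e-300
_LOGQ_FLOOR = -16.0


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best iterate and gradient norm."""

    def __init__(self, message: str, best_params: np.ndarray,
                 grad_norm: float) -> None:
        super().__init__(message)
        self.best_params = best_params
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# Specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsmmSpec:
    """Model structure: state space, covariate placement, epochs, pins.

    Parameters
    ----------
    state_space : allowed transitions and absorbing states.
    covariates : ordered covariate names.  ``"treatment"`` is synthesized
        from the panel's arm column (1 = treatment); any other name is
        looked up in the panel's baseline table.
    effect_map : mapping (r, s) -> tuple of covariate names carried by that
        transition, or ``"all"`` to put every covariate on every free
        transition (the global-treatment layout).
    breakpoints : strictly increasing times splitting follow-up into epochs
        of constant intensities; empty for a time-homogeneous model.
    death_mode : ``"exact"`` treats the time of entry into the absorbing
        state as known exactly (the trial convention); ``"panel"`` treats it
        as a panel observation like any other.
    observation : ``"panel"`` (the default; states seen only at visit
        times) or ``"exact"`` for completely observed processes where every
        record is an exact transition time — the complete-data likelihood
        whose MLE is the count/exposure closed form.
    pinned : transitions forced to intensity zero (removed from the
        parameter vector), mirroring the "set small intensities to zero"
        model-reduction workflow.
    """

    state_space: StateSpace = field(default_factory=StateSpace.reduced)
    covariates: tuple[str, ...] = ()
    effect_map: object = "all"
    breakpoints: tuple[float, ...] = ()
    death_mode: str = "exact"
    pinned: frozenset[tuple[int, int]] = frozenset()
    observation: str = "panel"

    def __post_init__(self) -> None:
        if self.death_mode not in ("exact", "panel"):
            raise ValueError("death_mode must be 'exact' or 'panel'")
        if self.observation not in ("panel", "exact"):
            raise ValueError("observation must be 'panel' or 'exact'")
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "pinned", frozenset(self.pinned))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.pinned <= self.state_space.allowed:
            raise ValueError("pinned transitions must be allowed transitions")
        if isinstance(self.effect_map, Mapping):
            em = {tuple(k): tuple(v) for k, v in self.effect_map.items()}
            bad = set(em) - set(self.state_space.allowed)
            if bad:
                raise ValueError(f"effect_map transitions not allowed: {bad}")
            for trans, names in em.items():
                unknown = set(names) - set(self.covariates)
                if unknown:
                    raise ValueError(f"effect_map names not in covariates: "
                                     f"{unknown}")
            object.__setattr__(self, "effect_map", em)

    # -- parameter layout ---------------------------------------------------
    @property
    def free_transitions(self) -> tuple[tuple[int, int], ...]:
        return tuple(t for t in self.state_space.sorted_transitions()
                     if t not in self.pinned)

    @property
    def n_epochs(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def beta_index(self) -> tuple[tuple[tuple[int, int], str], ...]:
        """Ordered ((r, s), covariate) pairs carrying a coefficient."""
        out = []
        for trans in self.free_transitions:
            if self.effect_map == "all":
                names = self.covariates
            else:
                names = self.effect_map.get(trans, ())
            for name in names:
                out.append((trans, name))
        return tuple(out)

    @property
    def n_params(self) -> int:
        return self.n_epochs * len(self.free_transitions) + len(self.beta_index)

    def epoch_of(self, t: float) -> int:
        return int(np.searchsorted(self.breakpoints, t, side="right"))


@dataclass
class MsmmParams:
    """Parameter container: per-epoch log baseline intensities and betas.

    ``log_q`` has shape (n_epochs, n_free_transitions) in the order of
    :attr:`MsmmSpec.free_transitions`; ``beta`` aligns with
    :attr:`MsmmSpec.beta_index`.  Hazard ratio = exp(beta).
    """

    log_q: np.ndarray
    beta: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.log_q, float).ravel(),
                               np.asarray(self.beta, float).ravel()])

    @classmethod
    def unpack(cls, vec: np.ndarray, spec: MsmmSpec) -> "MsmmParams":
        vec = np.asarray(vec, float)
        if vec.size != spec.n_params:
            raise ValueError(f"expected {spec.n_params} parameters, "
                             f"got {vec.size}")
        nq = spec.n_epochs * len(spec.free_transitions)
        return cls(log_q=vec[:nq].reshape(spec.n_epochs,
                                          len(spec.free_transitions)),
                   beta=vec[nq:].copy())


# ---------------------------------------------------------------------------
# Generator construction and transition probabilities
# ---------------------------------------------------------------------------

def build_Q(params: MsmmParams, spec: MsmmSpec,
            covariate_values: Mapping[str, float] | None = None,
            epoch: int = 0) -> np.ndarray:
    """Assemble the generator Q for one epoch and covariate setting.

    q_rs = exp(log_q_rs^(epoch)) * exp(sum_c beta_{rs,c} x_c) for allowed,
    non-pinned (r, s); the diagonal completes each row sum to zero; pinned
    and disallowed entries are exactly zero.
    """
    covariate_values = covariate_values or {}
    for name in spec.covariates:
        if name not in covariate_values:
            raise ValueError(f"missing covariate value for {name!r}")
    n = spec.state_space.n_states
    idx = {s: i for i, s in enumerate(spec.state_space.states)}
    Q = np.zeros((n, n))
    beta_lookup: dict[tuple[int, int], float] = {}
    for (trans, name), b in zip(spec.beta_index, np.atleast_1d(params.beta)):
        beta_lookup[trans] = beta_lookup.get(trans, 0.0) + b * covariate_values[name]
    log_q = np.atleast_2d(params.log_q)
    for j, (r, s) in enumerate(spec.free_transitions):
        Q[idx[r], idx[s]] = np.exp(log_q[epoch, j] + beta_lookup.get((r, s), 0.0))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = expm(Q dt): the interval transition-probability matrix."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    Q = np.asarray(Q, float)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("generator rows must sum to zero")
    if (Q - np.diag(np.diag(Q)) < -1e-12).any():
        raise ValueError("off-diagonal intensities must be non-negative")
    P = linalg.expm(Q * dt)
    np.clip(P, 0.0, 1.0, out=P)
    return P


# -- fast batched probabilities via eigendecomposition ----------------------

class _EigQ:
    """Cached eigendecomposition of one generator for batched expm(Q t).

    A generator without repeated defective eigenvalues satisfies
    expm(Qt) = U diag(exp(lambda t)) U^{-1}; a single decomposition then
    serves every interval length at once.  Falls back to scipy's expm per
    interval when U is ill-conditioned.
    """

    def __init__(self, Q: np.ndarray) -> None:
        self.Q = Q
        lam, U = np.linalg.eig(Q)
        ok = np.isfinite(U).all()
        cond = np.linalg.cond(U) if ok else np.inf
        if ok and cond < 1e8:
            self.lam, self.U, self.V = lam, U, np.linalg.inv(U)
            self.diagonalizable = True
        else:
            self.diagonalizable = False

    def P_batch(self, dts: np.ndarray) -> np.ndarray:
        dts = np.asarray(dts, float)
        if self.diagonalizable:
            E = np.exp(np.multiply.outer(dts, self.lam))
            P = np.einsum("ik,nk,kj->nij", self.U, E, self.V).real
        else:
            P = np.stack([linalg.expm(self.Q * t) for t in dts])
        np.clip(P, 0.0, None, out=P)
        return P


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class MultistateMarkovModel:
    """Panel-data multistate Markov model bound to one trial panel.

    Construction precomputes the interval structure (subject observation
    pairs split at epoch breakpoints and grouped by covariate pattern), so
    that each likelihood evaluation needs only one eigendecomposition per
    (covariate pattern, epoch) and batched matrix products over intervals.
    """

    def __init__(self, panel: TrialPanel, spec: MsmmSpec) -> None:
        self.panel = panel
        self.spec = spec
        self._idx = {s: i for i, s in enumerate(spec.state_space.states)}
        if len(spec.state_space.absorbing) > 1 and spec.death_mode == "exact":
            raise ValueError("exact death mode supports one absorbing state")
        self._death_i = (self._idx[next(iter(spec.state_space.absorbing))]
                         if spec.state_space.absorbing else None)
        self._build_design()
        self._build_intervals()

    # -- design -------------------------------------------------------------
    def _build_design(self) -> None:
        spec, panel = self.spec, self.panel
        arm = panel.arm_of()
        subjects = list(arm.index)
        X = np.zeros((len(subjects), len(spec.covariates)))
        for j, name in enumerate(spec.covariates):
            if name == "treatment":
                X[:, j] = (arm == "treatment").to_numpy(float)
            else:
                if panel.baseline is None or name not in panel.baseline.columns:
                    raise ValueError(f"missing covariate {name!r} in baseline "
                                     "table")
                vals = panel.baseline[name].reindex(subjects)
                if vals.isna().any():
                    missing = vals.index[vals.isna()].tolist()
                    raise ValueError(f"missing covariate {name!r} for "
                                     f"subjects {missing[:5]}")
                X[:, j] = vals.to_numpy(float)
        self._subjects = subjects
        patterns, inverse = (np.unique(X, axis=0, return_inverse=True)
                             if len(spec.covariates) else
                             (np.zeros((1, 0)), np.zeros(len(subjects), int)))
        self._patterns = patterns
        self._pattern_of = {sid: int(g) for sid, g in zip(subjects, inverse)}

    def _segments(self, t0: float, t1: float) -> tuple[tuple[int, ...],
                                                       tuple[float, ...]]:
        """Split [t0, t1] at epoch breakpoints into (epochs, durations)."""
        cuts = [b for b in self.spec.breakpoints if t0 < b < t1]
        edges = [t0] + cuts + [t1]
        epochs, dts = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            epochs.append(self.spec.epoch_of(a))
            dts.append(b - a)
        return tuple(epochs), tuple(dts)

    def _build_intervals(self) -> None:
        spec = self.spec
        absorbing = {self._idx[s] for s in spec.state_space.absorbing}
        groups: dict[tuple, list] = {}
        data = self.panel.data
        for sid, grp in data.groupby("subject_id", sort=False):
            g = self._pattern_of[sid]
            t = grp["time_days"].to_numpy(float)
            y = np.array([self._idx[s] for s in grp["state"]])
            for j in range(len(t) - 1):
                dt = t[j + 1] - t[j]
                if dt <= 0:
                    raise ValueError(f"non-positive interval for subject "
                                     f"{sid!r}")
                is_death = (y[j + 1] in absorbing
                            and spec.death_mode == "exact")
                epochs, dts = self._segments(t[j], t[j + 1])
                key = (g, epochs, is_death)
                groups.setdefault(key, []).append((dts, y[j], y[j + 1]))
        self._groups = []
        for (g, epochs, is_death), rows in groups.items():
            dts = np.array([r[0] for r in rows])
            y0 = np.array([r[1] for r in rows])
            y1 = np.array([r[2] for r in rows])
            self._groups.append((g, epochs, is_death, dts, y0, y1))
        self.n_intervals = sum(len(r[3]) for r in self._groups)

    # -- likelihood ---------------------------------------------------------
    def _Q_for(self, params: MsmmParams, g: int, epoch: int) -> np.ndarray:
        cov = dict(zip(self.spec.covariates, self._patterns[g]))
        return build_Q(params, self.spec, cov, epoch)

    def loglik(self, params: np.ndarray | MsmmParams) -> float:
        """Panel log-likelihood at `params` (flat vector or MsmmParams)."""
        if not isinstance(params, MsmmParams):
            params = MsmmParams.unpack(params, self.spec)
        cache: dict[tuple[int, int], _EigQ] = {}

        def eig(g: int, e: int) -> _EigQ:
            if (g, e) not in cache:
                cache[(g, e)] = _EigQ(self._Q_for(params, g, e))
            return cache[(g, e)]

        if self.spec.observation == "exact":
            # complete-data likelihood: exponential holding + jump intensity
            total = 0.0
            for g, epochs, is_death, dts, y0, y1 in self._groups:
                Qs = [self._Q_for(params, g, e) for e in epochs]
                hold = sum(Qs[j][y0, y0] * dts[:, j]
                           for j in range(len(epochs)))
                q_jump = Qs[-1][y0, y1]
                jump = np.where(y0 != y1,
                                np.log(np.maximum(q_jump, _TINY)), 0.0)
                total += float((hold + jump).sum())
            return total

        total = 0.0
        for g, epochs, is_death, dts, y0, y1 in self._groups:
            P = eig(g, epochs[0]).P_batch(dts[:, 0])
            for j in range(1, len(epochs)):
                P = np.einsum("nij,njk->nik", P,
                              eig(g, epochs[j]).P_batch(dts[:, j]))
            n = len(y0)
            if is_death:
                qcol = eig(g, epochs[-1]).Q[:, self._death_i]
                qcol = np.where(qcol > 0, qcol, 0.0)  # off-diagonal only
                lik = np.einsum("nk,k->n", P[np.arange(n), y0, :], qcol)
            else:
                lik = P[np.arange(n), y0, y1]
            total += float(np.log(np.maximum(lik, _TINY)).sum())
        return total

    # -- initialization -----------------------------------------------------
    def _adjacent_path(self, r: int, s: int) -> list[int]:
        """Shortest allowed decomposition of a panel move r -> s."""
        states = self.spec.state_space.states
        inv = {i: st for st, i in self._idx.items()}
        r_lab, s_lab = inv[r], inv[s]
        if s_lab in self.spec.state_space.absorbing:
            origins = sorted({a for (a, b) in self.spec.state_space.allowed
                              if b == s_lab})
            if not origins:
                return [r, s]
            target = min(origins, key=lambda o: (abs(o - r_lab), -o))
            step = 1 if target >= r_lab else -1
            path = list(range(r_lab, target + step, step)) if target != r_lab \
                else [r_lab]
            return [self._idx[p] for p in path] + [s]
        step = 1 if s_lab >= r_lab else -1
        return [self._idx[p] for p in range(r_lab, s_lab + step, step)]

    def crude_init(self) -> MsmmParams:
        """Counts/exposure starting values; multi-step moves decomposed
        along the shortest adjacent path with exposure split equally."""
        spec = self.spec
        free = spec.free_transitions
        t_index = {t: j for j, t in enumerate(free)}
        inv = {i: st for st, i in self._idx.items()}
        counts = np.zeros(len(free))
        exposure = np.zeros(spec.state_space.n_states)
        for g, epochs, is_death, dts, y0, y1 in self._groups:
            tot = dts.sum(axis=1)
            for dt, a, b in zip(tot, y0, y1):
                if a == b:
                    exposure[a] += dt
                    continue
                path = self._adjacent_path(a, b)
                nstep = len(path) - 1
                for p, q in zip(path[:-1], path[1:]):
                    trans = (inv[p], inv[q])
                    if trans in t_index:
                        counts[t_index[trans]] += 1.0
                    exposure[p] += dt / max(nstep, 1)
        rates = (counts + 0.5) / (exposure[[self._idx[r] for r, _ in free]] + 1.0)
        log_q = np.tile(np.clip(np.log(rates), _LOGQ_FLOOR + 2.0, 2.0),
                        (spec.n_epochs, 1))
        return MsmmParams(log_q=log_q, beta=np.zeros(len(spec.beta_index)))

    # -- fitting ------------------------------------------------------------
    def fit(self, start: MsmmParams | np.ndarray | None = None,
            maxiter: int = 500, gtol: float = 1e-6,
            log_q_floor: float = _LOGQ_FLOOR, se: bool = True,
            on_fail: str = "raise") -> "MsmmResults":
        """Maximize the panel likelihood by bounded quasi-Newton (L-BFGS-B).

        log intensities are floored at `log_q_floor` (a transition pushed to
        the floor is flagged as on the boundary — the smooth analogue of
        pinning it to zero); `se=False` skips the finite-difference Hessian
        when only the log-likelihood is needed (e.g. inside an LRT).
        """
        if start is None:
            start = self.crude_init()
        x0 = start.pack() if isinstance(start, MsmmParams) else np.asarray(start)
        nq = self.spec.n_epochs * len(self.spec.free_transitions)
        bounds = [(log_q_floor, 10.0)] * nq + \
                 [(None, None)] * len(self.spec.beta_index)

        def nll(x: np.ndarray) -> float:
            return -self.loglik(x)

        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": 1e-12,
                                         # maxfun counts finite-difference
                                         # evals: budget per gradient step
                                         "maxfun": maxiter * (x0.size + 5)})
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None \
            else np.nan
        converged = bool(res.success)
        if not converged and grad_norm < 1e-3:
            # stopped on an iteration/evaluation limit while essentially
            # stationary: accept, but say so
            logger.warning("optimizer stopped at the evaluation limit with "
                           "|grad|_inf = %.2g; accepting near-stationary "
                           "solution", grad_norm)
            converged = True
        if not converged and on_fail == "raise":
            raise ConvergenceError(
                f"MSMM fit did not converge: {res.message} "
                f"(|grad|_inf = {grad_norm:.3g})", res.x, grad_norm)
        params = MsmmParams.unpack(res.x, self.spec)
        boundary = np.zeros(self.spec.n_params, bool)
        boundary[:nq] = res.x[:nq] <= log_q_floor + 1e-6
        # an effectively-zero intensity leaves the likelihood flat long
        # before the optimizer reaches the floor: flag by profile flatness
        llf = -res.fun
        for j in np.flatnonzero((res.x[:nq] < -7.5) & ~boundary[:nq]):
            trial = res.x.copy()
            trial[j] = log_q_floor
            if self.loglik(trial) > llf - 0.02:
                boundary[j] = True
        vcov = None
        if se:
            vcov = self._vcov(res.x, boundary)
        return MsmmResults(model=self, params=params, llf=-res.fun,
                           vcov=vcov, converged=converged,
                           boundary=boundary, grad_norm=grad_norm,
                           n_iter=int(res.nit))

    def _vcov(self, x: np.ndarray, boundary: np.ndarray) -> np.ndarray:
        from statsmodels.tools.numdiff import approx_hess1
        free = ~boundary
        if not free.any():
            return np.full((x.size, x.size), np.nan)

        def nll_free(xf: np.ndarray) -> float:
            full = x.copy()
            full[free] = xf
            return -self.loglik(full)

        H = approx_hess1(x[free], nll_free)
        vcov = np.full((x.size, x.size), np.nan)
        try:
            Vf = np.linalg.inv(H)
            d = np.diag(Vf)
            if (d < 0).any():
                warnings.warn("observed information not positive definite; "
                              "some standard errors unavailable")
                Vf = Vf.copy()
                Vf[np.ix_(d < 0, d < 0)] = np.nan
            vcov[np.ix_(free, free)] = Vf
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; standard errors "
                          "unavailable")
        return vcov


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class MsmmResults:
    """Fitted MSMM: estimates, uncertainty, hazard ratios, diagnostics."""

    model: MultistateMarkovModel
    params: MsmmParams
    llf: float
    vcov: np.ndarray | None
    converged: bool
    boundary: np.ndarray
    grad_norm: float
    n_iter: int

    @property
    def spec(self) -> MsmmSpec:
        return self.model.spec

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def bse(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.n_params, np.nan)
        return np.sqrt(np.diag(self.vcov))

    def intensity_table(self) -> pd.DataFrame:
        """Baseline intensities exp(log_q) per epoch and transition."""
        rows = []
        for e in range(self.spec.n_epochs):
            for j, (r, s) in enumerate(self.spec.free_transitions):
                rows.append({"epoch": e, "from_state": r, "to_state": s,
                             "intensity": float(np.exp(self.params.log_q[e, j])),
                             "log_q": float(self.params.log_q[e, j])})
        return pd.DataFrame(rows)

    def hazard_ratio_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-(transition, covariate) hazard ratios with Wald CIs.

        CI bounds are exp(beta +/- z * SE) on the log scale; entries whose
        variance is unavailable (boundary or singular information) are NaN.
        """
        z = stats.norm.ppf(1 - alpha / 2)
        nq = self.spec.n_epochs * len(self.spec.free_transitions)
        bse = self.bse[nq:]
        rows = []
        for k, ((r, s), name) in enumerate(self.spec.beta_index):
            b = float(self.params.beta[k])
            se = float(bse[k]) if k < len(bse) else np.nan
            rows.append({
                "from_state": r, "to_state": s, "covariate": name,
                "log_hr": b, "se": se, "hr": float(np.exp(b)),
                "ci_lo": float(np.exp(b - z * se)) if np.isfinite(se) else np.nan,
                "ci_hi": float(np.exp(b + z * se)) if np.isfinite(se) else np.nan,
            })
        return pd.DataFrame(rows)

    # alias matching the functional surface
    hr_table = hazard_ratio_table

    def summary(self) -> str:
        lines = ["Multistate Markov model (panel likelihood)",
                 f"  states: {self.spec.state_space.states}  "
                 f"absorbing: {sorted(self.spec.state_space.absorbing)}",
                 f"  epochs: {self.spec.n_epochs} "
                 f"(breakpoints {list(self.spec.breakpoints)})  "
                 f"death_mode: {self.spec.death_mode}",
                 f"  n subjects: {len(self.model._subjects)}  "
                 f"n intervals: {self.model.n_intervals}",
                 f"  log-likelihood: {self.llf:.4f}  "
                 f"params: {self.n_params}  converged: {self.converged}"]
        if self.boundary.any():
            nb = int(self.boundary.sum())
            lines.append(f"  {nb} intensity parameter(s) at the lower "
                         "boundary (effectively zero)")
        hr = self.hazard_ratio_table()
        if len(hr):
            lines.append("  hazard ratios:")
            for _, row in hr.iterrows():
                lines.append(
                    f"    {row.from_state}->{row.to_state} [{row.covariate}]: "
                    f"HR {row.hr:.3f} ({row.ci_lo:.3f}, {row.ci_hi:.3f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def panel_loglik(panel: TrialPanel, spec: MsmmSpec,
                 params: MsmmParams) -> float:
    """Panel log-likelihood of `params` given the data (no fitting)."""
    return MultistateMarkovModel(panel, spec).loglik(params)


def fit_msmm(panel: TrialPanel, spec: MsmmSpec, **options) -> MsmmResults:
    """Fit a multistate Markov model; see :meth:`MultistateMarkovModel.fit`."""
    return MultistateMarkovModel(panel, spec).fit(**options)


def reduce_structure(fit: MsmmResults, threshold: float = 1e-4,
                     include_boundary: bool = True) -> MsmmSpec:
    """Pin transitions whose estimated baseline intensity is below
    `threshold` in every epoch — the data cannot support them.  Boundary-
    flagged intensities (profile-flat at zero) are pinned as well unless
    `include_boundary` is false."""
    spec = fit.spec
    q = np.exp(fit.params.log_q)  # (n_epochs, n_free)
    small = (q < threshold).all(axis=0)
    if include_boundary:
        nfree = len(spec.free_transitions)
        bflag = fit.boundary[:spec.n_epochs * nfree].reshape(
            spec.n_epochs, nfree).all(axis=0)
        small = small | bflag
    pins = {t for t, flag in zip(spec.free_transitions, small) if flag}
    if pins:
        logger.info("pinning %d transition(s) with intensity < %g: %s",
                    len(pins), threshold, sorted(pins))
    return replace(spec, pinned=frozenset(spec.pinned | pins))


def lrt(reduced_fit: MsmmResults, full_fit: MsmmResults
        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p)."""
    statistic = 2.0 * (full_fit.llf - reduced_fit.llf)
    if statistic < -1e-6:
        raise ValueError("full model has lower likelihood than reduced — "
                         "models not nested or fit not converged")
    statistic = max(statistic, 0.0)
    df = full_fit.n_params - reduced_fit.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters")
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def global_treatment_test(panel: TrialPanel, spec: MsmmSpec | None = None,
                          se: bool = False, **options
                          ) -> tuple[float, MsmmResults, MsmmResults]:
    """LRT of treatment on every free transition vs no treatment effect.

    Returns (p, fit_with_treatment, fit_without).  The null fit's solution
    warm-starts the alternative (betas at zero), which roughly halves the
    optimizer work.
    """
    spec = spec or MsmmSpec(covariates=("treatment",))
    if "treatment" not in spec.covariates:
        spec = replace(spec, covariates=spec.covariates + ("treatment",))
    drop = tuple(c for c in spec.covariates if c != "treatment")
    em = spec.effect_map
    if isinstance(em, Mapping):
        em = {t: tuple(n for n in names if n != "treatment")
              for t, names in em.items()}
    spec_without = replace(spec, covariates=drop, effect_map=em)
    fit0 = MultistateMarkovModel(panel, spec_without).fit(se=False, **options)
    model1 = MultistateMarkovModel(panel, spec)
    start = MsmmParams(log_q=fit0.params.log_q.copy(),
                       beta=np.zeros(len(spec.beta_index)))
    # carry over any non-treatment betas from the null fit
    for k, ((r, s), name) in enumerate(spec.beta_index):
        if name != "treatment":
            for k0, (t0, n0) in enumerate(spec_without.beta_index):
                if t0 == (r, s) and n0 == name:
                    start.beta[k] = fit0.params.beta[k0]
    fit1 = model1.fit(start=start, se=se, **options)
    _, _, p = lrt(fit0, fit1)
    return p, fit1, fit0
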