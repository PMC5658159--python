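"""Latent baseline mRS prediction from baseline covariates via PCA.

The mRS cannot be measured at the moment of stroke, yet much of the
recovery happens immediately after randomization.  A principal component
analysis of baseline severity measures (NIHSS items and total, age,
glucose, onset-to-randomization time, early CT score) yields a composite
severity score per subject; ranking subjects by that score and cutting the
ranks at the quantiles of a target mRS distribution assigns each subject a
latent baseline state 0-5, which can be prepended to the panel as a
pseudo-observation at time 0.

The score-to-state mapping is a reconstruction: a rank/quantile mapping
against a configurable target distribution, not a published algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import TrialPanel

logger = logging.getLogger("strokemsm")


@dataclass
class PcaModel:
    """Correlation-matrix PCA of the baseline covariates.

    Loadings are orthonormal eigenvectors of the correlation matrix,
    eigenvalues non-increasing.  Signs are fixed so each retained component
    correlates positively with the NIHSS total (or the first variable),
    making the composite a *severity* score (higher = worse).
    """

    variables: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray       # (n_vars, n_components), columns = components
    eigenvalues: np.ndarray
    retained: tuple[int, ...]
    score_mean: float = 0.0
    score_sd: float = 1.0

    def standardize(self, table: pd.DataFrame) -> np.ndarray:
        missing = set(self.variables) - set(table.columns)
        if missing:
            raise ValueError(f"missing PCA variables: {sorted(missing)}")
        Z = (table[list(self.variables)].to_numpy(float) - self.means) / self.sds
        return Z

    def raw_composite(self, table: pd.DataFrame) -> np.ndarray:
        """Eigenvalue-weighted sum of retained component scores."""
        Z = self.standardize(table)
        scores = Z @ self.loadings[:, list(self.retained)]
        weights = self.eigenvalues[list(self.retained)]
        return scores @ weights


def fit_pca(table: pd.DataFrame, retention: str = "kaiser",
            cumvar: float = 0.80, anchor: str = "nihss_total") -> PcaModel:
    """Fit a correlation-matrix PCA to a complete-case covariate table.

    Components with eigenvalue > 1 are retained under the default Kaiser
    rule; ``retention="cumvar"`` instead keeps the smallest leading set
    explaining at least `cumvar` of the variance.  Constant variables are
    dropped with a warning.
    """
    table = table.dropna()
    if table.shape[0] <= table.shape[1]:
        raise ValueError("need more complete cases than variables")
    sds = table.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant variable(s): {constant}")
        table = table.drop(columns=constant)
    if table.shape[1] == 0:
        raise ValueError("all variables constant")
    variables = tuple(table.columns)
    X = table.to_numpy(float)
    means = X.mean(axis=0)
    sds_arr = X.std(axis=0, ddof=1)
    Z = (X - means) / sds_arr
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: positive correlation with the anchor variable
    anchor_i = variables.index(anchor) if anchor in variables else 0
    for j in range(evecs.shape[1]):
        if evecs[anchor_i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    if retention == "kaiser":
        retained = tuple(int(j) for j in range(len(evals)) if evals[j] > 1.0)
        if not retained:
            retained = (0,)
    elif retention == "cumvar":
        frac = np.cumsum(evals) / evals.sum()
        k = int(np.searchsorted(frac, cumvar) + 1)
        retained = tuple(range(k))
    else:
        raise ValueError("retention must be 'kaiser' or 'cumvar'")
    model = PcaModel(variables=variables, means=means, sds=sds_arr,
                     loadings=evecs, eigenvalues=evals, retained=retained)
    raw = model.raw_composite(table)
    model.score_mean = float(raw.mean())
    model.score_sd = float(raw.std(ddof=0)) or 1.0
    return model


def composite_score(model: PcaModel, table: pd.DataFrame) -> pd.Series:
    """Standardized composite severity score (zero mean, unit variance over
    the fitting sample).  Subjects with missing variables get NaN and a log
    entry rather than a score."""
    complete = table[list(model.variables)].notna().all(axis=1)
    if (~complete).any():
        logger.warning("%d subject(s) missing PCA variables; no score "
                       "assigned", int((~complete).sum()))
    out = pd.Series(np.nan, index=table.index, name="composite_score")
    if complete.any():
        raw = model.raw_composite(table.loc[complete])
        out.loc[complete] = (raw - model.score_mean) / model.score_sd
    return out


@dataclass
class BaselineAssignment:
    """Per-subject composite score and assigned latent baseline state."""

    scores: pd.Series
    states: pd.Series            # int 0-5, indexed like scores

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"composite_score": self.scores,
                             "baseline_mrs": self.states})


DEFAULT_TARGET_DIST = {2: 0.10, 3: 0.20, 4: 0.35, 5: 0.35}
"""Default target distribution for the latent baseline: mass on moderate to
severe states, reflecting that trial-eligible acute strokes are rarely mild
at onset.  A reconstruction choice, supplied via config in real analyses."""


def assign_baseline_state(scores: pd.Series,
                          target_distribution: dict[int, float] | None = None,
                          ) -> BaselineAssignment:
    """Map composite severity scores to baseline states by rank quantiles.

    Subjects are ranked by score (ties broken by stable subject-id order);
    cumulative quantile thresholds of the target distribution over states
    0-5 partition the ranks, with the worst scores assigned the highest
    state.  The assignment is monotone in the score.
    """
    target = dict(target_distribution or DEFAULT_TARGET_DIST)
    bad = set(target) - set(range(6))
    if bad:
        raise ValueError(f"target states must be 0-5, got {sorted(bad)}")
    total = sum(target.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("target distribution must sum to 1")
    scores = scores.dropna()
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    n = len(scores)
    order = scores.reset_index()
    sid_col = order.columns[0]
    order = order.sort_values([scores.name or 0, sid_col],
                              kind="stable").set_index(sid_col)
    cum = 0.0
    boundaries = []           # (state, n_assigned) in ascending state order
    states_sorted = sorted(target)
    for k, st in enumerate(states_sorted):
        cum += target[st]
        hi = n if k == len(states_sorted) - 1 else int(round(cum * n))
        boundaries.append((st, hi))
    assigned = np.empty(n, int)
    lo = 0
    for st, hi in boundaries:
        assigned[lo:hi] = st
        lo = max(lo, hi)
    states = pd.Series(assigned, index=order.index, name="baseline_mrs")
    return BaselineAssignment(scores=scores, states=states.loc[scores.index])


def attach_baseline(panel: TrialPanel,
                    assignment: BaselineAssignment) -> TrialPanel:
    """Prepend the assigned baseline state as a time-0 record per subject."""
    if (panel.data["time_days"] == 0).any():
        raise ValueError("panel already has time-0 records; refusing to "
                         "attach a second baseline")
    missing = set(panel.subjects) - set(assignment.states.index)
    if missing:
        raise ValueError(f"no baseline assignment for subjects "
                         f"{sorted(missing)[:5]}")
    arm = panel.arm_of()
    extra = pd.DataFrame({
        "subject_id": list(panel.subjects),
        "arm": [arm[s] for s in panel.subjects],
        "time_days": 0.0,
        "state": [int(assignment.states[s]) for s in panel.subjects],
    })
    data = pd.concat([panel.data, extra], ignore_index=True)
    return TrialPanel(data, baseline=panel.baseline,
                      state_space=panel.state_space)
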