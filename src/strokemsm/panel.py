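"""Trial data model: state space, long-format panel container, summaries.

A trial panel is the long-format record of an ordinal outcome observed at
discrete visit times: one row per subject-visit carrying the subject id,
the arm, the time in days since randomization and the observed state, plus
an optional per-subject table of baseline covariates.  Times are real-valued
days; there is no calendar handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("strokemsm")

#: Default visit windows (days): the first visit is nominally at 7-10 days,
#: the later visits at 90/180/360 days with +/- 10 day jitter.
DEFAULT_VISIT_WINDOWS: tuple[tuple[float, float], ...] = (
    (7.0, 10.0), (80.0, 100.0), (170.0, 190.0), (350.0, 370.0),
)

ARMS = ("control", "treatment")


class PanelValidationError(ValueError):
    """Raised when a panel violates a structural invariant."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state space of the disability scale with allowed transitions.

    The default mRS space has states 0..6 with 6 (death) absorbing.  Because
    the underlying disease process is continuous, instantaneous transitions
    are only plausible between adjacent disability states; the *general*
    structure therefore allows r -> r+/-1 for transient states plus a direct
    transition to death from every transient state, while the *reduced*
    structure restricts death to origin states 4 and 5.
    """

    states: tuple[int, ...] = tuple(range(7))
    absorbing: frozenset[int] = frozenset({6})
    allowed: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for (r, s) in self.allowed:
            if r == s:
                raise ValueError(f"self-transition ({r},{r}) not allowed")
            if r in self.absorbing:
                raise ValueError(f"transition out of absorbing state {r}")
            if r not in self.states or s not in self.states:
                raise ValueError(f"transition ({r},{s}) outside state space")

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(s for s in self.states if s not in self.absorbing)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def is_allowed(self, r: int, s: int) -> bool:
        return (r, s) in self.allowed

    @classmethod
    def general(cls, n_disability: int = 6, death: int = 6) -> "StateSpace":
        """Adjacent transitions among 0..n_disability-1 plus any-state->death."""
        states = tuple(range(n_disability)) + (death,)
        allowed = set()
        for r in range(n_disability):
            if r + 1 < n_disability:
                allowed.add((r, r + 1))
                allowed.add((r + 1, r))
            allowed.add((r, death))
        return cls(states=states, absorbing=frozenset({death}),
                   allowed=frozenset(allowed))

    @classmethod
    def reduced(cls, death_from: Iterable[int] = (4, 5),
                n_disability: int = 6, death: int = 6) -> "StateSpace":
        """Adjacent transitions; death reachable only from `death_from`."""
        death_from = set(death_from)
        states = tuple(range(n_disability)) + (death,)
        allowed = set()
        for r in range(n_disability):
            if r + 1 < n_disability:
                allowed.add((r, r + 1))
                allowed.add((r + 1, r))
            if r in death_from:
                allowed.add((r, death))
        return cls(states=states, absorbing=frozenset({death}),
                   allowed=frozenset(allowed))

    def sorted_transitions(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.allowed))


class TrialPanel:
    """Long-format subject x visit ordinal observations with covariates.

    Parameters
    ----------
    data : DataFrame with columns ``subject_id``, ``arm``, ``time_days``,
        ``state`` (one row per subject-visit).
    baseline : optional DataFrame of per-subject baseline covariates,
        indexed by ``subject_id``.
    state_space : StateSpace the observations must live in.
    after_death : {"error", "drop"} — what to do with records observed after
        a death record.  The absorbing-state invariant is load-bearing for
        the Markov likelihood, so the default is a hard error.
    """

    REQUIRED = ("subject_id", "arm", "time_days", "state")

    def __init__(self, data: pd.DataFrame, baseline: pd.DataFrame | None = None,
                 state_space: StateSpace | None = None,
                 after_death: str = "error") -> None:
        self.state_space = state_space or StateSpace.reduced()
        data = data.copy()
        for col in self.REQUIRED:
            if col not in data.columns:
                raise PanelValidationError(f"missing required column {col!r}")
        data["time_days"] = data["time_days"].astype(float)
        data["state"] = data["state"].astype(int)
        data = data.sort_values(["subject_id", "time_days"], kind="stable")
        data = data.reset_index(drop=True)
        self._validate(data, after_death)
        if after_death == "drop":
            data = self._drop_after_death(data)
        self.data = data
        if baseline is not None:
            baseline = baseline.copy()
            if baseline.index.name != "subject_id":
                if "subject_id" in baseline.columns:
                    baseline = baseline.set_index("subject_id")
                else:
                    baseline.index.name = "subject_id"
        self.baseline = baseline

    # -- validation ---------------------------------------------------------
    def _validate(self, data: pd.DataFrame, after_death: str) -> None:
        bad_arm = set(data["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise PanelValidationError(f"unknown arm labels: {sorted(bad_arm)}")
        valid_states = set(self.state_space.states)
        bad = data.loc[~data["state"].isin(valid_states)]
        if len(bad):
            raise PanelValidationError(
                f"states outside state space for subjects "
                f"{sorted(bad['subject_id'].unique())}")
        if (data["time_days"] < 0).any():
            raise PanelValidationError("negative observation times")
        for sid, grp in data.groupby("subject_id", sort=False):
            t = grp["time_days"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise PanelValidationError(
                    f"non-increasing times within subject {sid!r}")
            arms = grp["arm"].unique()
            if len(arms) != 1:
                raise PanelValidationError(f"subject {sid!r} in multiple arms")
            absorbed = grp["state"].isin(self.state_space.absorbing).to_numpy()
            if absorbed[:-1].any() and after_death == "error":
                raise PanelValidationError(
                    f"record after death for subject {sid!r}")

    def _drop_after_death(self, data: pd.DataFrame) -> pd.DataFrame:
        keep = []
        for sid, grp in data.groupby("subject_id", sort=False):
            absorbed = grp["state"].isin(self.state_space.absorbing).to_numpy()
            if absorbed[:-1].any():
                first = int(np.argmax(absorbed))
                logger.warning("dropping %d record(s) after death for subject %r",
                               len(grp) - first - 1, sid)
                keep.append(grp.iloc[:first + 1])
            else:
                keep.append(grp)
        return pd.concat(keep, ignore_index=True)

    # -- accessors ----------------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.data["subject_id"].nunique())

    def arm_of(self) -> pd.Series:
        """Per-subject arm label, indexed by subject id."""
        return self.data.groupby("subject_id", sort=False)["arm"].first()

    def at_visit(self, window: tuple[float, float]) -> pd.DataFrame:
        """One record per subject inside `window`, nearest to its midpoint.

        Ties in distance to the midpoint are broken toward the earlier
        record; a subject observed twice in the window triggers a warning.
        """
        lo, hi = window
        mid = 0.5 * (lo + hi)
        sel = self.data[(self.data["time_days"] >= lo)
                        & (self.data["time_days"] <= hi)].copy()
        if sel.empty:
            return sel
        dup = sel["subject_id"].duplicated(keep=False)
        if dup.any():
            logger.warning("%d subject(s) observed more than once in window "
                           "%s; using record nearest the midpoint",
                           sel.loc[dup, "subject_id"].nunique(), window)
        sel["_dist"] = (sel["time_days"] - mid).abs()
        # stable sort keeps the earlier record first among equal distances
        sel = sel.sort_values(["subject_id", "_dist"], kind="stable")
        sel = sel.drop_duplicates("subject_id", keep="first")
        return sel.drop(columns="_dist").sort_index()

    def with_baseline_row(self) -> bool:
        return bool((self.data["time_days"] == 0).any())

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialPanel):
            return NotImplemented
        if not self.data.reset_index(drop=True).equals(
                other.data.reset_index(drop=True)):
            return False
        if (self.baseline is None) != (other.baseline is None):
            return False
        if self.baseline is not None:
            return self.baseline.sort_index().equals(other.baseline.sort_index())
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_panel(path: str | Path, state_space: StateSpace | None = None,
               after_death: str = "error") -> TrialPanel:
    """Read a long-format panel from delimited text (CSV/TSV by extension).

    The file must carry the columns ``subject_id``, ``arm``, ``time_days``
    and ``mrs`` (or ``state``); any further columns are treated as
    per-subject baseline covariates and collected into the baseline table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "mrs" in df.columns and "state" not in df.columns:
        df = df.rename(columns={"mrs": "state"})
    for col in TrialPanel.REQUIRED:
        if col not in df.columns:
            raise PanelValidationError(
                f"missing required column {col!r} in {path.name}")
    record_cols = list(TrialPanel.REQUIRED)
    if "death_exact" in df.columns:        # record-level flag, not a covariate
        record_cols.append("death_exact")
    covar_cols = [c for c in df.columns if c not in record_cols]
    baseline = None
    if covar_cols:
        baseline = (df[["subject_id"] + covar_cols]
                    .groupby("subject_id", sort=False).first())
    return TrialPanel(df[record_cols], baseline=baseline,
                      state_space=state_space, after_death=after_death)


def write_panel(panel: TrialPanel, path: str | Path) -> None:
    """Write a panel (and any baseline covariates) back to delimited text."""
    path = Path(path)
    df = panel.data.rename(columns={"state": "mrs"})
    if panel.baseline is not None:
        df = df.merge(panel.baseline.reset_index(), on="subject_id", how="left")
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Arm x state counts at one visit, with pooled-denominator percentages.

    Percentages use the pooled N over both arms as denominator, the
    convention of trial baseline/outcome tables, so all cells across both
    arms sum to 100 within rounding.
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    window: tuple[float, float]

    @property
    def pooled_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.astype(str) + " (" + self.percents.round(1).astype(str) + ")"
        out["N"] = self.counts.sum(axis=1)
        return out


def summarize_visit(panel: TrialPanel,
                    visit_window: tuple[float, float]) -> SummaryTable:
    """Tabulate arm x state occupancy at the visit in `visit_window`."""
    sel = panel.at_visit(visit_window)
    states = list(panel.state_space.states)
    counts = pd.DataFrame(0, index=list(ARMS), columns=states, dtype=int)
    if sel.empty:
        warnings.warn(f"no records in visit window {visit_window}")
        return SummaryTable(counts, counts.astype(float), visit_window)
    tab = pd.crosstab(sel["arm"], sel["state"])
    counts = tab.reindex(index=list(ARMS), columns=states, fill_value=0)
    counts.index.name = "arm"
    total = counts.to_numpy().sum()
    percents = 100.0 * counts / total
    return SummaryTable(counts, percents, visit_window)


@dataclass
class TransitionCountTable:
    """Observed state-to-state subject moves between consecutive visits.

    ``matrices[k]`` counts moves between visit windows k and k+1 among
    subjects observed at both; row sums equal state occupancy at the earlier
    visit within that doubly-observed set — the flow-conservation property a
    Sankey diagram renders.
    """

    matrices: list[pd.DataFrame]
    windows: tuple[tuple[float, float], ...]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for k, mat in enumerate(self.matrices):
            for r in mat.index:
                for s in mat.columns:
                    n = int(mat.loc[r, s])
                    if n:
                        rows.append({"visit_pair": k, "from_state": r,
                                     "to_state": s, "n": n})
        return pd.DataFrame(rows, columns=["visit_pair", "from_state",
                                           "to_state", "n"])


def transition_counts(panel: TrialPanel,
                      visit_schedule: Sequence[tuple[float, float]] = DEFAULT_VISIT_WINDOWS,
                      ) -> TransitionCountTable:
    """Count observed moves between consecutive visit windows."""
    if len(visit_schedule) < 2:
        raise ValueError("need at least two visit windows")
    states = list(panel.state_space.states)
    selections = [panel.at_visit(w).set_index("subject_id")["state"]
                  for w in visit_schedule]
    matrices = []
    for a, b in zip(selections[:-1], selections[1:]):
        both = a.index.intersection(b.index)
        mat = pd.crosstab(a.loc[both], b.loc[both])
        mat = mat.reindex(index=states, columns=states, fill_value=0)
        mat.index.name = "from_state"
        mat.columns.name = "to_state"
        matrices.append(mat)
    return TransitionCountTable(matrices, tuple(tuple(w) for w in visit_schedule))
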