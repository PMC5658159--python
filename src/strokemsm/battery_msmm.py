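"""Longitudinal battery entries: MSMM rows and baseline-augmented analyses.

Kept separate from :mod:`comparators` so the single-endpoint battery does
not import the Markov machinery (and vice versa) at module load.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .baseline import (assign_baseline_state, attach_baseline,
                       composite_score, fit_pca)
from .comparators import ComparatorResult
from .msmm import MsmmSpec, global_treatment_test
from .panel import TrialPanel


def predicted_baseline_panel(panel: TrialPanel,
                             target_dist: Mapping[int, float] | None = None,
                             ) -> TrialPanel:
    """PCA -> composite score -> rank assignment -> attach at time 0."""
    if panel.baseline is None:
        raise ValueError("panel has no baseline covariates for PCA")
    numeric = panel.baseline.select_dtypes("number")
    model = fit_pca(numeric)
    scores = composite_score(model, numeric)
    assignment = assign_baseline_state(scores, target_dist)
    return attach_baseline(panel, assignment)


def msmm_comparator(panel: TrialPanel, which: str = "msmm",
                    target_dist: Mapping[int, float] | None = None,
                    options: Mapping | None = None) -> ComparatorResult:
    """Battery adapters for the repeated-measures analyses.

    ``msmm``: time-homogeneous MSMM, treatment on every free transition,
    global LRT p.  ``msmm_baseline``: same but on the panel with the
    predicted baseline attached and a piecewise (90-day breakpoint)
    intensity structure.  ``gee_baseline``: the dichotomized GEE on the
    baseline-attached panel.
    """
    options = dict(options or {})
    if which == "gee_baseline":
        from .comparators import gee_repeated
        augmented = predicted_baseline_panel(panel, target_dist)
        return gee_repeated(augmented, with_baseline=True)
    if which == "msmm":
        spec = MsmmSpec(state_space=panel.state_space,
                        covariates=("treatment",),
                        **{k: v for k, v in options.items()
                           if k in ("breakpoints", "death_mode", "pinned")})
        target, outcome = panel, "mRS over follow-up"
    elif which == "msmm_baseline":
        target = predicted_baseline_panel(panel, target_dist)
        spec = MsmmSpec(state_space=panel.state_space,
                        covariates=("treatment",),
                        breakpoints=tuple(options.pop("breakpoints", (90.0,))),
                        **{k: v for k, v in options.items()
                           if k in ("death_mode", "pinned")})
        outcome = "predicted mRS at baseline and mRS over follow-up"
    else:
        raise ValueError(f"unknown battery entry {which!r}")
    se = bool(options.pop("se", True))
    fit_opts = {k: v for k, v in options.items()
                if k in ("maxiter", "gtol", "log_q_floor")}
    p, fit_with, _ = global_treatment_test(target, spec, se=se, **fit_opts)
    statistics = []
    if se:
        for _, row in fit_with.hazard_ratio_table().iterrows():
            statistics.append((f"HR {row.from_state}->{row.to_state}",
                               float(row.hr), float(row.ci_lo),
                               float(row.ci_hi)))
    return ComparatorResult(
        method=which, outcome=outcome, statistics=statistics, p_value=p,
        extra={"llf": fit_with.llf, "df": len(spec.beta_index),
               "converged": fit_with.converged})
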