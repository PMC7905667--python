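"""Confusion-matrix scoring of selections and the simulation-study harness.

The harness replays the benchmark protocol: simulate a multi-study
replicate, calibrate the penalty by K-fold CV over the (group count,
alpha) grid, fit, select, and score the selection against the simulated
truth at the variable and group level, averaging confusion counts over
replicates.  The single-study (pooled) model runs on the per-study
standardized concatenation; the joint model runs on the multi-study
structure directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import SelectionResult, StructuredDataset
from .errors import ParameterError, PleioPLSError
from .model_selection import CVConfig, cross_validate
from .pls_core import FitConfig, fit, selected_features
from .preprocessing import pool_studies
from .simulator import GroundTruth, build_design, simulate_study_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    level: str
    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def n_causal(self) -> float:
        return self.tp + self.fn

    @property
    def n_noncausal(self) -> float:
        return self.fp + self.tn


def evaluate_selection(
    selection: SelectionResult, truth: GroundTruth, level: str, dataset: StructuredDataset
) -> ConfusionCounts:
    """Confusion counts of a selection against the simulated truth."""
    if level == "variable":
        universe = dataset.variable_ids
        selected = set(selection.variables)
        causal = set(truth.causal_variables)
    elif level == "group":
        universe = dataset.var_groups.labels
        selected = set(selection.groups)
        causal = set(truth.causal_groups)
    else:
        raise ParameterError(f"unknown level '{level}'")
    unknown = (selected | causal) - set(universe)
    if unknown:
        from .errors import IdentifierError

        raise IdentifierError(f"ids outside the dataset universe: {sorted(unknown)}")
    tp = len(selected & causal)
    fp = len(selected - causal)
    fn = len(causal - selected)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(level, tp, fp, fn, tn)


def _run_method(
    dataset: StructuredDataset,
    method: str,
    cv_config: CVConfig,
    fit_template: FitConfig,
):
    """CV-calibrate and fit one method on one replicate; return selection + chosen params."""
    if method in ("spls", "sgpls"):
        data = pool_studies(dataset)
    elif method == "joint_sgpls":
        data = dataset
    else:
        raise ParameterError(f"unknown method '{method}'")
    template = replace(fit_template, method=method)
    _, best = cross_validate(data, cv_config, template)
    model = fit(data, replace(template, params=best))
    return selected_features(model), best


def run_simulation_study(
    cases,
    methods,
    n_reps: int,
    cv_config: CVConfig,
    seed: int = 0,
    fit_template: FitConfig | None = None,
) -> pd.DataFrame:
    """Mean (and SD of) confusion counts per case/method/level over replicates.

    Randomness is organised as replicate-indexed substreams of one master
    seed, so a given replicate's data is identical whichever methods run.
    Replicates where a method fails are excluded from that method's mean
    and counted in ``n_failed``.
    """
    fit_template = fit_template or FitConfig()
    records = []
    master = np.random.SeedSequence(seed)
    case_seeds = master.spawn(len(list(cases)))
    for case, case_ss in zip(cases, case_seeds):
        design = build_design(case)
        rep_seeds = case_ss.spawn(n_reps)
        for rep, rep_ss in enumerate(rep_seeds):
            data_seed, cv_seed = rep_ss.generate_state(2) % (2**31)
            dataset, truth = simulate_study_set(design, int(data_seed))
            cv = replace(cv_config, seed=int(cv_seed))
            for method in methods:
                try:
                    selection, best = _run_method(dataset, method, cv, fit_template)
                except PleioPLSError as exc:
                    logger.warning("case %s rep %d %s failed: %s", case, rep, method, exc)
                    records.append(
                        dict(case=case, rep=rep, method=method, failed=True)
                    )
                    continue
                for level in ("variable", "group"):
                    cc = evaluate_selection(selection, truth, level, dataset)
                    records.append(
                        dict(
                            case=case,
                            rep=rep,
                            method=method,
                            failed=False,
                            level=level,
                            tp=cc.tp,
                            fp=cc.fp,
                            fn=cc.fn,
                            tn=cc.tn,
                            chosen_groups=best.n_groups_kept,
                            chosen_alpha=best.alpha,
                        )
                    )
    return pd.DataFrame.from_records(records)


def summarize_study(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the per-replicate table to means/SDs per case/method/level."""
    ok = per_rep[~per_rep["failed"]]
    grouped = ok.groupby(["case", "method", "level"], as_index=False)
    summary = grouped.agg(
        tp=("tp", "mean"),
        fp=("fp", "mean"),
        fn=("fn", "mean"),
        tn=("tn", "mean"),
        tp_sd=("tp", "std"),
        n_reps=("tp", "size"),
    )
    failed = (
        per_rep[per_rep["failed"]]
        .groupby(["case", "method"], as_index=False)
        .size()
        .rename(columns={"size": "n_failed"})
    )
    summary = summary.merge(failed, on=["case", "method"], how="left")
    summary["n_failed"] = summary["n_failed"].fillna(0).astype(int)
    return summary
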