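"""Voting baselines and truth-based evaluation of selections.

``replicate_study`` reproduces the simulation-study tables: per replicate it
simulates a call matrix, fits the integration model, and evaluates the
Bayesian selections at nominal FDR 0.05/0.01/0.001 (Model-0.950/0.990/0.999)
against single tools and the two voting baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fdr import threshold_for_target, tool_fdr
from .model import McmcConfig, PriorConfig, run_mcmc
from .simulate import make_case, simulate

__all__ = ["MetricRow", "vote_baseline", "evaluate", "replicate_study",
           "summarize_study", "STUDY_METHODS"]

#: Row order of the study tables.
STUDY_METHODS = ("Tool1", "Tool2", "Tool3", "Tool4", "Tool5",
                 "Model-0.950", "Model-0.990", "Model-0.999",
                 "Vote 1", "Vote 2")


@dataclass
class MetricRow:
    """One method's metrics: predicted precision (1 - estimated FDR) and
    empirical precision/recall/F1 against the simulation truth."""

    method: str
    predicted_precision: float
    precision: float
    recall: float
    f1: float


def vote_baseline(Y: np.ndarray, rule: int) -> np.ndarray:
    """Voting decisions: rule 1 = at least half the tools, rule 2 = all tools."""
    Y = np.asarray(Y)
    if rule not in (1, 2):
        raise ValueError(f"unknown voting rule {rule}")
    J = Y.shape[1]
    x = Y.sum(axis=1)
    cutoff = math.ceil(J / 2) if rule == 1 else J
    return (x >= cutoff).astype(np.int8)


def evaluate(decisions: np.ndarray, z_true: np.ndarray,
             method: str = "", predicted_precision: float = float("nan")) -> MetricRow:
    """Precision, recall and F1 of a decision vector against the truth.

    Undefined metrics (no predicted positives, or no true positives) are
    reported as NaN, never as zero.
    """
    decisions = np.asarray(decisions).astype(bool)
    z_true = np.asarray(z_true).astype(bool)
    if decisions.shape != z_true.shape:
        raise ValueError("decisions and z_true must have equal length")
    tp = int(np.sum(decisions & z_true))
    fp = int(np.sum(decisions & ~z_true))
    fn = int(np.sum(~decisions & z_true))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricRow(method, predicted_precision, precision, recall, f1)


def _study_rows(cm, z_true, pep, targets=(0.05, 0.01, 0.001)) -> list[MetricRow]:
    rows = []
    tfdr = tool_fdr(pep, cm.Y)
    for j, t in enumerate(cm.tools):
        rows.append(evaluate(cm.Y[:, j], z_true, t.name, 1.0 - tfdr[j]))
    for target in targets:
        _, rep = threshold_for_target(pep, target)
        rows.append(evaluate(rep.decisions, z_true, f"Model-{1 - target:.3f}",
                             1.0 - rep.fdr_at_tau))
    for rule in (1, 2):
        dec = vote_baseline(cm.Y, rule)
        sel = dec == 1
        pred = 1.0 - float(pep[sel].mean()) if sel.any() else float("nan")
        rows.append(evaluate(dec, z_true, f"Vote {rule}", pred))
    return rows


def replicate_study(case_id: int, n_reps: int = 10,
                    prior: Optional[PriorConfig] = None,
                    mcmc: Optional[McmcConfig] = None,
                    seed: int = 0, n: Optional[int] = None,
                    return_details: bool = False):
    """Run the full comparison study for one simulation case.

    Returns a tidy DataFrame with one row per (replicate, method); with
    ``return_details`` also the per-replicate (CallMatrix, SimTruth,
    PosteriorSummary) triples.  The default fitting budget is 3000 sweeps
    with 1000 burn-in on a single chain per replicate.
    """
    prior = prior or PriorConfig()
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    records = []
    details = []
    for r, ss in enumerate(seeds):
        sim_seed, fit_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
        cfg = make_case(case_id, seed=sim_seed)
        if n is not None:
            cfg.n = n
        cm, truth = simulate(cfg)
        mcfg = mcmc or McmcConfig(iterations=3000, burn_in=1000, n_chains=1)
        mcfg = McmcConfig(iterations=mcfg.iterations, burn_in=mcfg.burn_in,
                          thin=mcfg.thin, seed=fit_seed, n_chains=mcfg.n_chains,
                          constraint_retry_cap=mcfg.constraint_retry_cap)
        summary = run_mcmc(cm, prior, mcfg)
        for row in _study_rows(cm, truth.z_true, summary.pep):
            records.append({"replicate": r, "method": row.method,
                            "predicted_precision": row.predicted_precision,
                            "precision": row.precision, "recall": row.recall,
                            "f1": row.f1})
        if return_details:
            details.append((cm, truth, summary))
    table = pd.DataFrame.from_records(records)
    return (table, details) if return_details else table


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per method and metric, in the study-table row order."""
    metrics = ["predicted_precision", "precision", "recall", "f1"]
    agg = table.groupby("method")[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    order = [m for m in STUDY_METHODS if m in agg.index]
    return agg.loc[order]
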