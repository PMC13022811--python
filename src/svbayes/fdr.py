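"""FDR control from posterior error probabilities.

The expected number of false positives in any selected set equals the sum of
its PEPs, so the estimated FDR of a selection is simply the mean PEP of the
selected positions.  Decisions threshold the PEP strictly: D_i = 1 iff
PEP_i < tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FdrReport",
    "tool_fdr",
    "fdr_at_threshold",
    "threshold_for_target",
    "pep_histogram_and_curve",
]


@dataclass
class FdrReport:
    """A thresholded selection: cutoff tau, decisions and the implied FDR."""

    tau: float
    decisions: np.ndarray
    fdr_at_tau: float  # NaN when nothing is selected
    n_selected: int
    tool_fdr: Optional[np.ndarray] = None


def tool_fdr(pep: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Estimated FDR of each tool's own call set: mean PEP over its calls.

    A tool that reports nothing gets NaN (undefined), never zero.
    """
    pep = np.asarray(pep, dtype=float)
    Y = np.asarray(Y)
    if Y.shape[0] != pep.shape[0]:
        raise ValueError("pep length must match the rows of Y")
    counts = Y.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (pep[:, None] * Y).sum(axis=0) / counts
    out[counts == 0] = np.nan
    return out


def fdr_at_threshold(pep: np.ndarray, tau: float) -> FdrReport:
    """Select positions with PEP strictly below tau and report their FDR."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    pep = np.asarray(pep, dtype=float)
    decisions = (pep < tau).astype(np.int8)
    n_sel = int(decisions.sum())
    fdr = float(pep[decisions == 1].mean()) if n_sel else float("nan")
    return FdrReport(tau=tau, decisions=decisions, fdr_at_tau=fdr, n_selected=n_sel)


def threshold_for_target(pep: np.ndarray, target_fdr: float) -> tuple[float, FdrReport]:
    """Largest selection whose estimated FDR stays at or below a target.

    Sorts the PEPs ascending and takes the longest prefix whose running mean
    is <= ``target_fdr`` (extending through, or dropping, a tied boundary
    value as a whole so the set is expressible as a strict PEP cutoff).
    Returns the implied tau together with its report.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must lie in (0, 1)")
    pep = np.asarray(pep, dtype=float)
    n = pep.size
    order = np.argsort(pep, kind="stable")
    srt = pep[order]
    if n == 0:
        return np.nextafter(0.0, 1.0), FdrReport(np.nextafter(0.0, 1.0),
                                                 np.zeros(0, np.int8), float("nan"), 0)
    means = np.cumsum(srt) / np.arange(1, n + 1)
    # a PEP of exactly 1 is a certain false positive and can never fall under
    # a strict cutoff tau < 1: never eligible
    ok = np.flatnonzero((means <= target_fdr) & (srt < 1.0))
    m = int(ok[-1]) + 1 if ok.size else 0
    if 0 < m < n and srt[m] == srt[m - 1]:
        # the cut falls inside a tie group: include it whole if affordable,
        # otherwise drop it whole
        hi = m
        while hi < n and srt[hi] == srt[m - 1]:
            hi += 1
        if means[hi - 1] <= target_fdr:
            m = hi
        else:
            lo = m - 1
            while lo > 0 and srt[lo - 1] == srt[m - 1]:
                lo -= 1
            m = lo
    if m == 0:
        tau = float(np.nextafter(0.0, 1.0))
        decisions = np.zeros(n, np.int8)
        return tau, FdrReport(tau, decisions, float("nan"), 0)
    tau = float(np.nextafter(srt[m - 1], 1.0))
    decisions = np.zeros(n, np.int8)
    decisions[order[:m]] = 1
    fdr = float(srt[:m].mean())
    return tau, FdrReport(tau=tau, decisions=decisions, fdr_at_tau=fdr, n_selected=m)


def pep_histogram_and_curve(pep: np.ndarray,
                            grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """FDR-control curve: estimated FDR and selection size along a tau grid."""
    pep = np.asarray(pep, dtype=float)
    if grid is None:
        grid = np.linspace(0.001, 0.999, 200)
    rows = []
    for tau in np.asarray(grid, dtype=float):
        rep = fdr_at_threshold(pep, float(tau))
        rows.append((float(tau), rep.n_selected, rep.fdr_at_tau))
    return pd.DataFrame(rows, columns=["tau", "n_selected", "fdr_hat"])
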