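"""Per-tool SV calls and their merger into an indexed position set.

A *merged position* is a cluster of calls, across callers, judged to describe
the same underlying variant.  The cluster set is the unit of inference for the
integration model: each position i carries a binary indicator row y_i
(which tools reported it), a support count x_i = sum_j y_ij >= 1, and the
reporting tools' quality scores where available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SVTYPES",
    "SVCall",
    "ToolMeta",
    "MergePolicy",
    "CallMatrix",
    "merge_calls",
]

#: Recognised SV type tokens after synonym normalisation.
SVTYPES = ("DEL", "INS", "DUP", "INV", "BND", "other")

_SVTYPE_SYNONYMS = {
    "DEL": "DEL",
    "DELETION": "DEL",
    "INS": "INS",
    "INSERTION": "INS",
    "DUP": "DUP",
    "DUP:TANDEM": "DUP",
    "DUP:INT": "DUP",
    "CNV": "DUP",
    "INV": "INV",
    "INVERSION": "INV",
    "BND": "BND",
    "TRA": "BND",
    "CTX": "BND",
}


def normalize_svtype(token: Optional[str]) -> str:
    """Map an SVTYPE token (or synonym) to a canonical type, else ``other``."""
    if token is None:
        return "other"
    return _SVTYPE_SYNONYMS.get(str(token).upper(), "other")


@dataclass
class ToolMeta:
    """Static description of one SV caller.

    ``has_score`` marks membership in the index set A of score-providing
    tools; ``(a, b)`` are that tool's fixed score bounds — observed scores at
    a bound are treated as censored values of a latent Gaussian.
    """

    name: str
    has_score: bool = True
    a: float = -np.inf
    b: float = np.inf
    score_field: str = "QUAL"

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"tool {self.name}: require a < b, got ({self.a}, {self.b})")


@dataclass
class SVCall:
    """One SV record extracted from a caller's VCF (1-based coordinates)."""

    tool_id: int
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    score: Optional[float] = None
    genotype: Optional[str] = None
    source_line: Optional[str] = None

    def __post_init__(self) -> None:
        if self.svtype != "INS" and self.end < self.pos:
            raise ValueError(f"end < pos for non-INS call at {self.chrom}:{self.pos}")


@dataclass
class MergePolicy:
    """Clustering thresholds for deciding that two calls describe one variant."""

    max_breakpoint_distance: int = 1000
    min_length_ratio: float = 0.7
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if self.max_breakpoint_distance < 0:
            raise ValueError("max_breakpoint_distance must be >= 0")
        if not 0.0 < self.min_length_ratio <= 1.0:
            raise ValueError("min_length_ratio must lie in (0, 1]")


@dataclass
class CallMatrix:
    """The merged evidence: indicators Y (n x J), counts X, scores S.

    ``S[i, j]`` is NaN unless tool j reported position i and provides scores;
    present scores are clipped into tool j's bounds so a bound value denotes a
    censored observation.  ``positions`` holds one representative record per
    row (the call from the lowest-index reporting tool).
    """

    Y: np.ndarray
    X: np.ndarray
    S: np.ndarray
    tools: list[ToolMeta]
    positions: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.Y.shape[0])

    @property
    def J(self) -> int:
        return int(self.Y.shape[1])

    @property
    def score_tools(self) -> tuple[int, ...]:
        """Indices of tools in the score index set A."""
        return tuple(j for j, t in enumerate(self.tools) if t.has_score)

    def validate(self) -> None:
        n, J = self.Y.shape
        if self.X.shape != (n,) or self.S.shape != (n, J) or len(self.tools) != J:
            raise ValueError("inconsistent CallMatrix shapes")
        if not np.array_equal(self.X, self.Y.sum(axis=1)):
            raise ValueError("X must equal the row sums of Y")
        if n and (self.X.min() < 1 or self.X.max() > J):
            raise ValueError("each position needs 1 <= x_i <= J")
        present = ~np.isnan(self.S)
        if np.any(present & (self.Y == 0)):
            raise ValueError("score present where y_ij = 0")
        for j, t in enumerate(self.tools):
            col = self.S[:, j]
            have = ~np.isnan(col)
            if not t.has_score and have.any():
                raise ValueError(f"scores present for score-less tool {t.name}")
            if have.any() and (np.any(col[have] < t.a) or np.any(col[have] > t.b)):
                raise ValueError(f"scores outside bounds for tool {t.name}")

    # -- serialisation (single TSV with a tool-metadata header comment) -----

    def to_tsv(self, path) -> None:
        import json

        df = self.positions.reset_index(drop=True).copy()
        for j, t in enumerate(self.tools):
            df[f"y_{t.name}"] = self.Y[:, j]
        for j, t in enumerate(self.tools):
            df[f"s_{t.name}"] = self.S[:, j]
        df["x"] = self.X
        meta = [
            {"name": t.name, "has_score": t.has_score, "a": repr(t.a), "b": repr(t.b),
             "score_field": t.score_field}
            for t in self.tools
        ]
        with open(path, "w") as fh:
            fh.write("#TOOLS\t" + json.dumps(meta) + "\n")
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "CallMatrix":
        import json

        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#TOOLS\t"):
                raise ValueError(f"{path} is not a serialized CallMatrix")
            meta = json.loads(header.split("\t", 1)[1])
            df = pd.read_csv(fh, sep="\t", na_values=["NA"])
        tools = [
            ToolMeta(m["name"], bool(m["has_score"]), float(m["a"]), float(m["b"]),
                     m["score_field"])
            for m in meta
        ]
        Y = df[[f"y_{t.name}" for t in tools]].to_numpy(dtype=np.int8)
        S = df[[f"s_{t.name}" for t in tools]].to_numpy(dtype=float)
        X = df["x"].to_numpy(dtype=np.int64)
        drop = [c for c in df.columns if c.startswith(("y_", "s_")) or c == "x"]
        positions = df.drop(columns=drop)
        cm = cls(Y=Y, X=X, S=S, tools=tools, positions=positions)
        cm.validate()
        return cm


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _abs_len(call: SVCall) -> int:
    return abs(int(call.svlen))


def _compatible(a: SVCall, b: SVCall, policy: MergePolicy) -> bool:
    """Single-linkage edge test between two calls in the same (chrom, type) stream."""
    if a.svtype == "INS" or b.svtype == "INS":
        dist = abs(a.pos - b.pos)
    else:
        dist = max(abs(a.pos - b.pos), abs(a.end - b.end))
    if dist > policy.max_breakpoint_distance:
        return False
    if a.svtype == "BND" or b.svtype == "BND":
        return True  # breakend length is not meaningful
    la, lb = _abs_len(a), _abs_len(b)
    if la == 0 and lb == 0:
        return True
    if min(la, lb) == 0:
        return False
    return min(la, lb) / max(la, lb) >= policy.min_length_ratio


def _sort_key(c: SVCall):
    return (c.pos, c.end, abs(c.svlen), c.tool_id,
            -np.inf if c.score is None else c.score)


def _cluster_stream(calls: list[SVCall], policy: MergePolicy) -> list[list[SVCall]]:
    """Single-linkage clustering of one sorted (chrom[, type]) stream."""
    done: list[list[SVCall]] = []
    active: list[list[SVCall]] = []
    for c in sorted(calls, key=_sort_key):
        still = []
        for cl in active:
            if max(m.pos for m in cl) < c.pos - policy.max_breakpoint_distance:
                done.append(cl)  # no later call can link to this cluster
            else:
                still.append(cl)
        active = still
        linked = [cl for cl in active if any(_compatible(m, c, policy) for m in cl)]
        if not linked:
            active.append([c])
        else:
            merged = [m for cl in linked for m in cl] + [c]
            active = [cl for cl in active if cl not in linked]
            active.append(merged)
    return done + active


def merge_calls(
    calls_by_tool: Sequence[Sequence[SVCall]],
    policy: MergePolicy | None = None,
    tools: Optional[Sequence[ToolMeta]] = None,
) -> CallMatrix:
    """Merge per-tool call lists into a :class:`CallMatrix`.

    Calls on the same chromosome (and, by default, of the same SV type) are
    clustered by single linkage: two calls are linked when their breakpoints
    lie within ``max_breakpoint_distance`` and their lengths agree within
    ``min_length_ratio``.  Within a cluster each tool contributes at most one
    call (highest score kept, leftmost on ties); the representative
    coordinates come from the lowest-index reporting tool.
    """
    policy = policy or MergePolicy()
    J = len(calls_by_tool)
    if J < 2:
        raise ValueError("merging requires at least two tools")
    if tools is None:
        tools = [ToolMeta(f"tool{j}", has_score=False) for j in range(J)]
    if len(tools) != J:
        raise ValueError("tools metadata length must match calls_by_tool")

    streams: dict[tuple, list[SVCall]] = {}
    for j, calls in enumerate(calls_by_tool):
        for c in calls:
            if c.tool_id != j:
                c = SVCall(j, c.chrom, c.pos, c.end, c.svtype, c.svlen,
                           c.score, c.genotype, c.source_line)
            key = (c.chrom, c.svtype) if policy.require_same_type else (c.chrom,)
            streams.setdefault(key, []).append(c)

    clusters: list[list[SVCall]] = []
    for key in sorted(streams):
        clusters.extend(_cluster_stream(streams[key], policy))

    rows = []
    for cl in clusters:
        best: dict[int, SVCall] = {}
        for c in sorted(cl, key=_sort_key):
            cur = best.get(c.tool_id)
            c_score = -np.inf if c.score is None else c.score
            if cur is None:
                best[c.tool_id] = c
            else:
                cur_score = -np.inf if cur.score is None else cur.score
                if c_score > cur_score:
                    best[c.tool_id] = c  # ties keep the leftmost (sorted order)
            del c_score
        rep = best[min(best)]
        rows.append((rep, best))

    rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].end, r[0].svtype))
    n = len(rows)
    Y = np.zeros((n, J), dtype=np.int8)
    S = np.full((n, J), np.nan)
    recs = []
    for i, (rep, best) in enumerate(rows):
        for j, c in best.items():
            Y[i, j] = 1
            if tools[j].has_score and c.score is not None:
                S[i, j] = float(np.clip(c.score, tools[j].a, tools[j].b))
        recs.append((rep.chrom, rep.pos, rep.end, rep.svtype, rep.svlen))
    positions = pd.DataFrame(recs, columns=["chrom", "pos", "end", "svtype", "svlen"])
    cm = CallMatrix(Y=Y, X=Y.sum(axis=1).astype(np.int64), S=S,
                    tools=list(tools), positions=positions)
    cm.validate()
    return cm
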