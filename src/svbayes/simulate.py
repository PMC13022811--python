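"""Synthetic call matrices with known truth, generated from the model itself.

The three study scenarios:

* **Case 1** — the model-true setting: n = 2000 positions, P(z=1) = 0.7,
  J = 5 equally weighted tools, ordered count probabilities
  omega1 = [.05, .10, .15, .25, .45] and omega0 = [.40, .25, .15, .12, .08];
  tools 3-5 (0-based 2-4) emit scores with mu1 = 2, mu0 = -2, sigma = 1, and
  tool 4 is left-censored at 0 (a = 0) while tool 5 is right-censored at 0
  (b = 0).
* **Case 2** — score mis-specification: as Case 1, but each generated score
  swaps its Gaussian component with probability 0.10 (applied independently
  per score, for every scoring tool).
* **Case 3** — voting mis-specification: as Case 1, but the true omega
  vectors are drawn fresh, unordered, from Dirichlet(50, 50, 50, 50, 50)
  per replicate; the fitted model keeps its ordering constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .callset import CallMatrix, ToolMeta
from .model import ModelParams

__all__ = ["SimConfig", "SimTruth", "make_case", "simulate",
           "attach_synthetic_coordinates"]


@dataclass
class SimConfig:
    """Generative settings for one synthetic call matrix."""

    n: int = 2000
    J: int = 5
    pi: float = 0.7
    omega1: np.ndarray = field(default_factory=lambda: np.array(
        [0.05, 0.10, 0.15, 0.25, 0.45]))
    omega0: np.ndarray = field(default_factory=lambda: np.array(
        [0.40, 0.25, 0.15, 0.12, 0.08]))
    v: Optional[np.ndarray] = None  # J x J inclusion weights; None = equal
    score_tools: tuple[int, ...] = (2, 3, 4)
    mu1: float | np.ndarray = 2.0
    mu0: float | np.ndarray = -2.0
    sigma1: float | np.ndarray = 1.0
    sigma0: float | np.ndarray = 1.0
    a: Optional[np.ndarray] = None  # per-tool lower bounds; None = unbounded
    b: Optional[np.ndarray] = None
    score_flip_prob: float = 0.0
    omega_random: Optional[float] = None  # Dirichlet concentration (Case 3)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega0 = np.asarray(self.omega0, dtype=float)
        for name, w in (("omega1", self.omega1), ("omega0", self.omega0)):
            if w.shape != (self.J,) or np.any(w < 0) or abs(w.sum() - 1) > 1e-8:
                raise ValueError(f"{name} must be a length-J probability vector")
        if not 0.0 <= self.score_flip_prob < 1.0:
            raise ValueError("score_flip_prob must lie in [0, 1)")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)
            if self.v.shape != (self.J, self.J) or \
                    not np.allclose(self.v.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("v columns must be probability vectors")

    def _per_tool(self, value) -> np.ndarray:
        out = np.full(self.J, np.nan)
        vals = np.broadcast_to(np.asarray(value, dtype=float),
                               (len(self.score_tools),))
        out[list(self.score_tools)] = vals
        return out

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.full(self.J, -np.inf) if self.a is None else np.asarray(self.a, float)
        b = np.full(self.J, np.inf) if self.b is None else np.asarray(self.b, float)
        return a, b

    def tools(self) -> list[ToolMeta]:
        a, b = self.bounds()
        return [ToolMeta(f"Tool{j + 1}", has_score=j in self.score_tools,
                         a=float(a[j]), b=float(b[j])) for j in range(self.J)]

    def params(self, omega1=None, omega0=None) -> ModelParams:
        """The generating parameters as a :class:`ModelParams` (no ordering check)."""
        a, b = self.bounds()
        v = self.v if self.v is not None else np.full((self.J, self.J), 1.0 / self.J)
        return ModelParams(
            pi=self.pi,
            omega1=self.omega1 if omega1 is None else np.asarray(omega1, float),
            omega0=self.omega0 if omega0 is None else np.asarray(omega0, float),
            mu1=self._per_tool(self.mu1), mu0=self._per_tool(self.mu0),
            sigma1=self._per_tool(self.sigma1), sigma0=self._per_tool(self.sigma0),
            a=a, b=b, v=v,
        )


@dataclass
class SimTruth:
    """Ground truth for one simulated call matrix."""

    z_true: np.ndarray
    params_true: ModelParams


def make_case(case_id: int, seed: Optional[int] = None) -> SimConfig:
    """The configuration of simulation Case 1, 2 or 3."""
    if case_id not in (1, 2, 3):
        raise ValueError(f"unknown simulation case {case_id}")
    a = np.array([-np.inf, -np.inf, -np.inf, 0.0, -np.inf])
    b = np.array([np.inf, np.inf, np.inf, np.inf, 0.0])
    cfg = SimConfig(a=a, b=b, seed=seed)
    if case_id == 2:
        cfg.score_flip_prob = 0.10
    elif case_id == 3:
        cfg.omega_random = 50.0
    return cfg


def _weighted_subsets(rng: np.random.Generator, w: np.ndarray, k: int,
                      m: int, J: int) -> np.ndarray:
    """m subsets of size k by successive weighted draws without replacement.

    Uses the Efraimidis-Spirakis keys u^(1/w): the k largest keys have
    exactly the sequential weighted-sampling distribution.
    """
    u = rng.random((m, J))
    with np.errstate(divide="ignore"):
        keys = np.log(u) / w  # monotone transform of u**(1/w); larger is better
    top = np.argpartition(-keys, kth=k - 1, axis=1)[:, :k]
    Y = np.zeros((m, J), dtype=np.int8)
    np.put_along_axis(Y, top, 1, axis=1)
    return Y


def simulate(cfg: SimConfig) -> tuple[CallMatrix, SimTruth]:
    """Draw one call matrix (with truth) from the generative model.

    Per position: z ~ Bernoulli(pi); x ~ Categorical(omega_z) on 1..J; the
    reporting set of size x is a weighted selection without replacement with
    weights v[:, x]; each reported score from a tool in A is a Gaussian draw
    from component z (swapped with probability ``score_flip_prob``) censored
    at that tool's bounds.
    """
    rng = np.random.default_rng(cfg.seed)
    n, J = cfg.n, cfg.J
    omega1, omega0 = cfg.omega1, cfg.omega0
    if cfg.omega_random is not None:
        conc = np.full(J, float(cfg.omega_random))
        omega1 = rng.dirichlet(conc)
        omega0 = rng.dirichlet(conc)

    z = (rng.random(n) < cfg.pi).astype(np.int8)
    u = rng.random(n)
    x = np.where(z == 1,
                 np.searchsorted(np.cumsum(omega1), u, side="right"),
                 np.searchsorted(np.cumsum(omega0), u, side="right")) + 1
    x = np.minimum(x, J).astype(np.int64)

    v = cfg.v if cfg.v is not None else np.full((J, J), 1.0 / J)
    Y = np.zeros((n, J), dtype=np.int8)
    for k in range(1, J + 1):
        rows = np.flatnonzero(x == k)
        if rows.size:
            Y[rows] = _weighted_subsets(rng, v[:, k - 1], k, rows.size, J)

    a, b = cfg.bounds()
    mu1 = cfg._per_tool(cfg.mu1)
    mu0 = cfg._per_tool(cfg.mu0)
    sg1 = cfg._per_tool(cfg.sigma1)
    sg0 = cfg._per_tool(cfg.sigma0)
    S = np.full((n, J), np.nan)
    for j in cfg.score_tools:
        rows = np.flatnonzero(Y[:, j] == 1)
        comp = z[rows].astype(int)
        if cfg.score_flip_prob > 0:
            flip = rng.random(rows.size) < cfg.score_flip_prob
            comp = np.where(flip, 1 - comp, comp)
        mu = np.where(comp == 1, mu1[j], mu0[j])
        sg = np.where(comp == 1, sg1[j], sg0[j])
        o = rng.normal(mu, sg)
        S[rows, j] = np.clip(o, a[j], b[j])

    positions = pd.DataFrame({
        "chrom": pd.array([pd.NA] * n),
        "pos": np.zeros(n, dtype=np.int64),
        "end": np.zeros(n, dtype=np.int64),
        "svtype": pd.array([pd.NA] * n),
        "svlen": np.zeros(n, dtype=np.int64),
    })
    cm = CallMatrix(Y=Y, X=x, S=S, tools=cfg.tools(), positions=positions)
    cm.validate()
    truth = SimTruth(z_true=z, params_true=cfg.params(omega1, omega0))
    return cm, truth


def attach_synthetic_coordinates(cm: CallMatrix, seed: int = 0,
                                 chrom: str = "chrS", spacing: int = 5000) -> CallMatrix:
    """Assign synthetic genomic coordinates so the VCF writer can be used.

    Positions are laid out on one synthetic chromosome with fixed spacing;
    types and lengths are drawn from a simple DEL/INS/DUP/INV mix.
    """
    rng = np.random.default_rng(seed)
    n = cm.n
    svtype = rng.choice(["DEL", "INS", "DUP", "INV"], size=n,
                        p=[0.5, 0.3, 0.12, 0.08])
    length = rng.integers(50, 2000, size=n)
    pos = spacing * (np.arange(n) + 1)
    end = np.where(svtype == "INS", pos, pos + length)
    svlen = np.where(svtype == "DEL", -length, length)
    cm.positions = pd.DataFrame({
        "chrom": chrom, "pos": pos, "end": end,
        "svtype": svtype, "svlen": svlen,
    })
    return cm
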