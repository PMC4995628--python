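"""Cancer network activity (CNA): expression-weighted communicability scoring.

For one sample with strictly positive expression x over a connected
interactome, each interaction {i, j} receives the weight

    w_ij = (x_j / sum_{k in U_i} x_k) * x_i + (x_i / sum_{k in U_j} x_k) * x_j

where U_i is the set of direct interactors of i — the expression of each
partner proportional to its share of the other's neighborhood. The weighted
adjacency W is then degree-normalized, W'_ij = w_ij / sqrt(d_i d_j) with
d_i = sum_j w_ij, which bounds the spectrum in [-1, 1] and corrects for hub
bias. Node centrality is the factorially damped closed-walk count
C(i) = (e^{W'})_ii (weighted subgraph centrality / self-communicability),
and the per-sample network activity score is CNA = sum_i C(i). Cohort scores
are mapped to (0, 1] via (x - a + 1) / (b - a + 1) with a, b the cohort
minimum and maximum.

Raw CNA is invariant to a global rescaling of the expression vector: w scales
linearly with x's scale and the sqrt(d_i d_j) normalization cancels it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .interactome import Interactome

__all__ = [
    "WeightedAdjacency",
    "edge_weights",
    "normalize_weights",
    "node_centrality",
    "node_centrality_series",
    "cna_score",
    "normalize_scores",
    "cna_profile",
]


@dataclass
class WeightedAdjacency:
    """A symmetric nonnegative weight matrix over an explicit node order."""

    nodes: list[str]
    W: np.ndarray
    stage: str  # "raw" | "normalized"

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node order")
        if not np.isfinite(W).all():
            raise ValueError("non-finite edge weights")
        if not np.allclose(W, W.T, rtol=0, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        self.W = W


def _expression_vector(x, nodes: list[str]) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [n for n in nodes if n not in x.index]
        if missing:
            raise ValueError(f"missing expression for {len(missing)} nodes, e.g. {missing[:3]}")
        vec = x.loc[nodes].to_numpy(dtype=float)
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (len(nodes),):
            raise ValueError("expression vector length does not match node count")
    if not np.isfinite(vec).all() or (vec <= 0).any():
        raise ValueError("expression must be strictly positive and finite")
    return vec


def edge_weights(inter: Interactome, x) -> WeightedAdjacency:
    """Expression-weighted adjacency for one sample.

    ``x`` may be a pandas Series over (at least) the node set, or an array in
    the order of ``sorted(inter.nodes)``. Requires a connected graph and
    strictly positive expression on every node.
    """
    if not inter.is_connected():
        raise ValueError("edge weights require a connected interactome")
    nodes = sorted(inter.nodes)
    vec = _expression_vector(x, nodes)
    A = nx.to_numpy_array(inter.graph, nodelist=nodes, dtype=float)
    nbr_sum = A @ vec  # sum_{k in U_i} x_k, positive on a connected graph
    # w_ij = x_i x_j (1/S_i + 1/S_j) on edges
    inv = 1.0 / nbr_sum
    W = A * np.outer(vec, vec) * (inv[:, None] + inv[None, :])
    return WeightedAdjacency(nodes, W, "raw")


def normalize_weights(wa: WeightedAdjacency) -> WeightedAdjacency:
    """Degree-normalize: W'_ij = w_ij / sqrt(d_i d_j), d_i = sum_j w_ij."""
    if wa.stage != "raw":
        raise ValueError("normalize_weights expects a raw-stage matrix")
    d = wa.W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("isolated node (zero weighted degree); graph must be connected")
    s = 1.0 / np.sqrt(d)
    return WeightedAdjacency(wa.nodes, wa.W * np.outer(s, s), "normalized")


def node_centrality(wa: WeightedAdjacency) -> pd.Series:
    """Diagonal of the matrix exponential: C(i) = (e^W)_ii.

    Computed by symmetric eigendecomposition, C(i) = sum_k e^{lambda_k} v_ik^2.
    With a zero diagonal and nonnegative weights every C(i) >= 1.
    """
    lam, V = scipy.linalg.eigh(wa.W)
    diag = (V * V) @ np.exp(lam)
    return pd.Series(diag, index=wa.nodes, name="centrality")


def node_centrality_series(wa: WeightedAdjacency, k_max: int = 40) -> pd.Series:
    """Truncated power-series oracle: diag(sum_{k<=k_max} W^k / k!).

    Independent verification path for :func:`node_centrality`; O(k n^3).
    """
    n = len(wa.nodes)
    term = np.eye(n)
    acc = np.eye(n)
    for k in range(1, k_max + 1):
        term = term @ wa.W / k
        acc += term
    return pd.Series(np.diag(acc).copy(), index=wa.nodes, name="centrality")


def cna_score(C: pd.Series) -> float:
    """Network activity of one sample: the sum of node centralities."""
    if len(C) == 0:
        raise ValueError("empty centrality vector")
    return float(np.asarray(C, dtype=float).sum())


def normalize_scores(raw) -> pd.Series:
    """Map cohort raw scores to (0, 1]: x -> (x - a + 1)/(b - a + 1).

    a, b are the cohort minimum and maximum, so the scores are
    cohort-dependent: recomputing on a different sample subset changes them.
    The maximum maps to exactly 1.
    """
    s = pd.Series(raw, dtype=float)
    if len(s) == 0:
        raise ValueError("no scores to normalize")
    a, b = s.min(), s.max()
    return (s - a + 1.0) / (b - a + 1.0)


def sample_centralities(inter: Interactome, x) -> pd.Series:
    """Per-node centralities for one sample (weights → normalize → exp)."""
    return node_centrality(normalize_weights(edge_weights(inter, x)))


def cna_profile(
    inter: Interactome,
    expr: pd.DataFrame,
    keep_centralities: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample raw and cohort-normalized CNA scores.

    Parameters
    ----------
    inter:
        Connected interactome (use :func:`cna.interactome.main_component`).
    expr:
        Gene × sample matrix aligned to the node set
        (:func:`cna.expression.align_to_network`).
    keep_centralities:
        Also return the sample × node centrality matrix (needed for
        tertile-deactivation analyses).

    Returns
    -------
    DataFrame indexed by sample with columns ``raw_cna`` and ``norm_cna``;
    with ``keep_centralities`` a second sample × node DataFrame.
    """
    nodes = sorted(inter.nodes)
    missing = [n for n in nodes if n not in expr.index]
    if missing:
        raise ValueError(
            f"expression not aligned to network: {len(missing)} nodes unmeasured"
        )
    raw = {}
    centr_rows = {}
    for sample in expr.columns:
        C = sample_centralities(inter, expr[sample])
        raw[sample] = cna_score(C)
        if keep_centralities:
            centr_rows[sample] = C
    scores = pd.DataFrame({"raw_cna": pd.Series(raw)})
    scores.index.name = "sample"
    scores["norm_cna"] = normalize_scores(scores["raw_cna"])
    if keep_centralities:
        centr = pd.DataFrame(centr_rows).T.loc[scores.index, nodes]
        centr.index.name = "sample"
        return scores, centr
    return scores
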