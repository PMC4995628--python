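"""Synthetic data generators emulating the analysis inputs.

Every downstream module is testable offline: connected scale-free (or
Erdős–Rényi) interactomes; strictly positive expression matrices with a
tunable planted co-expression of interacting gene pairs; IC50 matrices with
drug-class-specific planted correlations to a per-sample score; and
Loewe-additive or synergistic fixed-ratio dose-response surfaces with
multiplicative noise. Every generator is a pure function of its arguments
and the seed.

The co-expression construction uses a per-sample latent cell-state factor:
gene latents are z_g = sqrt(rho) * t + sqrt(1 - rho) * eps_g with t shared
within a sample, so any two genes (interacting pairs in particular) have
latent correlation rho; expression is exp(LATENT_SCALE * z + log-mean).
Exponentiation shrinks the Pearson correlation of the positive values to
(e^{s^2 rho} - 1)/(e^{s^2} - 1); at the default LATENT_SCALE s = 0.3 this is
~0.96 * rho (rho = 0.12 -> ~0.115), a calibration fixed once for the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome
from .synergy import DoseResponse, hill

__all__ = [
    "SimulationConfig",
    "simulate_network",
    "simulate_expression",
    "simulate_drug_response",
    "simulate_combination",
]

#: scale of the Gaussian latent behind the lognormal expression values
LATENT_SCALE = 0.3
#: mean log-intensity of simulated expression (arbitrary positive units)
LOG_MEAN = np.log(100.0)


@dataclass
class SimulationConfig:
    """Study-condition knobs shared by the generators.

    Defaults are desk-scale stand-ins for a cell-line pharmacogenomic
    screen: a few hundred network genes, ~100 cell lines, two drug classes
    with opposite planted CNA–IC50 correlation signs (broad-acting drugs
    negative, targeted drugs positive), interacting-pair co-expression
    rho = 0.12, and 2 % multiplicative assay noise on viability readouts.
    """

    seed: int
    n_nodes: int = 300
    n_samples: int = 100
    n_drugs: int = 30
    degree_model: str = "scale_free"  # or "erdos_renyi"
    attachment: int = 2               # preferential-attachment edges per node
    edge_prob: float = 0.02           # Erdős–Rényi edge probability
    coexpression_rho: float = 0.12
    class_effects: dict = field(
        default_factory=lambda: {"broad": -0.3, "targeted": 0.3})
    response_noise: float = 1.0       # sd of the residual IC50 component
    viability_noise: float = 0.02     # multiplicative dose-response noise sd
    missing_rate: float = 0.0         # fraction of IC50 entries masked
    alpha: float = 1.0                # Loewe interaction (1 additive, <1 synergy)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.coexpression_rho < 1.0:
            raise ValueError("coexpression_rho must lie in [0, 1)")


def _node_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_network(cfg: SimulationConfig) -> Interactome:
    """Connected simple undirected graph with the configured degree model.

    ``scale_free`` uses Barabási–Albert preferential attachment (connected
    by construction); ``erdos_renyi`` extracts the largest component when
    the draw is disconnected, reporting the reduction in the provenance tag.
    """
    if cfg.n_nodes < 4:
        raise ValueError("need >= 4 nodes")
    if cfg.degree_model == "scale_free":
        m = min(cfg.attachment, cfg.n_nodes - 1)
        g = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=cfg.seed)
        tag = f"synthetic scale-free n={cfg.n_nodes} m={m} seed={cfg.seed}"
    elif cfg.degree_model == "erdos_renyi":
        g = nx.gnp_random_graph(cfg.n_nodes, cfg.edge_prob, seed=cfg.seed)
        tag = f"synthetic G(n,p) n={cfg.n_nodes} p={cfg.edge_prob} seed={cfg.seed}"
        if not nx.is_connected(g):
            comp = max(nx.connected_components(g), key=len)
            g = g.subgraph(comp).copy()
            tag += f" [largest component: {g.number_of_nodes()} nodes]"
    else:
        raise ValueError(f"unknown degree model: {cfg.degree_model!r}")
    if g.number_of_edges() == 0:
        raise ValueError("simulated graph has no edges; raise edge_prob or n_nodes")
    labels = _node_labels(cfg.n_nodes)
    g = nx.relabel_nodes(g, {i: labels[i] for i in g.nodes})
    return Interactome(g, tag)


def simulate_expression(inter: Interactome, cfg: SimulationConfig) -> pd.DataFrame:
    """Strictly positive gene × sample matrix with planted pair co-expression.

    Latent correlation between any two genes equals ``cfg.coexpression_rho``
    (shared cell-state factor construction; see module docstring for the
    rho → Pearson calibration after exponentiation).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nodes = sorted(inter.nodes)
    rho = cfg.coexpression_rho
    t = rng.standard_normal(cfg.n_samples)               # cell-state factor
    eps = rng.standard_normal((len(nodes), cfg.n_samples))
    z = np.sqrt(rho) * t[None, :] + np.sqrt(1.0 - rho) * eps
    values = np.exp(LOG_MEAN + LATENT_SCALE * z)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    return pd.DataFrame(values, index=pd.Index(nodes, name="gene"), columns=samples)


def simulate_drug_response(
    cna_scores: pd.Series,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IC50 matrix with class-specific planted correlations to the CNA scores.

    Drugs are split evenly across ``cfg.class_effects`` (at least two
    classes); each drug's normalized IC50 vector is
    ``r * z(CNA) + sqrt(1 - r^2) * noise`` with r the class target
    correlation, so the per-drug empirical PCC fluctuates around r. A
    ``missing_rate`` fraction of entries is masked at random.

    Returns ``(responses, annotations)``: drug × sample IC50 values, and a
    per-drug annotation table with ``drug_class`` and a single/multiple node
    perturbation tag (broad-acting classes are "multiple").
    """
    if len(cfg.class_effects) < 2:
        raise ValueError("need >= 2 drug classes")
    for r in cfg.class_effects.values():
        if abs(r) >= 1:
            raise ValueError("target correlations must satisfy |r| < 1")
    rng = np.random.default_rng(cfg.seed + 2)
    z = (cna_scores - cna_scores.mean()) / cna_scores.std(ddof=0)
    zvec = z.to_numpy(dtype=float)
    classes = sorted(cfg.class_effects)
    rows, ann = [], []
    for i in range(cfg.n_drugs):
        klass = classes[i % len(classes)]
        r = cfg.class_effects[klass]
        noise = rng.standard_normal(len(zvec))
        y = r * zvec + np.sqrt(1.0 - r * r) * noise * cfg.response_noise
        rows.append(y)
        ann.append({"drug": f"D{i:03d}", "drug_class": klass,
                    "perturbation": "multiple" if r < 0 else "single"})
    resp = pd.DataFrame(rows, index=[a["drug"] for a in ann], columns=cna_scores.index)
    resp.index.name = "drug"
    if cfg.missing_rate > 0:
        mask = rng.random(resp.shape) < cfg.missing_rate
        resp = resp.mask(mask)
    annotations = pd.DataFrame(ann).set_index("drug")
    return resp, annotations


def _loewe_response(d1: float, d2: float, d50_1, m_1, d50_2, m_2, alpha: float) -> float:
    """Fraction unaffected of a (d1, d2) dose pair under scaled Loewe additivity.

    Solves d1/D1(fa) + d2/D2(fa) = alpha for fa, where D_i(fa) is the
    single-drug dose achieving fraction affected fa. At alpha = 1 this is
    exact Loewe additivity; alpha < 1 means the combination needs
    proportionally smaller doses (synergy), alpha > 1 larger (antagonism) —
    by construction the true combination index at every level equals alpha.
    """
    from scipy.optimize import brentq

    def g(fa):
        e1 = d50_1 * (fa / (1 - fa)) ** (1.0 / m_1)
        e2 = d50_2 * (fa / (1 - fa)) ** (1.0 / m_2)
        return d1 / e1 + d2 / e2 - alpha

    lo, hi = 1e-12, 1 - 1e-12
    # g decreases from +inf (fa -> 0) to -alpha (fa -> 1)
    if g(hi) >= 0:       # doses large enough to saturate the effect
        return 0.0
    fa = brentq(g, lo, hi, xtol=1e-14)
    return 1.0 - fa


def simulate_combination(
    cfg: SimulationConfig,
    d50_1: float = 1.0,
    m_1: float = 2.0,
    d50_2: float = 2.0,
    m_2: float = 1.5,
    ratio: float = 1.0,
    n_doses: int = 8,
    n_replicates: int = 1,
) -> tuple[DoseResponse, DoseResponse, DoseResponse]:
    """Single-drug and fixed-ratio combination viability series.

    Single drugs follow the median-effect model exactly; the combination at
    drug1-equivalent dose d pairs (d, ratio*d) and responds per scaled Loewe
    additivity with interaction ``cfg.alpha``. Multiplicative Gaussian noise
    of sd ``cfg.viability_noise`` is applied; with ``n_replicates`` > 1 the
    returned responses are replicate means. Dose grids are log-spaced
    (factor-8 span) around each curve's half-effect point.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    alpha = cfg.alpha

    def noisy(y: np.ndarray) -> np.ndarray:
        if cfg.viability_noise <= 0:
            return np.clip(y, 0.0, 1.2)
        reps = y[None, :] * (1.0 + cfg.viability_noise
                             * rng.standard_normal((n_replicates, len(y))))
        return np.clip(reps.mean(axis=0), 1e-6, 1.2)

    x1 = np.geomspace(d50_1 / 8, d50_1 * 8, n_doses)
    x2 = np.geomspace(d50_2 / 8, d50_2 * 8, n_doses)
    dr1 = DoseResponse(x1, noisy(hill(x1, d50_1, m_1)), "drug1")
    dr2 = DoseResponse(x2, noisy(hill(x2, d50_2, m_2)), "drug2")

    d_half = alpha / (1.0 / d50_1 + ratio / d50_2)  # additive-combo half-effect dose
    xc = np.geomspace(d_half / 8, d_half * 8, n_doses)
    yc = np.array([_loewe_response(d, ratio * d, d50_1, m_1, d50_2, m_2, alpha)
                   for d in xc])
    drc = DoseResponse(xc, noisy(yc), "combo", ratio=ratio)
    return dr1, dr2, drc
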