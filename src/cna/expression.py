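"""Expression-matrix preparation: probe collapse, network alignment, imputation.

Matrices are pandas DataFrames with gene identifiers as the index and sample
identifiers as columns; values are strictly positive normalized intensities.
Genes absent from the array are imputed with the per-sample mean over
measured genes so every network node carries an expression value.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .interactome import Interactome

logger = logging.getLogger(__name__)


def validate_expression(expr: pd.DataFrame, floor_zeros: bool = True) -> pd.DataFrame:
    """Check positivity/uniqueness invariants of an expression matrix.

    Negative values are a hard error. Zeros are floored at
    ``1e-8 * global mean`` (the edge-weight ratios divide by neighborhood
    expression sums, so exact zeros are not representable); a warning is
    emitted when flooring occurs.
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    vals = expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    if (vals < 0).any():
        raise ValueError("expression values must be positive")
    if (vals == 0).any():
        if not floor_zeros:
            raise ValueError("expression values must be strictly positive")
        eps = 1e-8 * vals.mean()
        n0 = int((vals == 0).sum())
        warnings.warn(f"floored {n0} zero expression values at {eps:.3g}")
        expr = expr.mask(expr == 0, eps)
    return expr


def collapse_probes(probes: pd.DataFrame, mode: str = "max_sd") -> pd.DataFrame:
    """Collapse a probe-level table to one expression row per gene.

    Parameters
    ----------
    probes:
        DataFrame whose first column is the probe id, second column the gene
        id, remaining columns per-sample values. (A DataFrame indexed by
        probe with a ``gene`` first column is also accepted.)
    mode:
        ``"max_sd"`` keeps, per gene, the probe with the largest
        across-sample standard deviation (population SD, ties broken by
        probe-id sort order); ``"mean"`` averages probes per gene per sample.
    """
    if probes.empty:
        raise ValueError("empty probe table")
    if mode not in ("max_sd", "mean"):
        raise ValueError(f"unknown collapse mode: {mode!r}")
    df = probes
    if df.index.name in (None, "") and df.shape[1] >= 3:
        df = df.set_index(df.columns[0])
    gene_col = df.columns[0]
    values = df.drop(columns=[gene_col]).astype(float)
    genes = df[gene_col].astype(str)

    if mode == "mean":
        out = values.groupby(genes).mean()
    else:
        sd = values.std(axis=1, ddof=0)
        # stable ordering: sort by probe id, then pick the max-SD probe per gene
        order = pd.DataFrame({"gene": genes, "sd": sd}).sort_index()
        keep = order.groupby("gene")["sd"].idxmax()
        out = values.loc[keep]
        out.index = keep.index
    out.index.name = "gene"
    return out.sort_index()


def align_to_network(
    expr: pd.DataFrame,
    inter: Interactome,
    impute: str = "global_mean",
) -> pd.DataFrame:
    """Restrict/extend an expression matrix to exactly the network node set.

    Genes measured but absent from the network are dropped. Network nodes
    without a measurement receive, per sample, the mean over all measured
    genes of that sample. The imputed-gene count is recorded in
    ``result.attrs["n_imputed"]``.
    """
    if impute != "global_mean":
        raise ValueError(f"unknown imputation mode: {impute!r}")
    nodes = sorted(inter.nodes)
    measured = [g for g in nodes if g in expr.index]
    if not measured:
        raise ValueError("no overlap between expression genes and network nodes")
    expr = validate_expression(expr)
    out = pd.DataFrame(index=pd.Index(nodes, name="gene"), columns=expr.columns, dtype=float)
    out.loc[measured] = expr.loc[measured].to_numpy(dtype=float)
    missing = [g for g in nodes if g not in expr.index]
    if missing:
        sample_means = expr.loc[measured].mean(axis=0)
        out.loc[missing] = np.broadcast_to(
            sample_means.to_numpy(dtype=float), (len(missing), len(expr.columns))
        )
        logger.info("imputed %d network genes absent from the array", len(missing))
    out.attrs["n_imputed"] = len(missing)
    out.attrs["n_dropped"] = int(len(expr.index) - len(measured))
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample TSV (first column gene id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return validate_expression(df)


def read_probe_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe table TSV (probe id, gene id, then per-sample values)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise ValueError("probe table needs probe, gene and >=1 sample column")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
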