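"""Plain-text readers/writers for the tool's tabular interchange formats.

All tables are TSV with explicit headers (dose-response series are CSV);
lines starting with ``#`` carry metadata (e.g. seeds) and are skipped on
read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synergy import DoseResponse


def read_response_tsv(path: str | Path) -> pd.DataFrame:
    """Drug × sample normalized IC50 matrix (first column drug id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "drug"
    return df


def write_response_tsv(resp: pd.DataFrame, path: str | Path) -> None:
    resp.to_csv(path, sep="\t", index_label="drug")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Per-sample CNA score table (columns sample, raw_cna, norm_cna)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df


def write_scores_tsv(scores: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        scores.to_csv(fh, sep="\t", index_label="sample")


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Per-drug annotation table (first column drug id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "drug"
    return df


def read_dose_response_csv(path: str | Path) -> list[DoseResponse]:
    """Dose-response CSV with columns label, dose, response[, replicate, ratio].

    Replicate rows sharing a (label, dose) are averaged before the series is
    assembled (replicate means are the default fitting input).
    """
    df = pd.read_csv(path, comment="#")
    required = {"label", "dose", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"dose-response file needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        ratio = None
        if "ratio" in grp.columns and grp["ratio"].notna().any():
            ratios = grp["ratio"].dropna().unique()
            if len(ratios) > 1:
                raise ValueError(f"series {label!r} has inconsistent ratios")
            ratio = float(ratios[0])
        means = grp.groupby("dose", sort=True)["response"].mean()
        out.append(DoseResponse(means.index.to_numpy(), means.to_numpy(),
                                str(label), ratio=ratio))
    if not out:
        raise ValueError(f"no dose-response series in {path}")
    return out


def write_dose_response_csv(series: list[DoseResponse], path: str | Path) -> None:
    rows = []
    for dr in series:
        for d, r in zip(dr.doses, dr.responses):
            row = {"label": dr.label, "dose": d, "response": r}
            if dr.ratio is not None:
                row["ratio"] = dr.ratio
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
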