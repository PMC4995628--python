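"""CNA–drug-response association testing.

Correlates per-sample network-activity scores with normalized IC50 profiles
(pairwise-complete, minimum 3 shared samples), assigns empirical
significance by permuting sample identities, compares coefficient
distributions between drug groups (rank-sum and label-permutation tests),
stratifies correlations by mutation status with Fisher-z per-drug contrasts,
and supports the centrality-tertile "deactivation" analysis in which the
centralities of a node subset are replaced by the component-wide mean.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SAMPLES = 3  # minimum pairwise-complete n for any correlation

TERTILE_LABELS = ("low", "mid", "high")


def _pairwise_complete(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    shared = x.index.intersection(y.index)
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    return xv[ok], yv[ok]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method: {method!r}")


def correlate_profiles(
    cna: pd.Series,
    resp: pd.DataFrame,
    method: str = "pearson",
    min_n: int = MIN_SAMPLES,
) -> pd.DataFrame:
    """Correlate CNA scores with each drug's IC50 profile.

    ``resp`` is drug × sample; missing IC50 values are handled
    pairwise-complete. Drugs with fewer than ``min_n`` shared non-missing
    samples, or with a degenerate (constant) profile, are skipped with a
    warning.

    Returns a DataFrame indexed by drug with columns ``r`` and ``n``.
    """
    records = {}
    for drug in resp.index:
        x, y = _pairwise_complete(cna, resp.loc[drug])
        if len(x) < min_n:
            logger.warning("drug %s skipped: only %d shared samples", drug, len(x))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("drug %s skipped: constant profile", drug)
            continue
        records[drug] = {"r": _corr(x, y, method), "n": len(x)}
    if not records:
        raise ValueError("no drug qualified for correlation")
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "drug"
    out["n"] = out["n"].astype(int)
    return out


def permutation_test(
    cna: pd.Series,
    resp_row: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Two-sided empirical p for one CNA–IC50 correlation.

    Permutes the CNA–sample identities ``n_perm`` times and applies the
    add-one estimator p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), so p
    is never exactly zero. Returns ``(r_obs, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, y = _pairwise_complete(cna, resp_row)
    if len(x) < MIN_SAMPLES:
        raise ValueError("fewer than 3 shared samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: correlation undefined")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    r_obs = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    # vectorized permuted Pearson: standardize once, shuffle x columns
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = len(x)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = (xs[idx] @ ys) / n
    p = (1.0 + np.count_nonzero(np.abs(r_perm) >= abs(r_obs))) / (n_perm + 1.0)
    return r_obs, float(p)


def associate(
    cna: pd.Series,
    resp: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlations plus permutation p for every qualifying drug."""
    recs = correlate_profiles(cna, resp, method=method)
    rng = np.random.default_rng(seed)
    pvals = {}
    for drug in recs.index:
        sub = int(rng.integers(0, 2**31 - 1))
        _, pvals[drug] = permutation_test(cna, resp.loc[drug], n_perm, sub, method)
    recs["p_perm"] = pd.Series(pvals)
    return recs


def compare_drug_groups(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p for two groups of correlation coefficients.

    Exact enumeration when both groups have <= 10 members and no ties span
    the groups; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= 10 and len(b) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


def group_label_permutation(
    records: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical p per category pair by shuffling category labels over drugs.

    ``records`` must carry an ``r`` column indexed by drug; ``labels`` maps
    drug → category. For each pair of categories with >= 2 drugs each, the
    observed rank-sum statistic is compared against ``n_perm`` label
    shuffles (add-one estimator). Categories with a single drug are skipped
    with a warning.
    """
    shared = records.index.intersection(labels.index)
    r = records.loc[shared, "r"]
    lab = labels.loc[shared]
    counts = lab.value_counts()
    cats = sorted(counts[counts >= 2].index)
    for c in counts[counts < 2].index:
        warnings.warn(f"category {c!r} has <2 drugs; its pairs are skipped")
    if len(cats) < 2:
        raise ValueError("need >=2 categories with >=2 drugs each")
    rng = np.random.default_rng(seed)
    rows = []
    for ca, cb in combinations(cats, 2):
        in_a = (lab == ca).to_numpy()
        in_b = (lab == cb).to_numpy()
        mask = in_a | in_b
        sub_ranks = stats.rankdata(r.to_numpy()[mask])
        obs = _ranksum_stat(sub_ranks, in_a[mask])
        n_ab = int(mask.sum())
        n_a = int(in_a.sum())
        count = 0
        for _ in range(n_perm):
            perm_a = np.zeros(n_ab, dtype=bool)
            perm_a[rng.choice(n_ab, size=n_a, replace=False)] = True
            if abs(_ranksum_stat(sub_ranks, perm_a)) >= abs(obs):
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        rows.append({"category_a": ca, "category_b": cb,
                     "n_a": n_a, "n_b": n_ab - n_a, "p_perm": p})
    return pd.DataFrame(rows)


def _ranksum_stat(ranks: np.ndarray, in_a: np.ndarray) -> float:
    """Centered rank-sum of group A within the pooled ranking."""
    n, n_a = len(ranks), int(in_a.sum())
    return float(ranks[in_a].sum() - n_a * (n + 1) / 2.0)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for H0: equal population correlations (Fisher z)."""
    if min(n1, n2) < 4:
        raise ValueError("Fisher z comparison needs n >= 4 per stratum")
    z1, z2 = np.arctanh(np.clip(r1, -1 + 1e-15, 1 - 1e-15)), np.arctanh(
        np.clip(r2, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z1 - z2) / se))


def stratified_association(
    cna: pd.Series,
    resp: pd.DataFrame,
    mut_row: pd.Series,
    alpha: float = 0.05,
    method: str = "pearson",
) -> dict:
    """Correlations within mutated vs wild-type sample strata.

    ``mut_row`` is a binary (1 = mutated/amplified) sample vector. Per-drug
    stratum contrast uses the Fisher z-transform; the stratum-level
    distribution shift of coefficients uses the rank-sum test.

    Returns a dict with keys ``mutated``, ``wildtype`` (per-drug record
    frames), ``per_drug`` (r/n per stratum plus ``p_diff`` and ``flagged``),
    and ``distribution_shift_p``.
    """
    mut_row = mut_row.dropna()
    mut_samples = mut_row.index[mut_row.astype(float) == 1]
    wt_samples = mut_row.index[mut_row.astype(float) == 0]
    strata = {}
    for name, samples in (("mutated", mut_samples), ("wildtype", wt_samples)):
        samples = cna.index.intersection(samples)
        if len(samples) < MIN_SAMPLES:
            raise ValueError(f"{name} stratum has <{MIN_SAMPLES} samples")
        strata[name] = correlate_profiles(
            cna.loc[samples], resp.loc[:, resp.columns.intersection(samples)],
            method=method)
    per_drug = strata["mutated"].join(
        strata["wildtype"], how="inner", lsuffix="_mut", rsuffix="_wt")
    pdiff = {}
    for drug, row in per_drug.iterrows():
        if min(row["n_mut"], row["n_wt"]) < 4:
            pdiff[drug] = np.nan
            continue
        pdiff[drug] = fisher_z_compare(
            row["r_mut"], int(row["n_mut"]), row["r_wt"], int(row["n_wt"]))
    per_drug["p_diff"] = pd.Series(pdiff)
    per_drug["flagged"] = per_drug["p_diff"] < alpha
    shift_p = compare_drug_groups(
        strata["mutated"]["r"].to_numpy(), strata["wildtype"]["r"].to_numpy())
    return {
        "mutated": strata["mutated"],
        "wildtype": strata["wildtype"],
        "per_drug": per_drug,
        "distribution_shift_p": shift_p,
    }


def centrality_tertiles(C: pd.Series, standardize: bool = True) -> pd.Series:
    """Split nodes into low/mid/high tertiles of (standardized) centrality.

    Centralities are z-standardized (cosmetic — the split is rank-based),
    then nodes are ordered by (value, label) — the label tie-break makes the
    assignment deterministic — and cut at the 1/3 and 2/3 boundaries, with
    remainders absorbed by the lower tertiles (low first, then mid).
    """
    if len(C) < 3:
        raise ValueError("tertiles need >=3 nodes")
    vals = C.astype(float)
    if vals.nunique() == 1:
        raise ValueError("all centralities identical; tertiles undefined")
    if standardize:
        vals = (vals - vals.mean()) / vals.std(ddof=0)
    # stable sort on pre-sorted labels => ties resolve by node label
    order = vals.loc[sorted(vals.index)].sort_values(kind="mergesort").index
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = pd.Series(index=C.index, dtype=object, name="tertile")
    start = 0
    for size, name in zip(sizes, TERTILE_LABELS):
        labels.loc[order[start:start + size]] = name
        start += size
    return labels


def deactivated_cna(
    centralities: pd.DataFrame,
    tertiles: pd.Series,
    active,
) -> pd.Series:
    """CNA after replacing non-active nodes' centralities by the network mean.

    ``centralities`` is the sample × node matrix from
    :func:`cna.core.cna_profile` (``keep_centralities=True``); ``active`` is
    a tertile label or set of labels whose nodes keep their own centrality.
    All other nodes receive, per sample, the mean centrality over the whole
    component — so deactivating everything conserves the CNA total exactly.
    """
    if isinstance(active, str):
        active = {active}
    unknown = set(active) - set(TERTILE_LABELS)
    if unknown:
        raise ValueError(f"unknown tertile label(s): {sorted(unknown)}")
    uncovered = centralities.columns.difference(tertiles.index)
    if len(uncovered):
        raise ValueError(f"tertile labeling misses {len(uncovered)} nodes")
    keep = tertiles.loc[centralities.columns].isin(active).to_numpy()
    Cmat = centralities.to_numpy(dtype=float)
    means = Cmat.mean(axis=1, keepdims=True)
    mod = np.where(keep[None, :], Cmat, means)
    return pd.Series(mod.sum(axis=1), index=centralities.index, name="modified_cna")


def select_uncorrelated_pairs(
    resp: pd.DataFrame,
    anchor: str,
    threshold_p: float = 0.05,
    min_n: int = MIN_SAMPLES,
) -> pd.DataFrame:
    """Partner drugs whose IC50 profile is uncorrelated with the anchor's.

    Pairwise Pearson r with the t-approximation p; partners with
    p >= ``threshold_p`` are candidate combination partners. Pairs with
    fewer than ``min_n`` shared samples are skipped with a warning.
    """
    if anchor not in resp.index:
        raise ValueError(f"anchor drug {anchor!r} not in response matrix")
    rows = {}
    anchor_row = resp.loc[anchor]
    for drug in resp.index:
        if drug == anchor:
            continue
        x, y = _pairwise_complete(anchor_row, resp.loc[drug])
        if len(x) < min_n:
            logger.warning("pair (%s, %s) skipped: %d shared samples", anchor, drug, len(x))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("pair (%s, %s) skipped: constant profile", anchor, drug)
            continue
        res = stats.pearsonr(x, y)
        rows[drug] = {"r": float(res.statistic), "p": float(res.pvalue),
                      "n": len(x), "candidate": bool(res.pvalue >= threshold_p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "drug"
    return out
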