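"""Final feature ranking and the univariate / enrichment comparators.

After K is tuned and the model's significance established, a final sparse
PLS-DA fit on *all* samples yields the selected SNVs, ranked by the absolute
value of their predictive coefficients (loadings).  Three companions put the
multivariate ranking in context:

* a 2 x 4 Fisher exact test per SNV locus (groups x alleles A,C,G,T), which
  sees only the differential *abundance* of alleles across groups;
* a Wilcoxon rank-sum test on the continuous allele fractions, which sees
  the differential *magnitude*;
* a Friedman rank-sum test asking whether the multivariate and univariate
  rankings of the selected features systematically disagree.

Finally, a resampling null asks whether the genes hosting selected SNVs are
enriched for significant allele-specific expression (ASE): the observed
fraction of significant gene/sample ASE pairs among selected genes is
compared to equally sized random gene subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SnvMatrix, parse_snv_key
from .splsda import fit_splsda_raw

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Final ranking
# ---------------------------------------------------------------------------


def final_rank(
    m: SnvMatrix,
    optimal_k: int,
    n_components: int = 1,
    with_univariate: bool = True,
) -> pd.DataFrame:
    """Train on all samples at the tuned K and rank selected SNVs by |loading|.

    Returns a DataFrame ordered by descending absolute loading (component-
    major for multi-component models; ties broken by feature order), with
    columns ``snv_key, component, loading, abs_loading, rank, gene, region``
    and, when requested, ``fisher_p`` and ``wilcoxon_p``.  The univariate
    columns never alter the multivariate ordering.
    """
    X = m.values.to_numpy(dtype=float).T
    y = m.labels.to_numpy()
    names = list(m.values.index)
    model = fit_splsda_raw(X, y, optimal_k, n_components=n_components, feature_names=names)
    rows = []
    for h in range(model.n_components):
        w = model.weights[:, h]
        sel = np.flatnonzero(w != 0)
        order = sel[np.argsort(-np.abs(w[sel]), kind="stable")]
        for i in order:
            rows.append(
                {
                    "snv_key": names[i],
                    "component": h + 1,
                    "loading": float(w[i]),
                    "abs_loading": float(abs(w[i])),
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = np.arange(1, len(out) + 1)
    ann = m.annotations
    out["gene"] = [ann.at[k, "gene"] if k in ann.index else "" for k in out["snv_key"]]
    out["region"] = [ann.at[k, "region"] if k in ann.index else "" for k in out["snv_key"]]
    if with_univariate:
        fisher, wilcox = [], []
        for k in out["snv_key"]:
            try:
                fisher.append(fisher_exact_2x4(allele_count_table(m, k)))
            except ValueError:
                fisher.append(np.nan)
            af = m.values.loc[k]
            a = af[m.labels == model.groups[0]].dropna().to_numpy()
            b = af[m.labels == model.groups[1]].dropna().to_numpy()
            try:
                wilcox.append(wilcoxon_af(a, b))
            except ValueError:
                wilcox.append(np.nan)
        out["fisher_p"] = fisher
        out["wilcoxon_p"] = wilcox
    return out


# ---------------------------------------------------------------------------
# 2 x 4 Fisher exact test on allele abundance
# ---------------------------------------------------------------------------


def allele_count_table(m: SnvMatrix, snv_key: str) -> pd.DataFrame:
    """Groups x (A, C, G, T) counts of samples with detectable reads per allele.

    A sample enters only when its coverage met the threshold (cell non-NA).
    The reference allele is detectable when AF < 1, the variant allele when
    AF > 0 — i.e. at least one read supports the allele; a heterozygous
    sample contributes to both columns.
    """
    _chrom, _pos, ref, alt = parse_snv_key(snv_key)
    af = m.values.loc[snv_key]
    groups = m.groups
    table = pd.DataFrame(0, index=pd.Index(groups, name="group"), columns=list(_BASES))
    for g in groups:
        vals = af[m.labels == g].dropna()
        table.at[g, ref] += int((vals < 1.0).sum())
        table.at[g, alt] += int((vals > 0.0).sum())
    return table


def fisher_exact_2x4(table) -> float:
    """Exact two-sided p for independence of group and allele in a 2 x c table.

    Conditions on both margins (multivariate hypergeometric null) and sums
    the probabilities of every margin-preserving table as or less probable
    than the observed one.  All arithmetic is exact integer combinatorics;
    zero-margin columns are dropped first.  Feasible for study-scale sample
    counts (the enumeration is over first-row vectors only).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero table: test undefined")
    col = t.sum(axis=0)
    t = t[:, col > 0]
    col = col[col > 0]
    r1 = int(t[0].sum())
    n_cols = t.shape[1]
    if n_cols == 1:
        return 1.0

    obs_num = 1
    for j in range(n_cols):
        obs_num *= comb(int(col[j]), int(t[0, j]))

    # enumerate first-row vectors x (0 <= x_j <= col_j, sum = r1); integer
    # table weight = prod_j C(col_j, x_j); p = sum of weights <= observed
    # weight, over the constant denominator C(N, r1)
    total_le = 0
    suffix = np.cumsum(col[::-1])[::-1]  # max attainable sum from column j on

    def recurse(j: int, remaining: int, num: int) -> None:
        nonlocal total_le
        if j == n_cols - 1:
            if 0 <= remaining <= col[j]:
                w = num * comb(int(col[j]), remaining)
                if w <= obs_num:
                    total_le += w
            return
        lo = max(0, remaining - int(suffix[j + 1]))
        hi = min(int(col[j]), remaining)
        for xj in range(lo, hi + 1):
            recurse(j + 1, remaining - xj, num * comb(int(col[j]), xj))

    recurse(0, r1, 1)
    denom = comb(int(col.sum()), r1)
    return total_le / denom


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum on allele fractions
# ---------------------------------------------------------------------------


def wilcoxon_af(af_group_a, af_group_b) -> float:
    """Two-sided rank-sum p comparing allele-fraction distributions.

    NA entries must already be removed (coverage failures carry no
    information); zeros are genuine observations and stay in.  Small
    tie-free samples (combined n <= 25) use the exact null distribution,
    everything else the normal approximation with continuity and tie
    correction.
    """
    a = np.asarray(af_group_a, dtype=float)
    b = np.asarray(af_group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test undefined: a group has no observed values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Friedman comparison of rankings
# ---------------------------------------------------------------------------


def friedman_compare(rankings) -> tuple[float, float]:
    """Friedman rank-sum test across >=2 rankings of the same feature set.

    Features are blocks, ranking methods are treatments.  Each element of
    ``rankings`` is a complete rank vector over the features (univariate
    methods are ranked by ascending p-value over the selected set).  Values
    are re-ranked within each block with midrank ties; the chi-square
    statistic uses the standard tie correction and (methods - 1) degrees of
    freedom.  Fully tied data yield statistic 0 and p = 1.
    """
    data = np.asarray([np.asarray(r, dtype=float) for r in rankings], dtype=float).T
    n, k = data.shape  # blocks x methods
    if k < 2 or n < 2:
        raise ValueError("need >=2 methods and >=2 features")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rj = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum_i sum_t (t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for i in range(n):
        _vals, counts = np.unique(data[i], return_counts=True)
        ties += float((counts**3 - counts).sum())
    corr = 1.0 - ties / (n * k * (k * k - 1))
    if corr <= 0:
        return 0.0, 1.0
    stat = chi / corr
    p = float(stats.chi2.sf(stat, k - 1))
    return float(stat), p


# ---------------------------------------------------------------------------
# ASE enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    fold: float  # observed / mean(null); NaN when the null mean is zero

    @property
    def percent(self) -> float:
        return 100.0 * self.observed_fraction


def ase_enrichment(
    selected_genes,
    universe_genes,
    ase_calls: pd.DataFrame,
    n_subsets: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Resampling enrichment of significant ASE among selected genes.

    ``ase_calls`` holds one row per testable gene/sample pair with columns
    ``gene`` and ``significant`` (an optional boolean ``testable`` column
    restricts the denominator).  The observed statistic is the fraction of
    significant pairs among testable pairs of the selected genes; the null
    draws ``n_subsets`` uniform gene subsets of the same size from the
    universe.  p = fraction of subsets at or above the observed fraction;
    fold = observed / mean(null).
    """
    selected = sorted(set(selected_genes))
    universe = sorted(set(universe_genes))
    if not set(selected) <= set(universe):
        raise ValueError("selected genes must be a subset of the universe")
    if not selected:
        raise ValueError("no selected genes")
    calls = ase_calls
    if "testable" in calls.columns:
        calls = calls[calls["testable"].astype(bool)]
    per_gene = calls.groupby("gene")["significant"].agg(["sum", "count"])
    n_test = per_gene["count"].reindex(universe).fillna(0).to_numpy(dtype=float)
    n_sig = per_gene["sum"].reindex(universe).fillna(0).to_numpy(dtype=float)

    gene_pos = {g: i for i, g in enumerate(universe)}
    sel_idx = np.array([gene_pos[g] for g in selected])
    denom = n_test[sel_idx].sum()
    if denom == 0:
        raise ValueError("selected genes have no testable ASE pairs")
    observed = float(n_sig[sel_idx].sum() / denom)

    rng = np.random.default_rng(seed)
    null = np.empty(n_subsets)
    for i in range(n_subsets):
        idx = rng.choice(len(universe), size=len(selected), replace=False)
        d = n_test[idx].sum()
        null[i] = n_sig[idx].sum() / d if d > 0 else 0.0
    p = float(np.mean(null >= observed))
    mean_null = float(null.mean())
    if mean_null == 0.0:
        logger.warning("null distribution mean is zero; fold change undefined")
        fold = float("nan")
    else:
        fold = observed / mean_null
    return EnrichmentResult(
        observed_fraction=observed, null_fractions=null, p_value=p, fold=fold
    )
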