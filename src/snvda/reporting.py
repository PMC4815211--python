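"""Tables and figures summarising a model run.

Every artifact here is a pure function of already-computed results (the
metrics bundle, the matrix, the ranking), so figures and tables can be
regenerated deterministically without re-running any model.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage

from .matrix import SnvMatrix, filter_min_nonzero, parse_snv_key, subset_by_region
from .splsda import standardize_fit

#: Row order for the region summary table; "exonic" counts include the
#: nonsynonymous subset, reported on its own row as well.
REGION_TABLE_ORDER = [
    "utr3",
    "exonic",
    "intronic",
    "nonsynonymous_exonic",
    "intergenic",
    "ncRNA",
    "utr5",
    "updownstream",
]


def summarize_regions(m: SnvMatrix, min_nonzero: int) -> pd.DataFrame:
    """Total and min-nonzero-filtered feature counts per region class,
    plus RNA-editing and all-SNVs rows."""
    filtered = filter_min_nonzero(m, min_nonzero)
    rows = []
    for region in REGION_TABLE_ORDER:
        rows.append(
            {
                "region": region,
                "total": subset_by_region(m, {region}).n_features,
                "filtered": subset_by_region(filtered, {region}).n_features,
            }
        )
    rows.append(
        {
            "region": "RNA-editing",
            "total": subset_by_region(m, editing_only=True).n_features,
            "filtered": subset_by_region(filtered, editing_only=True).n_features,
        }
    )
    rows.append(
        {"region": "all_SNVs", "total": m.n_features, "filtered": filtered.n_features}
    )
    return pd.DataFrame(rows)


def performance_table_row(
    model_name: str,
    grid,
    optimal_k: int,
    summary,
    permutation,
) -> pd.DataFrame:
    """One row in the shape of the per-model performance tables: tested K
    range, optimal K, AUC [95% CI], permutation p, accuracy, sensitivities."""
    row = {
        "model": model_name,
        "k_range": f"{grid.k_min}-{grid.k_max}, every {grid.step}",
        "optimal_k": optimal_k,
        "auc": round(summary.auc_mean, 3),
        "auc_ci": f"[{summary.auc_ci_low:.3f}-{summary.auc_ci_high:.3f}]",
        "p_value": permutation.p_display if permutation is not None else "NA",
        "predictive_accuracy": round(summary.predictive_accuracy, 3),
    }
    for g, s in summary.sensitivity.items():
        row[f"sensitivity_{g}"] = round(s, 3)
    return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def plot_k_density(selection, path: str | Path) -> None:
    """Kernel density of the selected K values with the optimum marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(selection.density_grid, selection.density_values, color="steelblue")
    ax.axvline(selection.optimal_k, color="firebrick", linestyle="--")
    ax.set_xlabel("K (features retained)")
    ax.set_ylabel("density")
    ax.set_title(f"Selected-K density (optimum = {selection.optimal_k})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_af_boxplots(
    m: SnvMatrix, ranking: pd.DataFrame, path: str | Path, top_n: int = 15
) -> None:
    """Per-group allele-fraction box plots of the top-ranked SNVs.

    Zero allele fractions contribute to the distributions; NA cells are
    dropped (they carry no observation).
    """
    top = ranking.head(top_n)
    groups = m.groups
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(top)), 4.5))
    data, positions, colors = [], [], []
    for i, key in enumerate(top["snv_key"]):
        af = m.values.loc[key]
        for gi, g in enumerate(groups):
            data.append(af[m.labels == g].dropna().to_numpy())
            positions.append(i * 3 + gi)
            colors.append("lightskyblue" if gi == 0 else "salmon")
    bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, c in zip(bp["boxes"], colors):
        patch.set_facecolor(c)
    ax.set_xticks([i * 3 + 0.5 for i in range(len(top))])
    ax.set_xticklabels(
        [f"{parse_snv_key(k)[0]}:{parse_snv_key(k)[1]}" for k in top["snv_key"]],
        rotation=90,
        fontsize=7,
    )
    ax.set_ylabel("allele fraction")
    ax.set_title(f"Top {len(top)} SNVs ({groups[0]} blue / {groups[1]} red)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_heatmap(
    m: SnvMatrix, ranking: pd.DataFrame, path: str | Path, top_n: int = 15
) -> None:
    """Clustered heatmap of the top-ranked SNVs; NA cells rendered black.

    Average-linkage hierarchical clustering on Euclidean distances of the
    standardized allele fractions; for the distance computation only, NA is
    replaced by the feature's midpoint between the group means.
    """
    keys = ranking.head(top_n)["snv_key"].tolist()
    sub = m.values.loc[keys]
    X = sub.to_numpy(dtype=float).T  # samples x features
    params = standardize_fit(X)
    Z = params.transform(X)
    fill = np.zeros(Z.shape[1])
    for gi, g in enumerate(m.groups):
        rows = Z[(m.labels == g).to_numpy()]
        with np.errstate(all="ignore"):
            fill = fill + np.nan_to_num(np.nanmean(rows, axis=0)) / 2.0
    Zimp = np.where(np.isnan(Z), fill, Z)

    def _order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 3:
            return list(range(mat.shape[0]))
        lk = linkage(mat, method="average", metric="euclidean")
        return dendrogram(lk, no_plot=True)["leaves"]

    s_order = _order(Zimp)
    f_order = _order(Zimp.T)
    masked = np.ma.masked_invalid(Z[np.ix_(s_order, f_order)].T)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(keys))))
    im = ax.imshow(masked, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_yticks(range(len(keys)))
    ax.set_yticklabels([keys[i] for i in f_order], fontsize=6)
    samples = list(sub.columns)
    ax.set_xticks(range(len(samples)))
    ax.set_xticklabels([samples[i] for i in s_order], rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="standardized AF (NA = black)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_selected_bed(ranking: pd.DataFrame, path: str | Path) -> None:
    """Selected SNV loci as 0-based BED for genome-browser loading."""
    with open(path, "w") as fh:
        for _, row in ranking.iterrows():
            chrom, pos, ref, alt = parse_snv_key(row["snv_key"])
            fh.write(
                f"{chrom}\t{pos - 1}\t{pos}\t{ref}>{alt}\t{row['abs_loading']:.6g}\n"
            )
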