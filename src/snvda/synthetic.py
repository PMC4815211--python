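"""Synthetic allele-fraction datasets with controllable ground truth.

The generator emulates the structure of an RNA-Seq SNV matrix for a
two-group cohort: most features are uninformative zero-inflated Beta allele
fractions, a chosen few carry a group effect, and a coverage model masks
cells as NA exactly when the simulated read depth falls below the threshold.

Two effect modes mirror the two signals a discriminant model can exploit:

* ``abundance`` — the probability of a nonzero AF differs between groups
  (the variant is called more often in one group);
* ``magnitude`` — the Beta mean of nonzero AFs differs between groups
  (allelic imbalance shifts);
* ``both`` applies the two shifts together.

Observed allele fractions are quantised to read counts (AF = k / depth), so
every non-NA cell is consistent with its depth.  Features are grouped into
genes, and a companion gene/sample ASE-call table is produced in which
designated genes are significant at an elevated rate — enough structure to
exercise the enrichment analysis without simulating reads or biochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DEFAULT_COVERAGE_THRESHOLD, REGION_CLASSES, SnvMatrix, snv_key

_BASES = np.array(["A", "C", "G", "T"])

#: Region class mix loosely shaped like an RNA-Seq SNV call set (UTRs and
#: exons dominate; intergenic and ncRNA present but rarer).
DEFAULT_REGION_PROBS = {
    "utr3": 0.28,
    "exonic": 0.15,
    "nonsynonymous_exonic": 0.12,
    "intronic": 0.22,
    "intergenic": 0.12,
    "ncRNA": 0.04,
    "utr5": 0.04,
    "updownstream": 0.03,
}


@dataclass
class GeneratorSpec:
    """Study-condition knobs for one synthetic dataset.

    Defaults describe a moderately powered two-group cohort: 40 samples per
    group, 500 features of which 10 are informative with combined abundance
    and magnitude effects, 10% missingness from the coverage model, and a
    background nonzero rate of 0.30 with symmetric Beta(5, 5) allele
    fractions (heterozygous-like, centred at 0.5).
    """

    n_per_group: tuple[int, int] = (40, 40)
    n_features: int = 500
    n_informative: int = 10
    effect_mode: str = "both"  # abundance | magnitude | both
    background_nonzero: float = 0.30
    abundance_shift: float = 0.45  # added to nonzero prob in group_B
    beta_mean_a: float = 0.35  # nonzero AF mean, group_A (informative)
    beta_mean_b: float = 0.65  # nonzero AF mean, group_B (informative)
    beta_concentration: float = 10.0
    background_beta: tuple[float, float] = (5.0, 5.0)
    na_rate: float = 0.10
    coverage_mean: float = 60.0
    coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD
    snvs_per_gene: int = 3
    ase_positive_genes: list[str] | None = None  # default: genes of informative SNVs
    ase_sig_rate_positive: float = 0.6
    ase_sig_rate_background: float = 0.1
    region_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROBS)
    )
    editing_fraction: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        for p in (self.background_nonzero, self.na_rate, self.editing_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_mode not in ("abundance", "magnitude", "both"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        unknown = set(self.region_probs) - REGION_CLASSES
        if unknown:
            raise ValueError(f"unknown region class(es) {sorted(unknown)}")


def _beta_ab(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def generate_dataset(
    spec: GeneratorSpec,
) -> tuple[SnvMatrix, list[str], pd.DataFrame]:
    """Draw one dataset: (matrix, informative feature keys, ASE call table).

    The NA mask is exact: a cell is NA iff its simulated depth is below
    ``coverage_threshold``; depths are drawn so the marginal NA rate equals
    ``na_rate`` (sub-threshold depths uniform on 0..threshold-1, adequate
    depths threshold + Poisson-distributed).  Fixed ``rng_seed`` gives an
    identical dataset on every call.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_a, n_b = spec.n_per_group
    n = n_a + n_b
    p = spec.n_features
    samples = [f"A{i + 1:03d}" for i in range(n_a)] + [
        f"B{i + 1:03d}" for i in range(n_b)
    ]
    labels = pd.Series(
        ["group_A"] * n_a + ["group_B"] * n_b,
        index=pd.Index(samples, name="sample_id"),
        name="group",
    )
    group_b = np.array([False] * n_a + [True] * n_b)

    # feature identities
    pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=p, replace=False))
    ref_idx = rng.integers(0, 4, size=p)
    alt_idx = (ref_idx + rng.integers(1, 4, size=p)) % 4
    keys = [
        snv_key("chr1", int(pos[i]), str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        for i in range(p)
    ]
    informative = sorted(rng.choice(p, size=spec.n_informative, replace=False).tolist())
    info_mask = np.zeros(p, dtype=bool)
    info_mask[informative] = True

    # nonzero indicator per cell
    p_nz = np.full((p, n), spec.background_nonzero)
    if spec.effect_mode in ("abundance", "both"):
        hi = min(1.0, spec.background_nonzero + spec.abundance_shift)
        p_nz[np.ix_(info_mask, group_b)] = hi
    nonzero = rng.random((p, n)) < p_nz

    # allele fractions for nonzero cells
    a_bg, b_bg = spec.background_beta
    af = rng.beta(a_bg, b_bg, size=(p, n))
    if spec.effect_mode in ("magnitude", "both"):
        aA, bA = _beta_ab(spec.beta_mean_a, spec.beta_concentration)
        aB, bB = _beta_ab(spec.beta_mean_b, spec.beta_concentration)
        af[np.ix_(info_mask, ~group_b)] = rng.beta(
            aA, bA, size=(spec.n_informative, n_a)
        )
        af[np.ix_(info_mask, group_b)] = rng.beta(
            aB, bB, size=(spec.n_informative, n_b)
        )
    af = np.where(nonzero, af, 0.0)

    # coverage model: NA iff depth < threshold, marginal NA rate = na_rate
    sub = rng.random((p, n)) < spec.na_rate
    depth = np.where(
        sub,
        rng.integers(0, spec.coverage_threshold, size=(p, n)),
        spec.coverage_threshold
        + rng.poisson(max(spec.coverage_mean - spec.coverage_threshold, 0.0), size=(p, n)),
    )

    # quantise AF to reads/depth; keep intended nonzeros nonzero
    reads = np.rint(af * depth).astype(int)
    reads = np.where(nonzero & (reads == 0) & (depth > 0), 1, reads)
    with np.errstate(divide="ignore", invalid="ignore"):
        af_obs = np.where(depth > 0, reads / np.maximum(depth, 1), 0.0)
    values = np.where(sub, np.nan, af_obs)

    # genes and annotations
    gene_ids = [f"GENE{(i // spec.snvs_per_gene) + 1:04d}" for i in range(p)]
    region_names = list(spec.region_probs)
    probs = np.array([spec.region_probs[r] for r in region_names], dtype=float)
    probs /= probs.sum()
    regions = rng.choice(region_names, size=p, p=probs)
    editing = rng.random(p) < spec.editing_fraction
    annotations = pd.DataFrame(
        {
            "region": regions,
            "gene": gene_ids,
            "dbsnp_id": "",
            "is_editing_site": editing,
        },
        index=pd.Index(keys, name="snv_key"),
    )

    matrix = SnvMatrix(
        values=pd.DataFrame(values, index=pd.Index(keys, name="snv_key"), columns=samples),
        annotations=annotations,
        labels=labels,
        coverage_threshold=spec.coverage_threshold,
    )
    truth = [keys[i] for i in informative]

    # gene/sample ASE calls: designated genes significant at an elevated rate
    if spec.ase_positive_genes is None:
        positive = {gene_ids[i] for i in informative}
    else:
        positive = set(spec.ase_positive_genes)
    genes = sorted(set(gene_ids))
    rows = []
    for g in genes:
        rate = (
            spec.ase_sig_rate_positive if g in positive else spec.ase_sig_rate_background
        )
        for s in samples:
            rows.append(
                {
                    "gene": g,
                    "sample": s,
                    "testable": True,
                    "significant": bool(rng.random() < rate),
                }
            )
    ase_calls = pd.DataFrame(rows)
    return matrix, truth, ase_calls


def null_spec(**overrides) -> GeneratorSpec:
    """A label-independent dataset: no informative features."""
    defaults = dict(n_informative=0)
    defaults.update(overrides)
    return GeneratorSpec(**defaults)
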