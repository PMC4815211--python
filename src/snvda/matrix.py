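"""Building, masking, filtering and (de)serialising SNV allele-fraction matrices.

The central object is :class:`SnvMatrix`: a features x samples matrix whose
entry (i, j) is the allele fraction (AF) of SNV i in sample j — the number of
reads supporting the variant allele divided by the total read coverage at
that position.  Cells whose read coverage falls below a threshold (default
10) carry no information and are masked as NA; cells with adequate coverage
but no variant call are genuine zeros.  The distinction matters downstream:
zeros enter group comparisons, NAs do not.

Input dialects
--------------
* SNV call files are BED-style TSV: chrom, start (0-based), end,
  "REF>ALT", allele fraction, depth.  Positions are converted to 1-based
  internally.
* Annotations are keyed by (chrom, pos, ref, alt) and carry an ANNOVAR-style
  region class, a gene symbol and a dbSNP id; a separate two-column file
  lists known RNA-editing sites.
* Sample labels are a two-column TSV (sample_id, group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of region classes (ANNOVAR-style).
REGION_CLASSES = frozenset(
    {
        "exonic",
        "nonsynonymous_exonic",
        "intronic",
        "utr5",
        "utr3",
        "intergenic",
        "updownstream",
        "ncRNA",
    }
)

_BASES = ("A", "C", "G", "T")

DEFAULT_COVERAGE_THRESHOLD = 10


class SnvFormatError(ValueError):
    """A file does not conform to the declared dialect."""


class SnvValidationError(ValueError):
    """A parsed value violates a domain invariant (e.g. AF outside [0, 1])."""


# ---------------------------------------------------------------------------
# Records and annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnvRecord:
    """One called variant in one sample.

    ``pos`` is 1-based; ``allele_fraction`` is variant reads / total reads at
    the position and lies in [0, 1].
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str
    allele_fraction: float
    depth: int

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise SnvValidationError(
                f"alleles must be one of {_BASES}: got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise SnvValidationError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise SnvValidationError(
                f"allele fraction {self.allele_fraction} outside [0, 1] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.depth < 0:
            raise SnvValidationError(f"negative depth at {self.chrom}:{self.pos}")
        if self.allele_fraction > 0 and self.depth == 0:
            raise SnvValidationError(
                f"positive allele fraction with zero depth at {self.chrom}:{self.pos}"
            )

    @property
    def snv_key(self) -> str:
        return snv_key(self.chrom, self.pos, self.ref_allele, self.alt_allele)


def snv_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical string identity of an SNV feature: ``chrom:pos:REF>ALT``.

    Identity is allele-specific — the same position with two different alt
    alleles is two features, because allele fractions are allele-specific.
    """
    return f"{chrom}:{pos}:{ref}>{alt}"


def parse_snv_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, alleles = key.rsplit(":", 2)
    ref, alt = alleles.split(">")
    return chrom, int(pos), ref, alt


# ---------------------------------------------------------------------------
# The matrix
# ---------------------------------------------------------------------------


@dataclass
class SnvMatrix:
    """Features x samples allele-fraction matrix with an explicit NA mask.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are SNV keys, columns sample ids, entries allele fractions in
        [0, 1]; NaN marks sub-threshold coverage.
    annotations : pandas.DataFrame
        Indexed like ``values``; columns ``region``, ``gene``, ``dbsnp_id``,
        ``is_editing_site``.
    labels : pandas.Series
        Sample id -> group name; exactly two groups for modelling.
    coverage_threshold : int
        Read depth below which a cell was masked NA.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    labels: pd.Series
    coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise SnvValidationError("duplicate feature keys in matrix")
        if not self.values.columns.is_unique:
            raise SnvValidationError("duplicate sample ids in matrix")
        self.annotations = self.annotations.reindex(self.values.index)
        if "is_editing_site" in self.annotations:
            self.annotations["is_editing_site"] = (
                self.annotations["is_editing_site"].fillna(False).astype(bool)
            )
        self.labels = self.labels.reindex(self.values.columns)
        vals = self.values.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise SnvValidationError("allele fractions outside [0, 1]")

    # -- basic views -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """The group names, sorted for a stable ordering (group_A, group_B)."""
        return sorted(self.labels.dropna().unique().tolist())

    def group_members(self, group: str) -> list[str]:
        return self.labels.index[self.labels == group].tolist()

    def check_modelable(self) -> None:
        """Two groups with at least two samples each."""
        counts = self.labels.value_counts()
        if len(counts) != 2 or (counts < 2).any():
            raise SnvValidationError(
                "modelling requires exactly two groups with >=2 samples each; "
                f"got {counts.to_dict()}"
            )

    def select_features(self, keys: Sequence[str]) -> "SnvMatrix":
        return replace(
            self,
            values=self.values.loc[list(keys)],
            annotations=self.annotations.loc[list(keys)],
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CALL_COLUMNS = ("chrom", "start", "end", "name", "allele_fraction", "depth")


def read_snv_calls(path: str | Path, sample_id: str) -> list[SnvRecord]:
    """Read one sample's SNV calls from a BED-style TSV.

    Columns: chrom, start (0-based), end, "REF>ALT", allele_fraction, depth.
    A header line is optional; ``#`` comment lines are ignored.  The 0-based
    BED start is converted to the 1-based position ``start + 1``.
    """
    records: list[SnvRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(fields) < len(_CALL_COLUMNS):
                missing = _CALL_COLUMNS[len(fields)]
                raise SnvFormatError(
                    f"{path}: line {lineno}: missing required column "
                    f"{missing!r} (expected {len(_CALL_COLUMNS)} columns, "
                    f"got {len(fields)})"
                )
            chrom, start, _end, name, af, depth = fields[:6]
            try:
                if ">" not in name:
                    raise SnvFormatError(f"allele column must be 'REF>ALT', got {name!r}")
                ref, alt = name.split(">", 1)
                rec = SnvRecord(
                    chrom=chrom,
                    pos=int(start) + 1,
                    ref_allele=ref.strip(),
                    alt_allele=alt.strip(),
                    sample_id=sample_id,
                    allele_fraction=float(af),
                    depth=int(depth),
                )
            except (ValueError, SnvFormatError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise SnvValidationError(f"{path}: malformed rows:\n" + "\n".join(errors))
    return records


def write_snv_calls(path: str | Path, records: Iterable[SnvRecord]) -> None:
    """Write records in the BED-style dialect read by :func:`read_snv_calls`."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tallele_fraction\tdepth\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.ref_allele}>{r.alt_allele}"
                f"\t{r.allele_fraction:.10g}\t{r.depth}\n"
            )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: chrom, pos (1-based), ref, alt, region, gene, dbsnp_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"chrom", "pos", "ref", "alt", "region"}
    missing = required - set(df.columns)
    if missing:
        raise SnvFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    bad = set(df["region"]) - REGION_CLASSES
    if bad:
        raise SnvValidationError(
            f"{path}: unknown region class(es) {sorted(bad)}; "
            f"valid: {sorted(REGION_CLASSES)}"
        )
    keys = [
        snv_key(c, int(p), r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    out = pd.DataFrame(
        {
            "region": df["region"].to_numpy(),
            "gene": df.get("gene", pd.Series([""] * len(df))).to_numpy(),
            "dbsnp_id": df.get("dbsnp_id", pd.Series([""] * len(df))).to_numpy(),
        },
        index=pd.Index(keys, name="snv_key"),
    )
    out["is_editing_site"] = False
    return out


def read_editing_sites(path: str | Path) -> set[tuple[str, int]]:
    """RNA-editing site list: TSV of chrom, pos (1-based)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "pos"], dtype=str
    )
    if df.iloc[0]["pos"].lower() in ("pos", "position"):
        df = df.iloc[1:]
    return {(c, int(p)) for c, p in zip(df["chrom"], df["pos"])}


def read_labels(path: str | Path) -> pd.Series:
    """Labels TSV: sample_id, group."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["sample_id", "group"], dtype=str
        )
    return pd.Series(
        df["group"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id"), name="group"
    )


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def build_snv_matrix(
    records: Sequence[SnvRecord],
    labels: pd.Series,
    coverage: pd.DataFrame | None = None,
    coverage_threshold: int = DEFAULT_COVERAGE_THRESHOLD,
    annotations: pd.DataFrame | None = None,
    editing_sites: set[tuple[str, int]] | None = None,
) -> SnvMatrix:
    """Assemble the allele-fraction matrix over all samples.

    The feature set is the union of SNV keys over all records; the sample set
    is the index of ``labels``.  Cell semantics:

    * a record with depth >= threshold contributes its allele fraction;
    * any cell whose coverage is below the threshold is NA;
    * a cell with adequate coverage but no variant call is 0.

    ``coverage`` is an optional per-locus (rows, keyed ``chrom:pos``) per-sample
    (columns) depth table; where absent, a cell's depth comes from its own
    record, and record-less cells are treated as sub-threshold (NA).

    Raises on duplicate (snv_key, sample) pairs with conflicting allele
    fractions.
    """
    samples = list(labels.index)
    sample_pos = {s: i for i, s in enumerate(samples)}
    keys: list[str] = []
    key_pos: dict[str, int] = {}
    for r in records:
        k = r.snv_key
        if k not in key_pos:
            key_pos[k] = len(keys)
            keys.append(k)

    vals = np.full((len(keys), len(samples)), np.nan)
    seen: dict[tuple[int, int], float] = {}
    for r in records:
        if r.sample_id not in sample_pos:
            raise SnvValidationError(f"sample {r.sample_id!r} not present in labels")
        i, j = key_pos[r.snv_key], sample_pos[r.sample_id]
        if (i, j) in seen:
            if seen[(i, j)] != r.allele_fraction:
                raise SnvValidationError(
                    f"conflicting allele fractions for {r.snv_key} in {r.sample_id}: "
                    f"{seen[(i, j)]} vs {r.allele_fraction}"
                )
            continue
        seen[(i, j)] = r.allele_fraction
        if r.depth >= coverage_threshold:
            vals[i, j] = r.allele_fraction

    if coverage is not None:
        # loci keyed "chrom:pos"; covered-but-uncalled cells become 0
        locus_of_key = {k: k.rsplit(":", 1)[0] for k in keys}
        for k in keys:
            locus = locus_of_key[k]
            if locus not in coverage.index:
                continue
            i = key_pos[k]
            for s in samples:
                j = sample_pos[s]
                if (i, j) in seen:
                    continue
                if s in coverage.columns and coverage.at[locus, s] >= coverage_threshold:
                    vals[i, j] = 0.0

    values = pd.DataFrame(vals, index=pd.Index(keys, name="snv_key"), columns=samples)
    if annotations is None:
        annotations = pd.DataFrame(
            {"region": "", "gene": "", "dbsnp_id": "", "is_editing_site": False},
            index=values.index,
        )
    else:
        annotations = annotations.reindex(values.index)
        annotations["region"] = annotations["region"].fillna("")
        annotations["gene"] = annotations["gene"].fillna("")
        annotations["dbsnp_id"] = annotations["dbsnp_id"].fillna("")
    if editing_sites is not None:
        flags = []
        for k in keys:
            chrom, pos, _r, _a = parse_snv_key(k)
            flags.append((chrom, pos) in editing_sites)
        annotations = annotations.copy()
        annotations["is_editing_site"] = flags
    return SnvMatrix(values, annotations, labels, coverage_threshold)


# ---------------------------------------------------------------------------
# Filtering and subsetting
# ---------------------------------------------------------------------------


def filter_min_nonzero(m: SnvMatrix, min_nonzero: int) -> SnvMatrix:
    """Keep features with at least ``min_nonzero`` samples showing a non-zero,
    observed allele fraction (NA cells never count)."""
    if min_nonzero < 0:
        raise ValueError("min_nonzero must be >= 0")
    vals = m.values.to_numpy(dtype=float)
    counts = np.nansum(np.nan_to_num(vals) > 0, axis=1)
    keep = m.values.index[counts >= min_nonzero]
    return m.select_features(list(keep))


def subset_by_region(
    m: SnvMatrix,
    regions: Iterable[str] | None = None,
    editing_only: bool = False,
) -> SnvMatrix:
    """Restrict features to region classes and/or known RNA-editing sites.

    A request for ``exonic`` also matches ``nonsynonymous_exonic`` features
    (nonsynonymous exonic SNVs are a subset of exonic).  ``regions=None``
    with ``editing_only=False`` is the all-SNVs identity.
    """
    if editing_only:
        keep = m.annotations.index[m.annotations["is_editing_site"]]
        return m.select_features(list(keep))
    if regions is None:
        return m.select_features(list(m.values.index))
    regions = set(regions)
    unknown = regions - REGION_CLASSES
    if unknown:
        raise ValueError(
            f"unknown region name(s) {sorted(unknown)}; valid names: "
            f"{sorted(REGION_CLASSES)}"
        )
    wanted = set(regions)
    if "exonic" in wanted:
        wanted.add("nonsynonymous_exonic")
    mask = m.annotations["region"].isin(wanted)
    return m.select_features(list(m.annotations.index[mask]))


# ---------------------------------------------------------------------------
# Matrix archive (TSV + JSON sidecar)
# ---------------------------------------------------------------------------


def write_snv_matrix(m: SnvMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (values, NA literal for masked cells),
    ``<prefix>.annotations.tsv`` and ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    # %.17g round-trips IEEE doubles exactly
    m.values.to_csv(f"{prefix}.tsv", sep="\t", na_rep="NA", float_format="%.17g")
    m.annotations.to_csv(f"{prefix}.annotations.tsv", sep="\t")
    meta = {
        "coverage_threshold": int(m.coverage_threshold),
        "labels": {str(s): str(g) for s, g in m.labels.items()},
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_snv_matrix(prefix: str | Path) -> SnvMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(
        f"{prefix}.tsv", sep="\t", index_col=0, na_values=["NA"],
        float_precision="round_trip",
    )
    annotations = pd.read_csv(f"{prefix}.annotations.tsv", sep="\t", index_col=0).fillna("")
    if "is_editing_site" in annotations:
        annotations["is_editing_site"] = annotations["is_editing_site"].astype(bool)
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    labels = pd.Series(meta["labels"], name="group")
    labels.index.name = "sample_id"
    labels = labels.reindex(values.columns)
    return SnvMatrix(values, annotations, labels, int(meta["coverage_threshold"]))
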