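"""Domain types and file I/O shared by every pipeline stage.

Tabular inputs follow the conventions of the upstream callers whose output
they represent: variant tables are MAF-like TSV (1-based inclusive
coordinates), copy-number segments are SEG-like TSV (1-based inclusive),
interval files are BED (0-based half-open, converted on read).  Expression
and protein matrices are genes x samples TSV with the gene symbol in the
first column.  Gene sets use the standard GMT dialect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANCER_TYPES = ("mPDAC", "CCA", "CRC", "other")
KRAS_STATUSES = ("wildtype", "mutant", "unknown")
CONSEQUENCES = ("missense", "nonsense", "inframe_indel", "frameshift", "other")
FUSION_CONFIDENCES = ("low", "medium", "high")
EXPRESSION_SCALES = ("raw_counts", "rpkm_log10", "zscore")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A row violates a domain-type invariant."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cancer_type: str = "other"
    kras_status: str = "unknown"
    rnaseq_batch: str = ""
    tumor_content: float | None = None
    biopsy_site: str | None = None

    def __post_init__(self):
        if self.cancer_type not in CANCER_TYPES:
            raise ValidationError(f"unknown cancer_type {self.cancer_type!r}")
        if self.kras_status not in KRAS_STATUSES:
            raise ValidationError(f"unknown kras_status {self.kras_status!r}")
        if self.tumor_content is not None and not (0.0 <= self.tumor_content <= 1.0):
            raise ValidationError(
                f"tumor_content {self.tumor_content} outside [0, 1] "
                f"for sample {self.sample_id}"
            )


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str
    vaf: float
    tumor_depth: int
    alt_count: int

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if self.alt_count > self.tumor_depth:
            raise ValidationError(
                f"alt_count {self.alt_count} > tumor_depth {self.tumor_depth} "
                f"at {self.chrom}:{self.pos} ({self.sample_id})"
            )
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        """chrom:pos:ref:alt identity used for blacklist matching."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CopySegment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    total_cn: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} ({self.sample_id} {self.chrom})"
            )
        if self.total_cn < 0:
            raise ValidationError(f"negative total_cn {self.total_cn}")


@dataclass(frozen=True)
class FusionEvent:
    sample_id: str
    gene_a: str
    gene_b: str
    in_frame: bool
    confidence: str
    oncogenic: bool

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-fusion {self.gene_a} ({self.sample_id})")
        if self.confidence not in FUSION_CONFIDENCES:
            raise ValidationError(f"unknown confidence {self.confidence!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with an explicit transform provenance.

    ``scale`` may only move forward along raw_counts -> rpkm_log10 -> zscore.
    """

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    scale: str = "raw_counts"

    def __post_init__(self):
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]]  # name -> (description, members)

    def __post_init__(self):
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class GenomeLayout:
    """Chromosome lengths, p/q arm split positions and gene coordinates.

    Coordinates are 1-based inclusive; ``arm_split[chrom]`` is the last base
    of the p arm (the q arm starts at arm_split + 1).
    """

    chrom_lengths: dict[str, int]
    arm_split: dict[str, int]
    genes: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)

    def __post_init__(self):
        for chrom, split in self.arm_split.items():
            if not (0 < split < self.chrom_lengths[chrom]):
                raise ValidationError(f"arm split {split} outside {chrom}")
        for gene, (chrom, start, end) in self.genes.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"gene {gene} on unknown chromosome {chrom}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValidationError(f"gene {gene} interval outside {chrom}")

    def arm_interval(self, arm: str) -> tuple[str, int, int]:
        """1-based inclusive interval of an arm named e.g. 'chr1q'."""
        chrom, pq = arm[:-1], arm[-1]
        if pq not in "pq":
            raise ValueError(f"arm name must end in p or q: {arm!r}")
        split = self.arm_split[chrom]
        if pq == "p":
            return chrom, 1, split
        return chrom, split + 1, self.chrom_lengths[chrom]


# ---------------------------------------------------------------------------
# readers / writers


_VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "vaf", "tumor_depth", "alt_count",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_variant_table(path) -> list[VariantCall]:
    """Read a MAF-like TSV of somatic SNV/indel calls.

    Rows violating invariants (alt_count > depth, VAF outside [0, 1]) are
    rejected with a diagnostic naming the 1-based data row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _VARIANT_COLUMNS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(VariantCall(
                sample_id=str(row.sample_id), gene=str(row.gene).strip(),
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alt=str(row.alt), consequence=str(row.consequence),
                vaf=float(row.vaf), tumor_depth=int(row.tumor_depth),
                alt_count=int(row.alt_count),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_variant_table(variants: Iterable[VariantCall], path) -> None:
    df = pd.DataFrame([v.__dict__ for v in variants], columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[CopySegment]:
    """Read a SEG-like TSV; segments are sorted and checked non-overlapping
    within each sample/chromosome."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["sample_id", "chrom", "start", "end", "total_cn"], path)
    segs = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segs.append(CopySegment(
                sample_id=str(row.sample_id), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), total_cn=float(row.total_cn),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    segs.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    check_segments_nonoverlapping(segs)
    return segs


def check_segments_nonoverlapping(segs: Sequence[CopySegment]) -> None:
    """Validate the per-sample, per-chromosome non-overlap invariant.

    Expects segments sorted by (sample_id, chrom, start).
    """
    for prev, cur in zip(segs, segs[1:]):
        if prev.sample_id == cur.sample_id and prev.chrom == cur.chrom:
            if cur.start <= prev.end:
                raise ValidationError(
                    f"overlapping segments for {cur.sample_id} {cur.chrom}: "
                    f"[{prev.start},{prev.end}] and [{cur.start},{cur.end}]"
                )


def write_segments(segs: Iterable[CopySegment], path) -> None:
    df = pd.DataFrame([s.__dict__ for s in segs],
                      columns=["sample_id", "chrom", "start", "end", "total_cn"])
    df.to_csv(path, sep="\t", index=False)


def read_ploidies(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "ploidy"], path)
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        p = float(row.ploidy)
        if p <= 0:
            raise ValidationError(f"{path} row {i}: ploidy {p} must be > 0")
        out[str(row.sample_id)] = p
    return out


def read_fusions(path) -> list[FusionEvent]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "gene_a", "gene_b", "in_frame",
                          "confidence", "oncogenic"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(FusionEvent(
                sample_id=str(row.sample_id), gene_a=str(row.gene_a).strip(),
                gene_b=str(row.gene_b).strip(),
                in_frame=_as_bool(row.in_frame), confidence=str(row.confidence),
                oncogenic=_as_bool(row.oncogenic),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return out


def write_fusions(events: Iterable[FusionEvent], path) -> None:
    df = pd.DataFrame([e.__dict__ for e in events],
                      columns=["sample_id", "gene_a", "gene_b", "in_frame",
                               "confidence", "oncogenic"])
    df.to_csv(path, sep="\t", index=False)


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot interpret {x!r} as boolean")


def filter_fusions(events: Sequence[FusionEvent]) -> list[FusionEvent]:
    """Keep in-frame events called at high confidence."""
    return [e for e in events if e.in_frame and e.confidence == "high"]


def read_expression_matrix(path, scale: str = "raw_counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene"
    return ExpressionMatrix(values=df, scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {i}: GMT needs >= 3 fields")
            name, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {i}: BED needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValidationError(f"{path} line {i}: empty interval")
            out.append((chrom, start + 1, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_cytobands(path) -> dict[str, int]:
    """Read a UCSC cytoBand-dialect TSV and return per-chromosome p/q split.

    The split is the end of the last p band (equivalently the start of the
    first q band); acen/gvar staining is not interpreted beyond band names.
    """
    splits: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path} line {i}: cytoBand needs 5 fields")
            chrom, _start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name.startswith("p"):
                splits[chrom] = max(splits.get(chrom, 0), end)
    return splits


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id"], path)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    return df.set_index("sample_id")


def read_samples(path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "cancer_type", "kras_status"], path)
    out = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.sample_id)
        if sid in seen:
            raise ValidationError(f"{path} row {i}: duplicate sample_id {sid}")
        seen.add(sid)
        tc = getattr(row, "tumor_content", None)
        tc = None if tc is None or (isinstance(tc, float) and np.isnan(tc)) else float(tc)
        out.append(Sample(
            sample_id=sid, cancer_type=str(row.cancer_type),
            kras_status=str(row.kras_status),
            rnaseq_batch=str(getattr(row, "rnaseq_batch", "")),
            tumor_content=tc,
            biopsy_site=str(getattr(row, "biopsy_site", "")) or None,
        ))
    return out


def write_samples(samples: Iterable[Sample], path) -> None:
    df = pd.DataFrame([s.__dict__ for s in samples])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression transforms


def rpkm_log10(counts: ExpressionMatrix, gene_lengths: Mapping[str, float],
               pseudocount: float = 1.0) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalization followed by log10.

    value = log10(1e9 * count / (library_size * gene_length) + pseudocount).
    With the default pseudocount of 1, zero counts map to 0.
    """
    if counts.scale != "raw_counts":
        raise ValueError(f"expected raw_counts, got {counts.scale}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"genes without length: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    lengths = np.array([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    vals = counts.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = vals.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("sample with zero library size")
    rpkm = 1e9 * vals / (libsize[None, :] * lengths[:, None])
    out = pd.DataFrame(np.log10(rpkm + pseudocount),
                       index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values=out, scale="rpkm_log10")


def zscore_rows(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-gene z-score (sample sd, ddof=1). Zero-variance rows map to zeros.

    Idempotent: z-scoring an already z-scored matrix returns it unchanged.
    """
    if m.scale not in ("rpkm_log10", "zscore"):
        raise ValueError(f"expected rpkm_log10 (or zscore), got {m.scale}")
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene rows set to 0",
                      stacklevel=2)
    sd[sd == 0] = 1.0
    out = pd.DataFrame((vals - mu) / sd, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, scale="zscore")
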