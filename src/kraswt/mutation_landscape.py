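"""Gene-level somatic event calling, recurrence filtering, group frequency
tests and tumor mutational burden.

Event classes follow the callers' conventions: a gene is amplified in a
sample when any overlapping copy segment has total copy number >= 2x the
tumor ploidy (boundary inclusive); homozygously deleted when any
overlapping segment has total_cn < 0.5 (real-valued CN from purity-
corrected callers rarely hits exactly 0); SNV/indel presence is per
patient, irrespective of consequence class.  TMB applies the standard
filter cascade (exonic, not common, VAF >= 0.05 & depth >= 25 & alt >= 3,
qualifying consequence) and divides by the 32.102474 Mb assayed-exome
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CopySegment, GenomeLayout, VariantCall
from .stats import bh_adjust, fisher_exact_2x2

logger = logging.getLogger(__name__)

TMB_DENOMINATOR_MB = 32.102474
HOMDEL_MAX_CN = 0.5
TMB_CONSEQUENCES = frozenset({"missense", "nonsense", "inframe_indel", "frameshift"})


@dataclass
class GeneEventMatrix:
    """Boolean genes x samples presence matrix for one somatic event class."""

    event_class: str  # snv_indel | amplification | homozygous_deletion | fusion
    matrix: pd.DataFrame  # bool, index genes, columns samples

    def __post_init__(self):
        if self.matrix.dtypes.ne(bool).any():
            raise ValueError("event matrix must be boolean")

    def frequency(self) -> pd.Series:
        return self.matrix.mean(axis=1)


def snv_event_matrix(variants: Sequence[VariantCall],
                     sample_ids: Sequence[str]) -> GeneEventMatrix:
    """Per-patient SNV/indel presence (multiple variants in one gene count
    once)."""
    genes = sorted({v.gene for v in variants})
    m = pd.DataFrame(False, index=genes, columns=list(sample_ids))
    for v in variants:
        if v.sample_id in m.columns:
            m.loc[v.gene, v.sample_id] = True
    return GeneEventMatrix(event_class="snv_indel", matrix=m)


def fusion_event_matrix(fusions, sample_ids: Sequence[str]) -> GeneEventMatrix:
    genes = sorted({g for f in fusions for g in (f.gene_a, f.gene_b)})
    m = pd.DataFrame(False, index=genes, columns=list(sample_ids))
    for f in fusions:
        if f.sample_id in m.columns:
            m.loc[f.gene_a, f.sample_id] = True
            m.loc[f.gene_b, f.sample_id] = True
    return GeneEventMatrix(event_class="fusion", matrix=m)


def call_gene_cnv(segments: Sequence[CopySegment],
                  ploidies: Mapping[str, float],
                  layout: GenomeLayout,
                  ) -> tuple[GeneEventMatrix, GeneEventMatrix]:
    """Ploidy-relative gene-level amplification and homozygous-deletion calls.

    A gene is amplified if ANY overlapping segment has
    total_cn >= 2 * ploidy, deleted if any overlapping segment has
    total_cn < 0.5.  Genes with no overlapping segment are neutral.
    """
    sample_ids = sorted({s.sample_id for s in segments})
    missing = [sid for sid in sample_ids if sid not in ploidies]
    if missing:
        raise ValueError(f"missing ploidy for samples: {missing[:5]}")
    genes = list(layout.genes)
    gene_by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for g, (chrom, st, en) in layout.genes.items():
        gene_by_chrom.setdefault(chrom, []).append((g, st, en))

    amp = pd.DataFrame(False, index=genes, columns=sample_ids)
    dele = pd.DataFrame(False, index=genes, columns=sample_ids)
    for seg in segments:
        entries = gene_by_chrom.get(seg.chrom, ())
        ploidy = ploidies[seg.sample_id]
        is_amp = seg.total_cn >= 2.0 * ploidy
        is_del = seg.total_cn < HOMDEL_MAX_CN
        if not (is_amp or is_del):
            continue
        hit = [g for g, st, en in entries if st <= seg.end and en >= seg.start]
        if not hit:
            continue
        if is_amp:
            amp.loc[hit, seg.sample_id] = True
        if is_del:
            dele.loc[hit, seg.sample_id] = True
    return (GeneEventMatrix("amplification", amp),
            GeneEventMatrix("homozygous_deletion", dele))


def recurrence_filter(matrix: GeneEventMatrix, min_patients: int = 3) -> list[str]:
    """Genes with an event in MORE than ``min_patients`` samples (strict)."""
    if min_patients < 0:
        raise ValueError("min_patients must be >= 0")
    counts = matrix.matrix.sum(axis=1)
    return list(counts.index[counts > min_patients])


def compare_group_frequencies(matrix: GeneEventMatrix,
                              groups: Mapping[str, Sequence[str]],
                              gene_list: Sequence[str]) -> pd.DataFrame:
    """Per-gene two-sided Fisher test of event frequency between two groups,
    BH-adjusted over the supplied gene family.

    ``groups`` maps exactly two group names to sample-id lists; the first
    group is treated as the wildtype-like group in the output columns.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")
    absent = [g for g in gene_list if g not in matrix.matrix.index]
    if absent:
        raise ValueError(f"genes absent from event matrix: {absent[:5]}")
    rows = []
    for gene in gene_list:
        a = int(matrix.matrix.loc[gene, list(ids_a)].sum())
        c = int(matrix.matrix.loc[gene, list(ids_b)].sum())
        b, d = len(ids_a) - a, len(ids_b) - c
        res = fisher_exact_2x2(a, b, c, d)
        rows.append({
            "gene": gene,
            f"n_{name_a}_with": a, f"n_{name_a}_without": b,
            f"n_{name_b}_with": c, f"n_{name_b}_without": d,
            f"freq_{name_a}": a / len(ids_a), f"freq_{name_b}": c / len(ids_b),
            "odds_ratio": res.statistic, "p_raw": res.p_value,
        })
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy()) if len(df) else []
    return df.sort_values(["p_adj", "gene"], kind="mergesort").reset_index(drop=True)


def tmb_filter(variants: Sequence[VariantCall],
               exons: Sequence[tuple[str, int, int]],
               blacklist: Iterable[str] = (),
               vaf_min: float = 0.05, depth_min: int = 25, alt_min: int = 3,
               ) -> tuple[list[VariantCall], dict[str, int]]:
    """Conjunctive TMB filter cascade with a per-filter attrition log.

    Order of attribution: exonic -> not blacklisted -> quality
    (VAF >= vaf_min AND depth >= depth_min AND alt >= alt_min) ->
    consequence in {missense, nonsense, inframe_indel, frameshift}.
    Filters are conjunctive, so the surviving set does not depend on order.
    """
    blackset = set(blacklist)
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, st, en in exons:
        exon_by_chrom.setdefault(chrom, []).append((st, en))
    for spans in exon_by_chrom.values():
        spans.sort()
    attrition = {"input": len(variants), "non_exonic": 0, "blacklisted": 0,
                 "quality": 0, "consequence": 0, "passing": 0}
    survivors = []
    for v in variants:
        spans = exon_by_chrom.get(v.chrom, ())
        exonic = _point_in_sorted(spans, v.pos)
        quality = v.vaf >= vaf_min and v.tumor_depth >= depth_min \
            and v.alt_count >= alt_min
        ok_conseq = v.consequence in TMB_CONSEQUENCES
        if not exonic:
            attrition["non_exonic"] += 1
        elif v.key in blackset:
            attrition["blacklisted"] += 1
        elif not quality:
            attrition["quality"] += 1
        elif not ok_conseq:
            attrition["consequence"] += 1
        else:
            survivors.append(v)
    attrition["passing"] = len(survivors)
    logger.info("TMB filter attrition: %s", attrition)
    return survivors, attrition


def _point_in_sorted(spans: Sequence[tuple[int, int]], pos: int) -> bool:
    import bisect
    i = bisect.bisect_right(spans, (pos, np.inf))
    return i > 0 and spans[i - 1][0] <= pos <= spans[i - 1][1]


def compute_tmb(filtered_variants: Sequence[VariantCall],
                sample_ids: Sequence[str]) -> pd.DataFrame:
    """Per-sample TMB = passing-variant count / 32.102474 Mb.

    Samples with zero passing variants are reported with TMB 0.
    """
    counts = {sid: 0 for sid in sample_ids}
    for v in filtered_variants:
        if v.sample_id in counts:
            counts[v.sample_id] += 1
    rows = [{"sample_id": sid, "n_passing": n,
             "tmb": n / TMB_DENOMINATOR_MB,
             "denominator_mb": TMB_DENOMINATOR_MB}
            for sid, n in counts.items()]
    return pd.DataFrame(rows)


def oncoprint_table(matrices: Sequence[GeneEventMatrix],
                    gene_list: Sequence[str]) -> pd.DataFrame:
    """Long-format (sample, gene, event_class) table, the tabular twin of an
    oncoprint panel."""
    rows = []
    for m in matrices:
        sub = m.matrix.reindex([g for g in gene_list if g in m.matrix.index])
        for gene, row in sub.iterrows():
            for sid in row.index[row]:
                rows.append({"sample_id": sid, "gene": gene,
                             "event_class": m.event_class})
    return pd.DataFrame(rows, columns=["sample_id", "gene", "event_class"])
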