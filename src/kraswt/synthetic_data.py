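"""Synthetic three-cancer-type metastatic cohort with planted, recoverable
structure.

The generator emulates the statistical shape of a metastatic pancreatic
adenocarcinoma (mPDAC) discovery cohort (n = 63, ~14% KRAS wildtype) joined
by cholangiocarcinoma (CCA, n = 14) and colorectal adenocarcinoma (CRC,
n = 63) comparator cohorts:

* a KRAS-wildtype expression signature shared by wildtype mPDAC and CCA,
  with CRC carrying an orthogonal expression pattern so it clusters apart;
* a basal-like / classical split within KRAS-mutant mPDAC;
* differential per-gene mutation frequencies (e.g. TP53 depleted in the
  wildtype group) over a background of recurrently mutated genes;
* broad chr1q (and chr8q) amplification in a subset of wildtype-like
  samples, coupled to an mRNA/protein dosage effect;
* negative-binomial counts with library-size variation and batch offsets,
  with batches unevenly distributed across cancer types;
* exponential survival with a planted log hazard ratio for wildtype status;
* a protein layer correlated with mRNA at a target across-gene rho;
* oncogenic in-frame high-confidence fusions confined to wildtype mPDAC
  and a subset of CCA.

Every planted effect is recorded in a truth object so downstream stages can
be tested for parameter recovery.  All output is deterministic given the
config seed.  The genome is a reduced eight-chromosome layout (10-25 Mb
chromosomes) so interval operations stay desk-sized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CopySegment, ExpressionMatrix, FusionEvent, GenomeLayout, Sample,
    VariantCall, write_bed, write_expression_matrix, write_fusions,
    write_samples, write_segments, write_variant_table,
)

TMB_DENOMINATOR_MB = 32.102474

GLYCOLYTIC_GENES = [
    "GAPDH", "ALDOA", "PKM", "ENO1", "TPI1", "PGK1", "GPI", "PGAM1",
    "PFKP", "PFKFB3", "ENO2", "PPP2R5D", "PFKM", "PFKFB4",
]
CHOLESTEROGENIC_GENES = [
    "FDPS", "FDFT1", "DHCR24", "EBP", "IDI1", "MVD", "HMGCS1", "SQLE",
    "NSDHL", "DHCR7", "HMGCR", "LSS", "SC5D", "MVK", "HSD1787",
]

# symbols given real names inside the synthetic gene universe
_SPECIAL_CHR1Q = ["NR5A2", "PROX1", "VTCN1"]
_SPECIAL_OTHER = ["TP53", "KRAS", "SMAD4", "CDKN2A", "MUC16"]


def _default_mut_freq_table() -> dict[str, tuple[float, float]]:
    # gene -> (P(mutated | wildtype mPDAC), P(mutated | mutant mPDAC))
    return {
        "KRAS": (0.0, 1.0),
        "TP53": (0.111, 0.815),
        "SMAD4": (0.22, 0.35),
        "CDKN2A": (0.22, 0.46),
        "MUC16": (0.8, 0.1),  # planted wildtype-enriched gene
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_pdac: int = 63
    n_cca: int = 14
    n_crc: int = 63
    frac_wildtype: float = 9 / 63
    seed: int = 123
    gene_universe: int = 2000
    n_signature_genes: int = 40
    signature_l2fc: float = 3.0
    nb_dispersion: float = 0.1
    # per-batch log2 offsets applied to a fixed 20% subset of genes
    batch_effects: dict[str, float] = field(
        default_factory=lambda: {"batch1": 0.0, "batch2": 0.5, "batch3": -0.5})
    mut_freq_table: dict[str, tuple[float, float]] = field(
        default_factory=_default_mut_freq_table)
    arm_amp_prob: float = 0.5          # chr1q in wildtype-like mPDAC
    chr8q_amp_prob: float = 0.33       # chr8q in wildtype-like mPDAC
    cca_amp_prob: float = 0.2          # chr1q in CCA
    background_arm_amp_prob: float = 0.05  # arm amplification in other samples
    homdel_prob: float = 0.2           # CDKN2A homozygous deletion, both groups
    planted_log_hr: float = float(np.log(0.25))
    protein_mrna_rho: float = 0.3
    tmb_target: dict[str, float] = field(
        default_factory=lambda: {"wildtype": 2.4, "mutant": 1.5})  # mut/Mb
    tmb_fail_frac: float = 0.15        # failing variants per filter, vs passing
    # secondary structure
    n_basal: int = 15                  # basal-like mutant mPDAC samples
    basal_l2fc: float = 2.0            # module offset in basal / classical groups
    crc_l2fc: float = 2.0              # orthogonal CRC pattern on signature genes
    dosage_l2fc: float = 0.5           # mRNA shift for amplified chr1q genes
    n_background_mut_genes: int = 40
    background_mut_prob: float = 0.08
    libsize_sigma: float = 0.25        # lognormal library-size spread
    baseline_median_months: float = 14.0
    censor_months: float = 60.0
    protein_fraction: float = 0.4      # genes observed in the protein layer
    protein_noise_sd: float = 0.4
    protein_missing_prob: float = 0.15

    def __post_init__(self):
        for name in ("frac_wildtype", "arm_amp_prob", "chr8q_amp_prob",
                     "cca_amp_prob", "background_arm_amp_prob", "homdel_prob",
                     "tmb_fail_frac", "protein_fraction", "protein_missing_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_signature_genes >= self.gene_universe:
            raise ValueError("n_signature_genes must be < gene_universe")
        if self.frac_wildtype * self.n_pdac < 1:
            raise ValueError("config implies < 1 wildtype sample")


@dataclass
class Truth:
    """Planted structure, keyed to emitted entities."""

    signature_up: list[str]
    signature_down: list[str]
    basal_genes: list[str]
    classical_genes: list[str]
    crc_pattern: dict[str, float]
    batch_affected_genes: dict[str, float]   # gene -> per-unit batch log2 offset
    chr1q_carriers: list[str]
    chr8q_carriers: list[str]
    homdel_carriers: list[str]
    true_log_hr: float
    cluster_labels: dict[str, int]   # 1 CRC, 2 wildtype+CCA, 3 basal, 4 classical
    tmb_n_passing: dict[str, int]
    gene_lengths: dict[str, float]
    mut_freq_table: dict[str, tuple[float, float]]


@dataclass
class SyntheticCohort:
    config: SimConfig
    layout: GenomeLayout
    samples: list[Sample]
    variants: list[VariantCall]
    segments: list[CopySegment]
    ploidies: dict[str, float]
    fusions: list[FusionEvent]
    counts: ExpressionMatrix
    proteins: pd.DataFrame            # log2 intensities, NaN = not quantified
    clinical: pd.DataFrame
    exons: list[tuple[str, int, int]]  # 1-based inclusive
    blacklist: set[str]
    truth: Truth


# ---------------------------------------------------------------------------
# genome layout


def default_genome_layout(n_genes: int = 2000) -> GenomeLayout:
    """Reduced synthetic genome: chr1 (25 Mb), chr2-7 (12 Mb), chr8 (15 Mb),
    genes tiled evenly (8 kb bodies), with a handful of named driver /
    metabolic genes placed on fixed chromosomes."""
    chrom_lengths = {"chr1": 25_000_000, "chr8": 15_000_000}
    for i in range(2, 8):
        chrom_lengths[f"chr{i}"] = 12_000_000
    arm_split = {"chr1": 10_000_000, "chr8": 5_000_000}
    for i in range(2, 8):
        arm_split[f"chr{i}"] = 6_000_000

    total = sum(chrom_lengths.values())
    chroms = ["chr1"] + [f"chr{i}" for i in range(2, 8)] + ["chr8"]
    per_chrom = {c: max(1, int(round(n_genes * chrom_lengths[c] / total)))
                 for c in chroms}
    # adjust rounding drift on the largest chromosome
    per_chrom["chr1"] += n_genes - sum(per_chrom.values())

    names = _gene_names(n_genes, per_chrom, arm_split, chrom_lengths)
    genes: dict[str, tuple[str, int, int]] = {}
    idx = 0
    for c in chroms:
        k = per_chrom[c]
        spacing = chrom_lengths[c] // (k + 1)
        for j in range(k):
            start = (j + 1) * spacing
            genes[names[idx]] = (c, start, min(start + 8000 - 1, chrom_lengths[c]))
            idx += 1
    return GenomeLayout(chrom_lengths=chrom_lengths, arm_split=arm_split,
                        genes=genes)


def _gene_names(n_genes, per_chrom, arm_split, chrom_lengths) -> list[str]:
    """Generic G#### names, with named driver and metabolic symbols spliced
    in at fixed positions (chr1q gets NR5A2/PROX1/VTCN1)."""
    chroms = ["chr1"] + [f"chr{i}" for i in range(2, 8)] + ["chr8"]
    names = []
    counter = 1
    special_other = list(_SPECIAL_OTHER) + GLYCOLYTIC_GENES + CHOLESTEROGENIC_GENES
    chr1_n = per_chrom["chr1"]
    spacing1 = chrom_lengths["chr1"] // (chr1_n + 1)
    q_start_idx = arm_split["chr1"] // spacing1 + 1  # first gene index on chr1q
    chr1q_specials = dict(zip(range(q_start_idx + 5, q_start_idx + 5 + len(_SPECIAL_CHR1Q)),
                              _SPECIAL_CHR1Q))
    oi = 0
    for c in chroms:
        for j in range(per_chrom[c]):
            if c == "chr1" and j in chr1q_specials:
                names.append(chr1q_specials[j])
            elif c in ("chr3", "chr4", "chr5") and j % 9 == 4 and oi < len(special_other):
                names.append(special_other[oi])
                oi += 1
            else:
                names.append(f"G{counter:04d}")
                counter += 1
    return names


# ---------------------------------------------------------------------------
# cohort assembly


def _assign_samples(cfg: SimConfig, rng: np.random.Generator) -> list[Sample]:
    n_wt = int(round(cfg.frac_wildtype * cfg.n_pdac))
    samples = []
    for i in range(cfg.n_pdac):
        wt = i < n_wt
        batch = "batch2" if i % 2 == 0 else "batch3"  # no batch1 in mPDAC
        samples.append(Sample(
            sample_id=f"PDAC_{i + 1:03d}", cancer_type="mPDAC",
            kras_status="wildtype" if wt else "mutant", rnaseq_batch=batch,
            tumor_content=float(np.round(rng.uniform(0.3, 0.75), 3)),
            biopsy_site="liver" if rng.random() < 0.86 else "other"))
    for i in range(cfg.n_cca):
        samples.append(Sample(
            sample_id=f"CCA_{i + 1:03d}", cancer_type="CCA",
            kras_status="mutant" if rng.random() < 0.1 else "wildtype",
            rnaseq_batch=f"batch{i % 3 + 1}",
            tumor_content=float(np.round(rng.uniform(0.3, 0.75), 3)),
            biopsy_site="liver" if rng.random() < 0.79 else "other"))
    for i in range(cfg.n_crc):
        batch = "batch1" if i % 2 == 0 else "batch2"  # no batch3 in CRC
        samples.append(Sample(
            sample_id=f"CRC_{i + 1:03d}", cancer_type="CRC",
            kras_status="mutant" if rng.random() < 0.45 else "wildtype",
            rnaseq_batch=batch,
            tumor_content=float(np.round(rng.uniform(0.3, 0.75), 3)),
            biopsy_site="liver" if rng.random() < 0.75 else "other"))
    return samples


def _signature_partition(cfg: SimConfig, genes: list[str]) -> tuple[list, list, list, list]:
    """Deterministic choice of signature genes away from chr1/chr8 so the
    planted signature is not conflated with the dosage effect.

    The basal-like module genes are part of the down-regulated signature
    (suppressed in wildtype-like samples, elevated in the basal-like
    mutant subgroup); the classical module is separate from the signature
    (elevated only in classical mutants), so wildtype samples sit below
    classical mutants on classical genes while still receiving classical
    subtype calls.
    """
    layout_free = [g for g in genes if g.startswith("G")]
    # spread across the middle of the universe
    step = max(1, len(layout_free) // (cfg.n_signature_genes + 2))
    sig = [layout_free[(i + 1) * step] for i in range(cfg.n_signature_genes)]
    n_up = int(round(cfg.n_signature_genes * 0.4))
    up = sig[:n_up]
    down = sig[n_up:]
    n_basal = min(12, len(down) // 2)
    basal = down[:n_basal]
    classical = [layout_free[(i + 1) * step + step // 2] for i in range(n_basal)]
    classical = [g for g in classical if g not in sig][:max(4, n_basal)]
    return up, down, basal, classical


def simulate_expression(cfg: SimConfig, effects_log2: pd.DataFrame,
                        rng: np.random.Generator,
                        baseline: np.ndarray | None = None) -> ExpressionMatrix:
    """Negative-binomial counts with mean = baseline * 2^effect * libsize.

    ``effects_log2`` is a genes x samples matrix of planted log2 offsets.
    Variance follows mu + dispersion * mu^2; library sizes vary
    log-normally.  With dispersion -> 0 the counts are Poisson.
    """
    genes = list(effects_log2.index)
    n = effects_log2.shape[1]
    if baseline is None:
        baseline = np.exp(rng.normal(3.0, 1.2, size=len(genes)))  # mean counts
    libfac = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n))
    mu = baseline[:, None] * np.exp2(effects_log2.to_numpy()) * libfac[None, :]
    alpha = cfg.nb_dispersion
    if alpha <= 1e-9:
        counts = rng.poisson(mu)
    else:
        # NB as gamma-Poisson: shape r = 1/alpha, mean mu
        r = 1.0 / alpha
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts.astype(np.int64), index=genes,
                      columns=effects_log2.columns)
    return ExpressionMatrix(values=df, scale="raw_counts")


def _build_effects(cfg: SimConfig, samples: list[Sample], genes: list[str],
                   up, down, basal, classical, chr1q_carriers,
                   layout: GenomeLayout, rng) -> tuple[pd.DataFrame, dict, dict, dict]:
    sample_ids = [s.sample_id for s in samples]
    eff = pd.DataFrame(0.0, index=genes, columns=sample_ids)
    wt_like = [s.sample_id for s in samples
               if (s.cancer_type == "mPDAC" and s.kras_status == "wildtype")
               or s.cancer_type == "CCA"]
    mutant_pdac = [s.sample_id for s in samples
                   if s.cancer_type == "mPDAC" and s.kras_status == "mutant"]
    basal_samples = mutant_pdac[:cfg.n_basal]
    classical_samples = mutant_pdac[cfg.n_basal:]
    crc = [s.sample_id for s in samples if s.cancer_type == "CRC"]

    l2 = cfg.signature_l2fc
    eff.loc[up, wt_like] += l2
    eff.loc[down, wt_like] -= l2
    eff.loc[basal, basal_samples] += cfg.basal_l2fc
    eff.loc[classical, classical_samples] += cfg.basal_l2fc
    # the classical state also carries a coherent offset on the non-basal
    # down genes, giving both mutant subgroups recoverable profiles in
    # signature-gene space (two mutant clusters, as planted)
    non_basal_down = [g for g in down if g not in set(basal)]
    eff.loc[non_basal_down, classical_samples] += 0.75 * cfg.basal_l2fc
    # orthogonal CRC pattern over the signature genes
    sig = up + down
    crc_pattern = {g: (cfg.crc_l2fc if i % 2 == 0 else -cfg.crc_l2fc)
                   for i, g in enumerate(sig)}
    for g, v in crc_pattern.items():
        eff.loc[g, crc] += v

    # batch offsets on a fixed 20% gene subset, alternating sign
    affected = [g for i, g in enumerate(genes) if i % 5 == 0]
    batch_genes = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(affected)}
    sign_vec = np.array([batch_genes[g] for g in affected])
    batch_vec = np.array([cfg.batch_effects.get(s.rnaseq_batch, 0.0)
                          for s in samples])
    eff.loc[affected, :] += sign_vec[:, None] * batch_vec[None, :]

    # chr1q dosage effect in amplified carriers
    chr1q = [g for g, (c, st, en) in layout.genes.items()
             if c == "chr1" and st > layout.arm_split["chr1"]]
    eff.loc[chr1q, [sid for sid in chr1q_carriers if sid in sample_ids]] \
        += cfg.dosage_l2fc

    groups = {"wt_like": wt_like, "basal": basal_samples,
              "classical": classical_samples, "crc": crc}
    return eff, crc_pattern, batch_genes, groups


def simulate_cnv(cfg: SimConfig, samples: list[Sample], layout: GenomeLayout,
                 rng: np.random.Generator
                 ) -> tuple[list[CopySegment], dict[str, float], dict[str, list[str]]]:
    """Background segments at the sample ploidy, with whole-arm amplified
    segments (total_cn >= 2 * ploidy) in planted carriers and a focal
    CDKN2A homozygous deletion in a fraction of samples."""
    ploidies = {}
    segments = []
    carriers: dict[str, list[str]] = {"chr1q": [], "chr8q": [], "homdel": []}
    cdkn2a = layout.genes.get("CDKN2A")
    for s in samples:
        ploidy = float(np.round(rng.uniform(1.8, 4.2), 3))
        ploidies[s.sample_id] = ploidy
        wt_like = ((s.cancer_type == "mPDAC" and s.kras_status == "wildtype"))
        p1q = (cfg.arm_amp_prob if wt_like
               else cfg.cca_amp_prob if s.cancer_type == "CCA"
               else cfg.background_arm_amp_prob)
        p8q = (cfg.chr8q_amp_prob if wt_like
               else cfg.background_arm_amp_prob)
        amp1 = rng.random() < p1q
        amp8 = rng.random() < p8q
        homdel = rng.random() < cfg.homdel_prob and cdkn2a is not None
        if amp1:
            carriers["chr1q"].append(s.sample_id)
        if amp8:
            carriers["chr8q"].append(s.sample_id)
        if homdel:
            carriers["homdel"].append(s.sample_id)
        for chrom, length in layout.chrom_lengths.items():
            base_cn = float(np.round(ploidy * rng.uniform(0.85, 1.15), 3))
            base_cn = min(base_cn, 1.9 * ploidy)
            base_cn = max(base_cn, 0.6)
            amp_here = (chrom == "chr1" and amp1) or (chrom == "chr8" and amp8)
            if amp_here:
                split = layout.arm_split[chrom]
                amp_cn = float(np.round(2 * ploidy + rng.uniform(0.0, 1.0), 3))
                segments.append(CopySegment(s.sample_id, chrom, 1, split, base_cn))
                segments.append(CopySegment(s.sample_id, chrom, split + 1,
                                            length, amp_cn))
            elif homdel and cdkn2a is not None and chrom == cdkn2a[0]:
                _, gst, gen = cdkn2a
                segments.append(CopySegment(s.sample_id, chrom, 1, gst - 1, base_cn))
                segments.append(CopySegment(s.sample_id, chrom, gst, gen, 0.0))
                segments.append(CopySegment(s.sample_id, chrom, gen + 1,
                                            length, base_cn))
            else:
                segments.append(CopySegment(s.sample_id, chrom, 1, length, base_cn))
    return segments, ploidies, carriers


def _simulate_variants(cfg: SimConfig, samples: list[Sample],
                       layout: GenomeLayout, rng
                       ) -> tuple[list[VariantCall], set[str], dict[str, int]]:
    """Driver-gene presence/absence calls plus a TMB layer with known
    per-filter failures."""
    genes = list(layout.genes)
    bg_candidates = [g for g in genes if g.startswith("G")]
    step = max(1, len(bg_candidates) // (cfg.n_background_mut_genes + 1))
    bg_genes = [bg_candidates[(i + 1) * step + 3]
                for i in range(cfg.n_background_mut_genes)]
    variants: list[VariantCall] = []
    blacklist: set[str] = set()
    n_passing: dict[str, int] = {}
    consequences = ["missense", "nonsense", "inframe_indel", "frameshift"]

    def passing_variant(sid, gene):
        chrom, gst, gen = layout.genes[gene]
        pos = int(rng.integers(gst, gen + 1))
        depth = int(rng.integers(40, 140))
        vaf = float(np.round(rng.uniform(0.1, 0.6), 3))
        alt = max(3, int(round(vaf * depth)))
        alt = min(alt, depth)
        return VariantCall(sid, gene, chrom, pos, "C", "T",
                           str(rng.choice(consequences)), vaf, depth, alt)

    for s in samples:
        sid = s.sample_id
        count = 0
        if s.cancer_type == "mPDAC":
            col = 0 if s.kras_status == "wildtype" else 1
            for gene, probs in cfg.mut_freq_table.items():
                if gene in layout.genes and rng.random() < probs[col]:
                    variants.append(passing_variant(sid, gene))
                    count += 1
            tmb = cfg.tmb_target["wildtype" if col == 0 else "mutant"]
        else:
            drivers = {"KRAS": 0.45, "TP53": 0.6} if s.cancer_type == "CRC" \
                else {"TP53": 0.3}
            for gene, p in drivers.items():
                if gene in layout.genes and rng.random() < p:
                    variants.append(passing_variant(sid, gene))
                    count += 1
            tmb = 1.5
        for gene in bg_genes:
            if rng.random() < cfg.background_mut_prob:
                variants.append(passing_variant(sid, gene))
                count += 1
        # top up the passing-variant count toward the group TMB target
        target = max(count, int(rng.poisson(tmb * TMB_DENOMINATOR_MB)))
        extra_genes = rng.choice(bg_candidates, size=target - count, replace=True)
        for gene in extra_genes:
            variants.append(passing_variant(sid, str(gene)))
        n_passing[sid] = target

        # planted failures, one per filter class
        n_fail = rng.poisson(cfg.tmb_fail_frac * max(target, 1), size=4)
        chrom_list = list(layout.chrom_lengths)
        for _ in range(int(n_fail[0])):  # outside exons
            chrom = str(rng.choice(chrom_list))
            pos = _intergenic_position(layout, chrom, rng)
            variants.append(VariantCall(sid, "INTERGENIC", chrom, pos, "A", "G",
                                        "other", 0.3, 60, 18))
        for _ in range(int(n_fail[1])):  # blacklisted (common) variant
            v = passing_variant(sid, str(rng.choice(bg_genes)))
            # distinct alt allele so the blacklist key can never collide
            # with a planted-passing variant in another sample
            v = dataclasses.replace(v, alt="G")
            blacklist.add(v.key)
            variants.append(v)
        for _ in range(int(n_fail[2])):  # quality filter failure
            v = passing_variant(sid, str(rng.choice(bg_genes)))
            mode = int(rng.integers(3))
            if mode == 0:
                v = dataclasses.replace(v, vaf=0.03, alt_count=min(3, v.tumor_depth))
            elif mode == 1:
                v = dataclasses.replace(v, tumor_depth=20, alt_count=4)
            else:
                v = dataclasses.replace(v, alt_count=2)
            variants.append(v)
        for _ in range(int(n_fail[3])):  # non-qualifying consequence
            v = passing_variant(sid, str(rng.choice(bg_genes)))
            variants.append(dataclasses.replace(v, consequence="other"))
    return variants, blacklist, n_passing


def _intergenic_position(layout: GenomeLayout, chrom: str, rng) -> int:
    """A position on ``chrom`` that overlaps no gene body."""
    spans = sorted((st, en) for c, st, en in layout.genes.values() if c == chrom)
    for _ in range(100):
        pos = int(rng.integers(1, layout.chrom_lengths[chrom] + 1))
        if not any(st <= pos <= en for st, en in spans):
            return pos
    return 1  # gene bodies cover ~1% of the synthetic genome; unreachable


def simulate_clinical(cfg: SimConfig, samples: list[Sample],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Survival, age, CA19-9 and exclusion flags for the mPDAC samples.

    Overall survival is exponential with the wildtype hazard scaled by
    exp(planted_log_hr); censoring is independent uniform on
    (0, censor_months).  Wildtype patients are younger with lower CA19-9,
    mirroring the discovery cohort's clinical contrasts.
    """
    rows = []
    lam0 = np.log(2.0) / cfg.baseline_median_months
    pdac = [s for s in samples if s.cancer_type == "mPDAC"]
    mutant_ids = [s.sample_id for s in pdac if s.kras_status == "mutant"]
    excluded = set(mutant_ids[:3])  # trial-enrolled patients, flagged not named
    for s in pdac:
        wt = s.kras_status == "wildtype"
        lam = lam0 * (np.exp(cfg.planted_log_hr) if wt else 1.0)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0.0, cfg.censor_months)
        time = min(t, c)
        event = t <= c
        age = rng.normal(51.4, 4.5) if wt else rng.normal(60.9, 6.5)
        ca199 = float(np.exp(rng.normal(np.log(58.0 if wt else 4900.0), 1.5)))
        rows.append({
            "sample_id": s.sample_id,
            "os_months": float(np.round(max(time, 0.03), 4)),
            "os_event": bool(event),
            "kras_wildtype": int(wt),
            "age_at_diagnosis": float(np.round(age, 1)),
            "ca19_9": float(np.round(ca199, 1)),
            "excluded_from_os": s.sample_id in excluded,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_fusions(cfg: SimConfig, samples: list[Sample], rng
                      ) -> list[FusionEvent]:
    partners = [("NRG1", "ATP1B1"), ("NRG1", "APP"), ("FGFR2", "GCC2"),
                ("NTRK2", "THAP1"), ("BRAF", "TNS3"), ("NRG1", "SDC4"),
                ("FGFR2", "BICC1"), ("FGFR2", "SORBS1")]
    fusions = []
    wt_pdac = [s for s in samples
               if s.cancer_type == "mPDAC" and s.kras_status == "wildtype"]
    cca = [s for s in samples if s.cancer_type == "CCA"]
    n_wt_fused = int(round(len(wt_pdac) * 2 / 3))
    for i, s in enumerate(wt_pdac[:n_wt_fused]):
        a, b = partners[i % len(partners)]
        fusions.append(FusionEvent(s.sample_id, a, b, True, "high", True))
    n_cca_fused = int(round(len(cca) * 0.21))
    for i, s in enumerate(cca[:n_cca_fused]):
        a, b = partners[(i + 6) % len(partners)]
        fusions.append(FusionEvent(s.sample_id, a, b, True, "high", True))
    # passenger events that the in-frame/high-confidence filter removes
    for s in samples:
        if rng.random() < 0.3:
            fusions.append(FusionEvent(
                s.sample_id, "G0001", "G0002", bool(rng.random() < 0.5),
                str(rng.choice(["low", "medium"])), False))
    return fusions


def _simulate_proteins(cfg: SimConfig, counts: ExpressionMatrix,
                       effects: pd.DataFrame, rng) -> pd.DataFrame:
    """Log2 protein intensities for a gene subset, correlated with mRNA.

    Per-gene abundance tracks log mRNA baseline at the target across-gene
    rho; per-sample deviations carry half of the planted log2 effects so
    group-level protein fold changes echo the mRNA fold changes.
    """
    genes = counts.gene_ids
    k = int(len(genes) * cfg.protein_fraction)
    step = max(1, len(genes) // (k + 1))
    chosen = [genes[i * step] for i in range(1, k + 1)]
    for g in _SPECIAL_CHR1Q:
        if g in genes and g not in chosen:
            chosen.append(g)
    log_mean = np.log2(counts.values.loc[chosen].mean(axis=1) + 1.0)
    z = (log_mean - log_mean.mean()) / log_mean.std()
    rho = cfg.protein_mrna_rho
    base = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=len(chosen))
    prot = (base.to_numpy()[:, None]
            + 0.5 * effects.loc[chosen].to_numpy()
            + rng.normal(0.0, cfg.protein_noise_sd,
                         size=(len(chosen), counts.values.shape[1])))
    df = pd.DataFrame(prot, index=chosen, columns=counts.sample_ids)
    mask = rng.random(df.shape) < cfg.protein_missing_prob
    df = df.mask(mask)
    return df


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Build every layer of the synthetic cohort, deterministic under the
    config seed."""
    rng = np.random.default_rng(cfg.seed)
    layout = default_genome_layout(cfg.gene_universe)
    genes = list(layout.genes)
    samples = _assign_samples(cfg, rng)
    up, down, basal, classical = _signature_partition(cfg, genes)
    segments, ploidies, carriers = simulate_cnv(cfg, samples, layout, rng)
    effects, crc_pattern, batch_genes, groups = _build_effects(
        cfg, samples, genes, up, down, basal, classical,
        carriers["chr1q"], layout, rng)
    # equalize baselines within basal/classical pairs so rank-based
    # subtype scoring reflects the planted modules, not arbitrary baselines
    baseline = np.exp(rng.normal(3.0, 1.2, size=len(genes)))
    pos = {g: i for i, g in enumerate(genes)}
    for gb, gc in zip(basal, classical):
        baseline[pos[gc]] = baseline[pos[gb]]
    counts = simulate_expression(cfg, effects, rng, baseline=baseline)
    variants, blacklist, n_passing = _simulate_variants(cfg, samples, layout, rng)
    clinical = simulate_clinical(cfg, samples, rng)
    fusions = _simulate_fusions(cfg, samples, rng)
    proteins = _simulate_proteins(cfg, counts, effects, rng)
    exons = sorted(layout.genes.values())

    labels = {}
    for s in samples:
        if s.cancer_type == "CRC":
            labels[s.sample_id] = 1
        elif s.cancer_type == "CCA" or s.kras_status == "wildtype":
            labels[s.sample_id] = 2
        elif s.sample_id in groups["basal"]:
            labels[s.sample_id] = 3
        else:
            labels[s.sample_id] = 4

    gene_lengths = {g: float(en - st + 1) for g, (c, st, en) in layout.genes.items()}
    truth = Truth(
        signature_up=up, signature_down=down, basal_genes=basal,
        classical_genes=classical, crc_pattern=crc_pattern,
        batch_affected_genes=batch_genes,
        chr1q_carriers=carriers["chr1q"], chr8q_carriers=carriers["chr8q"],
        homdel_carriers=carriers["homdel"],
        true_log_hr=cfg.planted_log_hr, cluster_labels=labels,
        tmb_n_passing=n_passing, gene_lengths=gene_lengths,
        mut_freq_table=dict(cfg.mut_freq_table),
    )
    return SyntheticCohort(
        config=cfg, layout=layout, samples=samples, variants=variants,
        segments=sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start)),
        ploidies=ploidies, fusions=fusions, counts=counts, proteins=proteins,
        clinical=clinical, exons=exons, blacklist=blacklist, truth=truth)


# ---------------------------------------------------------------------------
# on-disk cohort directory


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every layer in the pipeline's standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples(cohort.samples, out / "samples.tsv")
    write_variant_table(cohort.variants, out / "variants.tsv")
    write_segments(cohort.segments, out / "segments.tsv")
    pd.DataFrame(sorted(cohort.ploidies.items()),
                 columns=["sample_id", "ploidy"]).to_csv(
        out / "ploidies.tsv", sep="\t", index=False)
    write_fusions(cohort.fusions, out / "fusions.tsv")
    write_expression_matrix(cohort.counts, out / "counts.tsv")
    prot = cohort.proteins.copy()
    prot.index.name = "gene"
    prot.to_csv(out / "proteins.tsv", sep="\t")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    write_bed(cohort.exons, out / "exons.bed")
    with open(out / "blacklist.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(cohort.blacklist):
            fh.write(key.replace(":", "\t") + "\n")
    pd.DataFrame(sorted(cohort.truth.gene_lengths.items()),
                 columns=["gene", "length"]).to_csv(
        out / "gene_lengths.tsv", sep="\t", index=False)
    write_layout(cohort.layout, out / "genome")


def write_layout(layout: GenomeLayout, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(layout.chrom_lengths.items()),
                 columns=["chrom", "length"]).to_csv(
        out / "chrom_lengths.tsv", sep="\t", index=False)
    with open(out / "cytoband.tsv", "w") as fh:
        for chrom, length in sorted(layout.chrom_lengths.items()):
            split = layout.arm_split[chrom]
            fh.write(f"{chrom}\t0\t{split}\tp11\tgneg\n")
            fh.write(f"{chrom}\t{split}\t{length}\tq11\tgneg\n")
    write_bed_with_names(layout.genes, out / "genes.bed")


def write_bed_with_names(genes: dict[str, tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for gene, (chrom, start, end) in genes.items():
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")


def read_layout(indir) -> GenomeLayout:
    indir = Path(indir)
    lengths = dict(pd.read_csv(indir / "chrom_lengths.tsv", sep="\t")
                   .itertuples(index=False, name=None))
    from .core_io import read_cytobands
    splits = read_cytobands(indir / "cytoband.tsv")
    genes = {}
    with open(indir / "genes.bed") as fh:
        for line in fh:
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            genes[name] = (chrom, int(start) + 1, int(end))
    return GenomeLayout(chrom_lengths=lengths, arm_split=splits, genes=genes)
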