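"""End-to-end orchestration of all analysis stages on a cohort directory.

The pipeline reads the standard layer files written by
:func:`kraswt.synthetic_data.write_cohort` (or assembled from real caller
outputs in the same formats), runs each stage in the discovery order —
clinical comparison, mutation landscape, spatial CNV, differential
expression, enrichment, subtyping, consensus clustering, survival,
proteomics — and writes one TSV per stage plus a manifest recording the
seed, parameter values and per-stage row counts.  Re-running with the
same inputs and seed reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (ConsensusParams, cluster_enrichment, confound_checks,
                        consensus_matrices, final_labels, select_k)
from .cnv_spatial import arm_group_summary, build_tracks, group_bin_frequency, make_bins
from .core_io import (ExpressionMatrix, filter_fusions, read_clinical,
                      read_expression_matrix, read_fusions, read_ploidies,
                      read_samples, read_segments, read_variant_table,
                      rpkm_log10, zscore_rows)
from .dea import fit_nb_wald, l2fc_by_cnv_class, select_signature
from .enrichment import enrich
from .mutation_landscape import (call_gene_cnv, compare_group_frequencies,
                                 compute_tmb, oncoprint_table,
                                 recurrence_filter, snv_event_matrix,
                                 tmb_filter)
from .proteomics import mrna_protein_rho, protein_group_l2fc
from .stats import fisher_exact_2x2, wilcoxon_ranksum
from .subtyping import moffitt_calls
from .survival import cox_fit, forward_select, km_curve, logrank, prepare_records
from .synthetic_data import read_layout

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_dir: str
    out_dir: str
    seed: int = 123
    group_col: str = "kras_status"
    de_p_thresh: float = 0.005
    de_l2fc_thresh: float = 2.5
    bin_width: int = 100_000
    consensus_reps: int = 50
    consensus_p_item: float = 0.8
    consensus_max_k: int = 6
    arm_threshold: float = 0.7
    tmb_vaf_min: float = 0.05
    tmb_depth_min: int = 25
    tmb_alt_min: int = 3
    moffitt_basal_cut: float = 0.75
    moffitt_classical_cut: float = 0.25
    forward_entry_p: float = 0.1
    recurrence_min_patients: int = 3
    gene_sets_path: str | None = None


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["stages"][stage] = {"file": path.name, "rows": int(len(df))}


def compare_clinical(clinical: pd.DataFrame, groups: dict[str, list[str]],
                     continuous: list[str] = ("age_at_diagnosis", "ca19_9"),
                     ) -> pd.DataFrame:
    """Group comparison of clinical covariates: rank-sum for continuous,
    Fisher for binary categoricals; medians and IQRs reported."""
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    rows = []
    for cov in continuous:
        if cov not in clinical.columns:
            continue
        va = clinical.loc[[i for i in ids_a if i in clinical.index], cov].dropna()
        vb = clinical.loc[[i for i in ids_b if i in clinical.index], cov].dropna()
        if len(va) < 2 or len(vb) < 2:
            rows.append({"covariate": cov, "type": "continuous",
                         "note": "skipped: insufficient data"})
            continue
        res = wilcoxon_ranksum(va.to_numpy(), vb.to_numpy())
        rows.append({
            "covariate": cov, "type": "continuous",
            f"median_{name_a}": float(va.median()),
            f"iqr_{name_a}": float(va.quantile(0.75) - va.quantile(0.25)),
            f"median_{name_b}": float(vb.median()),
            f"iqr_{name_b}": float(vb.quantile(0.75) - vb.quantile(0.25)),
            "p_value": res.p_value, "note": "",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    A stage whose input layer is absent is skipped with an explicit
    notice; any stage failure halts the run with the stage name while
    preserving completed outputs.
    """
    cdir = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "skipped": [],
    }
    stage = "setup"
    try:
        samples = read_samples(cdir / "samples.tsv")
        layout = read_layout(cdir / "genome")
        pdac = [s for s in samples if s.cancer_type == "mPDAC"]
        wt = [s.sample_id for s in pdac if s.kras_status == "wildtype"]
        mut = [s.sample_id for s in pdac if s.kras_status == "mutant"]
        groups = {"wildtype": wt, "mutant": mut}
        all_ids = [s.sample_id for s in samples]
        pdac_ids = [s.sample_id for s in pdac]

        stage = "clinical"
        clinical = read_clinical(cdir / "clinical.tsv")
        _write(compare_clinical(clinical, groups), out / "clinical_comparison.tsv",
               manifest, stage)

        stage = "mutation_landscape"
        variants = read_variant_table(cdir / "variants.tsv")
        segments = read_segments(cdir / "segments.tsv")
        ploidies = read_ploidies(cdir / "ploidies.tsv")
        fusions = filter_fusions(read_fusions(cdir / "fusions.tsv"))
        pdac_variants = [v for v in variants if v.sample_id in set(pdac_ids)]
        snv = snv_event_matrix(pdac_variants, pdac_ids)
        amp, dele = call_gene_cnv(
            [s for s in segments if s.sample_id in set(pdac_ids)],
            ploidies, layout)
        freq_tables = []
        for m in (snv, amp, dele):
            genes = recurrence_filter(m, config.recurrence_min_patients)
            if genes:
                t = compare_group_frequencies(m, groups, genes)
                t.insert(0, "event_class", m.event_class)
                freq_tables.append(t)
        _write(pd.concat(freq_tables, ignore_index=True),
               out / "frequency_comparison.tsv", manifest, stage)
        onco = oncoprint_table(
            [snv, amp, dele], sorted(set(
                recurrence_filter(snv, config.recurrence_min_patients)
                + list(dict(sorted(
                    ((g, c) for g, c in snv.matrix.sum(axis=1).items()),
                    key=lambda kv: -kv[1])).keys())[:20])))
        _write(onco, out / "oncoprint_events.tsv", manifest, "oncoprint")
        # fusion-group contingency
        fused = {f.sample_id for f in fusions if f.oncogenic}
        a = len(fused & set(wt)); c = len(fused & set(mut))
        fisher = fisher_exact_2x2(a, len(wt) - a, c, len(mut) - c)
        _write(pd.DataFrame([{
            "n_wildtype_fused": a, "n_wildtype": len(wt),
            "n_mutant_fused": c, "n_mutant": len(mut),
            "p_value": fisher.p_value}]), out / "fusion_enrichment.tsv",
            manifest, "fusions")

        stage = "tmb"
        from .core_io import read_bed
        exons = read_bed(cdir / "exons.bed")
        bl = pd.read_csv(cdir / "blacklist.tsv", sep="\t", dtype=str)
        blacklist = {f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
                     for r in bl.itertuples(index=False)}
        passing, attrition = tmb_filter(
            variants, exons, blacklist, vaf_min=config.tmb_vaf_min,
            depth_min=config.tmb_depth_min, alt_min=config.tmb_alt_min)
        tmb = compute_tmb(passing, all_ids)
        _write(tmb, out / "tmb.tsv", manifest, stage)
        manifest["stages"][stage]["attrition"] = attrition

        stage = "cnv_spatial"
        bins = make_bins(layout, config.bin_width, chroms=["chr1", "chr8"])
        track = build_tracks(segments, ploidies, bins)
        binfreq = group_bin_frequency(
            track, {"wildtype": wt, "mutant": mut,
                    "all": [s.sample_id for s in samples]})
        _write(binfreq, out / "cnv_bin_frequency.tsv", manifest, stage)
        arms = pd.concat([
            arm_group_summary(track, layout, arm, groups,
                              threshold=config.arm_threshold)
            for arm in ("chr1q", "chr8q")], ignore_index=True)
        _write(arms, out / "arm_summary.tsv", manifest, "arm_summary")

        stage = "dea"
        counts = read_expression_matrix(cdir / "counts.tsv", scale="raw_counts")
        pdac_counts = ExpressionMatrix(values=counts.values[pdac_ids],
                                       scale="raw_counts")
        batches = sorted({s.rnaseq_batch for s in pdac})
        design = pd.DataFrame(index=pdac_ids)
        for b in batches[1:]:
            design[f"batch_{b}"] = [
                1.0 if s.rnaseq_batch == b else 0.0 for s in pdac]
        design["kras_wildtype"] = [
            1.0 if s.kras_status == "wildtype" else 0.0 for s in pdac]
        fit = fit_nb_wald(pdac_counts, design)
        de = fit.results.reset_index()
        _write(de, out / "de_results.tsv", manifest, stage)
        signature = select_signature(fit.results, config.de_p_thresh,
                                     config.de_l2fc_thresh)
        (out / "signature_up.txt").write_text("\n".join(signature.up) + "\n")
        (out / "signature_down.txt").write_text("\n".join(signature.down) + "\n")
        manifest["stages"]["signature"] = {
            "n_up": len(signature.up), "n_down": len(signature.down),
            "lenient_up": signature.lenient_up,
            "lenient_down": signature.lenient_down}

        stage = "dosage"
        chr1_amp_genes = _amplified_gene_classes(
            freq_tables, layout, p_cuts=(0.05, 0.001))
        if chr1_amp_genes:
            classes = {"background": [g for g in fit.results.index
                                      if g not in set().union(*chr1_amp_genes.values())]}
            classes.update(chr1_amp_genes)
            try:
                _write(l2fc_by_cnv_class(fit.results, classes),
                       out / "l2fc_by_cnv_class.tsv", manifest, stage)
            except ValueError as exc:
                manifest["skipped"].append(f"{stage}: {exc}")
        else:
            manifest["skipped"].append(f"{stage}: no amplified gene class")

        stage = "enrichment"
        gmt_path = config.gene_sets_path
        if gmt_path is None:
            from importlib import resources
            ref = resources.files("kraswt.data") / "bailey_synthetic.gmt"
            with resources.as_file(ref) as p:
                gmt_path = str(p)
                from .core_io import read_gene_sets
                sets = read_gene_sets(gmt_path)
        else:
            from .core_io import read_gene_sets
            sets = read_gene_sets(gmt_path)
        universe = list(fit.results.index)
        enr = []
        for direction, genes in (("up", signature.up), ("down", signature.down)):
            if genes:
                e = enrich(genes, sets, universe)
                e.insert(0, "direction", direction)
                enr.append(e)
        if enr:
            _write(pd.concat(enr, ignore_index=True), out / "enrichment.tsv",
                   manifest, stage)
        else:
            manifest["skipped"].append(f"{stage}: empty signature")

        stage = "subtyping"
        gene_lengths = dict(pd.read_csv(
            cdir / "gene_lengths.tsv", sep="\t").itertuples(index=False, name=None))
        rpkm = rpkm_log10(pdac_counts, gene_lengths)
        calls = moffitt_calls(rpkm)
        _write(calls, out / "moffitt_calls.tsv", manifest, stage)
        call_map = calls.set_index("sample_id")["call"]
        tab = pd.crosstab(
            [("wildtype" if sid in set(wt) else "mutant") for sid in call_map.index],
            call_map.to_numpy())
        n_wt_cls = int(tab.loc["wildtype", "classical"]) if "classical" in tab else 0
        n_mut_cls = int(tab.loc["mutant", "classical"]) if "classical" in tab else 0
        moffitt_fisher = fisher_exact_2x2(
            n_wt_cls, len(wt) - n_wt_cls, n_mut_cls, len(mut) - n_mut_cls)
        _write(pd.DataFrame([{
            "n_wildtype_classical": n_wt_cls, "n_wildtype": len(wt),
            "n_mutant_classical": n_mut_cls, "n_mutant": len(mut),
            "p_value": moffitt_fisher.p_value}]),
            out / "moffitt_contingency.tsv", manifest, "moffitt_contingency")

        stage = "consensus"
        rpkm_all = rpkm_log10(counts, gene_lengths)
        sig_present = [g for g in signature.genes if g in rpkm_all.values.index]
        if len(sig_present) >= 3:
            z = zscore_rows(ExpressionMatrix(
                values=rpkm_all.values.loc[sig_present], scale="rpkm_log10"))
            params = ConsensusParams(
                k_range=tuple(range(2, config.consensus_max_k + 1)),
                reps=config.consensus_reps, p_item=config.consensus_p_item,
                seed=config.seed)
            result = consensus_matrices(z.values, params)
            k_star = select_k(result)
            labels = final_labels(result, k_star)
            delta = pd.DataFrame({
                "k": sorted(result.cdf_areas),
                "cdf_area": [result.cdf_areas[k] for k in sorted(result.cdf_areas)],
                "delta_area": [result.delta_areas[k] for k in sorted(result.cdf_areas)],
            })
            _write(delta, out / "consensus_delta.tsv", manifest, "consensus_delta")
            lab_df = labels.rename_axis("sample_id").reset_index()
            _write(lab_df, out / "consensus_labels.tsv", manifest, stage)
            ann_type = pd.Series({s.sample_id: s.cancer_type for s in samples})
            ann_kras = pd.Series({
                s.sample_id: ("wildtype_mPDAC" if s.cancer_type == "mPDAC"
                              and s.kras_status == "wildtype" else "other")
                for s in samples})
            enr_t = cluster_enrichment(labels, ann_type)
            enr_t.insert(0, "annotation", "cancer_type")
            enr_k = cluster_enrichment(labels, ann_kras)
            enr_k.insert(0, "annotation", "kras_wildtype_mPDAC")
            _write(pd.concat([enr_t, enr_k], ignore_index=True),
                   out / "cluster_enrichment.tsv", manifest, "cluster_enrichment")
            tc = pd.Series({s.sample_id: s.tumor_content for s in samples})
            batch = pd.Series({s.sample_id: s.rnaseq_batch for s in samples})
            checks = confound_checks(labels, tc, batch)
            manifest["stages"]["confounds"] = {
                "tumor_content_anova_p": checks["tumor_content_anova_p"],
                "dominated_clusters": checks["dominated_clusters"],
                "note": checks["note"]}
            manifest["stages"][stage]["k_star"] = k_star
        else:
            manifest["skipped"].append(f"{stage}: signature too small")

        stage = "survival"
        records = prepare_records(clinical)
        records = records[records.index.isin(pdac_ids)].copy()
        km = km_curve(records.reset_index(), "kras_wildtype")
        _write(km, out / "km_curves.tsv", manifest, "km")
        lr = logrank(records.reset_index(), "kras_wildtype")
        uni = cox_fit(records, ["kras_wildtype"])
        records["age_le_55"] = (records["age_at_diagnosis"] <= 55).astype(float)
        moffitt_map = calls.set_index("sample_id")["call"]
        records["moffitt_basal"] = [
            1.0 if moffitt_map.get(sid) == "basal-like" else 0.0
            for sid in records.index]
        selected, multi = forward_select(
            records, ["age_le_55", "moffitt_basal"],
            entry_p=config.forward_entry_p)
        surv_rows = uni.table.assign(model="univariate")
        if not multi.table.empty:
            surv_rows = pd.concat(
                [surv_rows, multi.table.assign(model="multivariate")],
                ignore_index=True)
        surv_rows["logrank_p"] = lr.p_value
        _write(surv_rows, out / "survival.tsv", manifest, stage)
        manifest["stages"][stage]["selected_covariates"] = selected

        stage = "proteomics"
        prot_path = cdir / "proteins.tsv"
        if prot_path.exists():
            proteins = pd.read_csv(prot_path, sep="\t", index_col=0)
            rho = mrna_protein_rho(rpkm_all.values, proteins)
            res = protein_group_l2fc(proteins, groups)
            table = res.table.reset_index()
            _write(table, out / "protein_de.tsv", manifest, stage)
            manifest["stages"][stage].update(
                {"mrna_protein_rho": rho["rho"], "rho_n_genes": rho["n_genes"],
                 "prior_df": res.prior_df})
        else:
            manifest["skipped"].append("proteomics: proteins.tsv absent")
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        logger.error("pipeline halted at stage %s", stage)
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out


def _amplified_gene_classes(freq_tables, layout, p_cuts=(0.05, 0.001)):
    """Chr1 genes whose amplification frequency differs at each p cut,
    restricted to those more frequent in the wildtype group."""
    amp = [t for t in freq_tables if (t["event_class"] == "amplification").all()]
    if not amp:
        return {}
    t = amp[0]
    chr1 = {g for g, (c, _, _) in layout.genes.items() if c == "chr1"}
    out = {}
    for cut in p_cuts:
        sel = t[(t["p_raw"] < cut) & (t["gene"].isin(chr1))
                & (t["freq_wildtype"] > t["freq_mutant"])]["gene"].tolist()
        if sel:
            out[f"chr1_amp_p{str(cut).replace('0.', '')}"] = sel
    return out
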