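"""NB-Wald differential expression: calibration, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from kraswt.core_io import ExpressionMatrix
from kraswt.dea import (confounder_scan, crosscohort_concordance,
                        fit_nb_wald, l2fc_by_cnv_class, prefilter_genes,
                        select_signature, size_factors)
from kraswt.synthetic_data import SimConfig, simulate_expression
from tests.conftest import make_counts


def simulate_de(seed, l2fc, n_sig=30, n_genes=600, n_wt=9, n_mut=54,
                dispersion=0.1, batch_l2fc=0.5):
    """Two-group NB counts with a planted signature and batch offsets."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(gene_universe=max(n_genes, 50), nb_dispersion=dispersion)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    ids = [f"s{i}" for i in range(n_wt + n_mut)]
    grp = np.array([1.0] * n_wt + [0.0] * n_mut)
    batch = np.array([float(i % 2) for i in range(n_wt + n_mut)])
    eff = pd.DataFrame(0.0, index=genes, columns=ids)
    sig = genes[:n_sig]
    if n_sig:
        eff.loc[sig, [i for i, g in zip(ids, grp) if g == 1]] += l2fc
    affected = genes[:: 5]
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(affected))])
    eff.loc[affected, :] += batch_l2fc * signs[:, None] * batch[None, :]
    counts = simulate_expression(cfg, eff, rng)
    design = pd.DataFrame({"batch2": batch, "kras_wildtype": grp}, index=ids)
    return counts, design, sig, affected, signs


class TestPrefilter:
    def test_zero_gene_excluded_half_included(self):
        m = make_counts([[0, 0, 0, 0], [1, 2, 0, 0], [1, 0, 0, 0]])
        kept = prefilter_genes(m)
        assert kept == ["g1"]  # non-zero in exactly half of 4 samples

    def test_matches_direct_tally(self, rng):
        vals = rng.integers(0, 3, size=(50, 11))
        m = make_counts(vals)
        need = int(np.ceil(11 / 2))
        expected = [g for g, row in zip(m.gene_ids, vals)
                    if (row > 0).sum() >= need]
        assert prefilter_genes(m) == expected


class TestSizeFactors:
    def test_identical_columns_all_one(self):
        m = make_counts(np.tile([[5], [10], [3]], (1, 4)))
        assert size_factors(m).to_numpy() == pytest.approx([1, 1, 1, 1])

    def test_doubled_column_factor(self):
        vals = np.tile([[50], [100], [30], [70]], (1, 3)).astype(float)
        vals[:, 2] *= 2
        m = make_counts(vals)
        s = size_factors(m)
        assert s.iloc[2] / s.iloc[0] == pytest.approx(2.0)

    def test_geometric_mean_one_and_gene_order_invariance(self, rng):
        vals = rng.integers(1, 500, size=(40, 6))
        m = make_counts(vals)
        s = size_factors(m)
        assert np.exp(np.log(s).mean()) == pytest.approx(1.0)
        perm = rng.permutation(40)
        m2 = ExpressionMatrix(values=m.values.iloc[perm], scale="raw_counts")
        assert size_factors(m2).to_numpy() == pytest.approx(s.to_numpy())

    def test_no_all_positive_gene_raises(self):
        m = make_counts([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(m)


class TestFitCalibration:
    def test_null_type_i_error(self):
        counts, design, _, _, _ = simulate_de(1, 0.0, n_sig=0, n_genes=2000)
        fit = fit_nb_wald(counts, design)
        frac = (fit.results["p_raw"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_planted_gene_recovery(self):
        counts, design, sig, _, _ = simulate_de(2, 3.0, n_sig=30, n_genes=600)
        fit = fit_nb_wald(counts, design)
        res = fit.results.loc[sig]
        assert (res["p_adj"] < 0.005).mean() >= 0.9
        assert abs(res["l2fc"].mean() - 3.0) < 0.2

    def test_batch_coefficient_recovered(self):
        counts, design, _, affected, signs = simulate_de(
            3, 0.0, n_sig=0, n_genes=600, batch_l2fc=1.0)
        fit = fit_nb_wald(counts, design)
        present = [g for g in affected if g in fit.results.index]
        est = fit.results.loc[present, "beta_batch2_l2"].to_numpy()
        exp = np.array([s for g, s in zip(affected, signs)
                        if g in fit.results.index])
        assert abs((est * exp).mean() - 1.0) < 0.2
        # and the group coefficient stays null
        assert (fit.results["p_raw"] < 0.05).mean() < 0.08

    def test_sample_permutation_invariance(self):
        counts, design, sig, _, _ = simulate_de(4, 2.0, n_sig=10, n_genes=200)
        fit1 = fit_nb_wald(counts, design)
        perm = np.random.default_rng(0).permutation(counts.values.shape[1])
        cols = [counts.sample_ids[i] for i in perm]
        counts2 = ExpressionMatrix(values=counts.values[cols],
                                   scale="raw_counts")
        fit2 = fit_nb_wald(counts2, design.loc[cols])
        assert fit2.results["l2fc"].to_numpy() == pytest.approx(
            fit1.results["l2fc"].to_numpy(), abs=1e-6)

    def test_requires_raw_counts_and_both_groups(self):
        counts, design, _, _, _ = simulate_de(5, 0.0, n_sig=0, n_genes=60)
        with pytest.raises(ValueError, match="raw counts"):
            fit_nb_wald(ExpressionMatrix(values=counts.values.astype(float),
                                         scale="rpkm_log10"), design)
        bad = design.copy()
        bad["kras_wildtype"] = 0.0
        with pytest.raises(ValueError):
            fit_nb_wald(counts, bad)


class TestSignatureSelection:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "p_adj", "l2fc"])
        df["p_raw"] = df["p_adj"] / 2
        return df.set_index("gene")

    def test_strict_thresholds(self):
        res = self._results([
            ("in_up", 0.004, 2.6),
            ("at_l2fc_boundary", 0.004, 2.5),   # excluded: > is strict
            ("at_p_boundary", 0.005, 3.0),      # excluded: < is strict
            ("in_down", 0.001, -2.6),
        ])
        sig = select_signature(res)
        assert sig.up == ["in_up"]
        assert sig.down == ["in_down"]

    def test_planted_signature_recovery_with_null_background(self):
        counts, design, sig_true, _, _ = simulate_de(
            6, 3.0, n_sig=30, n_genes=230)
        fit = fit_nb_wald(counts, design)
        sig = select_signature(fit.results)
        assert len(set(sig.up) & set(sig_true)) >= 27
        assert len(set(sig.up) - set(sig_true)) + len(sig.down) <= 2


class TestConfounderScan:
    def test_monotone_gene_flagged_and_permutation_destroys(self, rng):
        n = 40
        age = np.sort(rng.normal(60, 8, n))
        vals = rng.normal(size=(5, n))
        vals[0] = np.arange(n) * 0.5 + rng.normal(0, 0.01, n)  # monotone in age
        m = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(n)]), scale="rpkm_log10")
        clin = pd.DataFrame({"age_at_diagnosis": age, "ca19_9": rng.uniform(1, 100, n)},
                            index=m.sample_ids)
        out = confounder_scan([f"g{i}" for i in range(5)], m, clin)
        age_rows = out[out["covariate"] == "age_at_diagnosis"].set_index("gene")
        assert age_rows.loc["g0", "rho"] > 0.99
        assert age_rows.loc["g0", "flagged"]
        # permuting the covariate removes the flag
        clin2 = clin.copy()
        clin2["age_at_diagnosis"] = rng.permutation(age)
        out2 = confounder_scan(["g0"], m, clin2)
        assert not out2[out2["covariate"] == "age_at_diagnosis"]["flagged"].any()

    def test_null_covariate_raw_rate(self, rng):
        n = 60
        vals = rng.normal(size=(300, n))
        m = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(n)]), scale="rpkm_log10")
        clin = pd.DataFrame({"age_at_diagnosis": rng.normal(60, 8, n),
                             "ca19_9": rng.uniform(1, 100, n)},
                            index=m.sample_ids)
        out = confounder_scan(list(m.gene_ids), m, clin)
        frac = (out["p_raw"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.03


class TestL2fcByCnvClass:
    def _results(self, rng, shift):
        genes = [f"g{i}" for i in range(300)]
        l2fc = rng.normal(0, 0.5, 300)
        l2fc[:50] += shift
        return (pd.DataFrame({"l2fc": l2fc}, index=genes),
                {"background": genes[50:], "chr_amp_p05": genes[:50]})

    def test_planted_dosage_detected(self, rng):
        res, classes = self._results(rng, 0.3)
        out = l2fc_by_cnv_class(res, classes)
        row = out[out["gene_class"] == "chr_amp_p05"].iloc[0]
        assert row["p_vs_background"] < 0.01
        assert abs(row["median_l2fc"] - 0.3) < 0.1

    def test_null_and_identical_class(self, rng):
        res, classes = self._results(rng, 0.0)
        out = l2fc_by_cnv_class(res, classes)
        p = out[out["gene_class"] == "chr_amp_p05"]["p_vs_background"].iloc[0]
        assert 0.0 <= p <= 1.0
        classes["same"] = classes["background"]
        out = l2fc_by_cnv_class(res, classes)
        assert out[out["gene_class"] == "same"]["p_vs_background"].iloc[0] > 0.9

    def test_empty_class_raises(self, rng):
        res, classes = self._results(rng, 0.0)
        classes["empty"] = ["missing_gene"]
        with pytest.raises(ValueError):
            l2fc_by_cnv_class(res, classes)


class TestCrosscohort:
    def _sig(self):
        from kraswt.dea import SignatureGenes
        return SignatureGenes(up=[f"u{i}" for i in range(20)],
                              down=[f"d{i}" for i in range(20)],
                              p_thresh=0.005, l2fc_thresh=2.5)

    def test_replica_concordant_flip_discordant(self, rng):
        sig = self._sig()
        val = pd.Series(
            np.concatenate([rng.uniform(1, 3, 20), rng.uniform(-3, -1, 20)]),
            index=sig.up + sig.down)
        out = crosscohort_concordance(sig, val)
        assert (out["p_one_sided"] < 1e-3).all()
        out_flip = crosscohort_concordance(sig, -val)
        assert (out_flip["p_one_sided"] > 0.99).all()

    def test_independent_validation_near_uniform(self, rng):
        sig = self._sig()
        ps = []
        for _ in range(100):
            val = pd.Series(rng.normal(size=40), index=sig.up + sig.down)
            ps.extend(crosscohort_concordance(sig, val)["p_one_sided"])
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.04

    def test_too_few_genes_raises(self):
        sig = self._sig()
        val = pd.Series([1.0, 2.0], index=["u0", "u1"])
        with pytest.raises(ValueError):
            crosscohort_concordance(sig, val)
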