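"""Gene-level event calling, recurrence filter, frequency tests, TMB."""

import numpy as np
import pandas as pd
import pytest

from kraswt.core_io import CopySegment, GenomeLayout, VariantCall
from kraswt.mutation_landscape import (TMB_DENOMINATOR_MB, call_gene_cnv,
                                       compare_group_frequencies, compute_tmb,
                                       recurrence_filter, snv_event_matrix,
                                       tmb_filter)


def toy_layout():
    return GenomeLayout(
        chrom_lengths={"chr1": 10_000},
        arm_split={"chr1": 5_000},
        genes={"gA": ("chr1", 100, 200), "gB": ("chr1", 900, 1100),
               "gC": ("chr1", 6000, 6100)})


class TestCnvCalls:
    def test_amplification_boundary_inclusive(self):
        segs = [CopySegment("s1", "chr1", 1, 10_000, 4.0)]
        amp, dele = call_gene_cnv(segs, {"s1": 2.0}, toy_layout())
        assert amp.matrix["s1"].all()  # cn == 2*ploidy exactly
        segs = [CopySegment("s2", "chr1", 1, 10_000, 3.9)]
        amp, _ = call_gene_cnv(segs, {"s2": 2.0}, toy_layout())
        assert not amp.matrix["s2"].any()

    def test_homozygous_deletion_threshold(self):
        segs = [CopySegment("s1", "chr1", 100, 200, 0.0),
                CopySegment("s1", "chr1", 201, 10_000, 2.0)]
        _, dele = call_gene_cnv(segs, {"s1": 2.0}, toy_layout())
        assert dele.matrix.loc["gA", "s1"]
        assert not dele.matrix.loc["gB", "s1"]

    def test_missing_ploidy_raises(self):
        segs = [CopySegment("s1", "chr1", 1, 100, 2.0)]
        with pytest.raises(ValueError, match="ploidy"):
            call_gene_cnv(segs, {}, toy_layout())

    def test_matches_bruteforce_overlap_on_random_layouts(self, rng):
        for _ in range(50):
            n_genes = 12
            genes = {}
            for i in range(n_genes):
                st = int(rng.integers(1, 9_000))
                genes[f"g{i}"] = ("chr1", st, st + int(rng.integers(10, 800)))
            lay = GenomeLayout(chrom_lengths={"chr1": 10_000},
                               arm_split={"chr1": 5_000}, genes=genes)
            # random non-overlapping segments
            cuts = np.sort(rng.choice(np.arange(2, 10_000), size=6,
                                      replace=False))
            bounds = [1, *cuts, 10_000]
            ploidy = 2.0
            segs, states = [], []
            for a, b in zip(bounds[:-1], bounds[1:]):
                cn = float(rng.choice([0.0, 2.0, 5.0]))
                segs.append(CopySegment("s", "chr1", a, b, cn))
                states.append(cn)
                bounds[bounds.index(b)] = b + 1  # next starts after
            amp, dele = call_gene_cnv(segs, {"s": ploidy}, lay)
            for g, (c, gst, gen) in genes.items():
                exp_amp = any(s.total_cn >= 2 * ploidy and s.start <= gen
                              and s.end >= gst for s in segs)
                exp_del = any(s.total_cn < 0.5 and s.start <= gen
                              and s.end >= gst for s in segs)
                assert amp.matrix.loc[g, "s"] == exp_amp
                assert dele.matrix.loc[g, "s"] == exp_del


class TestRecurrenceFilter:
    def _matrix(self, counts):
        cols = [f"s{i}" for i in range(10)]
        rows = {}
        for g, k in counts.items():
            rows[g] = [i < k for i in range(10)]
        from kraswt.mutation_landscape import GeneEventMatrix
        return GeneEventMatrix("snv_indel",
                               pd.DataFrame.from_dict(rows, orient="index",
                                                      columns=cols))

    def test_strictly_more_than_threshold(self):
        m = self._matrix({"exactly3": 3, "four": 4, "zero": 0})
        assert recurrence_filter(m, 3) == ["four"]

    def test_matches_direct_count(self, rng):
        counts = {f"g{i}": int(rng.integers(0, 10)) for i in range(30)}
        m = self._matrix(counts)
        got = set(recurrence_filter(m, 3))
        assert got == {g for g, k in counts.items() if k > 3}


class TestFrequencyComparison:
    def test_single_gene_family_adjusted_equals_raw(self):
        from kraswt.mutation_landscape import GeneEventMatrix
        m = GeneEventMatrix("snv_indel", pd.DataFrame(
            [[True, False, True, False]], index=["g"],
            columns=["a", "b", "c", "d"]))
        out = compare_group_frequencies(
            m, {"wt": ["a", "b"], "mut": ["c", "d"]}, ["g"])
        assert out["p_adj"].iloc[0] == out["p_raw"].iloc[0]

    def test_planted_differential_gene_top_ranked(self, rng):
        from kraswt.mutation_landscape import GeneEventMatrix
        wt = [f"w{i}" for i in range(9)]
        mut = [f"m{i}" for i in range(54)]
        data = {}
        data["planted"] = [rng.random() < 0.8 for _ in wt] + \
            [rng.random() < 0.1 for _ in mut]
        for g in range(30):
            p = 0.2
            data[f"null{g}"] = [rng.random() < p for _ in wt + mut]
        m = GeneEventMatrix("snv_indel", pd.DataFrame.from_dict(
            data, orient="index", columns=wt + mut))
        out = compare_group_frequencies(m, {"wt": wt, "mut": mut},
                                        list(data))
        assert out["gene"].iloc[0] == "planted"
        assert out["p_adj"].iloc[0] < 0.01

    def test_absent_gene_raises(self):
        from kraswt.mutation_landscape import GeneEventMatrix
        m = GeneEventMatrix("snv_indel", pd.DataFrame(
            [[True, False]], index=["g"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            compare_group_frequencies(m, {"x": ["a"], "y": ["b"]}, ["nope"])


def _v(sample="s1", gene="gA", chrom="chr1", pos=150, vaf=0.3, depth=60,
       alt=18, consequence="missense", ref="C", altb="T"):
    return VariantCall(sample, gene, chrom, pos, ref, altb, consequence,
                       vaf, depth, alt)


class TestTmb:
    EXONS = [("chr1", 100, 200), ("chr1", 900, 1100)]

    def test_crafted_cascade_fixture(self):
        """Six variants, one failing each filter; two survive and the
        attrition log shows one per filter."""
        variants = [
            _v(pos=150),                                # passes
            _v(pos=950),                                # passes
            _v(pos=500),                                # non-exonic
            _v(pos=160, ref="G", altb="A"),             # blacklisted below
            _v(pos=170, vaf=0.04, alt=3),               # fails VAF
            _v(pos=180, consequence="other"),           # bad consequence
        ]
        blacklist = {"chr1:160:G:A"}
        survivors, attrition = tmb_filter(variants, self.EXONS, blacklist)
        assert len(survivors) == 2
        assert attrition["non_exonic"] == 1
        assert attrition["blacklisted"] == 1
        assert attrition["quality"] == 1
        assert attrition["consequence"] == 1
        tmb = compute_tmb(survivors, ["s1"])
        assert tmb["tmb"].iloc[0] == pytest.approx(2 / 32.102474)

    def test_vaf_boundary_inclusive(self):
        v = _v(vaf=0.05, depth=25, alt=3)
        survivors, _ = tmb_filter([v], self.EXONS, set())
        assert survivors == [v]

    def test_empty_input(self):
        survivors, attrition = tmb_filter([], self.EXONS, set())
        assert survivors == [] and attrition["input"] == 0

    def test_tmb_linear_in_count(self):
        variants = [_v(pos=100 + i) for i in range(4)]
        out = compute_tmb(variants, ["s1", "s_empty"])
        got = out.set_index("sample_id")
        assert got.loc["s1", "tmb"] == pytest.approx(4 / TMB_DENOMINATOR_MB)
        assert got.loc["s_empty", "tmb"] == 0.0
        assert got.loc["s1", "tmb"] == pytest.approx(0.1246, abs=2e-4)

    def test_321_variants_is_ten_per_mb(self):
        variants = [_v(pos=150, sample=f"s{i % 1}") for i in range(321)]
        out = compute_tmb(variants, ["s0"])
        assert out["tmb"].iloc[0] == pytest.approx(10.0, abs=0.01)

    def test_filter_order_irrelevant(self, rng):
        variants = []
        for i in range(100):
            variants.append(_v(
                pos=int(rng.integers(1, 1200)),
                vaf=float(rng.uniform(0, 0.6)),
                depth=int(rng.integers(10, 100)),
                alt=int(rng.integers(0, 10)),
                consequence=str(rng.choice(
                    ["missense", "other", "frameshift"]))))
        variants = [v for v in variants if v.alt_count <= v.tumor_depth]
        s1, _ = tmb_filter(variants, self.EXONS, set())
        s2, _ = tmb_filter(list(reversed(variants)), self.EXONS, set())
        assert set(id(v) for v in s1) == set(id(v) for v in s2)


class TestSnvMatrix:
    def test_multiple_variants_count_once_per_patient(self):
        variants = [_v(pos=150), _v(pos=160), _v(sample="s2", pos=150)]
        m = snv_event_matrix(variants, ["s1", "s2", "s3"])
        assert m.matrix.loc["gA"].tolist() == [True, True, False]
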