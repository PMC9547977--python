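"""Readers/writers, domain-type invariants and expression transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kraswt.core_io import (CopySegment, ExpressionMatrix, FusionEvent,
                            GeneSetCollection, GenomeLayout, ValidationError,
                            VariantCall, filter_fusions, read_bed,
                            read_gene_sets, read_segments, read_variant_table,
                            rpkm_log10, write_bed, write_gene_sets,
                            write_segments, write_variant_table, zscore_rows)
from tests.conftest import make_counts


def _variant_rows():
    return pd.DataFrame([
        dict(sample_id="s1", gene="TP53", chrom="chr3", pos=100, ref="C",
             alt="T", consequence="missense", vaf=0.3, tumor_depth=60,
             alt_count=18),
        dict(sample_id="s1", gene="KRAS", chrom="chr3", pos=200, ref="G",
             alt="A", consequence="nonsense", vaf=0.5, tumor_depth=40,
             alt_count=20),
        dict(sample_id="s2", gene="TP53", chrom="chr3", pos=100, ref="C",
             alt="T", consequence="frameshift", vaf=0.1, tumor_depth=100,
             alt_count=10),
    ])


class TestVariantTable:
    def test_roundtrip_identity(self, tmp_path):
        path = tmp_path / "v.tsv"
        _variant_rows().to_csv(path, sep="\t", index=False)
        variants = read_variant_table(path)
        assert len(variants) == 3
        out = tmp_path / "v2.tsv"
        write_variant_table(variants, out)
        assert read_variant_table(out) == variants

    def test_alt_exceeding_depth_names_row(self, tmp_path):
        df = _variant_rows()
        df.loc[1, "alt_count"] = 45  # depth 40
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="row 2"):
            read_variant_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        df = _variant_rows().drop(columns=["vaf"])
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="vaf"):
            read_variant_table(path)


class TestSegments:
    def test_disjoint_segments_accepted_and_sorted(self, tmp_path, rng):
        starts = np.cumsum(rng.integers(10, 100, size=1000))
        rows = [dict(sample_id="s1", chrom="chr1", start=int(a), end=int(a + 5),
                     total_cn=2.0) for a in starts]
        rng.shuffle(rows)
        path = tmp_path / "seg.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        segs = read_segments(path)
        assert len(segs) == 1000
        assert all(s1.start < s2.start for s1, s2 in zip(segs, segs[1:]))

    def test_overlap_within_sample_rejected(self, tmp_path):
        rows = [dict(sample_id="s1", chrom="chr1", start=1, end=100, total_cn=2),
                dict(sample_id="s1", chrom="chr1", start=50, end=200, total_cn=3)]
        path = tmp_path / "seg.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="overlap"):
            read_segments(path)

    def test_same_interval_other_sample_ok(self, tmp_path):
        rows = [dict(sample_id="s1", chrom="chr1", start=1, end=100, total_cn=2),
                dict(sample_id="s2", chrom="chr1", start=1, end=100, total_cn=2)]
        path = tmp_path / "seg.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        assert len(read_segments(path)) == 2

    def test_roundtrip(self, tmp_path):
        segs = [CopySegment("s1", "chr1", 1, 10, 2.5),
                CopySegment("s1", "chr2", 5, 9, 0.0)]
        path = tmp_path / "seg.tsv"
        write_segments(segs, path)
        assert read_segments(path) == segs


class TestGeneSets:
    def test_read_dedup_and_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg2\tg3\n"
                        "setB\tother\tg4\tg5\n")
        coll = read_gene_sets(path)
        assert len(coll) == 2
        assert coll.members("setA") == ("g1", "g2", "g3")
        out = tmp_path / "out.gmt"
        write_gene_sets(coll, out)
        assert read_gene_sets(out).sets == coll.sets

    def test_short_line_is_format_error(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("setA\tdesc\n")
        with pytest.raises(ValueError):
            read_gene_sets(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            GeneSetCollection(sets={"s": ("d", ())})


class TestFusions:
    def test_filter_keeps_only_inframe_high(self):
        keep = FusionEvent("s1", "NRG1", "ATP1B1", True, "high", True)
        events = [
            keep,
            FusionEvent("s1", "A", "B", True, "medium", False),
            FusionEvent("s1", "C", "D", False, "high", False),
        ]
        assert filter_fusions(events) == [keep]
        assert filter_fusions([]) == []

    def test_self_fusion_rejected(self):
        with pytest.raises(ValidationError):
            FusionEvent("s1", "NRG1", "NRG1", True, "high", True)


class TestBed:
    def test_coordinate_conversion_roundtrip(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\nchr2\t50\t60\n")
        iv = read_bed(path)
        assert iv == [("chr1", 1, 100), ("chr2", 51, 60)]
        out = tmp_path / "w.bed"
        write_bed(iv, out)
        assert read_bed(out) == iv


class TestRpkm:
    def test_all_zero_counts_map_to_zero(self):
        m = make_counts(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            rpkm_log10(m, {g: 1000.0 for g in m.gene_ids})  # zero library

    def test_hand_arithmetic_single_gene(self):
        # 100 reads, 1 kb gene, library 1e6 -> RPKM 100 -> log10(101)
        vals = np.array([[100], [999_900]])
        m = make_counts(vals)
        out = rpkm_log10(m, {"g0": 1000.0, "g1": 999_900.0})
        assert out.values.iloc[0, 0] == pytest.approx(np.log10(101.0))
        assert out.scale == "rpkm_log10"

    def test_library_scale_invariance_up_to_pseudocount(self, rng):
        vals = rng.integers(1, 500, size=(20, 4))
        m = make_counts(vals)
        lengths = {g: float(rng.integers(500, 5000)) for g in m.gene_ids}
        a = rpkm_log10(m, lengths).values
        b = rpkm_log10(make_counts(vals * 2), lengths).values
        # doubling every count leaves RPKM unchanged exactly
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_missing_gene_length_listed(self):
        m = make_counts([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="g1"):
            rpkm_log10(m, {"g0": 100.0})


class TestZscore:
    def test_closed_form_row(self):
        m = ExpressionMatrix(values=pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")),
            scale="rpkm_log10")
        z = zscore_rows(m)
        assert z.values.loc["g"].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])
        # population-sd convention would give +-1.2247; sample sd gives +-1
        assert z.scale == "zscore"

    def test_constant_row_zeroed_with_warning(self):
        m = ExpressionMatrix(values=pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], index=["flat", "g"],
            columns=list("abc")), scale="rpkm_log10")
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_rows(m)
        assert (z.values.loc["flat"] == 0).all()

    @given(st.integers(3, 8), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_and_location_scale_invariant(self, n, seed):
        r = np.random.default_rng(seed)
        vals = r.normal(size=(4, n))
        vals[0] = vals[1] * 3.5 - 2.0  # affine copy of another row
        m = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(n)]), scale="rpkm_log10")
        z = zscore_rows(m)
        zz = zscore_rows(z)
        assert np.allclose(z.values.to_numpy(), zz.values.to_numpy())
        assert np.allclose(z.values.iloc[0].to_numpy(),
                           z.values.iloc[1].to_numpy())


class TestTypes:
    def test_vaf_bounds(self):
        with pytest.raises(ValidationError):
            VariantCall("s", "g", "chr1", 1, "A", "T", "missense", 1.2, 10, 3)

    def test_genome_layout_validation(self):
        with pytest.raises(ValidationError):
            GenomeLayout(chrom_lengths={"chr1": 100}, arm_split={"chr1": 200},
                         genes={})
        with pytest.raises(ValidationError):
            GenomeLayout(chrom_lengths={"chr1": 100}, arm_split={"chr1": 50},
                         genes={"g": ("chr1", 10, 150)})

    def test_arm_interval(self):
        lay = GenomeLayout(chrom_lengths={"chr1": 100}, arm_split={"chr1": 40},
                           genes={})
        assert lay.arm_interval("chr1p") == ("chr1", 1, 40)
        assert lay.arm_interval("chr1q") == ("chr1", 41, 100)
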