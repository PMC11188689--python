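"""Generator invariants: tiling, uniqueness, conservation, determinism,
and the closed-form selection model."""

import numpy as np
import pandas as pd
import pytest

from barfit import barseq, simulate
from barfit.errors import ConfigurationError, SizingError
from barfit.genome import GenomeAnnotation
from barfit.io import iter_fastq


class TestGenome:
    def test_tiling_no_overlaps(self):
        annotation, seq = simulate.simulate_genome(3_000_000, 3000, seed=1)
        g = annotation.genes
        assert len(g) == 3000
        assert len(seq) == 3_000_000
        assert (g["start"] >= 0).all() and (g["end"] <= 3_000_000).all()
        assert (g["end"] - g["start"] >= 300).all()
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_annotation_roundtrip(self, tmp_path):
        annotation, _ = simulate.simulate_genome(
            10_000, 1, seed=7, annotation_path=tmp_path / "ann.tsv"
        )
        back = GenomeAnnotation.from_tsv(tmp_path / "ann.tsv")
        assert back.length == annotation.length
        pd.testing.assert_frame_equal(back.genes, annotation.genes)

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        for run in ("a", "b"):
            simulate.simulate_genome(
                5_000,
                10,
                seed=42,
                fasta_path=tmp_path / f"{run}.fasta",
                annotation_path=tmp_path / f"{run}.tsv",
            )
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_impossible_tiling_raises(self):
        with pytest.raises(SizingError):
            simulate.simulate_genome(1_000, 10, seed=1)


class TestLibrary:
    def test_coding_fraction_within_binomial_bounds(self):
        annotation, _ = simulate.simulate_genome(3_000_000, 3000, seed=2)
        pool, ab = simulate.simulate_library(annotation, 60_000, coding_fraction=0.9, seed=3)
        assert pool["barcode"].is_unique and pool["pos"].is_unique
        n_assigned = pool["gene_id"].notna().sum()
        mean, sd = 60_000 * 0.9, np.sqrt(60_000 * 0.9 * 0.1)
        assert abs(n_assigned - mean) < 4 * sd
        assert abs(ab.sum() - 1.0) < 1e-12

    def test_all_coding_when_fraction_one(self, small_genome):
        annotation, _ = small_genome
        pool, _ = simulate.simulate_library(annotation, 100, coding_fraction=1.0, seed=4)
        assert pool["gene_id"].notna().all()

    def test_gene_assignment_matches_annotation(self, small_genome, small_library):
        annotation, _ = small_genome
        pool, _ = small_library
        expected = annotation.assign(pool["pos"].to_numpy())
        assert list(pool["gene_id"]) == list(expected)


class TestSelection:
    def test_neutral_effects_leave_proportions_unchanged(self, small_library):
        pool, ab = small_library
        out = simulate.simulate_selection(ab, {}, [("control", 0), ("filtered", 2)], pool)
        np.testing.assert_allclose(out[("filtered", 2)], out[("control", 0)])

    def test_single_gene_effect_closed_form(self):
        # 4 strains, one (in gene gA) holding 1% of mass with effect +1:
        # renormalization gives 2/(1.01) for it and 1/(1.01) for the rest.
        pool = pd.DataFrame(
            {
                "barcode": ["b1", "b2", "b3", "b4"],
                "rname": "chr",
                "pos": [0, 10, 20, 30],
                "strand": "+",
                "n_support": 1,
                "n_conflict": 0,
                "gene_id": ["gA", None, None, None],
            }
        )
        ab = pd.Series([0.01, 0.33, 0.33, 0.33], index=pool["barcode"])
        out = simulate.simulate_selection(
            ab, {"gA": {("filtered", 2): 1.0}}, [("control", 0), ("filtered", 2)], pool
        )
        p = out[("filtered", 2)]
        np.testing.assert_allclose(p["b1"] / 0.01, 2 / 1.01)
        np.testing.assert_allclose(p["b2"] / 0.33, 1 / 1.01)
        np.testing.assert_allclose(p.sum(), 1.0)

    def test_strong_negative_effect_stays_finite(self, small_library):
        pool, ab = small_library
        gene = pool["gene_id"].dropna().iloc[0]
        out = simulate.simulate_selection(
            ab, {gene: {("filtered", 2): -30.0}}, [("control", 0), ("filtered", 2)], pool
        )
        p = out[("filtered", 2)]
        assert np.isfinite(p).all()
        mask = (pool["gene_id"] == gene).to_numpy()
        assert p.to_numpy()[mask].max() < 1e-7

    def test_schedule_must_include_day0(self, small_library):
        pool, ab = small_library
        with pytest.raises(ConfigurationError):
            simulate.simulate_selection(ab, {}, [("filtered", 2)], pool)

    def test_unknown_gene_rejected(self, small_genome, small_library):
        annotation, _ = small_genome
        pool, ab = small_library
        with pytest.raises(ConfigurationError):
            simulate.simulate_selection(
                ab, {"nope": {("filtered", 2): 1.0}}, [("control", 0)], pool, annotation
            )


class TestBarseqReads:
    def test_even_split_within_binomial_bounds(self):
        ab = pd.Series([0.5, 0.5], index=["A" * 20, "C" * 20])
        counts = simulate.write_barseq_reads(ab, 10_000, seed=5)
        assert counts.sum() == 10_000  # multinomial conservation, exact
        assert abs(counts.iloc[0] - 5_000) < 4 * 50  # binomial sd = 50

    def test_zero_depth_gives_empty_counts(self):
        ab = pd.Series([1.0], index=["A" * 20])
        counts = simulate.write_barseq_reads(ab, 0, seed=5)
        assert counts.sum() == 0

    def test_fastq_reads_reproduce_counts(self, tmp_path, small_library):
        pool, ab = small_library
        path = tmp_path / "bs.fastq"
        counts = simulate.write_barseq_reads(ab, 2_000, offset=10, seed=6, path=path)
        col, stats = barseq.count_barcodes(str(path), pool, offset=10)
        assert stats["mapped_fraction"] == 1.0
        pd.testing.assert_series_equal(col, counts.astype(col.dtype), check_names=False)


class TestMappingReads:
    def test_defect_bookkeeping_exact(self, tmp_path, small_genome, small_library):
        annotation, seq = small_genome
        pool, _ = small_library
        truth = simulate.write_mapping_fastq(
            pool, seq, 1_000, invalid_mix={"bad-length": 50}, seed=7,
            path=tmp_path / "m.fastq",
        )
        assert (truth["category"] == "bad-length").sum() == 50
        assert (truth["category"] == "ok").sum() == 950

    def test_more_defects_than_reads_rejected(self, tmp_path, small_genome, small_library):
        _, seq = small_genome
        pool, _ = small_library
        with pytest.raises(SizingError):
            simulate.write_mapping_fastq(
                pool, seq, 10, invalid_mix={"no-U2": 20}, seed=7, path=tmp_path / "m.fastq"
            )

    def test_flank_errors_within_binomial_bounds(self, tmp_path, small_genome, small_library):
        annotation, seq = small_genome
        pool, _ = small_library
        rate, n_reads, flank_len = 0.01, 2_000, 50
        path = tmp_path / "err.fastq"
        truth = simulate.write_mapping_fastq(
            pool, seq, n_reads, error_rate=rate, seed=8, path=path, flank_len=flank_len
        )
        truth = truth.set_index("read_id")
        by_barcode = pool.set_index("barcode")
        mismatches = 0
        for title, read_seq, _q in iter_fastq(path):
            row = by_barcode.loc[truth.loc[title, "barcode"]]
            flank = simulate._flank_at(seq, int(row["pos"]), row["strand"], flank_len)
            observed = read_seq[-flank_len:]
            mismatches += sum(a != b for a, b in zip(flank, observed))
        total_bases = n_reads * flank_len
        mean, sd = total_bases * rate, np.sqrt(total_bases * rate * (1 - rate))
        assert abs(mismatches - mean) < 4 * sd

    def test_byte_identical_fastq_for_same_seed(self, tmp_path, small_genome, small_library):
        _, seq = small_genome
        pool, _ = small_library
        for run in ("a", "b"):
            simulate.write_mapping_fastq(
                pool, seq, 500, invalid_mix={"low-quality": 5}, seed=9,
                path=tmp_path / f"{run}.fastq", truth_path=tmp_path / f"{run}.tsv",
            )
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
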