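"""Read screening, flank placement and pool construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barfit import simulate, tnmap
from barfit.genome import GenomeAnnotation
from barfit.tnmap import U1, U2

Q40 = lambda n: "I" * n  # noqa: E731
BC = "A" * 20


def make_read(barcode=BC, flank="G" * 40, u2=U2, barcode_qual=None):
    seq = U1 + barcode + u2 + flank
    qual = Q40(len(U1)) + (barcode_qual or Q40(len(barcode))) + Q40(len(u2) + len(flank))
    return seq, qual


class TestScanRead:
    def test_clean_read_accepted_with_barcode(self):
        seq, qual = make_read()
        res = tnmap.scan_read(seq, qual)
        assert res.status == "ok"
        assert res.barcode == BC
        assert res.flank == "G" * 40

    def test_barcode_of_19_bases_is_bad_length(self):
        seq, qual = make_read(barcode="A" * 19)
        assert tnmap.scan_read(seq, qual).status == "bad-length"

    def test_quality_exactly_30_rejected(self):
        # Q>30 is strict: chr(30+33) = '?' fails, chr(31+33) = '@' passes
        qual_bad = "I" * 10 + "?" + "I" * 9
        seq, qual = make_read(barcode_qual=qual_bad)
        assert tnmap.scan_read(seq, qual).status == "low-quality"
        seq, qual = make_read(barcode_qual="I" * 10 + "@" + "I" * 9)
        assert tnmap.scan_read(seq, qual).status == "ok"

    def test_missing_sites(self):
        assert tnmap.scan_read("T" * 60, Q40(60)).status == "no-U1"
        seq = U1 + BC + "T" * 30
        assert tnmap.scan_read(seq, Q40(len(seq))).status == "no-U2"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tnmap.scan_read("ACGT", "II")

    @settings(derandomize=True, max_examples=30)
    @given(prefix=st.text(alphabet="ACGT", max_size=25))
    def test_prepending_bases_does_not_change_result(self, prefix):
        seq, qual = make_read()
        shifted = tnmap.scan_read(prefix + seq, Q40(len(prefix)) + qual)
        assert shifted.status == "ok"
        assert shifted.barcode == BC


@pytest.fixture(scope="module")
def reference():
    return simulate.random_sequence(5_000, np.random.default_rng(21))


class TestAlignFlank:
    def test_planted_forward_flank(self, reference):
        hit = tnmap.align_flank(reference[1234:1284], reference)
        assert (hit.status, hit.position, hit.strand) == ("hit", 1234, "+")

    def test_planted_reverse_flank(self, reference):
        flank = simulate.revcomp(reference[1000:1050])
        hit = tnmap.align_flank(flank, reference)
        # first flank base corresponds to the rightmost base of the window
        assert (hit.status, hit.position, hit.strand) == ("hit", 1049, "-")

    def test_wrap_around_origin(self, reference):
        flank = reference[-20:] + reference[:30]
        hit = tnmap.align_flank(flank, reference)
        assert (hit.status, hit.position, hit.strand) == ("hit", len(reference) - 20, "+")

    def test_repeat_is_ambiguous(self):
        unit = simulate.random_sequence(100, np.random.default_rng(22))
        ref = unit + simulate.random_sequence(300, np.random.default_rng(23)) + unit
        assert tnmap.align_flank(unit[:50], ref).status == "ambiguous"

    def test_short_and_absent_flanks(self, reference):
        assert tnmap.align_flank("ACGT", reference).status == "short"
        absent = "A" * 50
        if absent in reference:  # pragma: no cover - astronomically unlikely
            pytest.skip("homopolymer present in random reference")
        assert tnmap.align_flank(absent, reference).status == "none"

    def test_mismatches_tolerated_outside_seed(self, reference):
        flank = list(reference[2000:2050])
        flank[45] = {"A": "C"}.get(flank[45], "A")
        hit = tnmap.align_flank("".join(flank), reference, max_mismatch=3)
        assert (hit.status, hit.position) == ("hit", 2000)

    def test_agrees_with_brute_force_oracle(self):
        """Exhaustive all-positions scan over both strands as the oracle."""
        rng = np.random.default_rng(24)
        ref = simulate.random_sequence(10_000, rng)
        L, flen, min_len = len(ref), 50, 30
        enc = np.frombuffer((ref + ref[: flen - 1]).encode(), dtype=np.uint8)
        fwd_windows = np.lib.stride_tricks.sliding_window_view(enc, flen)[:L]

        def oracle(flank):
            fl = np.frombuffer(flank.encode(), dtype=np.uint8)
            cand = set()
            seed_ok = (fwd_windows[:, :min_len] == fl[:min_len]).all(axis=1)
            ext_mm = (fwd_windows[:, min_len:] != fl[min_len:]).sum(axis=1)
            for p in np.nonzero(seed_ok & (ext_mm <= 3))[0]:
                cand.add((int(p), "+"))
            rc = np.frombuffer(simulate.revcomp(flank).encode(), dtype=np.uint8)
            rc_seed_ok = (fwd_windows[:, flen - min_len :] == rc[flen - min_len :]).all(axis=1)
            rc_mm = (fwd_windows[:, : flen - min_len] != rc[: flen - min_len]).sum(axis=1)
            for p in np.nonzero(rc_seed_ok & (rc_mm <= 3))[0]:
                cand.add(((int(p) + flen - 1) % L, "-"))
            if not cand:
                return ("none", None, None)
            if len(cand) > 1:
                return ("ambiguous", None, None)
            pos, strand = cand.pop()
            return ("hit", pos, strand)

        for i in range(1000):
            kind = i % 10
            if kind < 4:  # planted forward
                p = int(rng.integers(0, L))
                flank = (ref + ref)[p : p + flen]
            elif kind < 8:  # planted reverse
                p = int(rng.integers(0, L))
                flank = simulate.revcomp((ref + ref)[p : p + flen])
            else:  # random, almost surely absent
                flank = simulate.random_sequence(flen, rng)
            hit = tnmap.align_flank(flank, ref, min_len=min_len, max_mismatch=3)
            assert (hit.status, hit.position, hit.strand) == oracle(flank)


class TestBuildPool:
    def test_clean_reads_recover_truth_pool(self, tmp_path, small_genome, small_library):
        _, seq = small_genome
        pool, _ = small_library
        simulate.write_mapping_fastq(pool, seq, 2_000, seed=25, path=tmp_path / "m.fastq")
        from barfit.io import iter_fastq

        built, stats = tnmap.build_pool(iter_fastq(tmp_path / "m.fastq"), seq)
        assert len(built) == len(pool)
        merged = built.merge(pool, on="barcode", suffixes=("_est", "_true"))
        assert (merged["pos_est"] == merged["pos_true"]).all()
        assert (merged["strand_est"] == merged["strand_true"]).all()

    def test_rejection_bookkeeping_sums_to_total(self, tmp_path, small_genome, small_library):
        _, seq = small_genome
        pool, _ = small_library
        simulate.write_mapping_fastq(
            pool, seq, 500,
            invalid_mix={"bad-length": 20, "low-quality": 15, "no-U2": 10, "bad-flank": 5},
            seed=26, path=tmp_path / "m.fastq",
        )
        from barfit.io import iter_fastq

        _, stats = tnmap.build_pool(iter_fastq(tmp_path / "m.fastq"), seq)
        scanned = sum(stats[s] for s in ("ok", "no-U1", "no-U2", "bad-length", "low-quality"))
        assert scanned == stats["n_reads"] == 500
        assert stats["bad-length"] == 20
        assert stats["low-quality"] == 15
        assert stats["no-U2"] == 10
        assert stats["flank-none"] == 5

    def test_impure_barcode_dropped(self):
        ref = simulate.random_sequence(2_000, np.random.default_rng(27))
        # one barcode seeded at two loci, 60:40 — below the 0.75 purity bar
        reads = []
        for pos, n in ((100, 6), (900, 4)):
            for _ in range(n):
                seq = U1 + BC + U2 + ref[pos : pos + 40]
                reads.append(("r", seq, "I" * len(seq)))
        pool, stats = tnmap.build_pool(reads, ref, purity=0.75)
        assert len(pool) == 0
        assert stats["dropped_low_purity"] == 1

    def test_single_read_barcode_dropped_at_min_support_2(self):
        ref = simulate.random_sequence(2_000, np.random.default_rng(28))
        seq = U1 + BC + U2 + ref[100:140]
        pool, stats = tnmap.build_pool([("r", seq, "I" * len(seq))], ref, min_support=2)
        assert len(pool) == 0
        assert stats["dropped_low_support"] == 1


@pytest.fixture(scope="module")
def annotation():
    genes = pd.DataFrame({"gene_id": ["gA"], "start": [100], "end": [200], "strand": ["+"]})
    return GenomeAnnotation(length=1_000, genes=genes)


class TestAssignGenes:
    def make_pool(self, positions):
        return pd.DataFrame(
            {
                "barcode": [f"b{i}" for i in range(len(positions))],
                "rname": "chr",
                "pos": positions,
                "strand": "+",
                "n_support": 2,
                "n_conflict": 0,
                "gene_id": None,
            }
        )

    def test_first_base_inclusive_and_upstream_excluded(self, annotation):
        pool = tnmap.assign_genes(self.make_pool([100, 99, 199, 200]), annotation)
        assert list(pool["gene_id"]) == ["gA", None, "gA", None]

    def test_central_trim_excludes_gene_edges(self, annotation):
        # 5% into a 100 bp gene is outside the 10–90% central window
        pool = tnmap.assign_genes(self.make_pool([105, 150]), annotation, central_trim=(0.1, 0.9))
        assert list(pool["gene_id"]) == [None, "gA"]
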