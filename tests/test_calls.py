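import io

import numpy as np
import pytest

import rddmkit as rk
from rddmkit.amplicon import reverse_complement
from rddmkit.calls import CALL_AMBIG, CALL_M, CALL_U, _call_full_length_batch


def fully_converted(seq: str) -> str:
    return seq.replace("C", "T")


class TestAlignAndCall:
    def test_fully_converted_read_is_all_u(self, small_amplicon):
        v = rk.align_and_call(fully_converted(small_amplicon.sequence), small_amplicon)
        assert set(v.calls) == {CALL_U}
        assert v.n_assayed == small_amplicon.n_sites

    def test_unconverted_read_is_all_m(self, small_amplicon):
        v = rk.align_and_call(small_amplicon.sequence, small_amplicon)
        assert set(v.calls) == {CALL_M}

    def test_single_converted_cg_site(self, mixed_amplicon):
        seq = list(mixed_amplicon.sequence)
        cg = next(s for s in mixed_amplicon.sites if s.context is rk.Context.CG)
        seq[cg.position] = "T"
        v = rk.align_and_call("".join(seq), mixed_amplicon)
        idx = mixed_amplicon.site_positions.index(cg.position)
        assert v.calls[idx] == CALL_U
        assert all(c == CALL_M for i, c in enumerate(v.calls) if i != idx)

    def test_reverse_complement_orientation_recovered(self, small_amplicon):
        rc = reverse_complement(fully_converted(small_amplicon.sequence))
        v = rk.align_and_call(rc, small_amplicon)
        assert set(v.calls) == {CALL_U}

    def test_partial_read_leaves_uncovered_sites_ambig(self, small_amplicon):
        sub = fully_converted(small_amplicon.sequence[30:120])
        v = rk.align_and_call(sub, small_amplicon)
        for i, site in enumerate(small_amplicon.sites):
            expected = CALL_U if 30 <= site.position < 120 else CALL_AMBIG
            assert v.calls[i] == expected

    def test_deletion_read_still_called(self, small_amplicon):
        seq = small_amplicon.sequence
        read = fully_converted(seq[:60] + seq[61:])
        v = rk.align_and_call(read, small_amplicon)
        assert v is not None
        assert v.calls.count(CALL_U) == small_amplicon.n_sites

    def test_high_mismatch_read_rejected(self, small_amplicon, rng):
        junk = "".join(rng.choice(list("ACGT"), size=len(small_amplicon.sequence)))
        assert rk.align_and_call(junk, small_amplicon) is None

    def test_short_read_rejected(self, small_amplicon):
        assert rk.align_and_call("ACGT" * 5, small_amplicon) is None

    def test_low_quality_site_is_ambig(self, small_amplicon):
        read = small_amplicon.sequence
        quals = [37] * len(read)
        pos = small_amplicon.site_positions[3]
        quals[pos] = 5
        v = rk.align_and_call(read, small_amplicon, qualities=quals)
        assert v.calls[3] == CALL_AMBIG
        assert v.calls[0] == CALL_M

    def test_empty_read_raises(self, small_amplicon):
        with pytest.raises(ValueError):
            rk.align_and_call("", small_amplicon)

    def test_unexpected_base_at_site_is_ambig(self, small_amplicon):
        seq = list(small_amplicon.sequence)
        seq[small_amplicon.site_positions[0]] = "G"
        v = rk.align_and_call("".join(seq), small_amplicon)
        assert v.calls[0] == CALL_AMBIG


class TestBatchConsistency:
    def test_batch_matches_aligner_on_full_length_reads(self, small_amplicon, rng):
        """The vectorized gap-free path and the pairwise aligner agree call
        for call on full-length substitution-only reads."""
        seq = small_amplicon.sequence
        reads = []
        for i in range(30):
            arr = list(fully_converted(seq))
            for pos in rng.choice(small_amplicon.site_positions, size=5, replace=False):
                arr[pos] = "C"
            reads.append((f"r{i}", "".join(arr), None))
        batch = _call_full_length_batch(
            [r[1] for r in reads], [r[0] for r in reads], small_amplicon, 0.1
        )
        for (rid, seq_i, _), bv in zip(reads, batch):
            av = rk.align_and_call(seq_i, small_amplicon, read_id=rid)
            assert bv is not None and av is not None
            assert bv.calls == av.calls

    def test_simulated_reads_recover_truth_exactly(self, small_amplicon):
        """With epsilon=0 and no sequencing error, calling inverts simulation."""
        cfg = rk.BisulfiteSimConfig(
            small_amplicon, n_reads=200, pi=0.6, m_cg=0.5, m_chg=0.5, m_chh=0.5,
            rho=0.3, epsilon=0.0, seq_error=0.0, seed=11,
        )
        reads, truth = rk.simulate_bisulfite_reads(cfg)
        vectors = rk.call_reads(reads, small_amplicon)
        assert len(vectors) == 200
        by_id = {v.read_id: v for v in vectors}
        for i, (rid, _, _) in enumerate(reads):
            calls = np.array(by_id[rid].calls) == CALL_M
            assert np.array_equal(calls, truth.true_methylation[i])


class TestAggregation:
    def test_counts(self, small_amplicon):
        n = small_amplicon.n_sites
        vs = [
            rk.ReadMethylationVector("a", "amp1", tuple([CALL_M] * n)),
            rk.ReadMethylationVector("b", "amp1", tuple([CALL_U] * n)),
            rk.ReadMethylationVector("c", "amp1", tuple([CALL_AMBIG] * n)),
        ]
        recs = rk.aggregate_site_counts(vs, small_amplicon)
        assert all(r.mc_count == 1 and r.total_count == 2 for r in recs)
        assert recs[0].position == small_amplicon.site_positions[0] + 1

    def test_empty_collection(self, small_amplicon):
        recs = rk.aggregate_site_counts([], small_amplicon)
        assert all(r.total_count == 0 for r in recs)

    def test_mixed_amplicons_rejected(self, small_amplicon):
        v = rk.ReadMethylationVector(
            "a", "other", tuple([CALL_M] * small_amplicon.n_sites)
        )
        with pytest.raises(ValueError):
            rk.aggregate_site_counts([v], small_amplicon)

    def test_percentages_consistent_with_vectors(self, small_amplicon, rng):
        """Percentages computed from the aggregate table equal percentages
        computed directly from the call vectors."""
        n = small_amplicon.n_sites
        vs = []
        for i in range(50):
            calls = tuple(
                rng.choice([CALL_M, CALL_U, CALL_AMBIG], p=[0.4, 0.5, 0.1])
                for _ in range(n)
            )
            vs.append(rk.ReadMethylationVector(f"r{i}", "amp1", calls))
        recs = rk.aggregate_site_counts(vs, small_amplicon)
        m_direct = sum(v.calls.count(CALL_M) for v in vs)
        t_direct = sum(v.n_assayed for v in vs)
        assert sum(r.mc_count for r in recs) == m_direct
        assert sum(r.total_count for r in recs) == t_direct


class TestAllcIO:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("amp1\t12\t+\tCGA\t5\t50\t1\n")
        (rec,) = rk.read_allc_table(p)
        assert (rec.position, rec.context, rec.mc_count, rec.total_count) == (
            12, rk.Context.CG, 5, 50,
        )

    def test_trinucleotide_collapse(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "amp1\t1\t+\tCTG\t0\t1\t1\namp1\t2\t+\tCAA\t0\t1\t1\namp1\t3\t+\tCCG\t0\t1\t1\n"
        )
        recs = rk.read_allc_table(p)
        assert [r.context for r in recs] == [
            rk.Context.CHG, rk.Context.CHH, rk.Context.CHG,
        ]

    def test_mc_exceeding_total_is_error_with_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("amp1\t1\t+\tCGA\t7\t5\t1\n")
        with pytest.raises(ValueError, match="line 1"):
            rk.read_allc_table(p)

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("amp1\t1\t+\n")
        with pytest.raises(ValueError):
            rk.read_allc_table(p)

    def test_roundtrip(self, small_amplicon, tmp_path):
        vs = [
            rk.ReadMethylationVector(
                "a", "amp1", tuple([CALL_M] * small_amplicon.n_sites)
            )
        ]
        recs = rk.aggregate_site_counts(vs, small_amplicon)
        p = tmp_path / "out.tsv"
        with open(p, "w") as fh:
            rk.write_allc_table(recs, fh, small_amplicon)
        back = rk.read_allc_table(p)
        assert [(r.position, r.mc_count, r.total_count) for r in back] == [
            (r.position, r.mc_count, r.total_count) for r in recs
        ]
        assert [r.context for r in back] == [r.context for r in recs]
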