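"""Insertion caller: coverage arithmetic, window support rules, sample
comparison and the validation report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retromob import insertions as ins, synth
from retromob.mapping import KmerIndex


class TestEstimateCoverage:
    def test_printed_formula(self):
        assert ins.estimate_coverage(1_000_000, 150, 5_000_000) == 30.0

    def test_unit_case(self):
        assert ins.estimate_coverage(5_000_000, 1, 5_000_000) == 1.0

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            ins.estimate_coverage(10, 150, 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(1, 10**7), rl=st.integers(30, 300),
           g=st.integers(1000, 10**8))
    def test_linearity_in_read_count(self, n, rl, g):
        one = ins.estimate_coverage(n, rl, g)
        two = ins.estimate_coverage(2 * n, rl, g)
        assert two == pytest.approx(2 * one)


class TestValidationReport:
    def test_paper_design_arithmetic(self):
        rep = ins.ValidationReport(n_sites=9, n_samples=4, fp_count=0,
                                   fn_count=0)
        assert rep.n_calls == 36

    def test_one_fn_among_36_is_2_8_percent(self):
        rep = ins.ValidationReport(n_sites=9, n_samples=4, fp_count=0,
                                   fn_count=1)
        assert rep.fn_rate == 2.8

    def test_two_fp_among_36(self):
        # 100 * 2 / 36 = 5.555... -> 5.6 at one decimal (half-even)
        rep = ins.ValidationReport(n_sites=9, n_samples=4, fp_count=2,
                                   fn_count=0)
        assert rep.fp_rate == 5.6

    def test_rates_bounded(self):
        rep = ins.ValidationReport(n_sites=3, n_samples=2, fp_count=6,
                                   fn_count=0)
        assert rep.fp_rate == 100.0 and rep.fn_rate == 0.0


@pytest.fixture(scope="module")
def caller_setup():
    """Small genome, one reference copy, one de novo insertion, reads."""
    spec = synth.ElementSpec(name="alex", ltr_len=150, internal_len=1200,
                             tsd_len=5)
    cfg = synth.SynthConfig(seed=21, n_chrom=1, chrom_len=80_000,
                            elements=(spec,), coverage=30, error_rate=0.0)
    genome, truth = synth.build_genome(cfg)
    elem_seqs = {
        c.name: genome.chroms[c.chrom][c.start : c.end] for c in truth.copies
    }
    ref_copy = truth.copies[0]
    # place the de novo site far from the reference copy
    pos = 15_000 if abs(ref_copy.start - 15_000) > 12_000 else 60_000
    site = synth.InsertionSite("s1", "chr1", pos, 5, "alex")
    sample_genome = synth.insert_elements(genome, [site], elem_seqs)
    pairs = synth.simulate_reads(
        {c: (s, False) for c, s in sample_genome.chroms.items()},
        cfg.coverage, cfg, np.random.default_rng(99),
    )
    return genome, truth, elem_seqs, site, pairs, cfg


@pytest.fixture(scope="module")
def called(caller_setup):
    genome, truth, elem_seqs, site, pairs, cfg = caller_setup
    calls, cache = ins.call_windows(
        pairs, KmerIndex(elem_seqs), KmerIndex(genome.chroms), "s1"
    )
    ins.refine_breakpoints(calls, cache, elem_seqs)
    return calls, cache


class TestCallWindows:
    def test_planted_insertion_window_called_with_high_support(
        self, caller_setup, called
    ):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        calls, _ = called
        hit = [c for c in calls
               if c.window_start <= site.position < c.window_end]
        assert hit and hit[0].support > 2
        # reference copy's own window is also flagged (later labelled)
        ref = truth.copies[0]
        assert any(c.window_start <= ref.start < c.window_end for c in calls)

    def test_single_read_support_not_called(self, called):
        calls, _ = called
        assert all(c.support >= 2 for c in calls)

    def test_window_calls_invariant_to_read_order(self, caller_setup, called):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        te, gi = KmerIndex(elem_seqs), KmerIndex(genome.chroms)
        fwd, _ = called
        rev, _ = ins.call_windows(list(reversed(pairs)), te, gi, "s1")
        key = lambda c: (c.chrom, c.window_start, c.subfamily, c.support)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_refined_interval_contains_breakpoint_and_tsd(
        self, caller_setup, called
    ):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        calls, _ = called
        hit = [c for c in calls
               if c.window_start <= site.position < c.window_end][0]
        assert hit.refined
        assert hit.refined_end - hit.refined_start <= 200
        assert hit.refined_start <= site.position <= hit.refined_end
        assert hit.tsd_len == site.tsd_len

    def test_null_reads_only_flag_reference_loci(self, caller_setup):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        null_pairs = synth.simulate_reads(
            {c: (s, False) for c, s in genome.chroms.items()},
            cfg.coverage, cfg, np.random.default_rng(7),
        )
        calls, _ = ins.call_windows(
            null_pairs, KmerIndex(elem_seqs), KmerIndex(genome.chroms), "ref"
        )
        ref = truth.copies[0]
        for c in calls:
            assert c.window_start - 10_000 <= ref.start <= c.window_end + 10_000


class TestCompareSamples:
    def _call(self, sample, chrom, a, b, sub="alex"):
        c = ins.InsertionCall(sample=sample, subfamily=sub, chrom=chrom,
                              window_start=(a // 10_000) * 10_000,
                              window_end=(a // 10_000 + 1) * 10_000,
                              support=5)
        c.refined_start, c.refined_end = a, b
        return c

    def test_nearby_refined_calls_merge_to_shared(self):
        calls = {
            "A": [self._call("A", "chr1", 5000, 5010)],
            "B": [self._call("B", "chr1", 5050, 5060)],
        }
        sites, matrix = ins.compare_samples(calls, [])
        assert len(sites) == 1
        assert sites[0]["status"] == "shared-non-reference"

    def test_reference_overlap_wins(self):
        calls = {"A": [self._call("A", "chr1", 5000, 5010)]}
        sites, _ = ins.compare_samples(calls, [("chr1", 4000, 9000)])
        assert sites[0]["status"] == "reference"

    def test_distant_sites_stay_private(self):
        calls = {
            "A": [self._call("A", "chr1", 5000, 5010)],
            "B": [self._call("B", "chr1", 11_000, 11_010)],
        }
        sites, _ = ins.compare_samples(calls, [])
        assert len(sites) == 2
        assert all(s["status"] == "private" for s in sites)


class TestMaskGenome:
    def test_excision_restores_empty_allele(self, caller_setup):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        c = truth.copies[0]
        masked = ins.mask_genome(
            genome,
            [{"chrom": c.chrom, "start": c.start, "end": c.end,
              "tsd_len": len(c.tsd), "element": c.name}],
        )
        elen = c.end - c.start
        assert len(masked.chroms[c.chrom]) == 80_000
        # flanks rejoin around a single TSD copy
        orig = genome.chroms[c.chrom]
        assert masked.chroms[c.chrom][: c.start] == orig[: c.start]
        assert masked.chroms[c.chrom][c.start:] == orig[c.end + len(c.tsd):]

    def test_n_mask_keeps_coordinates(self, caller_setup):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        c = truth.copies[0]
        masked = ins.mask_genome(
            genome,
            [{"chrom": c.chrom, "start": c.start, "end": c.end,
              "tsd_len": len(c.tsd), "element": c.name}],
            mode="n-mask",
        )
        seq = masked.chroms[c.chrom]
        assert len(seq) == len(genome.chroms[c.chrom])
        assert set(seq[c.start : c.end]) == {"N"}

    def test_excise_without_tsd_rejected(self, caller_setup):
        genome, truth, elem_seqs, site, pairs, cfg = caller_setup
        c = truth.copies[0]
        with pytest.raises(ValueError, match="TSD"):
            ins.mask_genome(
                genome,
                [{"chrom": c.chrom, "start": c.start, "end": c.end,
                  "tsd_len": None, "element": c.name}],
            )
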