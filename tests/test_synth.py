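"""Generator contracts: planting semantics, divergence calibration,
circle arithmetic and read simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retromob import synth
from retromob._util import encode, revcomp
from retromob.chronology import k80_distance


def _cfg(**kw):
    base = dict(seed=3, n_chrom=1, chrom_len=60_000)
    base.update(kw)
    return synth.SynthConfig(**base)


class TestBuildGenome:
    def test_zero_elements_gives_empty_ground_truth(self):
        genome, truth = synth.build_genome(_cfg())
        assert truth.copies == [] and truth.solo_ltrs == []
        assert len(genome.chroms["chr1"]) == 60_000

    def test_tsd_duplicates_the_host_flank(self):
        spec = synth.ElementSpec(name="e", ltr_len=300, internal_len=3000,
                                 tsd_len=5)
        genome, truth = synth.build_genome(_cfg(elements=(spec,)))
        (c,) = truth.copies
        seq = genome.chroms[c.chrom]
        assert seq[c.start - 5 : c.start] == c.tsd
        assert seq[c.end : c.end + 5] == c.tsd
        assert seq[c.start : c.start + 2] == "TG"
        assert seq[c.end - 2 : c.end] == "CA"

    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = synth.ElementSpec(name="e", ltr_len=300, internal_len=3000)
        paths = []
        for i in range(2):
            genome, _ = synth.build_genome(_cfg(elements=(spec,)))
            p = tmp_path / f"g{i}.fa"
            genome.write_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_oversized_element_rejected(self):
        spec = synth.ElementSpec(name="big", ltr_len=4000, internal_len=60_000)
        with pytest.raises(ValueError, match="does not fit"):
            synth.build_genome(_cfg(elements=(spec,)))

    def test_ground_truth_serialization_round_trip(self):
        spec = synth.ElementSpec(name="e", ltr_len=300, internal_len=3000)
        _, truth = synth.build_genome(
            _cfg(elements=(spec,), solo_ltrs=(synth.SoloSpec("e"),))
        )
        again = synth.GroundTruth.from_json(truth.to_json())
        assert again == truth

    def test_genes_do_not_overlap_each_other(self):
        _, truth = synth.build_genome(_cfg(n_genes_per_chrom=15))
        ivs = sorted((a, b) for _, a, b, _ in truth.genes)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))


class TestMutateLtrPair:
    def test_target_zero_keeps_sequence(self, rng0):
        ltr = synth.random_seq(rng0, 400, 0.4)
        assert synth.mutate_ltr_pair(ltr, 0.0, rng0) == ltr

    def test_transitions_only_reach_closed_form_k80(self):
        # 10% transitions, no transversions: K = -0.5 ln(0.8)
        seq = synth.random_seq(np.random.default_rng(1), 1000, 0.5)
        mut = synth.substitute(seq, 100, 0, np.random.default_rng(2))
        _, _, k = k80_distance(seq, mut)
        assert k == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_two_seeds_differ_but_share_expected_divergence(self):
        ltr = synth.random_seq(np.random.default_rng(3), 2000, 0.4)
        a = synth.mutate_ltr_pair(ltr, 0.05, np.random.default_rng(10))
        b = synth.mutate_ltr_pair(ltr, 0.05, np.random.default_rng(11))
        assert a != b
        for m in (a, b):
            _, _, k = k80_distance(ltr, m)
            assert 0.02 < k < 0.09

    def test_k80_round_trip_within_three_sd(self):
        target = 0.10
        ks = []
        for i in range(100):
            rng = np.random.default_rng(i)
            ltr = synth.random_seq(rng, 600, 0.4)
            mut = synth.mutate_ltr_pair(ltr, target, rng)
            ks.append(k80_distance(ltr, mut)[2])
        ks = np.array(ks)
        se = ks.std(ddof=1) / math.sqrt(len(ks))
        assert abs(ks.mean() - target) < 3 * se + 0.002  # tiny bias allowance

    def test_saturating_target_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            synth.k80_event_probabilities(50.0)


class TestMakeCircles:
    def test_two_ltr_deletion_shortens_circle(self, circle_element):
        spec, elem = circle_element
        (circ,) = synth.make_circles(elem, spec.ltr_len, "two-LTR", -3)
        assert len(circ) == len(elem) - 3

    def test_one_ltr_length(self, circle_element):
        spec, elem = circle_element
        (circ,) = synth.make_circles(elem, spec.ltr_len, "one-LTR", 0)
        assert len(circ) == spec.internal_len + spec.ltr_len

    def test_insertion_adds_bases(self, circle_element):
        spec, elem = circle_element
        (circ,) = synth.make_circles(elem, spec.ltr_len, "two-LTR", 4,
                                     rng=np.random.default_rng(0))
        assert len(circ) == len(elem) + 4

    def test_indel_longer_than_ltr_rejected(self, circle_element):
        spec, elem = circle_element
        with pytest.raises(ValueError, match="indel"):
            synth.make_circles(elem, spec.ltr_len, "two-LTR", -150)

    def test_unknown_topology_rejected(self, circle_element):
        spec, elem = circle_element
        with pytest.raises(ValueError, match="topology"):
            synth.make_circles(elem, spec.ltr_len, "three-LTR", 0)


class TestSimulateReads:
    def test_zero_coverage_zero_reads(self, circle_element):
        _, elem = circle_element
        cfg = _cfg()
        pairs = synth.simulate_reads({"t": (elem, False)}, 0, cfg,
                                     np.random.default_rng(0))
        assert pairs == []

    def test_error_free_reads_are_substrings(self, circle_element):
        _, elem = circle_element
        cfg = _cfg()
        doubled = elem + elem
        pairs = synth.simulate_reads({"t": (elem, True)}, 20, cfg,
                                     np.random.default_rng(1))
        for p in pairs:
            for s in (p.seq1, p.seq2):
                assert s in doubled or revcomp(s) in doubled

    def test_read_longer_than_linear_template_rejected(self):
        cfg = _cfg()
        with pytest.raises(ValueError, match="read length"):
            synth.simulate_reads({"t": ("ACGT" * 10, False)}, 10, cfg,
                                 np.random.default_rng(0))

    def test_read_count_tracks_coverage(self, circle_element):
        _, elem = circle_element
        cfg = _cfg()
        pairs = synth.simulate_reads({"t": (elem, True)}, 100, cfg,
                                     np.random.default_rng(2))
        expected = 100 * len(elem) / (2 * cfg.read_len)
        assert abs(len(pairs) - expected) < 4 * math.sqrt(expected)

    def test_junction_spanning_reads_occur_on_circles(self, circle_element):
        spec, elem = circle_element
        cfg = _cfg()
        pairs = synth.simulate_reads({"t": (elem, True)}, 100, cfg,
                                     np.random.default_rng(3))
        junction = elem[-30:] + elem[:30]
        assert any(
            junction in s or junction in revcomp(s)
            for p in pairs for s in (p.seq1, p.seq2)
        )

    @settings(deadline=None, max_examples=5, derandomize=True)
    @given(rate=st.sampled_from([0.01, 0.05]),
           seed=st.integers(0, 100))
    def test_empirical_error_rate_within_three_sd(self, rate, seed,
                                                  circle_element):
        _, elem = circle_element
        cfg = _cfg(error_rate=rate)
        pairs = synth.simulate_reads({"t": (elem, True)}, 10, cfg,
                                     np.random.default_rng(seed))
        doubled = encode(elem + elem)
        n = mism = 0
        for p in pairs:
            for s in (p.seq1, p.seq2):
                best = None
                for cand in (s, revcomp(s)):
                    arr = encode(cand)
                    for off in range(len(elem)):
                        d = int((arr != doubled[off : off + arr.size]).sum())
                        if best is None or d < best:
                            best = d
                n += len(s)
                mism += best
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(mism - n * rate) < 3 * sd + 2


def test_insert_elements_duplicates_tsd(planted_genome):
    genome, _ = planted_genome
    elem = "TG" + "A" * 500 + "CA"
    site = synth.InsertionSite("s", "chr1", 10_000, 5, "e")
    g2 = synth.insert_elements(genome, [site], {"e": elem})
    seq = g2.chroms["chr1"]
    tsd = genome.chroms["chr1"][9_995:10_000]
    assert seq[10_000 : 10_000 + len(elem)] == elem
    assert seq[10_000 + len(elem) : 10_000 + len(elem) + 5] == tsd
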