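"""End-to-end experiment drivers at the study's synthetic conditions.

Each driver generates its own data from an explicit seed, runs the
relevant pipeline stage and measures the outcome, so a single call
reproduces the whole experiment.  The conditions (genome sizes, element
geometries, coverages, error rates, divergences) are fixed here once;
they are what the test suite and the acceptance script both run.

Problem sizes are desk-scale by design: megabase genomes for mining,
a quarter-megabase two-chromosome genome for the subline comparison,
and a ~0.2-Mb genome with nine reference insertions for the validation
harness.
"""

from __future__ import annotations

import numpy as np

from . import classify, eccdna as ecc, insertions as ins, miner, synth
from .chronology import k80_distance
from .mapping import KmerIndex

# ---------------------------------------------------------------------------
# miner recovery
# ---------------------------------------------------------------------------

def _miner_specs():
    """Five recoverable elements: three recent (identical LTRs), two
    diverged (K=0.02) with LTRs long enough to retain an exact 80-bp
    seed with overwhelming probability."""
    return tuple(
        [synth.ElementSpec(name=f"id{i}", ltr_len=400, internal_len=3200,
                           tsd_len=4 + i) for i in range(3)]
        + [synth.ElementSpec(name=f"div{i}", ltr_len=2500, internal_len=3500,
                             tsd_len=5, target_K=0.02) for i in range(2)]
    )


def miner_recovery(seed: int, n_genomes: int = 10, chrom_len: int = 1_000_000,
                   n_controls: int = 10) -> dict:
    """Recall/precision of structural mining on planted megabase genomes
    plus element-free controls."""
    planted_total = found_exact = 0
    for g in range(n_genomes):
        cfg = synth.SynthConfig(seed=seed + g, n_chrom=1,
                                chrom_len=chrom_len, elements=_miner_specs())
        genome, truth = synth.build_genome(cfg)
        copies = miner.find_ltr_candidates(genome)
        mined = {(c.chrom, c.start, c.end) for c in copies}
        for t in truth.copies:
            planted_total += 1
            if (t.chrom, t.start, t.end) in mined:
                found_exact += 1
    false_candidates = 0
    for g in range(n_controls):
        cfg = synth.SynthConfig(seed=seed + 1000 + g, n_chrom=1,
                                chrom_len=chrom_len)
        genome, _ = synth.build_genome(cfg)
        false_candidates += len(miner.find_ltr_candidates(genome))
    return {
        "planted": planted_total,
        "recovered_exact": found_exact,
        "recall_pct": 100.0 * found_exact / planted_total,
        "false_candidates": false_candidates,
    }


# ---------------------------------------------------------------------------
# K80 dating round trip
# ---------------------------------------------------------------------------

def dating_round_trip(seed: int, target_k: float = 0.10, n_pairs: int = 100,
                      ltr_len: int = 600) -> dict:
    """Mean estimated K over mutated LTR pairs vs the generating target."""
    ks = []
    for i in range(n_pairs):
        rng = np.random.default_rng(seed + i)
        ltr = synth.random_seq(rng, ltr_len, 0.4)
        mut = synth.mutate_ltr_pair(ltr, target_k, rng)
        ks.append(k80_distance(ltr, mut)[2])
    ks = np.array(ks)
    return {
        "target_k": target_k,
        "mean_k": float(ks.mean()),
        "se": float(ks.std(ddof=1) / np.sqrt(n_pairs)),
    }


# ---------------------------------------------------------------------------
# subfamily clustering vs brute force
# ---------------------------------------------------------------------------

def clustering_agreement(seed: int, n_sets: int = 50) -> dict:
    """Fraction of random sequence sets on which single-linkage clustering
    equals brute-force connected components of the thresholded pair graph."""
    agree = 0
    for trial in range(n_sets):
        rng = np.random.default_rng(seed + trial)
        n_fam = int(rng.integers(1, 4))
        ancestors = [synth.random_seq(rng, 250, 0.4) for _ in range(n_fam)]
        seqs = {}
        for i in range(int(rng.integers(3, 8))):
            anc = ancestors[int(rng.integers(0, n_fam))]
            n_mut = int(rng.integers(0, 35))
            seqs[f"c{i}"] = synth.substitute(
                anc, n_mut * 2 // 3, n_mut - n_mut * 2 // 3, rng
            )
        part = classify.cluster_subfamilies(seqs)
        got = {}
        for cid, lab in part.assignment.items():
            got.setdefault(lab, set()).add(cid)
        agree += {frozenset(v) for v in got.values()} == _brute_components(seqs)
    return {"n_sets": n_sets, "agreement_pct": 100.0 * agree / n_sets}


def _brute_components(seqs: dict[str, str]) -> set[frozenset]:
    ids = sorted(seqs)
    adj = {i: set() for i in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            pid, pov = classify.ltr_pair_metrics(seqs[ids[x]], seqs[ids[y]])
            if pid >= 0.6 and pov >= 0.7:
                adj[ids[x]].add(ids[y])
                adj[ids[y]].add(ids[x])
    seen: set[str] = set()
    comps = set()
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# family tree cut on two-clade simulations
# ---------------------------------------------------------------------------

def treecut_recovery(seed: int, n_reps: int = 100, n_bootstrap: int = 100,
                     between: float = 0.5, within: float = 0.03,
                     clade_size: int = 4, rt_len: int = 300) -> dict:
    """How often the family cut recovers two generating rt clades."""
    ok = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        anc_a = synth.random_seq(rng, rt_len, 0.4)
        anc_b = synth.mutate_ltr_pair(anc_a, between, rng, protect_ends=0)
        seqs = {}
        for i in range(clade_size):
            seqs[f"a{i}"] = synth.mutate_ltr_pair(anc_a, within, rng,
                                                  protect_ends=0)
            seqs[f"b{i}"] = synth.mutate_ltr_pair(anc_b, within, rng,
                                                  protect_ends=0)
        aln = classify.align_and_filter(seqs)
        ftree = classify.build_family_tree(aln, "sim",
                                           n_bootstrap=n_bootstrap,
                                           seed=seed + rep)
        fams = classify.cut_families(ftree)
        groups = {}
        for cid, fam in fams.items():
            groups.setdefault(fam, set()).add(cid)
        want = {
            frozenset(f"a{i}" for i in range(clade_size)),
            frozenset(f"b{i}" for i in range(clade_size)),
        }
        ok += {frozenset(v) for v in groups.values()} == want
    return {"n_reps": n_reps, "recovery_pct": 100.0 * ok / n_reps}


# ---------------------------------------------------------------------------
# circle junction screen
# ---------------------------------------------------------------------------

def junction_screen(seed: int, coverage: float = 50.0,
                    indels=(-3, 0, 2), n_linear_controls: int = 10) -> dict:
    """Detect every synthetic circle with its topology and indel; count
    false junction calls on linear-only libraries."""
    rng = np.random.default_rng(seed)
    spec = synth.ElementSpec(name="alex", ltr_len=100, internal_len=600,
                             tsd_len=5)
    elem, _, _ = synth.build_element(spec, rng)
    model = ecc.ElementModel("alex", elem, spec.ltr_len)
    cfg = synth.SynthConfig(seed=seed, error_rate=0.003, insert_mean=350,
                            insert_sd=30)
    n_cases = correct = 0
    for topology in ("two-LTR", "one-LTR"):
        for indel in indels:
            (circ,) = synth.make_circles(elem, spec.ltr_len, topology, indel,
                                         rng=rng)
            pairs = synth.simulate_reads({"c": (circ, True)}, coverage, cfg,
                                         rng)
            ev = ecc.detect_junctions(pairs, [model])
            n_cases += 1
            correct += bool(ev) and (
                {(e.topology, e.indel) for e in ev} == {(topology, indel)}
            )
    linear_calls = 0
    for i in range(n_linear_controls):
        pairs = synth.simulate_reads(
            {"lin": (elem, False)}, coverage, cfg,
            np.random.default_rng(seed + 500 + i),
        )
        linear_calls += len(ecc.detect_junctions(pairs, [model]))
    return {
        "n_cases": n_cases,
        "correct": correct,
        "detection_pct": 100.0 * correct / n_cases,
        "linear_false_calls": linear_calls,
    }


# ---------------------------------------------------------------------------
# two sublines sharing and differing in de novo insertions
# ---------------------------------------------------------------------------

def subline_experiment(seed: int, coverage: float = 25.0,
                       n_shared: int = 3, n_private_a: int = 8,
                       n_private_b: int = 6) -> dict:
    """Insertion-calling comparison of two read sets ("sublines") that
    share ``n_shared`` de novo sites and carry private ones."""
    rng = np.random.default_rng(seed)
    specs = tuple(
        synth.ElementSpec(name=f"alex{i}", ltr_len=150, internal_len=1200,
                          tsd_len=5)
        for i in (1, 2)
    )
    cfg = synth.SynthConfig(seed=seed, n_chrom=2, chrom_len=250_000,
                            elements=specs, coverage=coverage,
                            error_rate=0.002)
    genome, truth = synth.build_genome(cfg)
    elem_seqs = {
        c.name: genome.chroms[c.chrom][c.start : c.end] for c in truth.copies
    }

    used = {c: [x.start for x in truth.copies if x.chrom == c]
            for c in ("chr1", "chr2")}

    def pick(n, chrom, min_gap=12_000):
        out = []
        while len(out) < n:
            p = int(rng.integers(5000, cfg.chrom_len - 10_000))
            if all(abs(p - u) > min_gap for u in used[chrom]):
                used[chrom].append(p)
                out.append(p)
        return out

    shared = [synth.InsertionSite("", "chr1", p, 5, "alex1")
              for p in pick(n_shared, "chr1")]
    half_a = n_private_a // 2
    priv_a = [synth.InsertionSite("A", "chr1", p, 5, "alex2")
              for p in pick(half_a, "chr1")] + \
             [synth.InsertionSite("A", "chr2", p, 5, "alex1")
              for p in pick(n_private_a - half_a, "chr2")]
    priv_b = [synth.InsertionSite("B", "chr2", p, 5, "alex2")
              for p in pick(n_private_b, "chr2")]

    te_index = KmerIndex(elem_seqs)
    genome_index = KmerIndex(genome.chroms)
    calls_by_sample = {}
    for sample, sites in (("A", shared + priv_a), ("B", shared + priv_b)):
        g = synth.insert_elements(genome, sites, elem_seqs)
        pairs = synth.simulate_reads(
            {c: (s, False) for c, s in g.chroms.items()},
            coverage, cfg, np.random.default_rng(seed * 97 + ord(sample)),
        )
        calls, cache = ins.call_windows(pairs, te_index, genome_index, sample)
        ins.refine_breakpoints(calls, cache, elem_seqs)
        calls_by_sample[sample] = calls

    sites_out, matrix = ins.compare_samples(
        calls_by_sample, [(c.chrom, c.start, c.end) for c in truth.copies]
    )
    planted = {(s.chrom, s.position)
               for s in shared + priv_a + priv_b}
    refined_ok = breakpoints_contained = n_nonref = 0
    for s in sites_out:
        if s["status"] == "reference":
            continue
        n_nonref += 1
        hits = [p for p in planted
                if p[0] == s["chrom"]
                and s["start"] - 50 <= p[1] <= s["end"] + 50]
        if all(c.refined and c.refined_end - c.refined_start <= 200
               for c in s["calls"]):
            refined_ok += 1
        if hits and all(
            any(c.refined_start <= p[1] <= c.refined_end for p in hits)
            for c in s["calls"] if c.refined
        ):
            breakpoints_contained += 1
    per = {}
    for s in sites_out:
        per.setdefault(s["status"], []).append(s)
    return {
        "shared_sites": len(per.get("shared-non-reference", [])),
        "private_a": sum(1 for s in per.get("private", [])
                         if s["samples"] == ["A"]),
        "private_b": sum(1 for s in per.get("private", [])
                         if s["samples"] == ["B"]),
        "n_nonreference_sites": n_nonref,
        "refined_ok": refined_ok,
        "breakpoints_contained": breakpoints_contained,
        "expected": (n_shared, n_private_a, n_private_b),
    }


# ---------------------------------------------------------------------------
# mask-and-revalidate harness on clean data
# ---------------------------------------------------------------------------

def clean_validation(seed: int, n_sites: int = 9, n_samples: int = 4,
                     coverage: float = 30.0) -> ins.ValidationReport:
    """The masking experiment on error-free reads: both rates must be 0."""
    specs = tuple(
        synth.ElementSpec(name=f"alex{i}", ltr_len=150, internal_len=1100,
                          tsd_len=5)
        for i in range(n_sites)
    )
    cfg = synth.SynthConfig(seed=seed, n_chrom=2, chrom_len=100_000,
                            elements=specs, coverage=coverage,
                            error_rate=0.0)
    genome, truth = synth.build_genome(cfg)
    elem_seqs = {
        c.name: genome.chroms[c.chrom][c.start : c.end] for c in truth.copies
    }
    sites = [
        {"chrom": c.chrom, "start": c.start, "end": c.end,
         "tsd_len": len(c.tsd), "element": c.name}
        for c in truth.copies
    ]
    read_sets = {
        f"s{i}": synth.simulate_reads(
            {c: (s, False) for c, s in genome.chroms.items()},
            coverage, cfg, np.random.default_rng(seed + 7000 + i),
        )
        for i in range(n_samples)
    }
    return ins.mask_and_validate(genome, sites, read_sets, elem_seqs)
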