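"""eccDNA (mobilome-seq) profiling against an LTR-RT library.

Read pairs are cleansed of organellar contamination, mapped to the
element library, summarized per subfamily as RPKM with a pairwise
chi-square enrichment test, and screened for circle junctions.  Two
circle topologies are recognized:

* two-LTR — the full element closed end-to-start, diagnosed by reads
  crossing the element 3' end -> 5' start adjacency (the LTR-LTR
  junction), which never occurs in the linear element;
* one-LTR — the internal region plus a single LTR, diagnosed by reads
  spanning the *entire* LTR with flanking internal sequence on both
  sides, an adjacency the linear element (with its two LTRs) cannot
  produce.  This requires LTRs shorter than the read length minus two
  anchors.

A signed indel at the junction (the NHEJ hallmark) is read off the
alignment; junction-spanning alignments are gapped (edlib) because the
indel itself must be crossed.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from ._util import revcomp
from .mapping import KmerIndex, ReadAlignment
from .synth import ReadPair


@dataclass
class SubfamilyProfile:
    subfamily: str
    read_count: int
    ref_length: int
    rpkm: float
    hit_fraction: float = 1.0
    genome_fraction: float | None = None
    chi2: float | None = None
    p: float | None = None
    p_adj: float | None = None


@dataclass
class JunctionEvidence:
    subfamily: str
    read_id: str
    topology: str           # "one-LTR" | "two-LTR"
    junction_offset: int    # offset of the junction on the model reference
    indel: int              # signed indel length at the junction
    left_anchor: int
    right_anchor: int


@dataclass(frozen=True)
class ElementModel:
    """An element sequence with its LTR annotation (for junction refs)."""

    subfamily: str
    seq: str
    ltr_len: int

    @property
    def internal(self) -> str:
        return self.seq[self.ltr_len : len(self.seq) - self.ltr_len]

    @property
    def ltr(self) -> str:
        return self.seq[: self.ltr_len]


# --------------------------------------------------------------------------
# organelle filtering
# --------------------------------------------------------------------------

def filter_organelle_reads(
    pairs: list[ReadPair],
    organelle_refs: dict[str, str],
    k: int = 21,
    min_matched_frac: float = 0.5,
) -> list[ReadPair]:
    """Drop read pairs with either mate mapping to an organelle genome."""
    if not organelle_refs:
        return list(pairs)
    index = KmerIndex(organelle_refs, k=k)
    kept = []
    for p in pairs:
        drop = False
        for seq in (p.seq1, p.seq2):
            aln = index.map_read(p.name, seq,
                                 min_matched=int(min_matched_frac * len(seq)))
            if aln is not None:
                drop = True
                break
        if not drop:
            kept.append(p)
    return kept


# --------------------------------------------------------------------------
# profiling
# --------------------------------------------------------------------------

def rpkm(count: int, ref_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of reference per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    return count * 1e9 / (ref_length_bp * total_mapped)


def profile_subfamilies(
    alignments: list[ReadAlignment],
    ref_lengths: dict[str, int],
    total_mapped: int | None = None,
    hit_fractions: dict[str, float] | None = None,
) -> list[SubfamilyProfile]:
    """Per-subfamily read counts and RPKM from library alignments."""
    counts: dict[str, int] = {name: 0 for name in ref_lengths}
    for a in alignments:
        counts[a.ref_id] = counts.get(a.ref_id, 0) + 1
    total = total_mapped if total_mapped is not None else len(alignments)
    if total <= 0:
        raise ValueError("total mapped reads must be > 0")
    out = []
    for name in sorted(ref_lengths):
        out.append(
            SubfamilyProfile(
                subfamily=name,
                read_count=counts.get(name, 0),
                ref_length=ref_lengths[name],
                rpkm=rpkm(counts.get(name, 0), ref_lengths[name], total),
                hit_fraction=(hit_fractions or {}).get(name, 1.0),
            )
        )
    return out


def test_enrichment(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    n_sim: int = 10_000,
    seed: int = 0,
):
    """Pairwise 2x2 chi-square between a cluster's read count and the
    total reads of each sample, without continuity correction.

    When any expected cell is below 5 the p-value is obtained by Monte
    Carlo simulation under fixed margins (the convention of reporting
    simulated p-values for small counts); the statistic itself is always
    the plain chi-square.  Returns (chi2, p, method).
    """
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("need totals >= counts >= 0")
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]],
        dtype=float,
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), float("nan"), "undefined"
    chi2 = _chi2_stat(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if expected.min() >= 5:
        return chi2, float(stats.chi2.sf(chi2, df=1)), "asymptotic"
    rng = np.random.default_rng(seed)
    col1 = int(table[:, 0].sum())
    row1 = int(table[0].sum())
    n = int(table.sum())
    draws = rng.hypergeometric(row1, n - row1, col1, size=n_sim)
    sims = np.array(
        [
            _chi2_stat(np.array([[a, row1 - a], [col1 - a, n - row1 - col1 + a]],
                                dtype=float))
            for a in draws
        ]
    )
    p = (1 + int((sims >= chi2 - 1e-9).sum())) / (n_sim + 1)
    return chi2, float(p), "simulated"


def _chi2_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (table - expected) ** 2 / expected
    return float(np.nansum(cells))


def exact_enrichment_p(count_a, total_a, count_b, total_b) -> float:
    """Exact-enumeration p for the 2x2 chi-square under fixed margins.

    Enumerates every table with the observed margins, weighting by the
    hypergeometric probability — the small-sample oracle the Monte Carlo
    p approximates.
    """
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]],
        dtype=float,
    )
    chi2 = _chi2_stat(table)
    row1 = count_a + (total_a - count_a)
    col1 = count_a + count_b
    n = total_a + total_b
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p = 0.0
    for a in range(lo, hi + 1):
        t = np.array([[a, row1 - a], [col1 - a, n - row1 - col1 + a]],
                     dtype=float)
        if _chi2_stat(t) >= chi2 - 1e-9:
            p += stats.hypergeom.pmf(a, n, row1, col1)
    return float(p)


def bonferroni(profiles: list[SubfamilyProfile]) -> None:
    """Attach Bonferroni-adjusted p-values across tested subfamilies."""
    tested = [p for p in profiles if p.p is not None and not np.isnan(p.p)]
    m = len(tested)
    for p in tested:
        p.p_adj = min(1.0, p.p * m)


def filter_candidates(
    profiles: list[SubfamilyProfile],
    min_reads: int = 500,
    min_hit_fraction: float = 0.5,
) -> list[SubfamilyProfile]:
    """Retain candidate-active subfamilies: mapped reads strictly above
    ``min_reads`` and library-hit fraction strictly above
    ``min_hit_fraction``."""
    return [
        p
        for p in profiles
        if p.read_count > min_reads and p.hit_fraction > min_hit_fraction
    ]


# --------------------------------------------------------------------------
# junction detection
# --------------------------------------------------------------------------

def detect_junctions(
    pairs: list[ReadPair],
    models: list[ElementModel],
    min_anchor: int = 15,
    max_indel: int = 20,
    max_divergence: float = 0.03,
    collapse_duplicates: bool = True,
) -> list[JunctionEvidence]:
    """Find reads that span a circle junction of either topology.

    For each element model two junction references are built: the
    two-LTR reference joins the element end to its start; the one-LTR
    reference embeds one full LTR between internal end and internal
    start.  A read is evidence when it aligns across the junction (the
    seal point for two-LTR; the whole LTR plus the seal for one-LTR)
    with at least ``min_anchor`` aligned bases on each side, within
    ``max_divergence`` edits per base.  The signed junction indel is the
    insertion-minus-deletion balance of the gapped alignment, and must
    not exceed ``max_indel``.

    Duplicate fragments (same read sequence) are collapsed first to damp
    rolling-circle amplification bias; disable with
    ``collapse_duplicates=False``.
    """
    reads: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        key = (p.seq1, p.seq2)
        if collapse_duplicates and key in seen:
            continue
        seen.add(key)
        reads.append((p.name + "/1", p.seq1))
        reads.append((p.name + "/2", p.seq2))

    evidence: list[JunctionEvidence] = []
    for model in models:
        read_len = max(len(s) for _, s in reads) if reads else 150
        refs = _junction_refs(model, read_len, min_anchor)
        for topology, (ref, jlo, jhi) in refs.items():
            for rid, seq in reads:
                ev = _probe(rid, seq, ref, jlo, jhi, topology, model,
                            min_anchor, max_indel, max_divergence)
                if ev is not None:
                    evidence.append(ev)
    return evidence


def _junction_refs(model: ElementModel, read_len: int, min_anchor: int):
    """topology -> (reference, junction zone start, junction zone end).

    The junction zone is the interval an alignment must fully bridge
    (with ``min_anchor`` aligned bases beyond each end) to count as
    junction-spanning.  The one-LTR reference is only usable when a
    single read can span the whole LTR plus both anchors.
    """
    w = read_len + 5
    elem, ltr_len = model.seq, model.ltr_len
    refs: dict[str, tuple[str, int, int]] = {}
    two = elem[-w:] + elem[:w]
    cut = min(w, len(elem))
    refs["two-LTR"] = (two, cut, cut)
    internal = model.internal
    if internal and ltr_len + 2 * min_anchor <= read_len:
        iw = min(w, len(internal))
        one = internal[-iw:] + model.seq[len(model.seq) - ltr_len :] \
            + internal[:iw]
        refs["one-LTR"] = (one, iw, iw + ltr_len)
    return refs


def _probe(rid, seq, ref, jlo, jhi, topology, model, min_anchor, max_indel,
           max_divergence):
    best = None
    for s in (seq, revcomp(seq)):
        res = edlib.align(s, ref, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        t0, t1 = res["locations"][0]
        t1 += 1
        if t0 > jlo - min_anchor or t1 < jhi + min_anchor:
            continue
        verdict = _inspect_path(
            res["cigar"], t0, jlo, jhi, max_indel, max_divergence,
            min_anchor=min_anchor,
        )
        if verdict is None:
            continue
        indel = verdict
        key = res["editDistance"]
        if best is None or key < best[0]:
            best = (key, JunctionEvidence(
                subfamily=model.subfamily, read_id=rid, topology=topology,
                junction_offset=jlo, indel=indel,
                left_anchor=jlo - t0, right_anchor=t1 - jhi,
            ))
    return best[1] if best else None


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield ch, int(num)
            num = ""


def _inspect_path(cigar, t0, jlo, jhi, max_indel, max_divergence,
                  min_anchor=15):
    """Validate a junction-spanning alignment path; return the signed
    junction indel, or None if the path does not look like a genuine
    junction read.

    Under a substitution-only error model the only indels in a genuine
    alignment are the junction indel itself (possibly split by short
    chance matches when inserted bases coincide with reference bases).
    All indel operations must therefore fall into one compact zone that
    touches the seal point, and the alignment outside that zone must be
    near-exact over at least ``min_anchor`` bases on each side, so
    chance alignments of foreign read ends cannot ride on the indel
    allowance.
    """
    tpos = t0
    indel = 0
    segments = []           # (kind, target_start, target_end) for =/X
    zone_lo = zone_hi = None
    for op, ln in _cigar_ops(cigar):
        if op in "=X":
            segments.append((op, tpos, tpos + ln))
            tpos += ln
        elif op == "D":
            indel -= ln
            lo, hi = tpos, tpos + ln
            tpos += ln
        elif op == "I":
            indel += ln
            lo, hi = tpos, tpos
        if op in "DI":
            zone_lo = lo if zone_lo is None else min(zone_lo, lo)
            zone_hi = hi if zone_hi is None else max(zone_hi, hi)
    t1 = tpos
    if abs(indel) > max_indel:
        return None
    if zone_lo is None:
        zone_lo, zone_hi = jlo, jhi
    else:
        zone_lo, zone_hi = zone_lo - 4, zone_hi + 4
        # the indel zone must sit at the seal, within the slack its own
        # size allows, and must not be a second event elsewhere
        if zone_hi < jlo - abs(indel) - 4 or zone_lo > jhi + abs(indel) + 4:
            return None
        if zone_lo < jlo - max_indel - 6 or zone_hi > jhi + max_indel + 6:
            return None
        zone_lo, zone_hi = min(zone_lo, jlo), max(zone_hi, jhi)
    left_span = left_mism = right_span = right_mism = 0
    for kind, a, b in segments:
        ov = min(b, zone_lo) - a
        if ov > 0:
            left_span += ov
            if kind == "X":
                left_mism += min(ov, b - a)
        ov = b - max(a, zone_hi)
        if ov > 0:
            right_span += ov
            if kind == "X":
                right_mism += min(ov, b - a)
    if left_span < min_anchor or right_span < min_anchor:
        return None
    if left_mism > max(2.0, max_divergence * left_span):
        return None
    if right_mism > max(2.0, max_divergence * right_span):
        return None
    return indel
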