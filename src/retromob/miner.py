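"""Structural detection of intact LTR-RT copies and solo LTRs.

An intact copy is reported when two same-strand repeats seeded by an
exact match of at least ``seed_len`` bp reach ``min_ltr_similarity``
identity, their start positions lie ``min_dist``..``max_dist`` apart,
both repeats carry the terminal TG...CA motif, and an identical flanking
target-site duplication of 2-20 bp is found near both element
boundaries.  Candidate boundaries are proposed from motif positions
within ``tsd_vicinity`` of the similarity-defined repeat edges and the
pair maximizing the ungapped match score is kept, so breakpoints on
clean data are exact.

The LTR pair is compared ungapped (substitution divergence only); pairs
whose LTRs differ by indels are recovered only if the seed-bearing
diagonal still satisfies the thresholds.  Nested insertions are not
resolved: an element inserted into another may shadow the outer copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import encode, kmer_hashes, xdrop_extend
from .synth import AnnotatedGenome


@dataclass(frozen=True)
class MinerParams:
    seed_len: int = 80
    min_ltr_len: int = 100
    max_ltr_len: int = 4000
    min_dist: int = 3000
    max_dist: int = 15000
    min_tsd: int = 2
    max_tsd: int = 20
    motif: tuple[str, str] = ("TG", "CA")
    motif_mismatches: int = 0
    min_ltr_similarity: float = 0.85
    tsd_vicinity: int = 60

    def __post_init__(self) -> None:
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_dist > self.max_dist:
            raise ValueError("min_dist > max_dist")
        if self.min_tsd > self.max_tsd:
            raise ValueError("min_tsd > max_tsd")
        if not 0 < self.min_ltr_similarity <= 1:
            raise ValueError("min_ltr_similarity must be in (0, 1]")


@dataclass
class LtrRtCopy:
    chrom: str
    start: int              # element interval, 0-based half-open
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    strand: str
    tsd: str
    motif_ok: bool
    ltr_identity: float
    id: str = ""

    @property
    def ltr_len(self) -> int:
        return self.ltr5_end - self.ltr5_start

    def ltr5_seq(self, genome: AnnotatedGenome) -> str:
        return genome.chroms[self.chrom][self.ltr5_start : self.ltr5_end]

    def ltr3_seq(self, genome: AnnotatedGenome) -> str:
        return genome.chroms[self.chrom][self.ltr3_start : self.ltr3_end]

    def element_seq(self, genome: AnnotatedGenome) -> str:
        return genome.chroms[self.chrom][self.start : self.end]


@dataclass
class SoloLtr:
    chrom: str
    start: int
    end: int
    strand: str
    source: str             # id of the query LTR / subfamily
    identity: float
    query_coverage: float


# --------------------------------------------------------------------------
# intact-copy detection
# --------------------------------------------------------------------------

def find_ltr_candidates(
    genome: AnnotatedGenome, params: MinerParams = MinerParams()
) -> list[LtrRtCopy]:
    """Scan every chromosome for structurally intact LTR-RT copies."""
    if not genome.chroms:
        raise ValueError("genome is empty")
    calls: list[LtrRtCopy] = []
    for chrom, seq in genome.chroms.items():
        calls.extend(_scan_chromosome(chrom, seq, params))
    # stable ids after overlap resolution
    for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start))):
        c.id = f"{c.chrom}:{c.start}-{c.end}"
    return sorted(calls, key=lambda c: (c.chrom, c.start))


def _scan_chromosome(chrom: str, seq: str, p: MinerParams) -> list[LtrRtCopy]:
    codes = encode(seq)
    n = codes.size
    k = p.seed_len
    if n < k + p.min_dist:
        return []
    hashes = kmer_hashes(codes, k)
    order = np.argsort(hashes, kind="stable")
    sh = hashes[order]
    # boundaries of equal-hash runs
    breaks = np.flatnonzero(sh[1:] != sh[:-1]) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [sh.size]))

    # collect verified seed pairs grouped by diagonal (start-position offset)
    pair_groups: dict[int, list[int]] = {}
    max_delta = p.max_dist
    for s, e in zip(starts, ends):
        if e - s < 2 or e - s > 64:  # ignore huge low-complexity families
            continue
        pos = np.sort(order[s:e])
        for i in range(pos.size):
            for j in range(i + 1, pos.size):
                delta = int(pos[j] - pos[i])
                if delta < p.min_dist:
                    continue
                if delta > max_delta:
                    break
                a, b = int(pos[i]), int(pos[j])
                if seq[a : a + k] == seq[b : b + k]:
                    pair_groups.setdefault(delta, []).append(a)

    candidates: list[LtrRtCopy] = []
    for delta, positions in pair_groups.items():
        positions.sort()
        # cluster seeds on the same diagonal into loci
        cluster = [positions[0]]
        for pos_ in positions[1:] + [None]:
            if pos_ is not None and pos_ - cluster[-1] <= p.max_ltr_len:
                cluster.append(pos_)
            else:
                cand = _resolve_locus(seq, codes, chrom, delta, cluster, p)
                if cand is not None:
                    candidates.append(cand)
                if pos_ is not None:
                    cluster = [pos_]
    return _resolve_overlaps(candidates)


def _resolve_locus(
    seq: str,
    codes: np.ndarray,
    chrom: str,
    delta: int,
    seeds: list[int],
    p: MinerParams,
) -> LtrRtCopy | None:
    """Turn one seed cluster (fixed diagonal) into at most one copy call."""
    n = codes.size
    smin, smax = seeds[0], seeds[-1] + p.seed_len
    a0 = max(0, smin - p.max_ltr_len)
    b0 = min(n - delta, smax + p.max_ltr_len)
    if b0 <= a0:
        return None
    match = codes[a0:b0] == codes[a0 + delta : b0 + delta]
    match &= codes[a0:b0] < 4
    ra, rb = xdrop_extend(match, smin - a0, smax - a0)
    # match-count prefix sums for O(1) identity of any proposed LTR interval
    cum = np.concatenate(([0], np.cumsum(match)))

    m0, m1 = p.motif
    start_cands = _motif_positions(
        seq, delta, m0, a0 + max(0, ra - p.tsd_vicinity),
        a0 + min(match.size, ra + p.tsd_vicinity + 1), p.motif_mismatches,
        terminal=False, n=n,
    )
    end_cands = _motif_positions(
        seq, delta, m1, a0 + max(0, rb - p.tsd_vicinity),
        a0 + min(match.size, rb + p.tsd_vicinity + 1), p.motif_mismatches,
        terminal=True, n=n,
    )
    if not start_cands or not end_cands:
        return None

    best = None  # (score, tsd_len, -start, record fields)
    for s in start_cands:
        for e in end_cands:
            L = e - s
            if not p.min_ltr_len <= L <= p.max_ltr_len:
                continue
            if s + delta + L > n:
                continue
            matches = int(cum[e - a0] - cum[s - a0])
            identity = matches / L
            if identity < p.min_ltr_similarity:
                continue
            tsd = _find_tsd(seq, s, s + delta + L, p)
            if tsd is None:
                continue
            score = matches - 2 * (L - matches)
            key = (score, len(tsd), -s)
            if best is None or key > best[0]:
                best = (
                    key,
                    LtrRtCopy(
                        chrom=chrom, start=s, end=s + delta + L,
                        ltr5_start=s, ltr5_end=s + L,
                        ltr3_start=s + delta, ltr3_end=s + delta + L,
                        strand=".", tsd=tsd, motif_ok=True,
                        ltr_identity=identity,
                    ),
                )
    return best[1] if best else None


def _motif_positions(seq, delta, motif, lo, hi, max_mm, terminal, n):
    """Positions where both repeat copies carry the motif.

    For a start motif the returned position is the LTR start; for a
    terminal motif it is the exclusive LTR end.
    """
    m = len(motif)
    out = []
    for pos in range(max(0, lo), hi):
        a = pos - m if terminal else pos
        b = a + delta
        if a < 0 or b + m > n:
            continue
        mm = sum(seq[a + i] != motif[i] for i in range(m))
        mm += sum(seq[b + i] != motif[i] for i in range(m))
        if mm <= max_mm:
            out.append(pos)
    return out


def _find_tsd(seq: str, elem_start: int, elem_end: int, p: MinerParams):
    """Longest identical flanking duplication, longest first."""
    for t in range(p.max_tsd, p.min_tsd - 1, -1):
        if elem_start - t < 0 or elem_end + t > len(seq):
            continue
        left = seq[elem_start - t : elem_start]
        right = seq[elem_end : elem_end + t]
        if left == right and "N" not in left:
            return left
    return None


def _resolve_overlaps(cands: list[LtrRtCopy]) -> list[LtrRtCopy]:
    """Greedy by (identity desc, element length desc, leftmost)."""
    kept: list[LtrRtCopy] = []
    for c in sorted(
        cands, key=lambda c: (-c.ltr_identity, -(c.end - c.start), c.start)
    ):
        if all(c.end <= k.start or k.end <= c.start for k in kept):
            kept.append(c)
    return kept


# --------------------------------------------------------------------------
# solo LTRs
# --------------------------------------------------------------------------

def find_solo_ltrs(
    genome: AnnotatedGenome,
    ltr_queries: dict[str, str],
    intact_copies: list[LtrRtCopy],
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    seed_k: int = 13,
) -> list[SoloLtr]:
    """Seed-and-extend similarity search for LTRs outside intact copies.

    Hits must reach ``min_identity`` over the aligned columns and align
    at least ``min_coverage`` of the query; any hit overlapping an intact
    copy interval by >= 1 bp is discarded.
    """
    if not ltr_queries:
        return []
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-5, extend_gap_score=-2,
    )
    hits: list[SoloLtr] = []
    for chrom, seq in genome.chroms.items():
        codes = encode(seq)
        ghash = kmer_hashes(codes, seed_k)
        gorder = np.argsort(ghash, kind="stable")
        gsorted = ghash[gorder]
        occupied = [
            (c.start, c.end) for c in intact_copies if c.chrom == chrom
        ]
        for qid, query in ltr_queries.items():
            for strand, qseq in (("+", query), ("-", _rc(query))):
                loci = _seed_loci(
                    qseq, seq, codes, gsorted, gorder, seed_k, len(query)
                )
                for lo, hi in loci:
                    aln = aligner.align(seq[lo:hi], qseq)
                    if len(aln) == 0:
                        continue
                    best = aln[0]
                    ident, qcov, t0, t1 = _alignment_stats(best, len(qseq))
                    if ident < min_identity or qcov < min_coverage:
                        continue
                    start, end = lo + t0, lo + t1
                    if any(a < end and start < b for a, b in occupied):
                        continue
                    hits.append(
                        SoloLtr(
                            chrom=chrom, start=start, end=end, strand=strand,
                            source=qid, identity=ident, query_coverage=qcov,
                        )
                    )
    return _dedupe_solos(hits)


def _rc(s: str) -> str:
    from ._util import revcomp

    return revcomp(s)


def _seed_loci(qseq, seq, codes, gsorted, gorder, k, qlen):
    """Genome windows sharing an exact k-mer with the query."""
    qcodes = encode(qseq)
    qh = kmer_hashes(qcodes, k)
    anchors: set[int] = set()
    for qi in range(0, qh.size, 4):  # every 4th query k-mer is plenty
        idx = np.searchsorted(gsorted, qh[qi])
        while idx < gsorted.size and gsorted[idx] == qh[qi]:
            gpos = int(gorder[idx])
            if seq[gpos : gpos + k] == qseq[qi : qi + k]:
                anchors.add(gpos - qi)
            idx += 1
    if not anchors:
        return []
    # merge anchor diagonals into windows
    pad = qlen // 2 + 50
    spans = sorted((a - pad, a + qlen + pad) for a in anchors)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(max(0, a), min(len(seq), b)) for a, b in merged]


def _alignment_stats(alignment, qlen):
    """(identity over aligned columns, query coverage, target span)."""
    t_aln, q_aln = alignment[0], alignment[1]
    matches = sum(a == b for a, b in zip(t_aln, q_aln) if a != "-" and b != "-")
    cols = len(t_aln)
    tstart = int(alignment.coordinates[0][0])
    tend = int(alignment.coordinates[0][-1])
    qstart = int(alignment.coordinates[1][0])
    qend = int(alignment.coordinates[1][-1])
    ident = matches / cols if cols else 0.0
    return ident, (qend - qstart) / qlen, tstart, tend


def _dedupe_solos(hits: list[SoloLtr]) -> list[SoloLtr]:
    """Keep the best-identity hit among mutually overlapping ones."""
    kept: list[SoloLtr] = []
    for h in sorted(hits, key=lambda h: (-h.identity, -(h.end - h.start))):
        if all(
            h.chrom != k.chrom or h.end <= k.start or k.end <= h.start
            for k in kept
        ):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.chrom, h.start))


# --------------------------------------------------------------------------
# summaries and I/O
# --------------------------------------------------------------------------

def solo_intact_ratio(
    solo_counts: dict[str, int], intact_counts: dict[str, int]
) -> pd.DataFrame:
    """Solo:intact ratio per group; NaN (missing) where no intact copies."""
    rows = []
    for group in sorted(set(solo_counts) | set(intact_counts)):
        ns = solo_counts.get(group, 0)
        ni = intact_counts.get(group, 0)
        if ns < 0 or ni < 0:
            raise ValueError("counts must be >= 0")
        rows.append(
            {
                "group": group,
                "n_solo": ns,
                "n_intact": ni,
                "ratio": (ns / ni) if ni > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_solo", "n_intact", "ratio"])


def audit_copy(copy: LtrRtCopy, genome: AnnotatedGenome, p: MinerParams) -> bool:
    """Independent re-validation of one emitted call against the params."""
    seq = genome.chroms[copy.chrom]
    L = copy.ltr_len
    if not p.min_ltr_len <= L <= p.max_ltr_len:
        return False
    if not p.min_dist <= copy.ltr3_start - copy.ltr5_start <= p.max_dist:
        return False
    if not p.min_tsd <= len(copy.tsd) <= p.max_tsd:
        return False
    if seq[copy.start - len(copy.tsd) : copy.start] != copy.tsd:
        return False
    if seq[copy.end : copy.end + len(copy.tsd)] != copy.tsd:
        return False
    ltr5, ltr3 = copy.ltr5_seq(genome), copy.ltr3_seq(genome)
    ident = sum(a == b for a, b in zip(ltr5, ltr3)) / L
    if ident < p.min_ltr_similarity:
        return False
    m0, m1 = p.motif
    mm = sum(x != y for x, y in zip(ltr5[: len(m0)], m0))
    mm += sum(x != y for x, y in zip(ltr3[-len(m1) :], m1))
    return mm <= p.motif_mismatches


def write_copies_gff3(copies: list[LtrRtCopy], path) -> None:
    """GFF3 with LTR_retrotransposon parents and long_terminal_repeat
    children (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            fh.write(
                f"{c.chrom}\tretromob\tLTR_retrotransposon\t{c.start + 1}\t"
                f"{c.end}\t.\t{c.strand}\t.\tID={c.id};tsd={c.tsd};"
                f"ltr_identity={c.ltr_identity:.4f}\n"
            )
            for tag, a, b in (
                ("five_prime", c.ltr5_start, c.ltr5_end),
                ("three_prime", c.ltr3_start, c.ltr3_end),
            ):
                fh.write(
                    f"{c.chrom}\tretromob\tlong_terminal_repeat\t{a + 1}\t{b}"
                    f"\t.\t{c.strand}\t.\tParent={c.id};side={tag}\n"
                )


def write_solos_bed(solos: list[SoloLtr], path) -> None:
    with open(path, "w") as fh:
        for s in solos:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.source}\t"
                f"{s.identity:.3f}\t{s.strand}\n"
            )
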