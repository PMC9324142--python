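"""Non-reference LTR-RT insertion calling from WGS read pairs.

The caller follows the windowed-signature design: the genome is split
into fixed non-overlapping windows (default 10 kb) and a window becomes
a candidate for subfamily S when at least ``min_support`` read pairs
have one mate aligned to S in the element library and the other mapped
uniquely inside the window.  Breakpoints are then refined from
soft-clipped reads whose clipped sequence matches an LTR terminus of S:
the clip-position cluster defines a refined interval reported only when
it spans at most 200 bp, and a target-site duplication is inferred when
the left- and right-clip clusters overlap by 2-20 bp.

``mask_and_validate`` reproduces the accuracy harness: reference
insertion sites are excised from the genome (restoring the empty,
pre-insertion allele, TSD included) and every read set is run against
both references; a soft-clip call at an unmasked reference site is a
false positive, a masked site with no soft-clip call a false negative,
and both rates are percentages of sites x samples calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .mapping import KmerIndex, ReadAlignment
from .synth import AnnotatedGenome, ReadPair


@dataclass
class InsertionCall:
    sample: str
    subfamily: str
    chrom: str
    window_start: int
    window_end: int
    support: int                       # discordant read-pair count
    refined_start: int | None = None   # <= 200 bp interval, when refinable
    refined_end: int | None = None
    softclip_reads: int = 0
    tsd_len: int | None = None
    status: str = "unassigned"  # reference | shared-non-reference | private

    @property
    def refined(self) -> bool:
        return self.refined_start is not None

    def locus(self) -> tuple[str, int, int]:
        if self.refined:
            return self.chrom, self.refined_start, self.refined_end
        return self.chrom, self.window_start, self.window_end


@dataclass
class ValidationReport:
    n_sites: int
    n_samples: int
    fp_count: int
    fn_count: int
    details: list[dict] = field(default_factory=list)

    @property
    def n_calls(self) -> int:
        return self.n_sites * self.n_samples

    @property
    def fp_rate(self) -> float:
        return round(100.0 * self.fp_count / self.n_calls, 1)

    @property
    def fn_rate(self) -> float:
        return round(100.0 * self.fn_count / self.n_calls, 1)


def estimate_coverage(n_mapped: int, read_len: int, genome_size: int) -> float:
    """Fold coverage = mapped read count * read length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    if n_mapped < 0 or read_len <= 0:
        raise ValueError("read count and read length must be positive")
    return n_mapped * read_len / genome_size


# --------------------------------------------------------------------------
# windowed candidate detection
# --------------------------------------------------------------------------

def call_windows(
    pairs: list[ReadPair],
    te_index: KmerIndex,
    genome_index: KmerIndex,
    sample: str,
    window: int = 10_000,
    min_support: int = 2,
    min_read_len: int = 50,
    te_min_matched: int = 40,
) -> tuple[list[InsertionCall], dict]:
    """Candidate insertion windows per subfamily from discordant pairs.

    Returns the calls plus a cache of per-window genome alignments of
    the discordant reads (reused by breakpoint refinement so nothing is
    mapped twice).
    """
    support: dict[tuple[str, str, int], int] = {}
    window_alignments: dict[tuple[str, int], list[tuple[ReadAlignment, str]]] = {}
    n_mapped = 0
    for pair in pairs:
        mates = [s for s in (pair.seq1, pair.seq2) if len(s) >= min_read_len]
        if len(mates) < 2:
            continue
        te_hits = []
        for seq in mates:
            te_hits.append(
                te_index.map_read(pair.name, seq, min_matched=te_min_matched)
            )
        for mate_i, te_aln in enumerate(te_hits):
            if te_aln is None:
                continue
            anchor_seq = mates[1 - mate_i]
            g_aln = genome_index.map_read(pair.name, anchor_seq)
            if g_aln is None or g_aln.n_best > 1:
                continue
            n_mapped += 1
            win = g_aln.pos // window
            key = (te_aln.ref_id, g_aln.ref_id, win)
            support[key] = support.get(key, 0) + 1
            window_alignments.setdefault((g_aln.ref_id, win), []).append(
                (g_aln, te_aln.ref_id)
            )
            # the TE-matching mate may itself straddle the breakpoint:
            # map it too so its soft clips are available for refinement
            g2 = genome_index.map_read(pair.name, mates[mate_i])
            if g2 is not None and g2.n_best == 1:
                window_alignments.setdefault(
                    (g2.ref_id, g2.pos // window), []
                ).append((g2, te_aln.ref_id))
    calls = [
        InsertionCall(
            sample=sample, subfamily=sub, chrom=chrom,
            window_start=win * window, window_end=(win + 1) * window,
            support=n,
        )
        for (sub, chrom, win), n in sorted(support.items())
        if n >= min_support
    ]
    return calls, {"window_alignments": window_alignments, "window": window}


# --------------------------------------------------------------------------
# soft-clip breakpoint refinement
# --------------------------------------------------------------------------

def refine_breakpoints(
    calls: list[InsertionCall],
    cache: dict,
    te_seqs: dict[str, str],
    min_clip: int = 8,
    min_clip_identity: float = 0.80,
    max_span: int = 200,
    min_tsd: int = 2,
    max_tsd: int = 20,
    terminus_len: int = 160,
    flank_margin: int = 600,
) -> None:
    """Refine each candidate window to a soft-clip breakpoint cluster.

    Clipped sequences of at least ``min_clip`` bp are realigned to the
    element termini of the supporting subfamily (both orientations); a
    clip that matches at >= ``min_clip_identity`` votes with its clip
    position, corrected for microhomology between the element terminus
    and the flanking sequence (the aligner extends through such bases,
    shifting the apparent clip point; the offset of the clip inside the
    terminus undoes the shift).  Votes are clustered (gap > ``max_span``
    starts a new cluster) and the best cluster overlapping the window
    becomes the refined interval, reported only when its span is <=
    ``max_span``; the window-level call is retained otherwise.  A
    target-site duplication is inferred when the left- and right-clip
    positions of the cluster overlap by ``min_tsd``..``max_tsd`` bp.
    """
    window = cache["window"]
    for call in calls:
        votes: list[tuple[int, str]] = []   # (breakpoint, side)
        win = call.window_start // window
        rows: list[tuple[ReadAlignment, str]] = []
        for w in (win - 1, win, win + 1):
            rows.extend(cache["window_alignments"].get((call.chrom, w), ()))
        elem = te_seqs[call.subfamily]
        for aln, sub in rows:
            if sub != call.subfamily:
                continue
            if aln.right_clip >= min_clip:
                off = _locate_clip(aln.right_clip_seq, elem, "right",
                                   min_clip_identity, terminus_len)
                if off is not None:
                    votes.append((aln.end - off, "right"))
            if aln.left_clip >= min_clip:
                off = _locate_clip(aln.left_clip_seq, elem, "left",
                                   min_clip_identity, terminus_len)
                if off is not None:
                    votes.append((aln.pos + off, "left"))
        if not votes:
            continue
        cluster = _pick_cluster(votes, call, max_span, flank_margin)
        if cluster is None:
            continue
        positions = [p for p, _ in cluster]
        call.softclip_reads = len(cluster)
        span = max(positions) - min(positions)
        if span <= max_span:
            call.refined_start = min(positions)
            call.refined_end = max(positions)
            right = [p for p, side in cluster if side == "right"]
            left = [p for p, side in cluster if side == "left"]
            if left and right:
                tsd = _mode(right) - _mode(left)
                if min_tsd <= tsd <= max_tsd:
                    call.tsd_len = tsd


def _locate_clip(clip: str, elem: str, side: str, min_identity: float,
                 terminus_len: int, max_offset: int = 25) -> int | None:
    """Match a clipped sequence to an element terminus.

    Returns the microhomology offset (how far inside the terminus the
    clip starts, for a right clip, or ends short of it, for a left
    clip), or None when the clip does not belong to this element.  Both
    element orientations are tried.
    """
    import edlib

    best = None
    if side == "right":
        # clip continues rightwards into the element: its prefix is the
        # element head (+) or the reverse-complemented tail (-)
        for term in (elem[:terminus_len], revcomp(elem[-terminus_len:])):
            res = edlib.align(clip, term, mode="HW", task="locations")
            ed = res["editDistance"]
            if ed < 0 or 1.0 - ed / len(clip) < min_identity:
                continue
            off = res["locations"][0][0]
            if off <= max_offset and (best is None or ed < best[0]):
                best = (ed, off)
    else:
        for term in (elem[-terminus_len:], revcomp(elem[:terminus_len])):
            res = edlib.align(clip, term, mode="HW", task="locations")
            ed = res["editDistance"]
            if ed < 0 or 1.0 - ed / len(clip) < min_identity:
                continue
            off = len(term) - (res["locations"][0][1] + 1)
            if off <= max_offset and (best is None or ed < best[0]):
                best = (ed, off)
    return best[1] if best else None


def _pick_cluster(votes, call, max_span, flank_margin):
    """Largest vote cluster within reach of the window (ties: nearest to
    the window center); clusters are runs split at gaps > ``max_span``.

    The reach extends ``flank_margin`` beyond the window edges because a
    discordant anchor inside the window can support a breakpoint up to
    roughly one insert size outside it.
    """
    votes = sorted(votes)
    clusters: list[list[tuple[int, str]]] = [[votes[0]]]
    for v in votes[1:]:
        if v[0] - clusters[-1][-1][0] > max_span:
            clusters.append([v])
        else:
            clusters[-1].append(v)
    lo, hi = call.window_start - flank_margin, call.window_end + flank_margin
    center = (call.window_start + call.window_end) / 2
    eligible = [c for c in clusters if c[-1][0] >= lo and c[0][0] <= hi]
    if not eligible:
        return None
    return min(eligible,
               key=lambda c: (-len(c), abs((c[0][0] + c[-1][0]) / 2 - center)))


def _mode(values: list[int]) -> int:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]


# --------------------------------------------------------------------------
# cross-sample comparison
# --------------------------------------------------------------------------

def compare_samples(
    calls_by_sample: dict[str, list[InsertionCall]],
    reference_copies: list[tuple[str, int, int]],
    merge_dist: int = 200,
):
    """Merge per-sample calls into sites and label their status.

    Calls whose refined intervals (or windows when unrefined) lie within
    ``merge_dist`` on the same chromosome are one site.  A site
    overlapping an annotated reference copy is ``reference``; otherwise
    it is ``shared-non-reference`` when present in >= 2 samples, else
    ``private``.  Returns (sites, presence matrix) where each site is a
    dict with locus, status and member calls.
    """
    entries = []
    for sample, calls in sorted(calls_by_sample.items()):
        for c in calls:
            chrom, a, b = c.locus()
            entries.append((chrom, a, b, sample, c))
    entries.sort(key=lambda e: (e[0], e[1]))
    sites: list[dict] = []
    for chrom, a, b, sample, call in entries:
        target = None
        for site in sites:
            if site["chrom"] != chrom:
                continue
            if _gap(site["start"], site["end"], a, b) <= merge_dist:
                target = site
                break
        if target is None:
            target = {"chrom": chrom, "start": a, "end": b, "calls": []}
            sites.append(target)
        target["start"] = min(target["start"], a)
        target["end"] = max(target["end"], b)
        target["calls"].append(call)
    for site in sites:
        samples = sorted({c.sample for c in site["calls"]})
        site["samples"] = samples
        if any(
            rc_chrom == site["chrom"] and rc_a < site["end"] and site["start"] < rc_b
            for rc_chrom, rc_a, rc_b in reference_copies
        ):
            status = "reference"
        elif len(samples) >= 2:
            status = "shared-non-reference"
        else:
            status = "private"
        site["status"] = status
        for c in site["calls"]:
            c.status = status
    matrix = {
        (site["chrom"], site["start"], site["end"]): {
            "status": site["status"],
            "samples": site["samples"],
        }
        for site in sites
    }
    return sites, matrix


def _gap(a0, a1, b0, b1) -> int:
    if a1 >= b0 and b1 >= a0:
        return 0
    return b0 - a1 if b0 > a1 else a0 - b1


# --------------------------------------------------------------------------
# mask-and-revalidate accuracy harness
# --------------------------------------------------------------------------

def mask_genome(
    genome: AnnotatedGenome,
    sites: list[dict],
    mode: str = "excise",
) -> AnnotatedGenome:
    """Remove reference insertions, restoring the pre-insertion allele.

    Each site dict needs chrom, start, end (element interval) and
    tsd_len.  ``excise`` removes the element plus one TSD copy — the
    empty allele an insertion created from — while ``n-mask`` replaces
    the element with Ns (keeping coordinates stable).
    """
    if mode not in ("excise", "n-mask"):
        raise ValueError(f"unknown masking mode {mode!r}")
    chroms = dict(genome.chroms)
    by_chrom: dict[str, list[dict]] = {}
    for s in sites:
        if mode == "excise" and s.get("tsd_len") is None:
            raise ValueError(
                f"site {s.get('chrom')}:{s.get('start')} lacks a TSD "
                "annotation, required for excision"
            )
        by_chrom.setdefault(s["chrom"], []).append(s)
    for chrom, chrom_sites in by_chrom.items():
        seq = chroms[chrom]
        for s in sorted(chrom_sites, key=lambda x: -x["start"]):
            a, b = s["start"], s["end"]
            if mode == "excise":
                seq = seq[:a] + seq[b + s["tsd_len"] :]
            else:
                seq = seq[:a] + "N" * (b - a) + seq[b:]
        chroms[chrom] = seq
    return AnnotatedGenome(chroms=chroms, genes=list(genome.genes))


def softclip_site_check(
    pairs: list[ReadPair],
    genome_index: KmerIndex,
    te_index: KmerIndex | None,
    sites: list[dict],
    te_seqs: dict[str, str],
    vicinity: int = 200,
    min_clip: int = 8,
    min_clip_identity: float = 0.80,
    te_min_matched: int = 40,
) -> dict[tuple[str, int], int]:
    """Count qualifying soft-clip reads near each site.

    Site positions are given in the coordinates of the indexed genome;
    only reads from pairs touching the element library are inspected,
    mirroring the calling pipeline.  Pass ``te_index=None`` when
    ``pairs`` has already been screened against the library.
    """
    counts: dict[tuple[str, int], int] = {
        (s["chrom"], s["pos"]): 0 for s in sites
    }
    for pair in pairs:
        mates = (pair.seq1, pair.seq2)
        if te_index is not None and not any(
            te_index.map_read(pair.name, m, min_matched=te_min_matched)
            is not None
            for m in mates
        ):
            continue
        for seq in mates:
            aln = genome_index.map_read(pair.name, seq)
            if aln is None:
                continue
            clip_points = []
            if aln.right_clip >= min_clip:
                clip_points.append((aln.end, aln.right_clip_seq, "right"))
            if aln.left_clip >= min_clip:
                clip_points.append((aln.pos, aln.left_clip_seq, "left"))
            for point, clip_seq, side in clip_points:
                for s in sites:
                    if s["chrom"] != aln.ref_id:
                        continue
                    if abs(point - s["pos"]) > vicinity:
                        continue
                    if _locate_clip(
                        clip_seq, te_seqs[s["element"]], side,
                        min_clip_identity, 160,
                    ) is not None:
                        counts[(s["chrom"], s["pos"])] += 1
    return counts


def mask_and_validate(
    genome: AnnotatedGenome,
    reference_sites: list[dict],
    read_sets: dict[str, list[ReadPair]],
    te_seqs: dict[str, str],
    mode: str = "excise",
    k: int = 21,
) -> ValidationReport:
    """Run the masking experiment and report FP/FN rates.

    ``reference_sites`` dicts carry chrom, start, end (element interval
    on the unmasked genome), tsd_len and element (library id).  For
    every read set the soft-clip assay runs at each site against the
    original genome (any call there is a false positive — the insertion
    is present in the reference, so no clipped reads should arise) and
    against the masked genome (no call is a false negative — the
    restored empty allele must reveal the insertion).  Rates are
    percentages of sites x samples, rounded to one decimal.
    """
    masked = mask_genome(genome, reference_sites, mode=mode)
    te_index = KmerIndex(te_seqs, k=k)
    plain_index = KmerIndex(genome.chroms, k=k)
    masked_index = KmerIndex(masked.chroms, k=k)

    plain_sites = [
        {"chrom": s["chrom"], "pos": s["start"], "element": s["element"]}
        for s in reference_sites
    ]
    masked_sites = [
        {"chrom": s["chrom"], "pos": _masked_pos(s, reference_sites, mode),
         "element": s["element"]}
        for s in reference_sites
    ]

    fp = fn = 0
    details = []
    for sample, pairs in sorted(read_sets.items()):
        screened = [
            p for p in pairs
            if any(
                te_index.map_read(p.name, m, min_matched=40) is not None
                for m in (p.seq1, p.seq2)
            )
        ]
        plain_counts = softclip_site_check(
            screened, plain_index, None, plain_sites, te_seqs
        )
        masked_counts = softclip_site_check(
            screened, masked_index, None, masked_sites, te_seqs
        )
        for ps, ms, site in zip(plain_sites, masked_sites, reference_sites):
            fp_hit = plain_counts[(ps["chrom"], ps["pos"])] > 0
            fn_hit = masked_counts[(ms["chrom"], ms["pos"])] == 0
            fp += int(fp_hit)
            fn += int(fn_hit)
            details.append(
                {
                    "sample": sample, "chrom": site["chrom"],
                    "site": site["start"], "false_positive": fp_hit,
                    "false_negative": fn_hit,
                }
            )
    return ValidationReport(
        n_sites=len(reference_sites), n_samples=len(read_sets),
        fp_count=fp, fn_count=fn, details=details,
    )


def _masked_pos(site: dict, all_sites: list[dict], mode: str) -> int:
    """Site position in masked-genome coordinates (excision shifts)."""
    if mode != "excise":
        return site["start"]
    shift = sum(
        (s["end"] - s["start"]) + s["tsd_len"]
        for s in all_sites
        if s["chrom"] == site["chrom"] and s["start"] < site["start"]
    )
    return site["start"] - shift
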