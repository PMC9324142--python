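"""Minimal seed-and-extend short-read mapper.

Reads are placed by exact k-mer seeds (default k=21) and extended along
the seed diagonal with an x-drop rule; the error model is substitution
only, so extension is ungapped and any read prefix/suffix that fails to
extend is recorded as a soft clip with its sequence.  This is exactly
the information the junction detector and the breakpoint refiner
consume.  External alignments can also be imported from SAM.

Placements are ranked by (most matched bases, fewest mismatches, lowest
reference id, lowest position); ``n_best`` counts co-optimal placements
so downstream callers can enforce unique mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import encode, kmer_hashes, revcomp, xdrop_extend


@dataclass
class ReadAlignment:
    read_id: str
    ref_id: str
    pos: int                  # 0-based start of the matched span
    strand: str
    matched_span: int
    left_clip: int
    right_clip: int
    left_clip_seq: str
    right_clip_seq: str
    edits: int                # mismatches inside the matched span
    n_best: int = 1           # co-optimal placements (uniqueness filter)

    @property
    def end(self) -> int:
        return self.pos + self.matched_span

    @property
    def read_len(self) -> int:
        return self.left_clip + self.matched_span + self.right_clip

    def matches(self) -> int:
        return self.matched_span - self.edits


class KmerIndex:
    """Exact k-mer index over a reference set."""

    def __init__(self, references: dict[str, str], k: int = 21):
        if not references:
            raise ValueError("reference set is empty")
        self.k = k
        self.names = sorted(references)
        self.seqs = {n: references[n] for n in self.names}
        self.codes = {n: encode(self.seqs[n]) for n in self.names}
        self._index: dict[int, list[tuple[int, int]]] = {}
        for ri, name in enumerate(self.names):
            h = kmer_hashes(self.codes[name], k)
            for pos, hv in enumerate(h.tolist()):
                self._index.setdefault(hv, []).append((ri, pos))

    # ------------------------------------------------------------------

    def map_read(
        self,
        read_id: str,
        seq: str,
        min_matched: int = 30,
        max_candidates: int = 64,
        seed_stride: int = 4,
    ) -> ReadAlignment | None:
        """Best placement of a read (both strands) or None if unmapped."""
        best: ReadAlignment | None = None
        best_key = None
        n_best = 0
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for cand in self._candidates(s, max_candidates, seed_stride):
                aln = self._extend(read_id, s, strand, *cand)
                if aln is None or aln.matched_span < min_matched:
                    continue
                key = (-aln.matches(), aln.edits, aln.ref_id, aln.pos,
                       aln.strand)
                if best_key is None or key < best_key:
                    best, best_key, n_best = aln, key, 1
                elif key[:2] == best_key[:2] and (
                    aln.ref_id != best.ref_id or aln.pos != best.pos
                ):
                    n_best += 1
        if best is not None:
            best.n_best = n_best
        return best

    def _candidates(self, s: str, max_candidates: int, stride: int):
        k = self.k
        codes = encode(s)
        if codes.size < k:
            return []
        h = kmer_hashes(codes, k)
        seen: set[tuple[int, int]] = set()
        out = []
        offsets = list(range(0, h.size, stride))
        if (h.size - 1) not in offsets:
            offsets.append(h.size - 1)
        for off in offsets:
            for ri, pos in self._index.get(int(h[off]), ()):
                name = self.names[ri]
                if self.seqs[name][pos : pos + k] != s[off : off + k]:
                    continue
                diag = (ri, pos - off)
                if diag in seen:
                    continue
                seen.add(diag)
                out.append((ri, pos - off, off))
                if len(out) >= max_candidates:
                    return out
        return out

    def _extend(self, read_id, s, strand, ri, diag, seed_off):
        name = self.names[ri]
        ref = self.codes[name]
        rcodes = encode(s)
        L = rcodes.size
        # overlap of the read's diagonal placement with the reference
        r_lo = max(0, -diag)
        r_hi = min(L, ref.size - diag)
        if r_hi - r_lo < self.k:
            return None
        window = ref[diag + r_lo : diag + r_hi]
        match = (rcodes[r_lo:r_hi] == window) & (rcodes[r_lo:r_hi] < 4)
        seed_lo = max(seed_off - r_lo, 0)
        seed_hi = min(seed_lo + self.k, match.size)
        a, b = xdrop_extend(match, seed_lo, seed_hi)
        span = b - a
        edits = int(span - match[a:b].sum())
        start_read = r_lo + a
        end_read = r_lo + b
        return ReadAlignment(
            read_id=read_id, ref_id=name, pos=diag + start_read,
            strand=strand, matched_span=span,
            left_clip=start_read, right_clip=L - end_read,
            left_clip_seq=s[:start_read], right_clip_seq=s[end_read:],
            edits=edits,
        )


def map_reads(
    reads: list[tuple[str, str]],
    references: dict[str, str],
    k: int = 21,
    min_matched: int = 30,
) -> list[ReadAlignment]:
    """Map a list of (id, sequence) reads; unmapped reads are omitted.

    Reads shorter than k are unmappable by construction.
    """
    index = KmerIndex(references, k=k)
    out = []
    for rid, seq in reads:
        aln = index.map_read(rid, seq, min_matched=min_matched)
        if aln is not None:
            out.append(aln)
    return out


# --------------------------------------------------------------------------
# SAM import/export
# --------------------------------------------------------------------------

def read_sam(path) -> list[ReadAlignment]:
    """Import mapped reads from a SAM file (soft clips from the CIGAR)."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            cig = rec.cigartuples or []
            lclip = cig[0][1] if cig and cig[0][0] == 4 else 0
            rclip = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            seq = rec.query_sequence
            span = len(seq) - lclip - rclip
            out.append(
                ReadAlignment(
                    read_id=rec.query_name, ref_id=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    matched_span=span, left_clip=lclip, right_clip=rclip,
                    left_clip_seq=seq[:lclip],
                    right_clip_seq=seq[len(seq) - rclip :],
                    edits=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    return out


def write_sam(alignments: list[ReadAlignment], references: dict[str, str],
              path) -> None:
    """Export alignments as SAM.

    The matched span is emitted as the reference bases (the alignment
    record does not retain per-base read sequence; mismatch positions
    are summarized by the NM tag), clipped ends as their stored
    sequence.
    """
    names = sorted(references)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for n in names:
            fh.write(f"@SQ\tSN:{n}\tLN:{len(references[n])}\n")
        for a in alignments:
            cigar = ""
            if a.left_clip:
                cigar += f"{a.left_clip}S"
            cigar += f"{a.matched_span}M"
            if a.right_clip:
                cigar += f"{a.right_clip}S"
            seq = (
                a.left_clip_seq
                + references[a.ref_id][a.pos : a.end]
                + a.right_clip_seq
            )
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.pos + 1}\t60\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\tNM:i:{a.edits}\n"
            )
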