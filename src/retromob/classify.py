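"""Hierarchical LTR-RT classification.

Superfamily and lineage come from translated protein-domain searches
(GAG/PR/INT/RT/RH) against a lineage-tagged reference set; subfamilies
from single-linkage clustering of LTR sequences at 60% identity / 70%
overlap; families from a neighbor-joining tree over rt-domain sequences
cut at branches with bootstrap support > 70 and length >= 0.3
substitutions/site.  Canonical names compose all four levels with the
genomic location.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._util import encode, revcomp
from .phylo import Node, attach_support, cut_tree, k80_matrix, neighbor_joining

logger = logging.getLogger(__name__)

DOMAINS = ("GAG", "PR", "INT", "RT", "RH")

#: lineage -> superfamily, after the usual plant LTR-RT taxonomy
LINEAGE_SUPERFAMILY = {
    "Ale": "Copia", "Alesia": "Copia", "Angela": "Copia", "Bianca": "Copia",
    "Ikeros": "Copia", "Ivana": "Copia", "SIRE": "Copia", "TAR": "Copia",
    "Tork": "Copia",
    "Athila": "Gypsy", "CRM": "Gypsy", "Galadriel": "Gypsy", "Ogre": "Gypsy",
    "Reina": "Gypsy", "Retand": "Gypsy", "Tekay": "Gypsy",
}

_HEADER_RE = re.compile(r"^([^#\s]+)#([^#\s]+)#(\S+)$")


@dataclass
class DomainHit:
    copy_id: str
    domain: str
    frame: int                  # +1..+3 / -1..-3
    start: int                  # nucleotide interval on the element
    end: int
    score: float
    lineage: str


@dataclass
class SubfamilyPartition:
    assignment: dict[str, str]  # copy id -> sNNNN
    ident: float = 0.6
    overlap: float = 0.7

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, lab in self.assignment.items():
            out.setdefault(lab, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}


@dataclass
class FamilyTree:
    lineage: str
    tree: Node | None
    assignment: dict[str, str]  # copy id -> f0..fn
    excluded: list[str] = field(default_factory=list)  # saturated / no rt


# --------------------------------------------------------------------------
# domain reference set
# --------------------------------------------------------------------------

def parse_domain_db(records: list[tuple[str, str]]) -> dict[tuple[str, str], str]:
    """Parse ``>LINEAGE#DOMAIN#id`` FASTA records into a reference dict."""
    db: dict[tuple[str, str], str] = {}
    for header, seq in records:
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(
                f"malformed domain reference header {header!r}; expected "
                "LINEAGE#DOMAIN#id"
            )
        lineage, domain, _ = m.groups()
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r} in header {header!r}")
        db[(lineage, f"{domain}#{m.group(3)}")] = seq
    return db


def read_domain_fasta(path) -> dict[tuple[str, str], str]:
    from Bio import SeqIO

    return parse_domain_db(
        [(rec.description.split()[0], str(rec.seq))
         for rec in SeqIO.parse(path, "fasta")]
    )


def default_score_min(db: dict[tuple[str, str], str]) -> float:
    """60% of the BLOSUM62 self-score of the shortest reference peptide."""
    aligner = _protein_aligner()
    shortest = min(db.values(), key=len)
    return 0.6 * aligner.score(shortest, shortest)


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


# --------------------------------------------------------------------------
# domain detection
# --------------------------------------------------------------------------

def detect_domains(
    copy_id: str,
    element_seq: str,
    domain_db: dict[tuple[str, str], str],
    score_min: float | None = None,
) -> list[DomainHit]:
    """Best protein-domain hit per domain type via six-frame search.

    The element is translated in all six frames and each reference
    peptide is locally aligned (BLOSUM62, affine gaps); per domain type
    only the best-scoring reference hit is kept, and hits below
    ``score_min`` (default: 60% of the shortest reference self-score)
    are dropped.
    """
    if score_min is None:
        score_min = default_score_min(domain_db)
    aligner = _protein_aligner()
    n = len(element_seq)
    frames: list[tuple[int, str]] = []
    rc = revcomp(element_seq)
    for off in range(3):
        frames.append((off + 1, _translate(element_seq[off:])))
        frames.append((-(off + 1), _translate(rc[off:])))

    best: dict[str, DomainHit] = {}
    for (lineage, dom_id), pep in domain_db.items():
        domain = dom_id.split("#")[0]
        for frame, prot in frames:
            if len(prot) < 10:
                continue
            score = aligner.score(prot, pep)
            if score < score_min:
                continue
            if domain in best and best[domain].score >= score:
                continue
            aln = aligner.align(prot, pep)[0]
            p0 = int(aln.coordinates[0][0])
            p1 = int(aln.coordinates[0][-1])
            off = abs(frame) - 1
            if frame > 0:
                start, end = off + 3 * p0, off + 3 * p1
            else:
                start, end = n - (off + 3 * p1), n - (off + 3 * p0)
            best[domain] = DomainHit(
                copy_id=copy_id, domain=domain, frame=frame,
                start=start, end=end, score=float(score), lineage=lineage,
            )
    return sorted(best.values(), key=lambda h: h.start)


def _translate(nt: str) -> str:
    usable = nt[: len(nt) - len(nt) % 3]
    return str(Seq(usable).translate())


# --------------------------------------------------------------------------
# lineage assignment
# --------------------------------------------------------------------------

def assign_lineage(hits: list[DomainHit]) -> tuple[str, str]:
    """(lineage, superfamily) from the members' domain hits.

    Majority vote over best-hit lineage labels; an exact tie is reported
    as unclassified rather than broken arbitrarily.
    """
    if not hits:
        return "unclassified", "unclassified"
    votes: dict[str, int] = {}
    for h in hits:
        votes[h.lineage] = votes.get(h.lineage, 0) + 1
    top = max(votes.values())
    winners = sorted(lab for lab, v in votes.items() if v == top)
    if len(winners) > 1:
        logger.warning(
            "lineage tie between %s; assigning 'unclassified'", winners
        )
        return "unclassified", "unclassified"
    lineage = winners[0]
    return lineage, LINEAGE_SUPERFAMILY.get(lineage, "unclassified")


# --------------------------------------------------------------------------
# subfamily clustering
# --------------------------------------------------------------------------

def ltr_pair_metrics(a: str, b: str) -> tuple[float, float]:
    """(identity, overlap) of the best local alignment of two LTRs.

    Identity is matches over aligned columns (gap columns included);
    overlap is the aligned fraction of the *longer* sequence — the
    conservative convention.
    """
    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-5, extend_gap_score=-2,
    )
    alns = aligner.align(a, b)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    sa, sb = aln[0], aln[1]
    cols = len(sa)
    matches = sum(x == y for x, y in zip(sa, sb) if x != "-" and y != "-")
    span_a = int(aln.coordinates[0][-1] - aln.coordinates[0][0])
    span_b = int(aln.coordinates[1][-1] - aln.coordinates[1][0])
    longer_span = span_a if len(a) >= len(b) else span_b
    return (
        matches / cols if cols else 0.0,
        longer_span / max(len(a), len(b)),
    )


def cluster_subfamilies(
    ltr_seqs: dict[str, str], ident: float = 0.6, overlap: float = 0.7
) -> SubfamilyPartition:
    """Single-linkage clustering of one representative LTR per copy.

    Copies are connected when alignment identity >= ``ident`` and the
    aligned fraction of the longer sequence >= ``overlap``; subfamilies
    are the connected components, labelled ``sNNNN`` by descending size,
    ties by smallest member id.
    """
    ids = sorted(ltr_seqs)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pid, pov = ltr_pair_metrics(ltr_seqs[a], ltr_seqs[b])
            if pid >= ident and pov >= overlap:
                g.add_edge(a, b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    assignment = {
        cid: f"s{i + 1:04d}" for i, comp in enumerate(comps) for cid in comp
    }
    return SubfamilyPartition(assignment=assignment, ident=ident, overlap=overlap)


# --------------------------------------------------------------------------
# rt alignment and family trees
# --------------------------------------------------------------------------

def align_and_filter(
    seqs: dict[str, str], min_occupancy: float = 0.9
) -> dict[str, str]:
    """Progressive multiple alignment plus occupancy-based column filter.

    Sequences are aligned along a star guide tree: the center minimizes
    total k-mer distance, every other sequence is globally aligned to it
    (affine gaps) and the pairwise alignments are merged on center
    coordinates ("once a gap, always a gap").  Columns with less than
    ``min_occupancy`` non-gap characters are then discarded.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = sorted(seqs)
    center = _star_center(seqs, ids)
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-1,
    )
    cseq = seqs[center]
    # per pairwise alignment: gaps opened inside the center at position i
    pair_rows: dict[str, tuple[list[str], dict[int, int]]] = {}
    ins_count = [0] * (len(cseq) + 1)  # insertions before center position i
    for sid in ids:
        if sid == center:
            continue
        aln = aligner.align(cseq, seqs[sid])[0]
        ca, sa = aln[0], aln[1]
        row, inserts = _project(ca, sa)
        pair_rows[sid] = (row, inserts)
        for cpos, k in inserts.items():
            ins_count[cpos] = max(ins_count[cpos], k)

    out: dict[str, list[str]] = {center: []}
    for cpos in range(len(cseq) + 1):
        out[center].extend("-" * ins_count[cpos])
        if cpos < len(cseq):
            out[center].append(cseq[cpos])
    for sid in ids:
        if sid == center:
            continue
        row, inserts = pair_rows[sid]
        merged: list[str] = []
        cursor = 0
        for cpos in range(len(cseq) + 1):
            k = inserts.get(cpos, 0)
            merged.extend(row[cursor : cursor + k])
            merged.extend("-" * (ins_count[cpos] - k))
            cursor += k
            if cpos < len(cseq):
                merged.append(row[cursor])
                cursor += 1
        out[sid] = merged

    width = len(out[center])
    mat = np.array([out[sid] for sid in ids])
    occ = (mat != "-").mean(axis=0)
    keep = occ >= min_occupancy
    return {sid: "".join(np.array(out[sid])[keep]) for sid in ids}


def _star_center(seqs: dict[str, str], ids: list[str], k: int = 6) -> str:
    profiles = {}
    for sid in ids:
        s = seqs[sid]
        profiles[sid] = {s[i : i + k] for i in range(max(1, len(s) - k + 1))}
    best, best_total = ids[0], float("inf")
    for sid in ids:
        total = 0.0
        for other in ids:
            if other == sid:
                continue
            pa, pb = profiles[sid], profiles[other]
            union = len(pa | pb)
            total += 1.0 - (len(pa & pb) / union if union else 0.0)
        if total < best_total:
            best, best_total = sid, total
    return best


def _project(center_row: str, seq_row: str):
    """Decompose a pairwise alignment into the sequence characters per
    center position and the insertion lengths before each center position."""
    row: list[str] = []
    inserts: dict[int, int] = {}
    cpos = 0
    pending = 0
    for c, s in zip(center_row, seq_row):
        if c == "-":
            row.append(s)
            pending += 1
        else:
            if pending:
                inserts[cpos] = pending
                pending = 0
            row.append(s)
            cpos += 1
    if pending:
        inserts[cpos] = pending
    return row, inserts


def build_family_tree(
    alignment: dict[str, str],
    lineage: str = "",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> FamilyTree:
    """Neighbor-joining tree on K80 distances with bootstrap support.

    Support per internal branch is the percentage of column-resampled
    replicates containing the same bipartition.  Sequences involved in a
    saturated (undefined) K80 pair are routed to the artificial family
    f0 with a warning rather than distorting the tree.
    """
    ids = sorted(alignment)
    codes = np.array([encode(alignment[i]) for i in ids])
    dm = k80_matrix(codes)
    bad = sorted(
        ids[i] for i in range(len(ids)) if np.isnan(np.delete(dm[i], i)).any()
    )
    if bad:
        logger.warning("saturated K80 distances; routing to f0: %s", bad)
    keep_idx = [i for i, sid in enumerate(ids) if sid not in bad]
    kept = [ids[i] for i in keep_idx]
    if len(kept) < 2:
        return FamilyTree(lineage=lineage, tree=None, assignment={},
                          excluded=bad)
    sub_codes = codes[keep_idx]
    tree = neighbor_joining(dm[np.ix_(keep_idx, keep_idx)], kept)
    rng = np.random.default_rng(seed)
    ncol = codes.shape[1]
    reps = []
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        rep_dm = k80_matrix(sub_codes[:, cols])
        if np.isnan(rep_dm).any():
            rep_dm = np.nan_to_num(rep_dm, nan=np.nanmax(rep_dm) * 2 + 1.0)
        reps.append(neighbor_joining(rep_dm, kept))
    attach_support(tree, reps)
    return FamilyTree(lineage=lineage, tree=tree, assignment={}, excluded=bad)


def cut_families(
    ftree: FamilyTree,
    min_support: float = 70.0,
    min_branch: float = 0.3,
    no_rt: list[str] | None = None,
) -> dict[str, str]:
    """Assign family labels from the supported long branches of the tree.

    Maximal clades with support > ``min_support`` and branch length >=
    ``min_branch`` become f1..fn, numbered by descending size with ties
    by smallest member id; remaining leaves form the residual family.
    Copies without an rt domain (``no_rt``) and saturated copies join f0.
    """
    assignment: dict[str, str] = {}
    for cid in (no_rt or []):
        assignment[cid] = "f0"
    for cid in ftree.excluded:
        assignment[cid] = "f0"
    if ftree.tree is None:
        ftree.assignment = dict(assignment)
        return ftree.assignment
    groups = cut_tree(ftree.tree, min_support=min_support, min_branch=min_branch)
    groups = sorted((sorted(g) for g in groups), key=lambda g: (-len(g), g[0]))
    for i, grp in enumerate(groups):
        for cid in grp:
            assignment[cid] = f"f{i + 1}"
    ftree.assignment = dict(assignment)
    return ftree.assignment


# --------------------------------------------------------------------------
# naming
# --------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"^(?P<head>.+?)_f(?P<family>\d+)\.s(?P<subfamily>\d+)_"
    r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$"
)
_HEAD_RE = re.compile(r"^(?P<superfamily>[^_]+)_(?P<prefix>[A-Z][a-z]*?)"
                      r"(?P<lineage>[A-Z].*)$")


def canonical_name(
    superfamily: str,
    lineage: str,
    family: str,
    subfamily: str,
    chrom: str,
    start: int,
    end: int,
    species_prefix: str = "Dc",
) -> str:
    """Compose the canonical copy name, e.g.
    ``Copia_DcAle_f2.s0082_chr3:100-5000``.

    Unclassified copies collapse the superfamily/lineage block to the
    ``unclassified`` placeholder and fall into f0.
    """
    fam = family.lstrip("f") if family else "0"
    sub = subfamily.lstrip("s") if subfamily else "0"
    if lineage == "unclassified" or not lineage:
        return f"unclassified_f{fam}.s{int(sub):04d}_{chrom}:{start}-{end}"
    return (
        f"{superfamily}_{species_prefix}{lineage}_f{fam}.s{int(sub):04d}_"
        f"{chrom}:{start}-{end}"
    )


def parse_name(name: str) -> dict:
    """Invert :func:`canonical_name` (round-trip contract)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable copy name {name!r}")
    d = m.groupdict()
    head = d.pop("head")
    if head == "unclassified":
        d["superfamily"] = d["lineage"] = "unclassified"
        d["prefix"] = None
    else:
        hm = _HEAD_RE.match(head)
        if not hm:
            raise ValueError(f"unparseable classification block {head!r}")
        d.update(hm.groupdict())
    d["family"] = f"f{int(d['family'])}"
    d["subfamily"] = f"s{int(d['subfamily']):04d}"
    d["start"] = int(d["start"])
    d["end"] = int(d["end"])
    return d
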