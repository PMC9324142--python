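"""Synthetic genomes, LTR-RT elements, eccDNA circles and read libraries.

The generator plants structurally complete LTR retrotransposons (paired
LTRs with TG...CA termini, a target-site duplication of 2-20 bp, and an
internal region optionally carrying GAG/PR/INT/RT/RH coding stretches)
into i.i.d. background sequence, together with solo LTRs and gene
intervals, and records every feature in a ground-truth manifest.  Circle
templates emulate the two eccDNA topologies (a full element closed end-
to-start, or the internal region plus a single LTR) with a configurable
small indel at the junction, the hallmark of NHEJ circularization.
Paired-end reads are drawn with uniform fragment starts (wrapping on
circles so junction-spanning reads occur), FR orientation and i.i.d.
substitution errors.

All randomness flows from one explicit seed; the same config yields
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    TRANSITION,
    TRANSVERSIONS,
    decode,
    encode,
    random_seq,
    revcomp,
)

#: domain order inside the coding region per superfamily
DOMAIN_ORDER = {
    "Copia": ("GAG", "PR", "INT", "RT", "RH"),
    "Gypsy": ("GAG", "PR", "RT", "RH", "INT"),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one (arbitrary) codon per amino acid, used to back-translate reference
# peptides into element coding sequence
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementSpec:
    """Blueprint of one intact LTR-RT to plant.

    ``target_K`` is the intended K80 divergence between the two LTRs
    (substitutions/site); 0 plants identical LTRs.  ``domains`` lists the
    internal protein domains to encode, in superfamily-appropriate order.
    """

    name: str
    ltr_len: int = 300
    internal_len: int = 2000
    tsd_len: int = 5
    motif: tuple[str, str] = ("TG", "CA")
    target_K: float = 0.0
    lineage: str = "Ale"
    superfamily: str = "Copia"
    domains: tuple[str, ...] = ("GAG", "PR", "INT", "RT", "RH")
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 2 <= self.tsd_len <= 20:
            raise ValueError(f"tsd_len must be in [2, 20], got {self.tsd_len}")
        if self.target_K < 0:
            raise ValueError("target_K must be >= 0")
        if self.ltr_len < 2 * (len(self.motif[0]) + len(self.motif[1])):
            raise ValueError("ltr_len too short for the terminal motif")
        unknown = set(self.domains) - {"GAG", "PR", "INT", "RT", "RH"}
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")

    @property
    def length(self) -> int:
        return 2 * self.ltr_len + self.internal_len


@dataclass(frozen=True)
class SoloSpec:
    """A solo LTR to plant: a copy of ``source`` element's LTR at the
    given sequence identity (fraction of positions left unmutated)."""

    source: str
    identity: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    n_chrom: int = 2
    chrom_len: int = 100_000
    gc: float = 0.38
    elements: tuple[ElementSpec, ...] = ()
    solo_ltrs: tuple[SoloSpec, ...] = ()
    n_genes_per_chrom: int = 10
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: float = 40.0
    error_rate: float = 0.0
    coverage: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")


# --------------------------------------------------------------------------
# ground truth records
# --------------------------------------------------------------------------

@dataclass
class PlantedCopy:
    name: str
    chrom: str
    start: int          # element start (0-based, half-open end below)
    end: int
    ltr_len: int
    tsd: str
    strand: str
    lineage: str
    superfamily: str
    target_K: float


@dataclass
class PlantedSolo:
    chrom: str
    start: int
    end: int
    source: str
    identity: float


@dataclass
class CircleRecord:
    name: str
    element: str
    topology: str       # "one-LTR" | "two-LTR"
    junction_indel: int
    length: int


@dataclass
class InsertionSite:
    sample: str
    chrom: str
    position: int       # insertion point in *reference* coordinates
    tsd_len: int
    element: str
    strand: str = "+"


@dataclass
class GroundTruth:
    copies: list[PlantedCopy] = field(default_factory=list)
    solo_ltrs: list[PlantedSolo] = field(default_factory=list)
    genes: list[tuple[str, int, int, str]] = field(default_factory=list)
    circles: list[CircleRecord] = field(default_factory=list)
    insertions: list[InsertionSite] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "copies": [dataclasses.asdict(c) for c in self.copies],
                "solo_ltrs": [dataclasses.asdict(s) for s in self.solo_ltrs],
                "genes": list(self.genes),
                "circles": [dataclasses.asdict(c) for c in self.circles],
                "insertions": [dataclasses.asdict(i) for i in self.insertions],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            copies=[PlantedCopy(**c) for c in d["copies"]],
            solo_ltrs=[PlantedSolo(**s) for s in d["solo_ltrs"]],
            genes=[tuple(g) for g in d["genes"]],
            circles=[CircleRecord(**c) for c in d["circles"]],
            insertions=[InsertionSite(**i) for i in d["insertions"]],
        )


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene intervals (0-based half-open)."""

    chroms: dict[str, str]
    genes: list[tuple[str, int, int, str]] = field(default_factory=list)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_genes_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, start, end, gid in self.genes:
                fh.write(
                    f"{chrom}\tretromob\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                    f"ID={gid}\n"
                )


# --------------------------------------------------------------------------
# LTR pair divergence under K80
# --------------------------------------------------------------------------

def k80_event_probabilities(
    target_K: float, ts_tv: float = 2.0
) -> tuple[float, float]:
    """Expected per-site transition/transversion difference proportions
    (P, Q) between two sequences separated by K80 distance ``target_K``
    with transition:transversion *rate* mix ``ts_tv`` (events, default 2:1).
    """
    if target_K < 0:
        raise ValueError("target_K must be >= 0")
    if target_K > 10:
        # e^{-2(alpha+beta)t} underflows towards 0: the K80 log argument
        # 1-2P-Q would be numerically <= 0 and the distance unrecoverable
        raise ValueError(f"target_K={target_K} is beyond K80 saturation")
    # alpha = 2*R*beta with R = ts_tv;  d = (alpha + 2 beta) t
    bt = target_K / (2.0 * (ts_tv + 1.0))
    at = 2.0 * ts_tv * bt
    p = 0.25 - 0.5 * math.exp(-2.0 * (at + bt)) + 0.25 * math.exp(-4.0 * bt)
    q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    return p, q


def mutate_ltr_pair(
    ltr: str,
    target_K: float,
    rng: np.random.Generator,
    ts_tv: float = 2.0,
    protect_ends: int = 2,
) -> str:
    """Return a diverged copy of ``ltr`` whose expected K80 distance to the
    original equals ``target_K``.

    Per site, a transition occurs with probability P and each transversion
    with probability Q/2, where (P, Q) are the exact K80 difference
    proportions at distance ``target_K``.  The first and last
    ``protect_ends`` bases (the TG...CA motif) are never touched, so the
    structural signal survives dating-scale divergence.
    """
    p, q = k80_event_probabilities(target_K, ts_tv)
    codes = encode(ltr).copy()
    u = rng.random(codes.size)
    tv_pick = rng.integers(0, 2, size=codes.size)
    mutable = np.ones(codes.size, dtype=bool)
    if protect_ends:
        mutable[:protect_ends] = False
        mutable[-protect_ends:] = False
    mutable &= codes < 4
    ts_mask = (u < p) & mutable
    tv_mask = (u >= p) & (u < p + q) & mutable
    out = codes.copy()
    out[ts_mask] = TRANSITION[codes[ts_mask]]
    out[tv_mask] = TRANSVERSIONS[codes[tv_mask], tv_pick[tv_mask]]
    return decode(out)


def substitute(
    seq: str,
    n_transitions: int,
    n_transversions: int,
    rng: np.random.Generator,
    protect_ends: int = 0,
) -> str:
    """Apply exact substitution counts at distinct random positions."""
    codes = encode(seq).copy()
    pos = np.arange(protect_ends, codes.size - protect_ends)
    pos = pos[codes[pos] < 4]
    total = n_transitions + n_transversions
    if total > pos.size:
        raise ValueError("more substitutions than mutable positions")
    chosen = rng.choice(pos, size=total, replace=False)
    ts, tv = chosen[:n_transitions], chosen[n_transitions:]
    codes[ts] = TRANSITION[codes[ts]]
    codes[tv] = TRANSVERSIONS[codes[tv], rng.integers(0, 2, size=tv.size)]
    return decode(codes)


def mutate_to_identity(
    seq: str, identity: float, rng: np.random.Generator
) -> str:
    """Degrade a sequence to roughly the given fraction of unchanged sites."""
    n = round((1.0 - identity) * len(seq))
    n_ts = n * 2 // 3  # 2:1 ts:tv, as elsewhere
    return substitute(seq, n_ts, n - n_ts, rng)


# --------------------------------------------------------------------------
# element and genome construction
# --------------------------------------------------------------------------

def make_domain_db(
    lineages: dict[str, str],
    rng: np.random.Generator,
    peptide_len: int = 100,
    domains: tuple[str, ...] = ("GAG", "PR", "INT", "RT", "RH"),
) -> dict[tuple[str, str], str]:
    """Random reference peptides, one per (lineage, domain).

    ``lineages`` maps lineage label -> superfamily.  Returned dict maps
    (lineage, domain) -> peptide; pair it with :func:`write_domain_fasta`
    for the ``>LINEAGE#DOMAIN#id`` header contract.
    """
    db: dict[tuple[str, str], str] = {}
    for lineage in lineages:
        for dom in domains:
            pep = "".join(_AA[i] for i in rng.integers(0, len(_AA), peptide_len))
            db[(lineage, dom)] = pep
    return db


def write_domain_fasta(db: dict[tuple[str, str], str], path) -> None:
    with open(path, "w") as fh:
        for i, ((lineage, dom), pep) in enumerate(sorted(db.items())):
            fh.write(f">{lineage}#{dom}#ref{i:03d}\n{pep}\n")


def build_element(
    spec: ElementSpec,
    rng: np.random.Generator,
    gc: float = 0.38,
    domain_db: dict[tuple[str, str], str] | None = None,
) -> tuple[str, str, str]:
    """Construct one element; returns (element_seq, ltr5, ltr3)."""
    m0, m1 = spec.motif
    core = random_seq(rng, spec.ltr_len - len(m0) - len(m1), gc)
    ltr5 = m0 + core + m1
    ltr3 = (
        mutate_ltr_pair(ltr5, spec.target_K, rng, protect_ends=2)
        if spec.target_K > 0
        else ltr5
    )
    internal = _build_internal(spec, rng, gc, domain_db)
    element = ltr5 + internal + ltr3
    if spec.strand == "-":
        element = revcomp(element)
        ltr5, ltr3 = revcomp(ltr3), revcomp(ltr5)
    return element, ltr5, ltr3


def _build_internal(spec, rng, gc, domain_db) -> str:
    if not domain_db or not spec.domains:
        return random_seq(rng, spec.internal_len, gc)
    order = [d for d in DOMAIN_ORDER[spec.superfamily] if d in spec.domains]
    coding = "".join(
        "".join(_CODON[a] for a in domain_db[(spec.lineage, d)]) for d in order
    )
    if len(coding) > spec.internal_len:
        raise ValueError(
            f"internal_len={spec.internal_len} too short for domain set "
            f"({len(coding)} bp of coding sequence)"
        )
    pad = spec.internal_len - len(coding)
    left = pad // 2
    return random_seq(rng, left, gc) + coding + random_seq(rng, pad - left, gc)


def build_genome(
    config: SynthConfig,
    domain_db: dict[tuple[str, str], str] | None = None,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Generate the genome and its ground-truth manifest.

    Elements are inserted with an exact target-site duplication: the
    ``tsd_len`` host bases preceding the insertion point are repeated
    immediately after the element, so ``genome[start-t:start] ==
    genome[end:end+t]`` for every planted copy.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    chroms: dict[str, str] = {}
    genes: list[tuple[str, int, int, str]] = []

    # round-robin assignment of elements/solos to chromosomes
    per_chrom_elems: list[list[ElementSpec]] = [[] for _ in range(config.n_chrom)]
    for i, spec in enumerate(config.elements):
        per_chrom_elems[i % config.n_chrom].append(spec)
    per_chrom_solos: list[list[SoloSpec]] = [[] for _ in range(config.n_chrom)]
    for i, solo in enumerate(config.solo_ltrs):
        per_chrom_solos[i % config.n_chrom].append(solo)

    # element sequences are built once so solos can reuse the LTRs
    elem_seqs: dict[str, tuple[str, str, str]] = {}
    for spec in config.elements:
        if spec.name in elem_seqs:
            raise ValueError(f"duplicate element name {spec.name!r}")
        elem_seqs[spec.name] = build_element(spec, rng, config.gc, domain_db)
    spec_by_name = {s.name: s for s in config.elements}

    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        background = random_seq(rng, config.chrom_len, config.gc)

        inserts: list[tuple[str, object]] = []  # (kind, payload)
        for spec in per_chrom_elems[ci]:
            if spec.length + 2 * spec.tsd_len >= config.chrom_len:
                raise ValueError(
                    f"element {spec.name!r} ({spec.length} bp) does not fit "
                    f"in a {config.chrom_len}-bp chromosome"
                )
            inserts.append(("element", spec))
        for solo in per_chrom_solos[ci]:
            if solo.source not in elem_seqs:
                raise ValueError(f"solo LTR source {solo.source!r} unknown")
            inserts.append(("solo", solo))

        # choose well-separated insertion points in background coordinates
        margin = 2000
        points = _spaced_points(
            rng, len(inserts), margin, config.chrom_len - margin,
            min_gap=max((i[1].length if i[0] == "element" else 500)
                        for i in inserts) + 500 if inserts else 1,
        )

        offset = 0
        parts: list[str] = []
        prev = 0
        for (kind, payload), p in zip(inserts, points):
            parts.append(background[prev:p])
            if kind == "element":
                spec = payload
                element, _, _ = elem_seqs[spec.name]
                tsd = background[p - spec.tsd_len : p]
                start = p + offset
                parts.append(element + tsd)
                truth.copies.append(
                    PlantedCopy(
                        name=spec.name, chrom=chrom, start=start,
                        end=start + len(element), ltr_len=spec.ltr_len,
                        tsd=tsd, strand=spec.strand, lineage=spec.lineage,
                        superfamily=spec.superfamily, target_K=spec.target_K,
                    )
                )
                offset += len(element) + len(tsd)
            else:
                solo = payload
                src = spec_by_name[solo.source]
                ltr = elem_seqs[solo.source][1]
                if solo.identity < 1.0:
                    ltr = mutate_to_identity(ltr, solo.identity, rng)
                start = p + offset
                parts.append(ltr)
                truth.solo_ltrs.append(
                    PlantedSolo(
                        chrom=chrom, start=start, end=start + len(ltr),
                        source=solo.source, identity=solo.identity,
                    )
                )
                offset += len(ltr)
            prev = p
        parts.append(background[prev:])
        seq = "".join(parts)
        chroms[chrom] = seq

        # non-overlapping gene intervals in the remaining space
        genes.extend(
            _place_genes(rng, chrom, ci, seq, truth, config.n_genes_per_chrom)
        )

    truth.genes = genes
    return AnnotatedGenome(chroms=chroms, genes=genes), truth


def _spaced_points(rng, n, lo, hi, min_gap):
    """n sorted points in [lo, hi) pairwise at least min_gap apart."""
    if n == 0:
        return []
    span = hi - lo - (n - 1) * min_gap
    if span <= 0:
        raise ValueError("chromosome too short for the requested plantings")
    raw = np.sort(rng.integers(0, span, size=n))
    return [int(lo + r + i * min_gap) for i, r in enumerate(raw)]


def _place_genes(rng, chrom, ci, seq, truth, n_genes):
    occupied = sorted(
        [(c.start - 25, c.end + 25) for c in truth.copies if c.chrom == chrom]
        + [(s.start - 25, s.end + 25) for s in truth.solo_ltrs
           if s.chrom == chrom]
    )
    genes = []
    tries = 0
    while len(genes) < n_genes and tries < 200 * max(n_genes, 1):
        tries += 1
        glen = int(rng.integers(1000, 3000))
        start = int(rng.integers(0, max(1, len(seq) - glen)))
        iv = (start, start + glen)
        clash = any(a < iv[1] and iv[0] < b for a, b in occupied) or any(
            a < iv[1] and iv[0] < b for _, a, b, _ in genes
        )
        if not clash:
            genes.append((chrom, iv[0], iv[1], f"gene{ci + 1}_{len(genes) + 1}"))
    return sorted(genes, key=lambda g: g[1])


# --------------------------------------------------------------------------
# circles
# --------------------------------------------------------------------------

def make_circles(
    element: str,
    ltr_len: int,
    topology: str,
    junction_indel: int,
    n: int = 1,
    rng: np.random.Generator | None = None,
    gc: float = 0.38,
) -> list[str]:
    """Circular eccDNA templates derived from an element.

    two-LTR: the full element closed end-to-start; one-LTR: the internal
    region plus exactly one LTR, closed.  ``junction_indel`` < 0 deletes
    that many bases at the junction (from the upstream side), > 0 inserts
    random bases.  The returned strings start at the base immediately
    after the junction, i.e. the junction sits between the last and first
    characters.
    """
    if topology not in ("one-LTR", "two-LTR"):
        raise ValueError(f"unknown topology {topology!r}")
    if abs(junction_indel) > ltr_len:
        raise ValueError("junction indel longer than the LTR")
    if rng is None:
        rng = np.random.default_rng(0)
    base = element if topology == "two-LTR" else element[ltr_len:]
    out = []
    for _ in range(n):
        circ = base[: len(base) + junction_indel] if junction_indel < 0 else base
        if junction_indel > 0:
            circ = circ + random_seq(rng, junction_indel, gc)
        out.append(circ)
    return out


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str


def simulate_reads(
    templates: dict[str, tuple[str, bool]],
    coverage: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Paired-end reads from (sequence, is_circular) templates.

    Fragment starts are uniform; circular templates wrap, so reads
    spanning the junction occur at the expected frequency.  Fragments are
    drawn from both strands (FR orientation) and substitution errors are
    applied at ``config.error_rate``.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    pairs: list[ReadPair] = []
    rl = config.read_len
    for name, (seq, circular) in templates.items():
        L = len(seq)
        if not circular and rl > L:
            raise ValueError(
                f"read length {rl} exceeds linear template {name!r} ({L} bp)"
            )
        n_pairs = int(rng.poisson(coverage * L / (2.0 * rl))) if coverage else 0
        doubled = seq + seq if circular else seq
        for i in range(n_pairs):
            frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            frag = max(rl, min(frag, L))
            start = int(rng.integers(0, L if circular else L - frag + 1))
            fragment = doubled[start : start + frag]
            r1, r2 = fragment[:rl], revcomp(fragment[-rl:])
            if rng.random() < 0.5:  # fragment sampled from the minus strand
                r1, r2 = revcomp(fragment[-rl:]), fragment[:rl]
            pairs.append(
                ReadPair(
                    name=f"{name}|{i}",
                    seq1=_add_errors(r1, config.error_rate, rng),
                    seq2=_add_errors(r2, config.error_rate, rng),
                )
            )
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hit = (rng.random(codes.size) < rate) & (codes < 4)
    if not hit.any():
        return seq
    shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
    codes[hit] = (codes[hit] + shift) % 4
    return decode(codes)


def write_fastq_pair(pairs: list[ReadPair], prefix: str) -> tuple[str, str]:
    """Write ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` (constant Q40)."""
    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")
    return p1, p2


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    from Bio import SeqIO

    it1 = SeqIO.parse(path1, "fastq")
    it2 = SeqIO.parse(path2, "fastq")
    pairs = []
    for r1, r2 in zip(it1, it2):
        name = r1.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(name=name, seq1=str(r1.seq), seq2=str(r2.seq)))
    return pairs


# --------------------------------------------------------------------------
# per-sample genomes with de novo insertions (sublines)
# --------------------------------------------------------------------------

def insert_elements(
    genome: AnnotatedGenome,
    sites: list[InsertionSite],
    element_seqs: dict[str, str],
) -> AnnotatedGenome:
    """Return a copy of the genome carrying the listed de novo insertions.

    Each insertion duplicates the ``tsd_len`` reference bases preceding
    ``position`` after the element, exactly as integration would.
    Positions are reference coordinates; insertions on the same
    chromosome are applied right-to-left so they do not shift each other.
    """
    chroms = dict(genome.chroms)
    by_chrom: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_sites in by_chrom.items():
        seq = chroms[chrom]
        for s in sorted(chrom_sites, key=lambda x: -x.position):
            elem = element_seqs[s.element]
            if s.strand == "-":
                elem = revcomp(elem)
            tsd = seq[s.position - s.tsd_len : s.position]
            seq = seq[: s.position] + elem + tsd + seq[s.position :]
        chroms[chrom] = seq
    return AnnotatedGenome(chroms=chroms, genes=list(genome.genes))
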