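"""Insertion dating from LTR divergence and genomic-context statistics.

Because the two LTRs of an element are identical at integration, their
K80 divergence K dates the insertion via T = K / (2r), with r the
substitution rate per site per year (default 1.3e-8).  Transition and
transversion proportions are computed over the ungapped columns of a
global LTR-LTR alignment; saturated pairs (a K80 log argument <= 0) are
reported as missing rather than clamped and are excluded from means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from ._util import encode
from .phylo import k80_counts, k80_from_pq

logger = logging.getLogger(__name__)

DEFAULT_RATE = 1.3e-8  # substitutions / site / year


@dataclass
class AgeRecord:
    copy_id: str
    P: float | None
    Q: float | None
    K: float | None          # substitutions/site; None = saturated/missing
    T: float | None          # age, Myr
    r: float = DEFAULT_RATE


@dataclass
class GeneContext:
    copy_id: str
    distance: float | None   # bp to nearest gene; 0 if overlapping
    klass: str               # "genic" | "intergenic"
    bin: int | None          # 1-kb bin index over 1..10 kb


# --------------------------------------------------------------------------
# K80 and ages
# --------------------------------------------------------------------------

def k80_distance(ltr5: str, ltr3: str):
    """(P, Q, K) between the two LTRs of one element.

    The LTRs are globally aligned with affine gap costs; P and Q are the
    transition/transversion difference proportions over ungapped columns
    and K the closed-form K80 distance.  K is None when the alignment
    leaves no ungapped overlap or the distance is saturated.
    """
    if ltr5 == ltr3:
        return 0.0, 0.0, 0.0
    if len(ltr5) == len(ltr3):
        a, b = encode(ltr5), encode(ltr3)
        nv, ts, tv = k80_counts(a, b)
        # fall through to gapped alignment when the ungapped comparison
        # looks frame-shifted (more economical alignments likely exist)
        if nv and (ts + tv) / nv <= 0.3:
            return _finish(ts / nv, tv / nv)
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-1,
    )
    aln = aligner.align(ltr5, ltr3)[0]
    a, b = encode(aln[0]), encode(aln[1])
    nv, ts, tv = k80_counts(a, b)
    if nv == 0:
        logger.warning("no ungapped overlap between LTRs; distance missing")
        return None, None, None
    return _finish(ts / nv, tv / nv)


def _finish(p: float, q: float):
    k = k80_from_pq(p, q)
    if k is None:
        logger.warning("saturated K80 distance (P=%.3f, Q=%.3f)", p, q)
    return p, q, k


def estimate_age(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age T = K / (2 r), in Myr."""
    if r <= 0:
        raise ValueError("substitution rate must be > 0")
    if K is None:
        raise ValueError("K is missing")
    return K / (2.0 * r) / 1e6


def age_copy(copy_id: str, ltr5: str, ltr3: str,
             r: float = DEFAULT_RATE) -> AgeRecord:
    p, q, k = k80_distance(ltr5, ltr3)
    t = estimate_age(k, r) if k is not None else None
    return AgeRecord(copy_id=copy_id, P=p, Q=q, K=k, T=t, r=r)


def age_histogram(ages, bin_width: float = 0.1) -> dict[int, int]:
    """Counts per half-open age bin [k*w, (k+1)*w), in Myr."""
    out: dict[int, int] = {}
    for t in ages:
        if t is None:
            continue
        if t < 0:
            raise ValueError("ages must be >= 0")
        b = int(t // bin_width)
        out[b] = out.get(b, 0) + 1
    return dict(sorted(out.items()))


def mean_age_ci(ages, conf: float = 0.95):
    """(mean, lo, hi): t-based confidence interval on the mean age."""
    arr = np.array([a for a in ages if a is not None], dtype=float)
    if arr.size == 0:
        return None, None, None
    m = float(arr.mean())
    if arr.size == 1:
        return m, m, m
    half = stats.t.ppf(0.5 + conf / 2, arr.size - 1) * arr.std(ddof=1) / math.sqrt(arr.size)
    return m, m - half, m + half


# --------------------------------------------------------------------------
# gene context
# --------------------------------------------------------------------------

def gene_context(
    copies: list[tuple[str, str, int, int]],
    genes: list[tuple[str, int, int, str]],
    flank: int = 1000,
    max_bin_distance: int = 10_000,
) -> list[GeneContext]:
    """Distance to the nearest gene per copy (0 when overlapping).

    A copy is genic when at most ``flank`` bp from a gene, intergenic
    beyond that; distances of 1..10 kb are additionally binned into 1-kb
    bins (bin = ceil(d/1000)).  Copies on gene-less chromosomes get a
    missing distance and class intergenic.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b, _ in genes:
        by_chrom.setdefault(chrom, []).append((a, b))
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts[chrom] = np.array([a for a, _ in ivs])
        ends[chrom] = np.array([b for _, b in ivs])

    out = []
    for cid, chrom, a, b in copies:
        if chrom not in starts:
            out.append(GeneContext(cid, None, "intergenic", None))
            continue
        s, e = starts[chrom], ends[chrom]
        overlap = (s < b) & (a < e)
        if overlap.any():
            d = 0
        else:
            gaps = np.concatenate((s[s >= b] - b, a - e[e <= a]))
            d = int(gaps.min())
        klass = "genic" if d <= flank else "intergenic"
        bin_ = math.ceil(d / 1000) if 1 <= d <= max_bin_distance else None
        out.append(GeneContext(cid, d, klass, bin_))
    return out


def compare_context_distributions(
    distances_a, distances_b, bin_width: int = 1000, max_distance: int = 10_000
):
    """Chi-square GOF and two-sample KS comparison of two gene-distance
    distributions over 1-kb bins spanning 1..10 kb.

    The GOF test measures sample A's binned counts against expected
    proportions from sample B; the KS test runs on the raw distance
    samples within the same range.  Returns a dict with both statistics
    and raw two-sided p-values.
    """
    da = np.asarray([d for d in distances_a if d is not None], dtype=float)
    db = np.asarray([d for d in distances_b if d is not None], dtype=float)
    da = da[(da >= 1) & (da <= max_distance)]
    db = db[(db >= 1) & (db <= max_distance)]
    if da.size == 0 or db.size == 0:
        raise ValueError("empty distance sample in the 1..10 kb range")
    edges = np.arange(0, max_distance + bin_width, bin_width)
    ca, _ = np.histogram(da, bins=edges)
    cb, _ = np.histogram(db, bins=edges)
    expected = cb / cb.sum() * ca.sum()
    keep = expected > 0
    chi2, chi2_p = stats.chisquare(ca[keep], f_exp=expected[keep])
    ks_stat, ks_p = stats.ks_2samp(da, db)
    return {
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "ks_stat": float(ks_stat),
        "ks_p": float(ks_p),
        "counts_a": ca.tolist(),
        "counts_b": cb.tolist(),
    }


def chi2_gof(observed, expected_proportions) -> float:
    """Plain goodness-of-fit statistic sum((O-E)^2/E)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_proportions, dtype=float) * obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


# --------------------------------------------------------------------------
# lineage-level correlations
# --------------------------------------------------------------------------

def lineage_correlations(summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson r, R^2 and p for every pair of numeric lineage features.

    Expects one row per lineage (>= 3) with numeric columns such as copy
    number, solo-LTR count and mean age.  Zero-variance columns yield
    missing correlations with a warning.
    """
    num = summary.select_dtypes("number")
    if len(num) < 3:
        raise ValueError("need >= 3 lineages for correlation")
    cols = list(num.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = num[a].to_numpy(float), num[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("zero variance in %s/%s; correlation missing",
                               a, b)
                r = p = float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"feature_a": a, "feature_b": b, "r": float(r),
                         "r2": float(r) ** 2, "p": float(p)})
    return pd.DataFrame(rows)
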