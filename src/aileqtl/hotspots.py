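"""Trans-eQTL hotspot detection by confidence-interval overlap.

A hotspot is a maximal chromosome interval where the number of overlapping
eQTL confidence intervals meets or exceeds a chromosome-specific threshold:
the 95th percentile of the maximum overlap count when the same number of
average-length intervals is placed uniformly at random on the chromosome
(1000 replicates).  Chromosomes with fewer than 10 eQTL are skipped.
Intervals are closed: touching endpoints count as overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import EqtlRecord

log = logging.getLogger(__name__)

MIN_EQTL_PER_CHROM = 10


@dataclass
class Hotspot:
    chrom: str
    interval_lo_cm: float
    interval_hi_cm: float
    peak_overlap: int
    threshold: int
    member_eqtl: list = field(default_factory=list)   # probeset ids
    n_rjf: int = 0
    n_wl: int = 0

    # serialization aliases
    @property
    def n_members(self) -> int:
        return len(self.member_eqtl)


def overlap_profile(ci_list: Sequence[tuple[float, float]],
                    chromosome_span: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Coverage step function along the chromosome.

    Returns (breakpoints, counts): ``breakpoints`` are the sorted unique CI
    endpoints and ``counts[k]`` the number of closed intervals covering
    ``breakpoints[k]``.  Between consecutive breakpoints coverage is
    constant and never exceeds the counts at the flanking breakpoints, so
    the maximum of the profile is attained on the returned grid.
    """
    lo_span, hi_span = chromosome_span
    los = np.array([c[0] for c in ci_list], float)
    his = np.array([c[1] for c in ci_list], float)
    if los.size and (los.min() < lo_span - 1e-9 or his.max() > hi_span + 1e-9):
        raise ValueError("confidence interval outside chromosome span")
    if np.any(los > his):
        raise ValueError("inverted confidence interval")
    points = np.unique(np.concatenate([los, his])) if los.size else np.array([])
    counts = np.array([int(np.sum((los <= p) & (his >= p))) for p in points])
    return points, counts


def hotspot_threshold(n_eqtl: int, mean_ci_length: float, chromosome_length: float,
                      n_perm: int = 1000, percentile: float = 95.0,
                      seed: int | np.random.Generator = 0) -> int:
    """Permutation threshold: place ``n_eqtl`` intervals of the average CI
    length uniformly on [0, L], record the max overlap, repeat ``n_perm``
    times; threshold = the given percentile of the maxima."""
    if mean_ci_length > chromosome_length:
        raise ValueError("mean CI length exceeds chromosome length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = chromosome_length - mean_ci_length
    starts = rng.uniform(0.0, max(span, 0.0), size=(n_perm, n_eqtl))
    starts.sort(axis=1)
    # intervals [s, s+len] overlap at a point iff starts within len of each
    # other; max coverage is attained at some interval start
    maxima = np.empty(n_perm, int)
    L = mean_ci_length
    for t in range(n_perm):
        s = starts[t]
        lo_idx = np.searchsorted(s, s - L, side="left")
        hi_idx = np.searchsorted(s, s, side="right")
        maxima[t] = int((hi_idx - lo_idx).max())
    return int(np.ceil(np.percentile(maxima, percentile)))


def call_hotspots(profile: tuple[np.ndarray, np.ndarray], threshold: int,
                  ci_list: Sequence[tuple[float, float]],
                  records: Sequence[EqtlRecord] | None = None,
                  chrom: str = "") -> list[Hotspot]:
    """Maximal intervals where the overlap profile >= threshold.

    Sub-threshold gaps split qualifying regions into distinct hotspots.
    Members are the eQTL whose CI intersects the hotspot interval.
    """
    points, counts = profile
    hotspots: list[Hotspot] = []
    if points.size == 0 or threshold <= 0:
        return hotspots
    los = np.array([c[0] for c in ci_list], float)
    his = np.array([c[1] for c in ci_list], float)

    # segment coverage between consecutive breakpoints (open interval)
    def seg_cover(a: float, b: float) -> int:
        mid = 0.5 * (a + b)
        return int(np.sum((los <= mid) & (his >= mid)))

    # coverage of an open segment never exceeds that of its flanking
    # breakpoints, so qualifying runs start and end at breakpoints; a run
    # continues through a segment only if the segment itself qualifies.
    runs: list[tuple[float, float, int]] = []
    cur_lo = None
    cur_peak = 0
    for k, p in enumerate(points):
        if counts[k] >= threshold:
            if cur_lo is None:
                cur_lo, cur_peak = float(p), int(counts[k])
            else:
                cur_peak = max(cur_peak, int(counts[k]))
            cont = (k + 1 < points.size
                    and seg_cover(p, points[k + 1]) >= threshold)
            if not cont:
                runs.append((cur_lo, float(p), cur_peak))
                cur_lo = None

    for lo, hi, peak in runs:
        members, n_rjf, n_wl = [], 0, 0
        for i in range(los.size):
            if los[i] <= hi and his[i] >= lo:
                if records is not None:
                    members.append(records[i].probeset)
                    n_rjf += records[i].direction == "RJF"
                    n_wl += records[i].direction == "WL"
                else:
                    members.append(i)
        hotspots.append(Hotspot(
            chrom=chrom, interval_lo_cm=lo, interval_hi_cm=hi,
            peak_overlap=int(peak), threshold=int(threshold),
            member_eqtl=members, n_rjf=n_rjf, n_wl=n_wl,
        ))
    return hotspots


def find_hotspots(records: Sequence[EqtlRecord], gmap, n_perm: int = 1000,
                  percentile: float = 95.0, min_eqtl: int = MIN_EQTL_PER_CHROM,
                  seed: int | np.random.Generator = 0,
                  trans_only: bool = False) -> list[Hotspot]:
    """Full per-chromosome hotspot pipeline over called eQTL records.

    ``trans_only`` restricts the overlapped CIs to trans eQTL (the default
    uses every eQTL on the chromosome).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    use = [r for r in records if not trans_only or r.cis_trans == "trans"]
    out: list[Hotspot] = []
    for chrom in gmap.chromosomes:
        recs = [r for r in use if r.chrom == chrom]
        if len(recs) < min_eqtl:
            if recs:
                log.info("chromosome %s skipped: %d eQTL < %d", chrom, len(recs), min_eqtl)
            continue
        span = gmap.chrom_span(chrom)
        cis = [(max(r.ci_lo_cm, span[0]), min(r.ci_hi_cm, span[1])) for r in recs]
        profile = overlap_profile(cis, span)
        mean_len = float(np.mean([hi - lo for lo, hi in cis]))
        length = span[1] - span[0]
        thr = hotspot_threshold(len(recs), min(mean_len, length), length,
                                n_perm=n_perm, percentile=percentile, seed=rng)
        # place the null on [0, L]; the observed profile lives on the same scale
        out.extend(call_hotspots(profile, thr, cis, recs, chrom=chrom))
    return out
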