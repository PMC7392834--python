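"""Haley-Knott genome scans, permutation thresholds, peaks, CIs and effects.

LOD at a grid position is (n/2) * log10(RSS0 / RSS1) where RSS0 regresses
the phenotype on the fixed covariates only (intercept, sex, batch) and RSS1
adds the additive and dominance genotype scores -- plus their sex
interactions for the sex-interactive model.  Thresholds are the 80th
(suggestive) and 95th (significant) percentiles of pooled genome-wide
maximum LODs from joint permutations of (phenotype, covariates) against the
genotypes; the cis tier restricts each probeset's maxima to its marker-
extended +/-50 cM window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import CovariateTable, CrossData, GeneticMap
from .linkage import GenotypeProbGrid

log = logging.getLogger(__name__)

DEFAULT_CIS_HALF_WINDOW_CM = 50.0
DEFAULT_LOD_DROP = 1.8


# ---------------------------------------------------------------------------
# least squares helpers

def _batched_rss(X: np.ndarray, Y: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Residual sums of squares for a stack of designs.

    X: (P, n, p) design per position; Y: (n, m) phenotypes.
    Returns (P, m).  Rank-deficient positions fall back to an SVD
    projection so collinear genotype columns cannot inflate the fit.
    """
    yy = np.einsum("nm,nm->m", Y, Y)
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
    scale = diag.max(axis=1, keepdims=True)
    bad = (diag < tol * np.maximum(scale, 1.0)).any(axis=1)
    QtY = np.einsum("pnk,nm->pkm", Q, Y)
    rss = yy[None, :] - np.einsum("pkm,pkm->pm", QtY, QtY)
    if bad.any():
        for p in np.flatnonzero(bad):
            U, s, _ = np.linalg.svd(X[p], full_matrices=False)
            r = int((s > tol * max(s[0], 1.0)).sum())
            proj = U[:, :r].T @ Y
            rss[p] = yy - np.einsum("km,km->m", proj, proj)
    return np.maximum(rss, 0.0)


def _rss_single(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RSS of Y (n, m) on one design X (n, p), rank-aware."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > 1e-8 * max(s[0], 1.0)).sum())
    proj = U[:, :r].T @ Y
    return np.maximum(np.einsum("nm,nm->m", Y, Y) - np.einsum("km,km->m", proj, proj), 0.0)


def _stack_designs(X0: np.ndarray, A: np.ndarray, D: np.ndarray,
                   sex: np.ndarray | None) -> np.ndarray:
    """Build (P, n, p) designs: covariates + a + d (+ a*sex + d*sex)."""
    n, p0 = X0.shape
    P = A.shape[1]
    extra = 2 if sex is None else 4
    X = np.empty((P, n, p0 + extra))
    X[:, :, :p0] = X0[None, :, :]
    X[:, :, p0] = A.T
    X[:, :, p0 + 1] = D.T
    if sex is not None:
        X[:, :, p0 + 2] = A.T * sex[None, :]
        X[:, :, p0 + 3] = D.T * sex[None, :]
    return X


# ---------------------------------------------------------------------------
# results containers

@dataclass
class ScanResult:
    """LOD curves for many phenotypes on the shared grid."""

    ids: list[str]
    chromosomes: list[str]
    chrom_slices: dict[str, slice]
    positions: np.ndarray            # concatenated grid positions
    lod_add: np.ndarray              # (m, P)
    lod_int: np.ndarray              # (m, P)
    n_used: np.ndarray               # (m,)

    def curve(self, pid: str) -> "LodCurve":
        i = self.ids.index(pid)
        return LodCurve(
            id=pid, chromosomes=self.chromosomes, chrom_slices=self.chrom_slices,
            positions=self.positions, lod_additive=self.lod_add[i],
            lod_interactive=self.lod_int[i], n_used=int(self.n_used[i]),
        )

    def window_mask(self, windows: dict[str, tuple[str, float, float] | None]) -> np.ndarray:
        """(m, P) bool mask of each probeset's cis window (False rows when unknown)."""
        mask = np.zeros((len(self.ids), self.positions.size), bool)
        for i, pid in enumerate(self.ids):
            w = windows.get(pid)
            if w is None:
                continue
            chrom, lo, hi = w
            if chrom in self.chrom_slices:
                sl = self.chrom_slices[chrom]
                pos = self.positions[sl]
                mask[i, sl] = (pos >= lo) & (pos <= hi)
        return mask


@dataclass
class LodCurve:
    """Genome-scan output for one phenotype: additive and sex-interactive LOD."""

    id: str
    chromosomes: list[str]
    chrom_slices: dict[str, slice]
    positions: np.ndarray
    lod_additive: np.ndarray
    lod_interactive: np.ndarray
    n_used: int

    def on_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sl = self.chrom_slices[chrom]
        return self.positions[sl], self.lod_additive[sl], self.lod_interactive[sl]


@dataclass
class ThresholdSet:
    """Permutation LOD tiers; each pair is (nonsex, sex-interactive)."""

    trans_suggestive: tuple[float, float]
    trans_significant: tuple[float, float]
    cis_suggestive: tuple[float, float] | None = None
    cis_significant: tuple[float, float] | None = None
    provenance: dict = field(default_factory=dict)

    def suggestive(self, cis: bool, sex: bool) -> float:
        pair = self.cis_suggestive if (cis and self.cis_suggestive is not None) else self.trans_suggestive
        return pair[1] if sex else pair[0]

    def significant(self, cis: bool, sex: bool) -> float:
        pair = self.cis_significant if (cis and self.cis_significant is not None) else self.trans_significant
        return pair[1] if sex else pair[0]


@dataclass
class QtlPeak:
    """A called peak with its support interval and effect estimates."""

    id: str
    chrom: str
    peak_cm: float
    lod: float
    model: str                      # "additive" | "sex-interactive"
    ci_lo_cm: float = float("nan")
    ci_hi_cm: float = float("nan")
    pct_var: float = float("nan")
    additive: float = float("nan")
    dominance: float = float("nan")
    additive_sex: float = float("nan")
    dominance_sex: float = float("nan")
    cis: bool = False
    tier: str = "suggestive"
    direction: str = ""


# ---------------------------------------------------------------------------
# scanning

def scan_all(Y: np.ndarray, ids: Sequence[str], grid: GenotypeProbGrid,
             covariates: CovariateTable, min_n: int = 10) -> ScanResult:
    """Scan many phenotypes (rows of Y, probesets x individuals).

    Missing phenotype values are handled by case-wise deletion; probesets
    sharing a missingness pattern are scanned together.
    """
    X0 = covariates.design()
    sex = covariates.sex_indicator()
    Y = np.asarray(Y, float)
    m, n = Y.shape
    if X0.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype columns")

    chrom_slices: dict[str, slice] = {}
    pos_parts = []
    offset = 0
    for chrom in grid.chromosomes:
        cp = grid.chroms[chrom].positions
        chrom_slices[chrom] = slice(offset, offset + cp.size)
        pos_parts.append(cp)
        offset += cp.size
    positions = np.concatenate(pos_parts)
    P = positions.size

    lod_add = np.zeros((m, P))
    lod_int = np.zeros((m, P))
    n_used = np.zeros(m, int)

    finite = np.isfinite(Y)
    patterns: dict[bytes, list[int]] = {}
    for i in range(m):
        patterns.setdefault(finite[i].tobytes(), []).append(i)

    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        nn = int(mask.sum())
        n_used[rows] = nn
        if nn < min_n:
            if nn == 0:
                raise ValueError(f"phenotype(s) {[ids[r] for r in rows]} are all-missing")
            log.warning("skipping %d phenotype(s) with n=%d < %d", len(rows), nn, min_n)
            continue
        Ysub = Y[np.ix_(rows, np.flatnonzero(mask))].T        # (nn, g)
        Ysub = Ysub - Ysub.mean(axis=0)
        X0s, sexs = X0[mask], sex[mask]
        rss0 = _rss_single(X0s, Ysub)
        for chrom in grid.chromosomes:
            sl = chrom_slices[chrom]
            A, D = grid.design_scores(chrom)
            A, D = A[mask], D[mask]
            rss1 = _batched_rss(_stack_designs(X0s, A, D, None), Ysub)
            rss2 = _batched_rss(_stack_designs(X0s, A, D, sexs), Ysub)
            with np.errstate(divide="ignore", invalid="ignore"):
                la = 0.5 * nn * np.log10(rss0[None, :] / rss1)
                li = 0.5 * nn * np.log10(rss0[None, :] / rss2)
            la[~np.isfinite(la)] = 0.0
            li[~np.isfinite(li)] = 0.0
            lod_add[np.ix_(rows, range(sl.start, sl.stop))] = np.maximum(la.T, 0.0)
            lod_int[np.ix_(rows, range(sl.start, sl.stop))] = np.maximum(li.T, 0.0)

    lod_int = np.maximum(lod_int, lod_add)  # nested models, guard numeric dust
    return ScanResult(
        ids=[str(i) for i in ids], chromosomes=list(grid.chromosomes),
        chrom_slices=chrom_slices, positions=positions,
        lod_add=lod_add, lod_int=lod_int, n_used=n_used,
    )


def hk_scan(y: np.ndarray, grid: GenotypeProbGrid, covariates: CovariateTable,
            pid: str = "trait") -> LodCurve:
    """Single-phenotype Haley-Knott scan (both models)."""
    res = scan_all(np.asarray(y, float)[None, :], [pid], grid, covariates)
    return res.curve(pid)


# ---------------------------------------------------------------------------
# permutation thresholds

def _permutation_maxima(Y: np.ndarray, grid: GenotypeProbGrid, covariates: CovariateTable,
                        n_perm: int, rng: np.random.Generator,
                        window_mask: np.ndarray | None = None,
                        min_n: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide (or cis-window) max LOD per permutation x phenotype.

    Permutes rows of (phenotype, covariates) jointly against the genotype
    designs.  Returns (maxima_nonsex, maxima_sex), each (n_perm, m).
    """
    X0 = covariates.design()
    sex = covariates.sex_indicator()
    Y = np.asarray(Y, float)
    m, n = Y.shape
    out_a = np.full((n_perm, m), np.nan)
    out_i = np.full((n_perm, m), np.nan)

    finite = np.isfinite(Y)
    patterns: dict[bytes, list[int]] = {}
    for i in range(m):
        patterns.setdefault(finite[i].tobytes(), []).append(i)

    designs = {c: grid.design_scores(c) for c in grid.chromosomes}

    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        nn = int(mask.sum())
        if nn < min_n:
            continue
        keep = np.flatnonzero(mask)
        Ysub = Y[np.ix_(rows, keep)].T
        Ysub = Ysub - Ysub.mean(axis=0)
        X0s, sexs = X0[mask], sex[mask]
        rss0 = _rss_single(X0s, Ysub)
        wmask = window_mask[rows][:, :] if window_mask is not None else None

        for t in range(n_perm):
            perm = rng.permutation(nn)
            Yp, X0p, sexp = Ysub[perm], X0s[perm], sexs[perm]
            la_parts, li_parts = [], []
            for chrom in grid.chromosomes:
                A, D = designs[chrom]
                A, D = A[mask], D[mask]
                rss1 = _batched_rss(_stack_designs(X0p, A, D, None), Yp)
                rss2 = _batched_rss(_stack_designs(X0p, A, D, sexp), Yp)
                with np.errstate(divide="ignore", invalid="ignore"):
                    la = 0.5 * nn * np.log10(rss0[None, :] / rss1)
                    li = 0.5 * nn * np.log10(rss0[None, :] / rss2)
                la[~np.isfinite(la)] = 0.0
                li[~np.isfinite(li)] = 0.0
                la_parts.append(np.maximum(la, 0.0))
                li_parts.append(np.maximum(li, 0.0))
            LA = np.concatenate(la_parts, axis=0)      # (P, g)
            LI = np.maximum(np.concatenate(li_parts, axis=0), LA)
            if wmask is not None:
                LAm = np.where(wmask.T, LA, -np.inf)
                LIm = np.where(wmask.T, LI, -np.inf)
                out_a[t, rows] = LAm.max(axis=0)
                out_i[t, rows] = LIm.max(axis=0)
            else:
                out_a[t, rows] = LA.max(axis=0)
                out_i[t, rows] = LI.max(axis=0)
    return out_a, out_i


def permutation_thresholds(expression: np.ndarray, ids: Sequence[str],
                           grid: GenotypeProbGrid, covariates: CovariateTable,
                           n_perm: int = 1000, n_probesets: int = 1000,
                           iterations: int = 10,
                           seed: int | np.random.Generator = 0,
                           suggestive_pct: float = 80.0,
                           significant_pct: float = 95.0) -> ThresholdSet:
    """Genome-wide (trans-tier) permutation thresholds.

    Per iteration a random probeset subsample is drawn; per permutation the
    individual labels of (expression, covariates) are shuffled jointly
    against the genotypes and the genome-wide max LOD recorded for the
    plain and sex-interactive models.  Tier values are percentiles of the
    maxima pooled over iterations.
    """
    if n_perm < 100:
        log.warning("n_perm=%d < 100: threshold percentiles will be unstable", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(expression, float)
    m = Y.shape[0]
    pooled_a, pooled_i = [], []
    for _ in range(iterations):
        take = rng.choice(m, size=min(n_probesets, m), replace=False)
        ma, mi = _permutation_maxima(Y[take], grid, covariates, n_perm, rng)
        pooled_a.append(ma.ravel())
        pooled_i.append(mi.ravel())
    pa = np.concatenate(pooled_a)
    pi = np.concatenate(pooled_i)
    pa, pi = pa[np.isfinite(pa)], pi[np.isfinite(pi)]
    ts = ThresholdSet(
        trans_suggestive=(float(np.percentile(pa, suggestive_pct)),
                          float(np.percentile(pi, suggestive_pct))),
        trans_significant=(float(np.percentile(pa, significant_pct)),
                           float(np.percentile(pi, significant_pct))),
        provenance={"n_perm": n_perm, "n_probesets": n_probesets,
                    "iterations": iterations, "kind": "trans"},
    )
    return ts


def cis_permutation_thresholds(expression: np.ndarray, ids: Sequence[str],
                               grid: GenotypeProbGrid, covariates: CovariateTable,
                               windows: dict[str, tuple[str, float, float] | None],
                               thresholds: ThresholdSet,
                               n_perm: int = 1000, n_probesets: int = 1000,
                               iterations: int = 10,
                               seed: int | np.random.Generator = 0,
                               suggestive_pct: float = 80.0,
                               significant_pct: float = 95.0) -> ThresholdSet:
    """Add cis-tier thresholds: identical scheme but each probeset's maxima
    are restricted to its own marker-extended +/-50 cM window.  Probesets
    without a gene position are excluded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(expression, float)
    ids = [str(i) for i in ids]
    usable = [i for i, pid in enumerate(ids) if windows.get(pid) is not None]
    if not usable:
        raise ValueError("no probesets with a gene position for cis permutation")
    # mask built once on the full set, subset per iteration
    dummy = ScanResult(ids=ids, chromosomes=list(grid.chromosomes),
                       chrom_slices={}, positions=np.array([]),
                       lod_add=np.empty((0, 0)), lod_int=np.empty((0, 0)),
                       n_used=np.empty(0))
    # rebuild slices/positions as scan_all would
    offset = 0
    pos_parts = []
    for chrom in grid.chromosomes:
        cp = grid.chroms[chrom].positions
        dummy.chrom_slices[chrom] = slice(offset, offset + cp.size)
        pos_parts.append(cp)
        offset += cp.size
    dummy.positions = np.concatenate(pos_parts)
    full_mask = dummy.window_mask(windows)

    pooled_a, pooled_i = [], []
    for _ in range(iterations):
        take = rng.choice(len(usable), size=min(n_probesets, len(usable)), replace=False)
        take = np.asarray(usable)[take]
        ma, mi = _permutation_maxima(Y[take], grid, covariates, n_perm, rng,
                                     window_mask=full_mask[take])
        pooled_a.append(ma.ravel())
        pooled_i.append(mi.ravel())
    pa = np.concatenate(pooled_a)
    pi = np.concatenate(pooled_i)
    pa, pi = pa[np.isfinite(pa)], pi[np.isfinite(pi)]
    return ThresholdSet(
        trans_suggestive=thresholds.trans_suggestive,
        trans_significant=thresholds.trans_significant,
        cis_suggestive=(float(np.percentile(pa, suggestive_pct)),
                        float(np.percentile(pi, suggestive_pct))),
        cis_significant=(float(np.percentile(pa, significant_pct)),
                         float(np.percentile(pi, significant_pct))),
        provenance={**thresholds.provenance, "cis_n_perm": n_perm,
                    "cis_iterations": iterations},
    )


# ---------------------------------------------------------------------------
# windows, peaks, intervals, effects

def cis_window(gene_cm: float, marker_positions: np.ndarray,
               half_window_cm: float = DEFAULT_CIS_HALF_WINDOW_CM) -> tuple[float, float]:
    """The cis window: gene +/- half_window, each bound extended outward to
    the closest flanking marker at least that far away (clamped to the
    terminal markers)."""
    mp = np.asarray(marker_positions, float)
    below = mp[mp <= gene_cm - half_window_cm]
    above = mp[mp >= gene_cm + half_window_cm]
    lo = float(below.max()) if below.size else float(mp.min())
    hi = float(above.min()) if above.size else float(mp.max())
    return lo, hi


def probeset_windows(annotation, gmap: GeneticMap,
                     half_window_cm: float = DEFAULT_CIS_HALF_WINDOW_CM
                     ) -> dict[str, tuple[str, float, float] | None]:
    """Per-probeset cis window (chrom, lo, hi); None when position unknown."""
    windows: dict[str, tuple[str, float, float] | None] = {}
    chroms = set(gmap.chromosomes)
    t = annotation.table
    for pid in t.index:
        chrom = str(t.loc[pid, "chrom"])
        cm = t.loc[pid, "pos_cm"]
        if chrom in chroms and np.isfinite(cm):
            lo, hi = cis_window(float(cm), gmap.positions(chrom), half_window_cm)
            windows[str(pid)] = (chrom, lo, hi)
        else:
            windows[str(pid)] = None
    return windows


def lod_interval(curve: LodCurve, chrom: str, peak_idx: int, gmap: GeneticMap,
                 drop: float = DEFAULT_LOD_DROP, model: str = "additive") -> tuple[float, float]:
    """1.8-LOD-drop support interval, expanded outward to the nearest marker.

    ``peak_idx`` indexes the chromosome's grid.  The contiguous region
    around the peak with LOD >= peak - drop is found, then each endpoint is
    moved outward to the closest marker at or beyond it (clamping at the
    terminal markers gives the chromosome-end behaviour for free).
    """
    pos, la, li = curve.on_chrom(chrom)
    lod = li if model == "sex-interactive" else la
    cut = lod[peak_idx] - drop
    lo_i = peak_idx
    while lo_i > 0 and lod[lo_i - 1] >= cut:
        lo_i -= 1
    hi_i = peak_idx
    while hi_i < lod.size - 1 and lod[hi_i + 1] >= cut:
        hi_i += 1
    mp = gmap.positions(chrom)
    below = mp[mp <= pos[lo_i]]
    above = mp[mp >= pos[hi_i]]
    lo = float(below.max()) if below.size else float(mp.min())
    hi = float(above.min()) if above.size else float(mp.max())
    return lo, hi


def call_peaks(curve: LodCurve, thresholds: ThresholdSet,
               window: tuple[str, float, float] | None, gmap: GeneticMap,
               drop: float = DEFAULT_LOD_DROP) -> list[QtlPeak]:
    """At most one peak per chromosome: the max-LOD position, kept when it
    clears the applicable suggestive threshold.

    Tier selection: cis thresholds apply when the candidate position lies in
    the probeset's cis window, else trans.  The sex-interactive model is
    selected when its LOD clears the sex-tier suggestive threshold AND the
    interactive-minus-additive LOD difference exceeds the sex/nonsex
    threshold gap; otherwise the additive model is reported.
    """
    peaks: list[QtlPeak] = []
    for chrom in curve.chromosomes:
        pos, la, li = curve.on_chrom(chrom)
        if pos.size == 0 or not np.any(la > 0) and not np.any(li > 0):
            continue

        def in_window(p: float) -> bool:
            return (window is not None and window[0] == chrom
                    and window[1] <= p <= window[2])

        ii = int(np.argmax(li))
        cis_i = in_window(pos[ii])
        gap = thresholds.suggestive(cis_i, True) - thresholds.suggestive(cis_i, False)
        use_sex = (li[ii] >= thresholds.suggestive(cis_i, True)
                   and (li[ii] - la[ii]) > gap)
        if use_sex:
            idx, lod, model, cis = ii, float(li[ii]), "sex-interactive", cis_i
        else:
            ia = int(np.argmax(la))
            cis_a = in_window(pos[ia])
            if la[ia] < thresholds.suggestive(cis_a, False):
                continue
            idx, lod, model, cis = ia, float(la[ia]), "additive", cis_a
        tier = ("significant"
                if lod >= thresholds.significant(cis, model == "sex-interactive")
                else "suggestive")
        ci_lo, ci_hi = lod_interval(curve, chrom, idx, gmap, drop=drop, model=model)
        peaks.append(QtlPeak(
            id=curve.id, chrom=chrom, peak_cm=float(pos[idx]), lod=lod,
            model=model, ci_lo_cm=ci_lo, ci_hi_cm=ci_hi, cis=cis, tier=tier,
        ))
    return peaks


def estimate_effects(y: np.ndarray, prob_triples: np.ndarray,
                     covariates: CovariateTable, lod: float,
                     sex_model: bool = False) -> dict:
    """Peak-position HK regression coefficients and summaries.

    ``prob_triples`` are the genotype probabilities at the peak
    (n_individuals, 3).  pct_var = 100 * (1 - 10^(-2 LOD / n));
    direction is WL when the additive (WW - RR) coefficient is positive.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    yk = y[keep]
    X0 = covariates.design()[keep]
    sex = covariates.sex_indicator()[keep]
    a = prob_triples[keep, 2] - prob_triples[keep, 0]
    d = prob_triples[keep, 1]
    cols = [X0, a[:, None], d[:, None]]
    if sex_model:
        cols += [(a * sex)[:, None], (d * sex)[:, None]]
    X = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(X, yk, rcond=None)
    p0 = X0.shape[1]
    n = int(keep.sum())
    out = {
        "additive": float(beta[p0]),
        "dominance": float(beta[p0 + 1]),
        "additive_sex": float(beta[p0 + 2]) if sex_model else float("nan"),
        "dominance_sex": float(beta[p0 + 3]) if sex_model else float("nan"),
        "pct_var": float(100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))),
    }
    out["direction"] = "WL" if out["additive"] > 0 else "RJF"
    return out


def peak_prob_triples(grid: GenotypeProbGrid, chrom: str, peak_cm: float) -> np.ndarray:
    """Genotype probability triples at the grid position nearest a peak."""
    cg = grid.chroms[chrom]
    idx = int(np.argmin(np.abs(cg.positions - peak_cm)))
    return cg.probs[:, idx, :]
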