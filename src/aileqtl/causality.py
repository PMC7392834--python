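"""eQTL / phenotypic-QTL colocalization tests and causal edge orienting.

Overlapping confidence intervals are followed up with an expression-trait
regression (batch and sex as covariates), Bonferroni correction by the
number of *uncorrelated* candidate transcripts in the trait QTL interval,
and SEM model comparison: the causal model (marker -> transcript -> trait)
against reactive, confounded and collider alternatives.  The leo.nb score
is log10 of the causal model's chi-square p-value over the best
alternative's; a single-anchor edge is called at leo.nb >= 1.0 and a
multi-anchor (oca) edge at leo.nb.oca >= 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import CovariateTable, CrossData
from .linkage import GenotypeProbGrid
from .sem import PathModel, SemFit

log = logging.getLogger(__name__)

P_FLOOR = 1e-300
LEO_SINGLE_THRESHOLD = 1.0
LEO_OCA_THRESHOLD = 0.3


@dataclass
class TraitQtl:
    """Phenotypic QTL: one trait, possibly several loci (epistatic pairs)."""

    trait: str
    loci: list[tuple[str, float, float, float]]  # (chrom, ci_lo, ci_hi, peak_cm)

    def __post_init__(self) -> None:
        for chrom, lo, hi, _peak in self.loci:
            if lo > hi:
                raise ValueError(f"inverted CI for {self.trait} on {chrom}")


@dataclass
class OverlapTest:
    trait: str
    probeset: str
    qtl_ci: tuple[str, float, float]
    eqtl_ci: tuple[str, float, float]
    overlap: tuple[float, float]
    raw_p: float
    adjusted_p: float
    t_value: float
    adj_r_squared: float
    n_effective_tests: int
    flagged: bool = False


@dataclass
class LeoResult:
    trait: str
    probeset: str
    anchors: list[str]
    model_p: dict
    leo_nb: float = float("nan")
    leo_nb_oca: float = float("nan")
    leo_nb_cpa: float = float("nan")
    edge_call: str = "none"          # "probeset->trait" | "trait->probeset" | "none"
    threshold_used: float = LEO_SINGLE_THRESHOLD
    best_model: str = ""
    flagged: bool = False


def ci_overlap(eqtl_ci: tuple[str, float, float],
               qtl_ci: tuple[str, float, float]) -> tuple[float, float] | None:
    """Intersection of two closed (chrom, lo, hi) intervals, or None."""
    c1, lo1, hi1 = eqtl_ci
    c2, lo2, hi2 = qtl_ci
    if str(c1) != str(c2):
        return None
    lo, hi = max(lo1, lo2), min(hi1, hi2)
    return (lo, hi) if lo <= hi else None


def overlap_regression(trait_values: np.ndarray, expression: np.ndarray,
                       covariates: CovariateTable) -> tuple[float, float, float]:
    """Trait ~ expression + sex + batch.

    Returns (two-sided p for the expression coefficient, its t value,
    adjusted R^2 of the full model).  Constant expression is undefined and
    reported as p = 1, t = 0.
    """
    y = np.asarray(trait_values, float)
    x = np.asarray(expression, float)
    keep = np.isfinite(y) & np.isfinite(x)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 complete cases for overlap regression")
    X0 = covariates.design()[keep]
    xk = x[keep]
    if np.ptp(xk) == 0:
        return 1.0, 0.0, float("nan")
    X = np.column_stack([X0, xk])
    fit = sm.OLS(y[keep], X).fit()
    return float(fit.pvalues[-1]), float(fit.tvalues[-1]), float(fit.rsquared_adj)


def bonferroni_uncorrelated(p_values: np.ndarray, expression_submatrix: np.ndarray,
                            r_cutoff: float = 0.7) -> tuple[np.ndarray, int]:
    """Bonferroni correction by the number of uncorrelated transcripts.

    Probesets (rows of ``expression_submatrix``) are single-linkage
    clustered on |pairwise correlation| >= r_cutoff; the effective test
    count m is the number of clusters and adjusted p = min(1, p * m).
    """
    p_values = np.asarray(p_values, float)
    E = np.asarray(expression_submatrix, float)
    k = E.shape[0]
    if k != p_values.size:
        raise ValueError("one p-value per probeset row required")
    if k <= 1:
        return np.minimum(p_values, 1.0), max(k, 1)
    # pairwise |r| on pairwise-complete observations
    with np.errstate(invalid="ignore"):
        R = np.abs(pd.DataFrame(E.T).corr().to_numpy())
    np.fill_diagonal(R, 1.0)
    R = np.nan_to_num(R, nan=0.0)
    dist = squareform(1.0 - R, checks=False)
    Z = linkage(dist, method="single")
    labels = fcluster(Z, t=1.0 - r_cutoff, criterion="distance")
    m = int(labels.max())
    return np.minimum(p_values * m, 1.0), m


def sem_fit(model: PathModel, sample_covariance: np.ndarray, n: int) -> SemFit:
    """Fit one path model; see :class:`aileqtl.sem.PathModel`."""
    return model.fit(sample_covariance, n)


def _leo_score(p_target: float, p_alternatives: list[float]) -> float:
    pt = max(p_target, P_FLOOR)
    pa = max(max(p_alternatives), P_FLOOR)
    return float(np.log10(pt) - np.log10(pa))


def _cov_complete(columns: list[np.ndarray]) -> tuple[np.ndarray, int]:
    X = np.column_stack(columns)
    keep = np.all(np.isfinite(X), axis=1)
    Xk = X[keep]
    return np.cov(Xk, rowvar=False), int(keep.sum())


def leo_single(marker_genotype: np.ndarray, expression_a: np.ndarray,
               trait_b: np.ndarray, trait: str = "trait", probeset: str = "probeset",
               anchors: list[str] | None = None,
               threshold: float = LEO_SINGLE_THRESHOLD) -> LeoResult:
    """Single-anchor edge orienting between a transcript A and a trait B.

    Fits four models on the 3x3 covariance of (M, A, B):
    causal M->A->B, reactive M->B->A, confounded A<-M->B (A and B
    independent given M), collider M->A<-B (M independent of B).
    leo.nb = log10 p_causal - log10 max(alternative p).
    """
    S, n = _cov_complete([np.asarray(marker_genotype, float),
                          np.asarray(expression_a, float),
                          np.asarray(trait_b, float)])
    v = ["M", "A", "B"]
    models = {
        "causal": PathModel(v, [("M", "A"), ("A", "B")]),
        "reactive": PathModel(v, [("M", "B"), ("B", "A")]),
        "confounded": PathModel(v, [("M", "A"), ("M", "B")]),
        "collider": PathModel(v, [("M", "A"), ("B", "A")]),
    }
    fits = {name: m.fit(S, n) for name, m in models.items()}
    pvals = {name: f.p_value for name, f in fits.items()}
    flagged = any(f.flagged for f in fits.values()) or any(p <= 0 for p in pvals.values())

    leo_nb = _leo_score(pvals["causal"], [pvals[k] for k in ("reactive", "confounded", "collider")])
    leo_reactive = _leo_score(pvals["reactive"], [pvals[k] for k in ("causal", "confounded", "collider")])
    best = max(pvals, key=lambda k: pvals[k])
    if leo_nb >= threshold:
        call = "probeset->trait"
    elif leo_reactive >= threshold:
        call = "trait->probeset"
    else:
        call = "none"
    return LeoResult(
        trait=trait, probeset=probeset, anchors=anchors or ["M"],
        model_p=pvals, leo_nb=leo_nb, edge_call=call,
        threshold_used=threshold, best_model=best, flagged=flagged,
    )


def leo_multi(anchors_a: np.ndarray, anchors_b: np.ndarray,
              expression_a: np.ndarray, trait_b: np.ndarray, mode: str = "oca",
              trait: str = "trait", probeset: str = "probeset",
              anchor_names: list[str] | None = None,
              threshold: float = LEO_OCA_THRESHOLD) -> LeoResult:
    """Multi-anchor edge orienting.

    ``oca`` (orthogonal causal anchors): transcript anchors M_A drive A,
    trait anchors M_B drive B, and the three orientations of the A-B edge
    (A->B, B->A, absent) are compared.  ``cpa`` (common pleiotropic
    anchors): shared anchors M drive A (causal: M->A->B), B (reactive:
    M->B->A) or both (confounded).  Anchor covariances are free parameters
    in every model, so linkage between anchors is not penalized.
    """
    A = np.atleast_2d(np.asarray(anchors_a, float))
    if A.shape[0] == len(np.asarray(expression_a)):
        A = A.T
    if mode == "oca":
        Bm = np.atleast_2d(np.asarray(anchors_b, float))
        if Bm.shape[0] == len(np.asarray(trait_b)):
            Bm = Bm.T
        ka, kb = A.shape[0], Bm.shape[0]
        names_a = [f"MA{i}" for i in range(ka)]
        names_b = [f"MB{i}" for i in range(kb)]
        v = names_a + names_b + ["A", "B"]
        cols = [A[i] for i in range(ka)] + [Bm[i] for i in range(kb)] + \
               [np.asarray(expression_a, float), np.asarray(trait_b, float)]
        S, n = _cov_complete(cols)
        exog = list(combinations(names_a + names_b, 2))
        base_a = [(m, "A") for m in names_a]
        base_b = [(m, "B") for m in names_b]
        models = {
            "causal": PathModel(v, base_a + base_b + [("A", "B")], exog),
            "reactive": PathModel(v, base_a + base_b + [("B", "A")], exog),
            "independent": PathModel(v, base_a + base_b, exog),
        }
    elif mode == "cpa":
        ka = A.shape[0]
        names = [f"M{i}" for i in range(ka)]
        v = names + ["A", "B"]
        cols = [A[i] for i in range(ka)] + [np.asarray(expression_a, float),
                                            np.asarray(trait_b, float)]
        S, n = _cov_complete(cols)
        exog = list(combinations(names, 2))
        models = {
            "causal": PathModel(v, [(m, "A") for m in names] + [("A", "B")], exog),
            "reactive": PathModel(v, [(m, "B") for m in names] + [("B", "A")], exog),
            "confounded": PathModel(v, [(m, "A") for m in names] + [(m, "B") for m in names], exog),
        }
    else:
        raise ValueError("mode must be 'oca' or 'cpa'")

    fits = {name: m.fit(S, n) for name, m in models.items()}
    pvals = {name: f.p_value for name, f in fits.items()}
    flagged = any(f.flagged for f in fits.values())
    alts = [p for k, p in pvals.items() if k != "causal"]
    score = _leo_score(pvals["causal"], alts)
    reactive_score = _leo_score(pvals["reactive"],
                                [p for k, p in pvals.items() if k != "reactive"])
    if score >= threshold:
        call = "probeset->trait"
    elif reactive_score >= threshold:
        call = "trait->probeset"
    else:
        call = "none"
    res = LeoResult(
        trait=trait, probeset=probeset,
        anchors=anchor_names or (v[:-2]), model_p=pvals,
        edge_call=call, threshold_used=threshold,
        best_model=max(pvals, key=lambda k: pvals[k]), flagged=flagged,
    )
    if mode == "oca":
        res.leo_nb_oca = score
    else:
        res.leo_nb_cpa = score
    return res


def _anchor_scores(grid: GenotypeProbGrid, chrom: str, peak_cm: float,
                   mode: str = "expected") -> np.ndarray:
    """Additive genotype score at a locus: the HK expectation at the grid
    position nearest the peak ('expected') or the hard score at the nearest
    genotyped marker ('marker')."""
    cg = grid.chroms[chrom]
    if mode == "marker":
        cand = np.flatnonzero(cg.is_marker)
        idx = cand[np.argmin(np.abs(cg.positions[cand] - peak_cm))]
    else:
        idx = int(np.argmin(np.abs(cg.positions - peak_cm)))
    p = cg.probs[:, idx, :]
    return p[:, 2] - p[:, 0]


def run_overlap_causality(records, trait_qtls: list[TraitQtl], cross: CrossData,
                          grid: GenotypeProbGrid, r_cutoff: float = 0.7,
                          alpha: float = 0.05, anchor_mode: str = "expected",
                          leo_single_threshold: float = LEO_SINGLE_THRESHOLD,
                          leo_oca_threshold: float = LEO_OCA_THRESHOLD,
                          ) -> tuple[list[OverlapTest], list[LeoResult]]:
    """Colocalization screen plus edge orienting.

    Enumerates eQTL CIs overlapping any trait-QTL locus CI, runs the
    expression-trait regression per pair, Bonferroni-adjusts within each
    trait-QTL locus by the number of uncorrelated transcripts, and sends
    pairs passing the nominal 5% level to LEO with all the trait's loci as
    anchors (the 'distal' convention when only some loci overlap).
    """
    expr = cross.expression.values
    tests: list[OverlapTest] = []
    leos: list[LeoResult] = []
    # candidate lists per trait locus for the Bonferroni denominator
    for tq in trait_qtls:
        trait_vals = cross.phenotypes.table.get(tq.trait)
        if trait_vals is None:
            log.warning("trait %s has no phenotype column; skipped", tq.trait)
            continue
        trait_vals = trait_vals.to_numpy(float)
        for chrom, lo, hi, peak in tq.loci:
            cand = []
            for rec in records:
                ov = ci_overlap((rec.chrom, rec.ci_lo_cm, rec.ci_hi_cm), (chrom, lo, hi))
                if ov is not None:
                    cand.append((rec, ov))
            if not cand:
                continue
            pvals, tvals, r2s, flags = [], [], [], []
            for rec, _ov in cand:
                x = expr.loc[rec.probeset].to_numpy(float)
                p, t, r2 = overlap_regression(trait_vals, x, cross.covariates)
                pvals.append(p)
                tvals.append(t)
                r2s.append(r2)
                flags.append(not np.isfinite(r2))
            E = expr.loc[[rec.probeset for rec, _ in cand]].to_numpy(float)
            adj, m = bonferroni_uncorrelated(np.array(pvals), E, r_cutoff=r_cutoff)
            for (rec, ov), p, ap, t, r2, fl in zip(cand, pvals, adj, tvals, r2s, flags):
                tests.append(OverlapTest(
                    trait=tq.trait, probeset=rec.probeset,
                    qtl_ci=(chrom, lo, hi),
                    eqtl_ci=(rec.chrom, rec.ci_lo_cm, rec.ci_hi_cm),
                    overlap=ov, raw_p=p, adjusted_p=float(ap), t_value=t,
                    adj_r_squared=r2, n_effective_tests=m, flagged=fl,
                ))
                if p < alpha:
                    x = expr.loc[rec.probeset].to_numpy(float)
                    m_scores = _anchor_scores(grid, rec.chrom, rec.peak_cm, anchor_mode)
                    single = leo_single(
                        m_scores, x, trait_vals, trait=tq.trait,
                        probeset=rec.probeset,
                        anchors=[f"{rec.chrom}@{rec.peak_cm:g}"],
                        threshold=leo_single_threshold)
                    trait_anchors = np.vstack([
                        _anchor_scores(grid, c, pk, anchor_mode)
                        for c, _lo, _hi, pk in tq.loci if c in grid.chroms
                    ])
                    oca = leo_multi(
                        m_scores, trait_anchors, x, trait_vals, mode="oca",
                        trait=tq.trait, probeset=rec.probeset,
                        anchor_names=[f"{rec.chrom}@{rec.peak_cm:g}"] + [
                            f"{c}@{pk:g}" for c, _l, _h, pk in tq.loci],
                        threshold=leo_oca_threshold)
                    cpa = leo_multi(
                        m_scores, None, x, trait_vals, mode="cpa",
                        trait=tq.trait, probeset=rec.probeset,
                        threshold=leo_oca_threshold)
                    single.leo_nb_oca = oca.leo_nb_oca
                    single.leo_nb_cpa = cpa.leo_nb_cpa
                    # multi-anchor call takes precedence when informative
                    if oca.edge_call != "none":
                        single.edge_call = oca.edge_call
                    leos.append(single)
    return tests, leos
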