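"""Maximum-likelihood path models for causal edge orienting.

Linear Gaussian structural equation models over a small set of variables.
All models used here are recursive (DAG-structured) with mutually
independent residuals, so the Gaussian likelihood factorizes over the
nodes: the ML solution is exact per-node least squares on the sample
covariance matrix -- no iterative optimizer is required.  The fit statistic
is the standard ML discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

with chi-square = (n - 1) * F_min on df = p(p+1)/2 - (number of free
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class SemFit:
    chi_square: float
    df: int
    p_value: float
    f_min: float
    coefficients: dict
    flagged: bool = False


@dataclass
class PathModel:
    """A recursive path model.

    ``edges``: (parent, child) pairs.  Exogenous variables (no parents) are
    assumed mutually independent unless listed in ``exog_cov_pairs`` (their
    covariance is then a free parameter estimated at its sample value).
    """

    variables: list[str]
    edges: list[tuple[str, str]]
    exog_cov_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parents: dict[str, list[str]] = {v: [] for v in self.variables}
        for a, b in self.edges:
            if a not in self.parents or b not in self.parents:
                raise ValueError(f"edge ({a}, {b}) references unknown variable")
            self.parents[b].append(a)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[str] = set()
        remaining = set(self.variables)
        while remaining:
            free = {v for v in remaining if all(p in seen for p in self.parents[v])}
            if not free:
                raise ValueError("path model contains a cycle")
            seen |= free
            remaining -= free

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if not self.parents[v]]

    def n_free(self) -> int:
        n = 0
        for v in self.variables:
            n += len(self.parents[v]) + 1      # coefficients + (residual) variance
        n += len(self.exog_cov_pairs)
        return n

    def fit(self, S: np.ndarray, n: int) -> SemFit:
        """ML fit to a sample covariance matrix ``S`` from ``n`` observations."""
        S = np.asarray(S, float)
        p = len(self.variables)
        if S.shape != (p, p):
            raise ValueError("covariance shape does not match variable list")
        if n <= p:
            raise ValueError("need more observations than variables")
        idx = {v: i for i, v in enumerate(self.variables)}

        B = np.zeros((p, p))       # B[child, parent]
        psi = np.zeros((p, p))     # residual (co)variances
        coefs: dict = {}
        for v in self.variables:
            i = idx[v]
            pa = self.parents[v]
            if not pa:
                psi[i, i] = S[i, i]
                coefs[f"var({v})"] = float(S[i, i])
                continue
            j = [idx[u] for u in pa]
            Spp = S[np.ix_(j, j)]
            Spv = S[np.ix_(j, [i])]
            beta = np.linalg.solve(Spp, Spv).ravel()
            B[i, j] = beta
            resid = float(S[i, i] - beta @ Spv.ravel())
            psi[i, i] = max(resid, 1e-12)
            for u, b in zip(pa, beta):
                coefs[f"{u}->{v}"] = float(b)
            coefs[f"resid({v})"] = psi[i, i]
        for a, b in self.exog_cov_pairs:
            i, j = idx[a], idx[b]
            psi[i, j] = psi[j, i] = S[i, j]
            coefs[f"cov({a},{b})"] = float(S[i, j])

        ident = np.eye(p)
        inv = np.linalg.inv(ident - B)
        sigma = inv @ psi @ inv.T

        sign_s, logdet_s = np.linalg.slogdet(S)
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        flagged = False
        if sign_s <= 0 or sign_m <= 0:
            return SemFit(float("nan"), self.df(), float("nan"), float("nan"),
                          coefs, flagged=True)
        f_min = float(logdet_m + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)
        f_min = max(f_min, 0.0)
        df = self.df()
        chi2 = (n - 1) * f_min
        if df == 0:
            return SemFit(chi2, 0, 1.0, f_min, coefs, flagged=True)
        return SemFit(chi2, df, float(stats.chi2.sf(chi2, df)), f_min, coefs)

    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free()


def fit_model(variables: Sequence[str], edges: Sequence[tuple[str, str]],
              S: np.ndarray, n: int,
              exog_cov_pairs: Sequence[tuple[str, str]] = ()) -> SemFit:
    return PathModel(list(variables), list(edges), list(exog_cov_pairs)).fit(S, n)
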