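"""Map functions and conditional genotype probabilities for an intercross.

The advanced intercross is scanned with F2-type machinery on its own
expanded map: genotype states {RR, RW, WW} follow a Markov chain along each
chromosome with transition probabilities built from the map function, and a
forward-backward pass conditions on all observed markers (including
partially informative calls and a genotyping-error emission model).
Pseudomarkers at a fixed cM step carry uninformative emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GeneticMap, GenotypeMatrix

F2_PRIOR = np.array([0.25, 0.5, 0.25])  # P(RR), P(RW), P(WW)


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: r = (1 - exp(-2 d / 100)) / 2, no interference."""
    d = np.asarray(d_cm, float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def kosambi_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map function: r = tanh(2 d / 100) / 2."""
    d = np.asarray(d_cm, float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(d_cm) else r


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


def f2_transition(r: float) -> np.ndarray:
    """One-step genotype transition matrix for an intercross at recombination
    fraction r (two independent meioses)."""
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def emission_probs(code: str, error_prob: float) -> np.ndarray:
    """P(observed code | true genotype) for states (RR, RW, WW)."""
    e = error_prob
    table = {
        "RR": (1 - e, e / 2, e / 2),
        "RW": (e / 2, 1 - e, e / 2),
        "WW": (e / 2, e / 2, 1 - e),
        "R-": (1 - e / 2, 1 - e / 2, e),   # not WW
        "W-": (e, 1 - e / 2, 1 - e / 2),   # not RR
        "NA": (1.0, 1.0, 1.0),
    }
    return np.array(table[code])


@dataclass
class ChromGrid:
    """Evaluation grid for one chromosome."""

    chrom: str
    positions: np.ndarray           # sorted cM grid (markers + pseudomarkers)
    is_marker: np.ndarray           # bool per position
    marker_positions: np.ndarray    # cM of the true markers
    probs: np.ndarray               # (n_individuals, n_positions, 3)


@dataclass
class GenotypeProbGrid:
    """Conditional genotype probabilities on a cM grid, per chromosome."""

    individuals: list[str]
    chroms: dict[str, ChromGrid] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chroms)

    def design_scores(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Additive and dominance regressor matrices, (n_individuals, n_positions)."""
        p = self.chroms[chrom].probs
        return p[:, :, 2] - p[:, :, 0], p[:, :, 1]


def _chromosome_grid(marker_pos: np.ndarray, step_cm: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = marker_pos[0], marker_pos[-1]
    if step_cm and step_cm > 0 and hi > lo:
        pseudo = np.arange(lo, hi, step_cm)
    else:
        pseudo = np.array([])
    pos = np.union1d(np.round(marker_pos, 9), np.round(pseudo, 9))
    is_marker = np.isin(pos, np.round(marker_pos, 9))
    return pos, is_marker


def genotype_probs(genotypes: GenotypeMatrix, gmap: GeneticMap, step_cm: float = 1.0,
                   error_prob: float = 1e-4, map_function: str = "haldane") -> GenotypeProbGrid:
    """Forward-backward conditional genotype probabilities for every
    individual at every grid position (markers plus pseudomarkers)."""
    rfun = MAP_FUNCTIONS[map_function]
    genotypes.check_against_map(gmap)
    n = len(genotypes)
    grid = GenotypeProbGrid(individuals=genotypes.individuals)
    code_arr = genotypes.codes.to_numpy(dtype=object)
    marker_index = {m: j for j, m in enumerate(gmap.markers)}

    # precompute emission vectors per code
    emis_lut = {c: emission_probs(c, error_prob) for c in ("RR", "RW", "WW", "R-", "W-", "NA")}

    for chrom in gmap.chromosomes:
        sub = gmap.table[gmap.table["chrom"].astype(str) == chrom]
        mpos = sub["pos_cm"].to_numpy(float)
        if mpos.size == 0:  # pragma: no cover - map invariant forbids this
            continue
        pos, is_marker = _chromosome_grid(mpos, step_cm)
        n_pos = pos.size

        # emission matrix E: (n, n_pos, 3); uninformative at pseudomarkers
        E = np.ones((n, n_pos, 3))
        marker_cols = [marker_index[m] for m in sub["marker"]]
        marker_grid_idx = np.searchsorted(pos, np.round(mpos, 9))
        for k, (gidx, col) in enumerate(zip(marker_grid_idx, marker_cols)):
            for i in range(n):
                E[i, gidx] *= emis_lut[code_arr[i, col]]

        T = [f2_transition(float(rfun(pos[k + 1] - pos[k]))) for k in range(n_pos - 1)]

        # scaled forward-backward, vectorized over individuals
        alpha = np.empty((n, n_pos, 3))
        a = F2_PRIOR[None, :] * E[:, 0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for k in range(1, n_pos):
            a = (a @ T[k - 1]) * E[:, k]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, k] = a
        beta = np.empty((n, n_pos, 3))
        b = np.ones((n, 3))
        beta[:, -1] = b
        for k in range(n_pos - 2, -1, -1):
            b = (b * E[:, k + 1]) @ T[k].T
            b /= b.sum(axis=1, keepdims=True)
            beta[:, k] = b
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        grid.chroms[str(chrom)] = ChromGrid(
            chrom=str(chrom), positions=pos, is_marker=is_marker,
            marker_positions=mpos, probs=post,
        )
    return grid


def hk_design(prob_triple: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Haley-Knott regressors from genotype probabilities.

    additive = P(WW) - P(RR) (so a positive coefficient means the White
    Leghorn allele increases the phenotype); dominance = P(RW).
    """
    p = np.asarray(prob_triple, float)
    return p[..., 2] - p[..., 0], p[..., 1]


def brute_force_probs(codes: list[str], marker_pos: np.ndarray, query_pos: np.ndarray,
                      error_prob: float = 1e-4, map_function: str = "haldane") -> np.ndarray:
    """Exhaustive-path reference for the HMM on small chromosomes.

    Enumerates all 3^(n_markers+1) joint genotype paths over the markers
    plus one query position, and marginalizes.  Exponential: use only for
    chromosomes with a handful of markers (test oracle).
    """
    from itertools import product

    rfun = MAP_FUNCTIONS[map_function]
    out = np.zeros((query_pos.size, 3))
    for qi, q in enumerate(query_pos):
        pts = sorted(set(np.round(marker_pos, 9)) | {np.round(q, 9)})
        which_marker = {p: k for k, p in enumerate(np.round(marker_pos, 9))}
        Ts = [f2_transition(float(rfun(pts[j + 1] - pts[j]))) for j in range(len(pts) - 1)]
        probs = np.zeros(3)
        for path in product(range(3), repeat=len(pts)):
            w = F2_PRIOR[path[0]]
            for j in range(len(pts) - 1):
                w *= Ts[j][path[j], path[j + 1]]
            for j, p in enumerate(pts):
                if p in which_marker:
                    w *= emission_probs(codes[which_marker[p]], error_prob)[path[j]]
            probs[path[pts.index(np.round(q, 9))]] += w
        out[qi] = probs / probs.sum()
    return out
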