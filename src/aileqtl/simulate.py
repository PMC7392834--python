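"""Forward simulation of an advanced intercross with planted ground truth.

Founders are two fixed lines (R and W).  An F1 generation is bred from a
small founder set, then the population is randomly mated for the requested
number of generations (intermediate census ~100) before the final cohort is
sampled.  Meiosis follows the Haldane model (no crossover interference):
along each chromosome the transmitted parental haplotype switches between
the two homologs with probability r(d) per marker interval.  Expression is
generated with planted cis effects, one trans master-regulator hotspot, sex
and batch effects plus Gaussian noise; organismal traits are wired to
expression through causal / reactive / confounded / collider structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CovariateTable,
    CrossData,
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    ProbesetAnnotation,
)
from .linkage import haldane_r

CODE_BY_W_COUNT = {0: "RR", 1: "RW", 2: "WW"}
BP_PER_CM = 300_000  # synthetic bp scale used for annotation spans


@dataclass
class SimConfig:
    """Study-condition defaults: 59 F8 birds (26 F / 33 M) on a
    multi-chromosome map averaging ~16 cM between markers."""

    n_chromosomes: int = 10
    chromosome_lengths_cm: Sequence[float] | None = None   # default 160 cM each
    marker_spacing_cm: float = 16.0
    n_generations: int = 8
    n_individuals: int = 59
    n_females: int = 26
    n_f1: int = 41
    census: int = 100
    n_batches: int = 4
    n_probesets: int = 200
    # planted architecture
    n_cis: int = 20
    cis_pct_var: float = 25.0
    cis_dominance_ratio: float = 0.0
    hotspot_targets: int = 30
    hotspot_pct_var: float = 25.0
    sex_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3
    noise_sd: float = 1.0
    # trait wiring: name -> (structure, probeset index or None, beta)
    trait_beta: float = 0.6
    trait_noise_sd: float = 1.0
    partial_marker_fraction: float = 0.1
    genotyping_missing_rate: float = 0.0
    seed: int = 0

    def lengths(self) -> list[float]:
        if self.chromosome_lengths_cm is not None:
            return [float(x) for x in self.chromosome_lengths_cm]
        return [160.0] * self.n_chromosomes


@dataclass
class GroundTruth:
    """Planted architecture: what the pipeline should recover."""

    cis: list[dict] = field(default_factory=list)        # probeset, chrom, pos_cm, additive, dominance
    hotspot: dict | None = None                          # chrom, pos_cm, targets, effects
    traits: dict = field(default_factory=dict)           # trait -> wiring description
    marker_info: dict = field(default_factory=dict)      # marker -> "full" | "R-dom" | "W-dom"


# ---------------------------------------------------------------------------
# genotypes

def _make_map(config: SimConfig) -> GeneticMap:
    rows = []
    for c, length in enumerate(config.lengths(), start=1):
        pos = np.arange(0.0, length + 1e-9, config.marker_spacing_cm)
        if pos.size < 2:
            # a zero-length chromosome keeps a single marker (no recombination)
            pos = np.array([0.0]) if length <= 0 else np.array([0.0, length])
        for k, p in enumerate(pos, start=1):
            rows.append({"marker": f"c{c}m{k}", "chrom": str(c), "pos_cm": float(p)})
    return GeneticMap(pd.DataFrame(rows))


def _gamete(hap1: np.ndarray, hap2: np.ndarray, switch_p: list[np.ndarray],
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant haplotype per chromosome (lists of marker arrays)."""
    out = []
    for h1, h2, sp in zip(hap1, hap2, switch_p):
        n = h1.size
        cur = rng.integers(0, 2)
        choice = np.empty(n, dtype=np.int8)
        choice[0] = cur
        if n > 1:
            flips = rng.random(n - 1) < sp
            choice[1:] = (cur + np.cumsum(flips)) % 2
        out.append(np.where(choice == 0, h1, h2))
    return out


def simulate_ail(config: SimConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[GenotypeMatrix, GeneticMap, GroundTruth]:
    """Breed the intercross forward and emit F_k marker genotypes.

    Haplotypes carry allele 0 = R (wild founder), 1 = W (domestic founder).
    A fraction of markers is made partially informative: at an 'R-dom'
    marker the W homozygote is distinguishable but RR/RW collapse to 'R-'
    (and symmetrically for 'W-dom').
    """
    rng = rng or np.random.default_rng(config.seed)
    gmap = _make_map(config)
    chroms = gmap.chromosomes
    marker_pos = [gmap.positions(c) for c in chroms]
    switch_p = [haldane_r(np.diff(p)) if p.size > 1 else np.array([]) for p in marker_pos]
    switch_p = [np.atleast_1d(sp) for sp in switch_p]

    def founder(allele: int) -> list[np.ndarray]:
        return [np.full(p.size, allele, dtype=np.int8) for p in marker_pos]

    # F1: R x W, heterozygous everywhere
    f1 = [(founder(0), founder(1)) for _ in range(config.n_f1)]

    def breed(parents: list, n_off: int) -> list:
        if len(parents) < 2:
            raise RuntimeError("population collapse: fewer than 2 parents")
        offspring = []
        for _ in range(n_off):
            i, j = rng.choice(len(parents), size=2, replace=False)
            p1, p2 = parents[i], parents[j]
            offspring.append((
                _gamete(p1[0], p1[1], switch_p, rng),
                _gamete(p2[0], p2[1], switch_p, rng),
            ))
        return offspring
    pop = f1
    for gen in range(2, config.n_generations + 1):
        n_off = config.n_individuals if gen == config.n_generations else config.census
        pop = breed(pop, n_off)

    n_markers = sum(p.size for p in marker_pos)
    w_count = np.empty((config.n_individuals, n_markers), dtype=np.int8)
    for i, (h1, h2) in enumerate(pop):
        w_count[i] = np.concatenate(h1) + np.concatenate(h2)

    codes = np.empty(w_count.shape, dtype=object)
    for g, code in CODE_BY_W_COUNT.items():
        codes[w_count == g] = code

    truth = GroundTruth()
    markers = gmap.markers
    n_partial = int(round(config.partial_marker_fraction * n_markers))
    partial_idx = rng.choice(n_markers, size=n_partial, replace=False)
    for j in range(n_markers):
        truth.marker_info[markers[j]] = "full"
    for j in partial_idx:
        kind = "R-dom" if rng.random() < 0.5 else "W-dom"
        truth.marker_info[markers[j]] = kind
        if kind == "R-dom":       # RR and RW indistinguishable
            codes[np.isin(w_count[:, j], (0, 1)), j] = "R-"
        else:                     # WW and RW indistinguishable
            codes[np.isin(w_count[:, j], (1, 2)), j] = "W-"
    if config.genotyping_missing_rate > 0:
        miss = rng.random(codes.shape) < config.genotyping_missing_rate
        codes[miss] = "NA"

    ids = [f"F{config.n_generations}_{i + 1:03d}" for i in range(config.n_individuals)]
    geno = GenotypeMatrix(pd.DataFrame(codes, index=pd.Index(ids, name="id"), columns=markers))
    geno._w_count = w_count  # true dosage kept for the expression generator
    return geno, gmap, truth


# ---------------------------------------------------------------------------
# expression

def _effect_for_pct_var(pct: float, noise_sd: float) -> float:
    """Additive effect a with var(a * score) ~= a^2/2 explaining ``pct``% of
    the probeset variance at intercross allele frequencies (score in
    {-1, 0, 1} with probs 1/4, 1/2, 1/4)."""
    f = pct / 100.0
    return float(np.sqrt(2.0 * noise_sd**2 * f / (1.0 - f)))


def simulate_expression(genotypes: GenotypeMatrix, gmap: GeneticMap, config: SimConfig,
                        truth: GroundTruth, covariates: CovariateTable,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionMatrix, ProbesetAnnotation]:
    """Expression with planted cis eQTL, one trans hotspot, sex/batch effects."""
    rng = rng or np.random.default_rng(config.seed + 1)
    w_count = getattr(genotypes, "_w_count", None)
    if w_count is None:
        w_count = np.select(
            [genotypes.codes.to_numpy(object) == c for c in ("RR", "RW", "WW")],
            [0, 1, 2], default=1).astype(np.int8)
    add = w_count.astype(float) - 1.0          # -1 = RR, +1 = WW
    dom = (w_count == 1).astype(float)
    n, n_markers = add.shape
    m = config.n_probesets
    markers = gmap.markers
    chrom_of = dict(zip(gmap.table["marker"], gmap.table["chrom"].astype(str)))
    pos_of = dict(zip(gmap.table["marker"], gmap.table["pos_cm"]))

    sexv = covariates.sex_indicator()
    batch_lab = covariates.table["batch"].astype(str)
    batches = sorted(batch_lab.unique())
    batch_mat = np.column_stack([(batch_lab == b).to_numpy(float) for b in batches])

    expr = rng.normal(0.0, config.noise_sd, size=(m, n))
    expr += rng.normal(0.0, config.sex_effect_sd, size=(m, 1)) * sexv[None, :]
    expr += (rng.normal(0.0, config.batch_effect_sd, size=(m, len(batches))) @ batch_mat.T)

    a_cis = _effect_for_pct_var(config.cis_pct_var, config.noise_sd)
    probesets = [f"ps{k + 1:04d}" for k in range(m)]
    # cis probesets sit at distinct markers
    cis_marker_idx = rng.choice(n_markers, size=min(config.n_cis, n_markers, m),
                                replace=False)
    for k, mj in enumerate(cis_marker_idx):
        sign = rng.choice([-1.0, 1.0])
        a = sign * a_cis
        d = config.cis_dominance_ratio * a
        expr[k] += a * add[:, mj] + d * dom[:, mj]
        truth.cis.append({
            "probeset": probesets[k], "marker": markers[mj],
            "chrom": chrom_of[markers[mj]], "pos_cm": float(pos_of[markers[mj]]),
            "additive": a, "dominance": d,
        })

    # one master regulator driving trans eQTL in a block of target probesets
    n_cis_used = len(cis_marker_idx)
    n_targets = min(config.hotspot_targets, m - n_cis_used)
    if n_targets > 0:
        remaining = [j for j in range(n_markers) if j not in set(cis_marker_idx)]
        reg = int(rng.choice(remaining))
        a_hot = _effect_for_pct_var(config.hotspot_pct_var, config.noise_sd)
        t0 = n_cis_used
        targets = probesets[t0:t0 + n_targets]
        effects = []
        for k in range(t0, t0 + n_targets):
            sign = rng.choice([-1.0, 1.0], p=[0.8, 0.2])  # skewed allelic direction
            expr[k] += sign * a_hot * add[:, reg]
            effects.append(sign * a_hot)
        truth.hotspot = {
            "marker": markers[reg], "chrom": chrom_of[markers[reg]],
            "pos_cm": float(pos_of[markers[reg]]), "targets": targets,
            "effects": effects,
        }

    values = pd.DataFrame(expr, index=pd.Index(probesets, name="probeset"),
                          columns=genotypes.codes.index)
    # annotation: cis probesets at their marker, the rest scattered or EST
    ann_rows = []
    for k, pid in enumerate(probesets):
        if k < n_cis_used:
            info = truth.cis[k]
            chrom, cm = info["chrom"], info["pos_cm"]
        elif rng.random() < 0.7:
            mj = int(rng.integers(0, n_markers))
            chrom, cm = chrom_of[markers[mj]], float(pos_of[markers[mj]])
        else:                      # EST: no genomic annotation
            ann_rows.append({"probeset": pid, "gene_symbol": "", "chrom": "",
                             "bp_start": np.nan, "bp_end": np.nan, "pos_cm": np.nan})
            continue
        bp_mid = cm * BP_PER_CM
        ann_rows.append({
            "probeset": pid, "gene_symbol": f"GENE{k + 1:04d}", "chrom": chrom,
            "bp_start": max(bp_mid - 5_000, 0.0), "bp_end": bp_mid + 5_000,
            "pos_cm": cm,
        })
    annotation = ProbesetAnnotation(pd.DataFrame(ann_rows).set_index("probeset"))
    return ExpressionMatrix(values), annotation


# ---------------------------------------------------------------------------
# covariates and traits

def simulate_covariates(config: SimConfig, ids: Sequence[str],
                        rng: np.random.Generator | None = None) -> CovariateTable:
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(ids)
    sex = np.array(["M"] * n, dtype=object)
    females = rng.choice(n, size=min(config.n_females, n), replace=False)
    sex[females] = "F"
    batch = np.array([f"b{(i % config.n_batches) + 1}" for i in rng.permutation(n)])
    return CovariateTable(pd.DataFrame({"sex": sex, "batch": batch},
                                       index=pd.Index(list(ids), name="id")))


def simulate_traits(expression: ExpressionMatrix, genotypes: GenotypeMatrix,
                    gmap: GeneticMap, config: SimConfig, truth: GroundTruth,
                    rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Organismal traits wired to expression with known causal structure.

    causal:      trait = beta * expr(A) + noise          (A cis-driven)
    reactive:    trait genetically driven; expr(A) = beta * trait + noise
    confounded:  trait and expr(A) independently driven by the same marker
    collider:    expr(A) = a * marker + beta * trait + noise, trait ~ noise
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    if not truth.cis:
        raise ValueError("trait wiring references planted cis probesets; none present")
    w_count = getattr(genotypes, "_w_count", None)
    if w_count is None:
        w_count = np.select(
            [genotypes.codes.to_numpy(object) == c for c in ("RR", "RW", "WW")],
            [0, 1, 2], default=1).astype(np.int8)
    add = w_count.astype(float) - 1.0
    n = add.shape[0]
    beta = config.trait_beta
    sd = config.trait_noise_sd
    markers = gmap.markers
    E = expression.values

    def marker_idx(marker: str) -> int:
        return markers.index(marker)

    traits = {}
    used = truth.cis[: 4] if len(truth.cis) >= 4 else truth.cis * 4
    # causal
    a0 = used[0]
    traits["mass_causal"] = beta * E.loc[a0["probeset"]].to_numpy(float) + rng.normal(0, sd, n)
    truth.traits["mass_causal"] = {"structure": "causal", "probeset": a0["probeset"],
                                   "beta": beta, "locus": a0["marker"]}
    # reactive: trait driven by the marker; expression rewritten from trait
    a1 = used[1]
    g = add[:, marker_idx(a1["marker"])]
    tr = a1["additive"] * g + rng.normal(0, sd, n)
    E.loc[a1["probeset"]] = beta * tr + rng.normal(0, config.noise_sd, n)
    traits["mass_reactive"] = tr
    truth.traits["mass_reactive"] = {"structure": "reactive", "probeset": a1["probeset"],
                                     "beta": beta, "locus": a1["marker"]}
    # confounded: same marker drives both, no direct edge
    a2 = used[2]
    g = add[:, marker_idx(a2["marker"])]
    traits["mass_confounded"] = a2["additive"] * g + rng.normal(0, sd, n)
    truth.traits["mass_confounded"] = {"structure": "confounded", "probeset": a2["probeset"],
                                       "beta": 0.0, "locus": a2["marker"]}
    # collider: expression receives both marker and trait
    a3 = used[3]
    tr = rng.normal(0, sd, n)
    E.loc[a3["probeset"]] = E.loc[a3["probeset"]].to_numpy(float) + beta * tr
    traits["mass_collider"] = tr
    truth.traits["mass_collider"] = {"structure": "collider", "probeset": a3["probeset"],
                                     "beta": beta, "locus": a3["marker"]}
    return PhenotypeTable(pd.DataFrame(traits, index=E.columns))


def simulate_cross(config: SimConfig) -> tuple[CrossData, GroundTruth]:
    """Full synthetic dataset: genotypes, covariates, expression, traits."""
    rng = np.random.default_rng(config.seed)
    geno, gmap, truth = simulate_ail(config, rng)
    cov = simulate_covariates(config, geno.individuals, rng)
    expr, ann = simulate_expression(geno, gmap, config, truth, cov, rng)
    phe = simulate_traits(expr, geno, gmap, config, truth, rng)
    cross = CrossData(gmap=gmap, genotypes=geno, covariates=cov,
                      phenotypes=phe, expression=expr, annotation=ann)
    return cross, truth
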