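"""eQTL classification (cis/trans), summary counts and cross-tissue overlap."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneticMap, ProbesetAnnotation
from .scan import DEFAULT_CIS_HALF_WINDOW_CM, QtlPeak, cis_window


@dataclass
class EqtlRecord:
    """One called eQTL with its classification."""

    probeset: str
    gene_symbol: str
    chrom: str
    peak_cm: float
    lod: float
    model: str
    ci_lo_cm: float
    ci_hi_cm: float
    pct_var: float
    additive: float
    dominance: float
    additive_sex: float
    dominance_sex: float
    cis_trans: str                  # "cis" | "trans"
    sex_flag: str                   # "sex" | "nonsex"
    direction: str                  # "RJF" | "WL"
    tier: str                       # "suggestive" | "significant"


def classify_cis_trans(peak: QtlPeak, annotation: ProbesetAnnotation,
                       gmap: GeneticMap,
                       half_window_cm: float = DEFAULT_CIS_HALF_WINDOW_CM) -> str:
    """cis iff the peak sits on the gene's chromosome inside the gene's
    +/-50 cM marker-extended window; unknown gene position => trans."""
    t = annotation.table
    if peak.id not in t.index:
        return "trans"
    chrom = str(t.loc[peak.id, "chrom"])
    cm = t.loc[peak.id, "pos_cm"]
    if not chrom or chrom != peak.chrom or not np.isfinite(cm):
        return "trans"
    lo, hi = cis_window(float(cm), gmap.positions(chrom), half_window_cm)
    return "cis" if lo <= peak.peak_cm <= hi else "trans"


def build_records(peaks: Iterable[QtlPeak], annotation: ProbesetAnnotation,
                  gmap: GeneticMap,
                  half_window_cm: float = DEFAULT_CIS_HALF_WINDOW_CM) -> list[EqtlRecord]:
    records = []
    t = annotation.table
    for pk in peaks:
        gene = str(t.loc[pk.id, "gene_symbol"]) if pk.id in t.index else ""
        records.append(EqtlRecord(
            probeset=pk.id, gene_symbol=gene, chrom=pk.chrom, peak_cm=pk.peak_cm,
            lod=pk.lod, model=pk.model, ci_lo_cm=pk.ci_lo_cm, ci_hi_cm=pk.ci_hi_cm,
            pct_var=pk.pct_var, additive=pk.additive, dominance=pk.dominance,
            additive_sex=pk.additive_sex, dominance_sex=pk.dominance_sex,
            cis_trans=classify_cis_trans(pk, annotation, gmap, half_window_cm),
            sex_flag="sex" if pk.model == "sex-interactive" else "nonsex",
            direction=pk.direction, tier=pk.tier,
        ))
    return records


def records_to_frame(records: Sequence[EqtlRecord]) -> pd.DataFrame:
    from .io import EQTL_COLUMNS, _records_frame
    return _records_frame(records, EQTL_COLUMNS)


def summarize_counts(records: Sequence[EqtlRecord]) -> dict:
    """Tissue-summary counts: total, cis|trans, RJF|WL, sex|nonsex,
    distinct probesets and distinct annotated genes."""
    recs = list(records)
    return {
        "n_eqtl": len(recs),
        "n_cis": sum(r.cis_trans == "cis" for r in recs),
        "n_trans": sum(r.cis_trans == "trans" for r in recs),
        "n_rjf": sum(r.direction == "RJF" for r in recs),
        "n_wl": sum(r.direction == "WL" for r in recs),
        "n_sex": sum(r.sex_flag == "sex" for r in recs),
        "n_nonsex": sum(r.sex_flag == "nonsex" for r in recs),
        "n_probesets": len({r.probeset for r in recs}),
        "n_genes": len({r.gene_symbol for r in recs if r.gene_symbol}),
    }


@dataclass
class TissueEqtlSet:
    """Probesets (or genes) possessing at least one eQTL in one tissue,
    restricted to the probeset universe shared between the arrays."""

    tissue: str
    members: set = field(default_factory=set)


def compare_tissue_sets(sets: Mapping[str, set], shared_universe: set) -> dict:
    """Venn-style overlap counts for two or three tissue eQTL sets.

    Every set is intersected with the shared universe first.  For each pair
    the inclusive intersection size and the exclusive region (pair minus
    the triple intersection, matching Venn-diagram semantics) are reported;
    with three sets the triple count and exclusive singles are included.
    """
    if not shared_universe:
        raise ValueError("shared probeset universe is empty")
    names = list(sets)
    clipped = {k: set(v) & set(shared_universe) for k, v in sets.items()}
    out: dict = {"universe": len(set(shared_universe)),
                 "union": len(set().union(*clipped.values())) if clipped else 0}
    triple = set.intersection(*clipped.values()) if len(names) >= 3 else set()
    if len(names) >= 3:
        out["triple"] = len(triple)
    for i in range(len(names)):
        only = clipped[names[i]].copy()
        for j in range(len(names)):
            if j != i:
                only -= clipped[names[j]]
        out[f"{names[i]}_only"] = len(only)
        for j in range(i + 1, len(names)):
            inter = clipped[names[i]] & clipped[names[j]]
            out[f"{names[i]}&{names[j]}"] = len(inter)
            out[f"{names[i]}&{names[j]}_exclusive"] = len(inter - triple)
    return out


def to_gene_sets(records: Sequence[EqtlRecord]) -> set:
    """Collapse probesets to gene symbols where annotated (probeset id kept
    for ESTs) -- the unit used for cross-tissue 'gene' overlap counts."""
    return {r.gene_symbol if r.gene_symbol else r.probeset for r in records}
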