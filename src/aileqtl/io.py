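"""Readers and writers for the cross file dialect.

Genotype file (CSV, transposed qtl-cross layout):
    row 1: ``id`` then marker names
    row 2: ``chrom`` then chromosome label per marker
    row 3: ``cM`` then map position per marker
    rows 4+: individual id then genotype codes (RR/RW/WW/R-/W-/NA)

Phenotype/covariate file (CSV): one row per individual with columns
``id, sex, batch`` followed by named numeric traits.

Expression file (TSV): probesets as rows (first column ``probeset``),
individuals as columns.

Annotation file (TSV): ``probeset, gene_symbol, chrom, bp_start, bp_end``
with an optional ``pos_cm`` column.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AlignmentError,
    CovariateTable,
    CrossData,
    ExpressionMatrix,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    ProbesetAnnotation,
    align_individuals,
)

EQTL_COLUMNS = [
    "probeset", "gene_symbol", "chrom", "peak_cm", "lod", "model",
    "ci_lo_cm", "ci_hi_cm", "pct_var", "additive", "dominance",
    "additive_sex", "dominance_sex", "cis_trans", "sex_flag", "direction", "tier",
]

HOTSPOT_COLUMNS = [
    "chrom", "interval_lo_cm", "interval_hi_cm", "peak_overlap", "threshold",
    "n_members", "n_rjf", "n_wl", "members",
]

LEO_COLUMNS = [
    "trait", "probeset", "anchors", "edge_call", "leo_nb", "leo_nb_oca",
    "leo_nb_cpa", "best_model", "p_causal", "p_reactive", "p_confounded", "p_collider",
]


def read_genotypes(path: str | Path) -> tuple[GeneticMap, GenotypeMatrix]:
    raw = pd.read_csv(path, header=None, dtype=str)
    if len(raw) < 4:
        raise FormatError(f"{path}: genotype file needs 3 header rows plus individuals")
    markers = raw.iloc[0, 1:].tolist()
    chroms = raw.iloc[1, 1:].tolist()
    try:
        pos = raw.iloc[2, 1:].astype(float).tolist()
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric cM row: {e}") from e
    # positions must already increase within each chromosome as written
    by_chrom: dict[str, float] = {}
    for mk, ch, p in zip(markers, chroms, pos):
        if ch in by_chrom and p <= by_chrom[ch]:
            raise FormatError(
                f"{path}: non-increasing cM at marker {mk} on chromosome {ch}")
        by_chrom[ch] = p
    gmap = GeneticMap(pd.DataFrame({"marker": markers, "chrom": chroms, "pos_cm": pos}))
    body = raw.iloc[3:]
    ids = body.iloc[:, 0].astype(str).tolist()
    codes = body.iloc[:, 1:].fillna("NA")
    codes.index = pd.Index(ids, name="id")
    codes.columns = markers
    # readers keep the file's marker order; the map may have re-sorted
    codes = codes[gmap.markers]
    return gmap, GenotypeMatrix(codes)


def read_phenotypes(path: str | Path) -> tuple[CovariateTable, PhenotypeTable]:
    t = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "sex", "batch"):
        if col not in t.columns:
            raise FormatError(f"{path}: phenotype file missing column {col!r}")
    t = t.set_index("id")
    t.index = t.index.astype(str)
    cov = CovariateTable(t[["sex", "batch"]].astype(str))
    traits = t.drop(columns=["sex", "batch"]).apply(pd.to_numeric, errors="coerce")
    return cov, PhenotypeTable(traits)


def read_expression(path: str | Path) -> ExpressionMatrix:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    t.columns = t.columns.astype(str)
    return ExpressionMatrix(t.astype(float))


def read_annotation(path: str | Path) -> ProbesetAnnotation:
    t = pd.read_csv(path, sep="\t", dtype={"probeset": str, "gene_symbol": str, "chrom": str})
    if "probeset" not in t.columns:
        raise FormatError(f"{path}: annotation file missing 'probeset' column")
    t = t.set_index("probeset")
    t["gene_symbol"] = t.get("gene_symbol", "").fillna("")
    t["chrom"] = t.get("chrom", "").fillna("")
    return ProbesetAnnotation(t)


def read_cross(genotype_path: str | Path, phenotype_path: str | Path,
               expression_path: str | Path,
               annotation_path: str | Path | None = None) -> CrossData:
    """Load and align the cross tables into a validated :class:`CrossData`."""
    gmap, geno = read_genotypes(genotype_path)
    cov, phe = read_phenotypes(phenotype_path)
    expr = read_expression(expression_path)
    ids = geno.individuals
    cov_t, phe_t, expr_t = align_individuals(
        [cov.table, phe.table, expr.values.T], ids,
        ["phenotype/covariate file", "phenotype file", "expression file"],
    )
    annotation = read_annotation(annotation_path) if annotation_path else None
    return CrossData(
        gmap=gmap,
        genotypes=geno,
        covariates=CovariateTable(cov_t),
        phenotypes=PhenotypeTable(phe_t),
        expression=ExpressionMatrix(expr_t.T),
        annotation=annotation,
    )


def write_cross(cross: CrossData, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the four dialect files; returns the path of each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / f"{prefix}genotypes.csv",
        "phenotypes": outdir / f"{prefix}phenotypes.csv",
        "expression": outdir / f"{prefix}expression.tsv",
        "annotation": outdir / f"{prefix}annotation.tsv",
    }
    gmap = cross.gmap.table
    header = pd.DataFrame(
        [["id"] + gmap["marker"].tolist(),
         ["chrom"] + gmap["chrom"].astype(str).tolist(),
         ["cM"] + [repr(float(p)) for p in gmap["pos_cm"]]]
    )
    body = cross.genotypes.codes.reset_index()
    body.columns = range(body.shape[1])
    pd.concat([header, body]).to_csv(paths["genotypes"], header=False, index=False)

    phe = pd.concat([cross.covariates.table, cross.phenotypes.table], axis=1)
    phe.index.name = "id"
    phe.to_csv(paths["phenotypes"])

    cross.expression.values.rename_axis("probeset").to_csv(paths["expression"], sep="\t")
    cross.annotation.table.rename_axis("probeset").to_csv(paths["annotation"], sep="\t")
    return paths


def _records_frame(records: Sequence, columns: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r):
            d = dataclasses.asdict(r)
        elif isinstance(r, dict):
            d = dict(r)
        else:
            d = vars(r)
        rows.append({c: d.get(c, np.nan) for c in columns})
    return pd.DataFrame(rows, columns=columns)


def write_eqtl_table(records: Sequence, path: str | Path) -> None:
    """Called-eQTL TSV: location, CI, LOD, effects, cis/trans, direction, tier."""
    _records_frame(records, EQTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probeset": str, "chrom": str})


def write_hotspot_table(records: Sequence, path: str | Path) -> None:
    frame = _records_frame(records, HOTSPOT_COLUMNS)
    if len(frame):
        frame["members"] = [
            ",".join(map(str, r.member_eqtl)) if hasattr(r, "member_eqtl") else r.get("members", "")
            for r in records
        ]
    frame.to_csv(path, sep="\t", index=False)


def read_hotspot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_leo_table(records: Sequence, path: str | Path) -> None:
    frame = _records_frame(records, LEO_COLUMNS)
    if len(frame):
        frame["anchors"] = [",".join(map(str, getattr(r, "anchors", []) or [])) for r in records]
    frame.to_csv(path, sep="\t", index=False)


def read_leo_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probeset": str})


def read_trait_qtl_table(path: str | Path) -> pd.DataFrame:
    """Trait-QTL TSV: trait, chrom, ci_lo_cm, ci_hi_cm, peak_cm."""
    t = pd.read_csv(path, sep="\t", dtype={"trait": str, "chrom": str})
    needed = {"trait", "chrom", "ci_lo_cm", "ci_hi_cm", "peak_cm"}
    if not needed.issubset(t.columns):
        raise FormatError(f"{path}: trait QTL file needs columns {sorted(needed)}")
    return t
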