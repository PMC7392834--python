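"""Core containers for one intercross population.

All tabular state is pandas-backed; the classes here add the invariants a
linkage analysis relies on (sorted maps, closed genotype alphabets, aligned
individual ids) and fail loudly when a file violates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Genotype code alphabet.  R = Red junglefowl origin allele, W = White
#: Leghorn origin.  ``R-`` / ``W-`` are partially informative calls: the
#: carried allele is known, the homolog is not (``R-`` = not WW,
#: ``W-`` = not RR).  ``NA`` = missing.
GENOTYPE_CODES = ("RR", "RW", "WW", "R-", "W-", "NA")


class FormatError(ValueError):
    """A file or table violates the documented dialect."""


class AlignmentError(ValueError):
    """Individual or probeset ids disagree between component tables."""


@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome and sex-averaged cM."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cm; sorted

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos_cm"}
        if not required.issubset(t.columns):
            raise FormatError(f"genetic map needs columns {sorted(required)}")
        t = t.reset_index(drop=True)
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise FormatError(f"duplicated marker names: {dups}")
        if (t["pos_cm"] < 0).any():
            raise FormatError("negative cM positions in map")
        # preserve chromosome order of first appearance, sort within
        order = {c: i for i, c in enumerate(t["chrom"].astype(str).unique())}
        t = t.assign(_c=t["chrom"].astype(str).map(order))
        t = t.sort_values(["_c", "pos_cm"], kind="stable").drop(columns="_c").reset_index(drop=True)
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"non-increasing cM positions on chromosome {chrom}")
        self.table = t

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"].astype(str)))

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"].astype(str) == str(chrom)]
        return sub["pos_cm"].to_numpy(float)

    def chrom_span(self, chrom: str) -> tuple[float, float]:
        pos = self.positions(chrom)
        if pos.size == 0:
            raise KeyError(f"no markers on chromosome {chrom}")
        return float(pos[0]), float(pos[-1])

    def total_length(self) -> float:
        """Sum over chromosomes of (max - min marker position)."""
        return float(sum(p.max() - p.min() for _, p in self._by_chrom()))

    def _by_chrom(self) -> Iterable[tuple[str, np.ndarray]]:
        for chrom in self.chromosomes:
            yield chrom, self.positions(chrom)

    def summary(self) -> dict:
        gaps = np.concatenate([np.diff(p) for _, p in self._by_chrom() if p.size > 1])
        return {
            "n_markers": len(self.table),
            "n_chromosomes": len(self.chromosomes),
            "total_length_cm": self.total_length(),
            "mean_spacing_cm": float(gaps.mean()) if gaps.size else float("nan"),
        }

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals x markers table of genotype codes (strings)."""

    codes: pd.DataFrame  # index: individual ids, columns: marker names

    def __post_init__(self) -> None:
        vals = self.codes.to_numpy(dtype=object)
        bad = ~np.isin(vals, GENOTYPE_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"unknown genotype code {vals[i, j]!r} for individual "
                f"{self.codes.index[i]!r} at marker {self.codes.columns[j]!r}"
            )

    @property
    def individuals(self) -> list[str]:
        return [str(i) for i in self.codes.index]

    def check_against_map(self, gmap: GeneticMap) -> None:
        if list(self.codes.columns) != gmap.markers:
            raise AlignmentError("genotype columns do not match map markers")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class ExpressionMatrix:
    """Probesets x individuals log-intensity matrix; NaN = missing."""

    values: pd.DataFrame  # index: probesets, columns: individuals

    @property
    def probesets(self) -> list[str]:
        return [str(p) for p in self.values.index]

    @property
    def individuals(self) -> list[str]:
        return [str(i) for i in self.values.columns]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CovariateTable:
    """Per-individual fixed covariates: sex in {F, M} and batch label."""

    table: pd.DataFrame  # index: individuals; columns: sex, batch

    def __post_init__(self) -> None:
        for col in ("sex", "batch"):
            if col not in self.table.columns:
                raise FormatError(f"covariate table missing column {col!r}")
        if self.table[["sex", "batch"]].isna().any().any():
            raise FormatError("missing sex/batch covariate values")
        bad = set(self.table["sex"].astype(str)) - {"F", "M"}
        if bad:
            raise FormatError(f"sex codes must be F/M, found {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def design(self) -> np.ndarray:
        """Intercept + sex (M=1) + batch dummies (first level dropped)."""
        sex = (self.table["sex"].astype(str) == "M").to_numpy(float)
        batches = pd.get_dummies(self.table["batch"].astype(str), drop_first=True)
        cols = [np.ones(len(self.table)), sex] + [batches[c].to_numpy(float) for c in batches.columns]
        return np.column_stack(cols)

    def sex_indicator(self) -> np.ndarray:
        return (self.table["sex"].astype(str) == "M").to_numpy(float)


@dataclass
class PhenotypeTable:
    """Per-individual organismal traits (masses, body weights)."""

    table: pd.DataFrame  # index: individuals; numeric columns

    @property
    def individuals(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def traits(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class ProbesetAnnotation:
    """Probeset -> gene symbol and genomic span; cM position once interpolated.

    ESTs carry an empty gene_symbol; unplaced probesets have empty
    chromosome and NaN coordinates.
    """

    table: pd.DataFrame  # index: probeset; gene_symbol, chrom, bp_start, bp_end, pos_cm

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col, default in (
            ("gene_symbol", ""), ("chrom", ""), ("bp_start", np.nan),
            ("bp_end", np.nan), ("pos_cm", np.nan),
        ):
            if col not in t.columns:
                t[col] = default
        both = t["bp_start"].notna() & t["bp_end"].notna()
        if (t.loc[both, "bp_start"] > t.loc[both, "bp_end"]).any():
            raise FormatError("bp_start > bp_end in annotation")
        self.table = t

    @property
    def probesets(self) -> list[str]:
        return [str(p) for p in self.table.index]

    def midpoint_bp(self) -> pd.Series:
        return (self.table["bp_start"] + self.table["bp_end"]) / 2.0


@dataclass
class CrossData:
    """One intercross population: map, genotypes, covariates, phenotypes,
    expression and probeset annotation with mutually consistent ids."""

    gmap: GeneticMap
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    phenotypes: PhenotypeTable
    expression: ExpressionMatrix
    annotation: ProbesetAnnotation = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = ProbesetAnnotation(
                pd.DataFrame(index=pd.Index(self.expression.probesets, name="probeset"))
            )
        self.validate()

    def validate(self) -> None:
        self.genotypes.check_against_map(self.gmap)
        ids = self.genotypes.individuals
        for name, other in (
            ("covariates", self.covariates.individuals),
            ("phenotypes", self.phenotypes.individuals),
            ("expression", self.expression.individuals),
        ):
            if list(other) != ids:
                missing = sorted(set(ids) - set(other))
                extra = sorted(set(other) - set(ids))
                raise AlignmentError(
                    f"{name} individuals misaligned with genotypes "
                    f"(missing {missing}, extra {extra})"
                )

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)


def mean_marker_spacing(total_length_cm: float, n_markers: int) -> float:
    """Average cM between markers as quoted in map summaries
    (total map length divided by the marker count)."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return total_length_cm / n_markers


def align_individuals(frames: Sequence[pd.DataFrame], reference: Sequence[str],
                      names: Sequence[str]) -> list[pd.DataFrame]:
    """Reindex each frame's rows to ``reference`` ids, raising on mismatch."""
    out = []
    ref = [str(i) for i in reference]
    for frame, name in zip(frames, names):
        idx = [str(i) for i in frame.index]
        if set(idx) != set(ref):
            missing = sorted(set(ref) - set(idx))
            extra = sorted(set(idx) - set(ref))
            raise AlignmentError(f"{name}: individual ids differ (missing {missing}, extra {extra})")
        frame = frame.copy()
        frame.index = idx
        out.append(frame.loc[ref])
    return out
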