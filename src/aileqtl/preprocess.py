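"""Expression preprocessing: chi-square outlier removal and gene cM interpolation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneticMap, ProbesetAnnotation

log = logging.getLogger(__name__)


def chisq_outlier_p(values: np.ndarray) -> tuple[int, float]:
    """Index of the most extreme value and its one-outlier chi-square p.

    The statistic is X^2 = (x - mean)^2 / variance (sample variance, n-1
    denominator) for the value farthest from the mean, with the p-value
    from the upper tail of chi-square with 1 df.
    """
    mean = values.mean()
    var = values.var(ddof=1)
    if var == 0:
        return int(np.argmax(np.abs(values - mean))), 1.0
    idx = int(np.argmax(np.abs(values - mean)))
    x2 = (values[idx] - mean) ** 2 / var
    return idx, float(stats.chi2.sf(x2, df=1))


def remove_outliers(expression: ExpressionMatrix, p_threshold: float = 1e-6,
                    max_removed: int = 2) -> ExpressionMatrix:
    """Iteratively blank extreme values per probeset (at most ``max_removed``).

    Each pass recomputes mean/variance on the remaining values, tests the
    most extreme value and sets it missing while its chi-square (1 df)
    p-value is below ``p_threshold``.  Zero-variance probesets are left
    unchanged with a logged warning.
    """
    vals = expression.values.to_numpy(float).copy()
    for i in range(vals.shape[0]):
        removed = 0
        while removed < max_removed:
            present = np.flatnonzero(np.isfinite(vals[i]))
            if present.size < 3:
                break
            sub = vals[i, present]
            if sub.var(ddof=1) == 0:
                if not np.all(sub == sub[0]):  # pragma: no cover - numeric guard
                    pass
                log.warning("probeset %s has zero variance; no outlier test",
                            expression.values.index[i])
                break
            idx, p = chisq_outlier_p(sub)
            if p < p_threshold:
                vals[i, present[idx]] = np.nan
                removed += 1
            else:
                break
    out = expression.values.copy()
    out.iloc[:, :] = vals
    return ExpressionMatrix(out)


def interpolate_gene_cm(annotation: ProbesetAnnotation, gmap: GeneticMap,
                        marker_bp: pd.DataFrame) -> ProbesetAnnotation:
    """Fill ``pos_cm`` by linear bp->cM interpolation between flanking markers.

    ``marker_bp`` has columns ``marker, bp`` (chromosome comes from the map).
    Gene position is the midpoint of the annotated bp span; genes outside
    the terminal anchored markers are clamped to the terminal marker's cM;
    genes on chromosomes with fewer than two bp-anchored markers (or with no
    chromosome) are left unknown.
    """
    bp = marker_bp.set_index("marker")["bp"] if "marker" in marker_bp.columns else marker_bp["bp"]
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.table[gmap.table["chrom"].astype(str) == chrom]
        known = sub[sub["marker"].isin(bp.index)]
        if len(known) < 2:
            log.warning("chromosome %s has <2 bp-anchored markers; genes left unplaced", chrom)
            continue
        b = bp.loc[known["marker"]].to_numpy(float)
        c = known["pos_cm"].to_numpy(float)
        order = np.argsort(b)
        anchors[str(chrom)] = (b[order], c[order])

    table = annotation.table.copy()
    mid = annotation.midpoint_bp()
    pos_cm = table["pos_cm"].to_numpy(float).copy()
    for i, probeset in enumerate(table.index):
        chrom = str(table["chrom"].iloc[i])
        if not chrom or chrom == "nan" or chrom not in anchors or not np.isfinite(mid.iloc[i]):
            continue
        b, c = anchors[chrom]
        pos_cm[i] = float(np.interp(mid.iloc[i], b, c))  # np.interp clamps at ends
    table["pos_cm"] = pos_cm
    return ProbesetAnnotation(table)
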