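"""Analytic power for interval mapping in an intercross.

The genome-scan test at a marker is a 2-df likelihood-ratio test (additive
plus dominance) whose statistic 2 ln(10) * LOD is approximately noncentral
chi-square with noncentrality

    lambda = n * h2 / (1 - h2)

where h2 is the fraction of phenotypic variance explained by the QTL.
Power at a genome-wide LOD threshold T is P(chi2_2(lambda) > 2 ln(10) T);
solving for h2 at a target power gives the minimum detectable effect size.

The default threshold is 3.44, the suggestive tier at which an eQTL is
called in this pipeline's study design (the lowest LOD that yields a call).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

DEFAULT_LOD_THRESHOLD = 3.44
DEFAULT_DF = 2


def scan_power(pct_var: float, n: int, lod_threshold: float = DEFAULT_LOD_THRESHOLD,
               df: int = DEFAULT_DF) -> float:
    """Power to detect a QTL explaining ``pct_var`` percent of variance."""
    if not 0 < pct_var < 100:
        raise ValueError("pct_var must be in (0, 100)")
    h2 = pct_var / 100.0
    ncp = n * h2 / (1.0 - h2)
    crit = 2.0 * np.log(10.0) * lod_threshold
    return float(stats.ncx2.sf(crit, df, ncp))


def detectable_effect_pct(n: int = 59, power: float = 0.80,
                          lod_threshold: float = DEFAULT_LOD_THRESHOLD,
                          df: int = DEFAULT_DF) -> float:
    """Minimum QTL effect size (% variance explained) detectable at the
    given power -- e.g. ~27% at 80% power for an intercross of 59."""
    f = lambda pct: scan_power(pct, n, lod_threshold, df) - power
    return float(optimize.brentq(f, 1e-3, 99.9))
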