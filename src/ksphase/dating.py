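"""Molecular dating of duplication/divergence events from Ks.

Uses the standard molecular-clock conversion T = Ks / (2μ) with the
Brassicaceae synonymous rate μ = 6.51648e-9 substitutions/site/year as the
default, plus peak location for (unimodal) Ks distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

#: Brassicaceae synonymous substitution rate (substitutions/site/year).
DEFAULT_MU = 6.51648e-09


@dataclass(frozen=True)
class DatingResult:
    ks_used: float
    mu: float
    T_years: float
    T_mya: float

    @property
    def T_mya_rounded(self) -> float:
        """Half-up rounding to 0.1 Mya for report display."""
        return np.floor(self.T_mya * 10 + 0.5) / 10


def date_from_ks(ks: float, mu: float = DEFAULT_MU) -> DatingResult:
    """Age in years of a divergence with synonymous distance ``ks``.

    T = Ks / (2μ): both lineages accumulate substitutions at rate μ, so the
    pairwise distance grows at 2μ per year.
    """
    if ks < 0:
        raise ValueError(f"ks must be non-negative, got {ks}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    years = ks / (2.0 * mu)
    return DatingResult(ks_used=ks, mu=mu, T_years=years, T_mya=years / 1e6)


def ks_peak(ks_values, method: str = "median") -> float:
    """Peak of a Ks sample: sample median or Gaussian-KDE mode.

    ``kde_mode`` evaluates a Silverman-bandwidth Gaussian kernel density on
    a fine grid over [0, 0.75] and returns its argmax; ``median`` is the
    default because reported ages pair with distribution medians.  Only
    finite values are used.
    """
    vals = np.asarray(list(ks_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite Ks values")
    if method == "median":
        return float(np.median(vals))
    if method == "kde_mode":
        if vals.size == 1 or np.allclose(vals, vals[0]):
            return float(vals[0])
        kde = gaussian_kde(vals, bw_method="silverman")
        grid = np.linspace(0.0, 0.75, 1501)
        return float(grid[int(np.argmax(kde(grid)))])
    raise ValueError(f"unknown peak method {method!r}")
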