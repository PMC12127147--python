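"""Narrowest-purity-window sample filter.

Tumor purity scales every bulk methylation change by the same factor, so
comparing samples across the full purity spectrum confounds correlations
between change magnitudes.  Rather than regressing purity out (purity
estimates are noisy and method-dependent), the filter keeps the samples
inside the narrowest purity interval that still covers a target fraction
(default half) of the cohort: a variable-sized window slides over [0, 1] on
a 0.01 grid, the smallest window covering enough samples wins, and ties are
broken toward higher purity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PurityWindow:
    """Closed purity interval [lo, hi] on the step grid."""

    lo: float
    hi: float
    n_inside: int
    coverage: float = 0.5
    step: float = 0.01

    @property
    def width(self) -> float:
        return self.hi - self.lo


_EPS = 1e-9


def narrowest_window(
    purities, coverage: float = 0.5, step: float = 0.01
) -> PurityWindow:
    """Smallest closed window on the step grid holding >= coverage of samples.

    Missing purities are dropped before counting.  Among equal-width windows
    the one with the larger lower bound wins.  Window endpoints lie on the
    grid; the purity values themselves are not rounded.
    """
    vals = np.asarray(pd.Series(purities).dropna(), dtype=float)
    if vals.size == 0:
        raise ValueError("no non-missing purity values")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    need = math.ceil(coverage * vals.size)
    vals.sort()
    n_grid = int(round(1.0 / step))
    # widths ascending, lower bound descending: first hit is the narrowest
    # window, tie-broken toward higher purity
    for w in range(n_grid + 1):
        for lo_i in range(n_grid - w, -1, -1):
            lo = lo_i * step
            hi = (lo_i + w) * step
            count = int(
                np.searchsorted(vals, hi + _EPS, side="left")
                - np.searchsorted(vals, lo - _EPS, side="left")
            )
            if count >= need:
                return PurityWindow(round(lo, 10), round(hi, 10), count, coverage, step)
    raise ValueError("no window on the grid covers the requested fraction")


def select_samples(
    samples: pd.DataFrame,
    window: PurityWindow,
    mode: str = "inside",
    purity_col: str = "purity",
) -> pd.Index:
    """Sample ids passing the purity filter.

    ``inside`` keeps ``lo <= purity <= hi`` (both bounds closed);
    ``above_lo`` keeps ``purity >= lo``, i.e. the window samples plus every
    higher-purity sample.
    """
    purity = samples[purity_col]
    if mode == "inside":
        keep = (purity >= window.lo - _EPS) & (purity <= window.hi + _EPS)
    elif mode == "above_lo":
        keep = purity >= window.lo - _EPS
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return samples.index[keep.fillna(False)]
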