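"""Epi-allele analysis of hypermethylated CGIs: read-level histograms and RIN-hyper.

Each bisulfite read covering a CpG island is summarised by its mean CpG
methylation ``m``.  The per-region distribution of ``m`` separates fully
methylated epi-alleles from the incompletely methylated ones produced by
maintenance loss, and RIN-hyper quantifies that balance:

    RIN-hyper = #reads with 0.5 < m < 0.9  /  #reads with m > 0.9

Both inequalities are strict — reads at exactly 0.5 or 0.9 belong to neither
class — and the ratio is undefined (not an error) when no fully methylated
reads exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ReadMethRecord

INCOMPLETE_LO = 0.5
INCOMPLETE_HI = 0.9  # also the lower (strict) bound of the complete class


@dataclass(frozen=True)
class EpialleleHistogram:
    """Binned read-methylation-level distribution for one region.

    Bins are left-closed right-open over [0, 1] with the last bin closed, so
    m = 0.1 falls in the second bin and m = 1.0 in the last.
    """

    region_id: str
    edges: np.ndarray
    counts: np.ndarray

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RinHyper:
    n_incomplete: int
    n_complete: int

    @property
    def defined(self) -> bool:
        return self.n_complete > 0

    @property
    def value(self) -> float:
        return self.n_incomplete / self.n_complete if self.defined else math.nan


def _m_values(reads: Iterable) -> np.ndarray:
    vals = [r.m if isinstance(r, ReadMethRecord) else float(r) for r in reads]
    return np.asarray(vals, dtype=float)


def region_histogram(
    reads: Sequence[ReadMethRecord],
    region_id: str,
    bin_width: float = 0.1,
) -> EpialleleHistogram:
    """Histogram of read methylation levels for one region (empty input is fine)."""
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    m = _m_values(r for r in reads if r.region_id == region_id)
    counts, _ = np.histogram(m, bins=edges)
    return EpialleleHistogram(region_id, edges, counts)


def rin_hyper(reads: Iterable) -> RinHyper:
    """RIN-hyper over a multiset of reads (ReadMethRecord) or raw m values."""
    m = _m_values(reads)
    n_inc = int(((m > INCOMPLETE_LO) & (m < INCOMPLETE_HI)).sum())
    n_com = int((m > INCOMPLETE_HI).sum())
    return RinHyper(n_inc, n_com)


def sample_rin_hyper(
    reads: Sequence[ReadMethRecord],
    hyper_region_ids: Iterable[str],
    mode: str = "pooled",
) -> RinHyper | float:
    """Sample-level RIN-hyper over a set of hypermethylated regions.

    ``pooled`` feeds all reads from the listed regions to one ratio (the
    default aggregate); ``per_region_median`` returns the median of the
    defined per-region values (NaN when none is defined).
    """
    wanted = set(hyper_region_ids)
    in_regions = [r for r in reads if r.region_id in wanted]
    if mode == "pooled":
        return rin_hyper(in_regions)
    if mode == "per_region_median":
        values = []
        for rid in sorted(wanted):
            rh = rin_hyper(r for r in in_regions if r.region_id == rid)
            if rh.defined:
                values.append(rh.value)
        return float(np.median(values)) if values else math.nan
    raise ValueError(f"unknown mode {mode!r}")
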