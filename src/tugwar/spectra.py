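"""Observed site frequency spectra and cumulative tails.

The site frequency spectrum (SFS) of a sample of ``n`` cells counts, for
each ``k = 1..n-1``, the number ``S(k)`` of mutant sites carried by exactly
``k`` cells.  Only segregating sites are counted: sites fixed in the sample
(truncal mutations, ``k = n``) and extinct sites (``k = 0``) are excluded by
default.  On the frequency axis ``x = k/n`` the cumulative tail

    T(x) = number (or fraction) of mutations with frequency >= x

is the discrete evaluation of the integral of the spectrum over [x, 1].
Normalized tails are inscribed in the unit square, which makes tails from
models with different mutation counts directly comparable; semi-log
coordinates (x, log10 T) resolve the deep tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteFrequencySpectrum",
    "CumulativeTail",
    "observed_sfs",
    "cumulative_tail",
    "vaf_frequencies",
    "tail_export",
]

logger = logging.getLogger(__name__)


@dataclass
class SiteFrequencySpectrum:
    """Counts S(k) of mutations carried by exactly k of n cells."""

    n: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for k, s in self.counts.items():
            if not 1 <= k <= self.n:
                raise ValueError(f"carrier class {k} outside 1..n={self.n}")
            if s < 0:
                raise ValueError("spectrum counts must be >= 0")

    @property
    def segregating_sites(self) -> int:
        return sum(s for k, s in self.counts.items() if k < self.n)

    def frequencies(self) -> np.ndarray:
        """Multiset of per-mutation frequencies k/n (sorted)."""
        out = np.concatenate(
            [np.full(s, k / self.n) for k, s in sorted(self.counts.items())]
            or [np.empty(0)]
        )
        return out

    def as_array(self) -> np.ndarray:
        """Dense vector (S(1), ..., S(n-1))."""
        arr = np.zeros(self.n - 1, dtype=np.int64)
        for k, s in self.counts.items():
            if k < self.n:
                arr[k - 1] = s
        return arr


@dataclass
class CumulativeTail:
    """Tail T(x) of an SFS evaluated on a grid of frequencies."""

    grid: np.ndarray
    T: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.grid.shape != self.T.shape:
            raise ValueError("grid and T must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.T) > 1e-12):
            raise ValueError("tail must be non-increasing")
        if self.normalized and np.any(self.T > 1 + 1e-12):
            raise ValueError("normalized tail must satisfy T <= 1")


def observed_sfs(
    carriers: Mapping[object, int] | Sequence[int],
    n: int,
    include_fixed: bool = False,
) -> SiteFrequencySpectrum:
    """Observed SFS from per-mutation carrier counts.

    Parameters
    ----------
    carriers
        Mapping mutation id -> carrier count, or a bare sequence of counts.
    n
        Sample size (number of cells).
    include_fixed
        Keep mutations carried by all n cells (truncal); default drops them
        along with extinct (count 0) mutations.
    """
    if isinstance(carriers, Mapping):
        values = list(carriers.values())
    else:
        values = list(carriers)
    counts: dict[int, int] = {}
    for c in values:
        c = int(c)
        if c < 0 or c > n:
            raise ValueError(f"carrier count {c} outside [0, n={n}]")
        if c == 0 or (c == n and not include_fixed):
            continue
        counts[c] = counts.get(c, 0) + 1
    return SiteFrequencySpectrum(n=n, counts=counts)


def cumulative_tail(
    freqs: Sequence[float] | np.ndarray,
    grid: Sequence[float] | None = None,
    normalized: bool = True,
) -> CumulativeTail:
    """Cumulative tail T(x) = #{frequencies >= x} of a frequency multiset.

    ``grid`` defaults to the sorted distinct observed frequencies; when
    ``normalized`` the count is divided by the total number of frequencies
    so the tail lives in the unit square.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("frequencies must lie in (0, 1]")
    if f.size == 0 and normalized:
        raise ValueError("cannot normalize the tail of an empty spectrum")
    if grid is None:
        grid = np.unique(f)
        if grid.size == 0:
            grid = np.array([1.0])
    x = np.asarray(grid, dtype=float)
    fs = np.sort(f)
    # count of frequencies >= x  (weak inequality)
    tail = f.size - np.searchsorted(fs, x, side="left")
    T = tail / f.size if normalized else tail.astype(float)
    return CumulativeTail(grid=x, T=T, normalized=normalized)


def vaf_frequencies(table: "VariantTable") -> np.ndarray:  # noqa: F821
    """Per-site variant allele frequencies variant_reads / total_reads.

    Sites with zero total reads are dropped (their number is logged).
    Zero-VAF sites are retained; filtering is a downstream decision.
    """
    df = table.df
    zero = df["total_reads"] == 0
    if zero.any():
        logger.info(
            "dropping %d sites with zero total reads (sample %s)",
            int(zero.sum()),
            table.sample,
        )
    kept = df[~zero]
    if (kept["variant_reads"] > kept["total_reads"]).any():
        raise ValueError("variant_reads exceeds total_reads")
    return (kept["variant_reads"] / kept["total_reads"]).to_numpy(dtype=float)


def tail_export(tail: CumulativeTail, scale: str = "semilog") -> pd.DataFrame:
    """Tail as a plotting-ready table.

    ``semilog`` gives columns (x, T, log10_T); ``loglog`` additionally
    log10_x.  Zero tail values map to -inf in log columns.
    """
    if scale not in ("semilog", "loglog"):
        raise ValueError("scale must be 'semilog' or 'loglog'")
    with np.errstate(divide="ignore"):
        logT = np.log10(tail.T)
        df = pd.DataFrame({"x": tail.grid, "T": tail.T, "log10_T": logT})
        if scale == "loglog":
            df["log10_x"] = np.log10(tail.grid)
    return df
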