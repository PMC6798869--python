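"""Floral diversity: richness, Shannon H, Pielou J, rank abundance, and
individual-based rarefaction with percentile confidence bands.

All logarithms are natural.  Rarefaction draws individuals without
replacement, repeatedly, and summarizes the distinct-species count at
each subsample size by its Monte-Carlo mean and 2.5/97.5 percentiles;
the analytic expectation of that mean is the hypergeometric form
``sum_i 1 - C(N - n_i, m) / C(N, m)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RarefactionCurve:
    """Monte-Carlo rarefaction summary at a grid of subsample sizes."""

    sizes: np.ndarray
    mean_richness: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("sizes", "mean_richness", "lower95", "upper95"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (np.all(self.lower95 <= self.mean_richness + 1e-12)
                and np.all(self.mean_richness <= self.upper95 + 1e-12)):
            raise ValueError("percentile band must bracket the mean")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "mean_richness": self.mean_richness,
            "lower95": self.lower95,
            "upper95": self.upper95,
        })

    def write(self, path: str | Path) -> None:
        """Write the curve as delimited text with a metadata header line."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# n_resamples={self.n_resamples} seed={self.seed}\n")
            self.to_frame().to_csv(fh, index=False)


def _counts_array(counts: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(counts) if not hasattr(counts, "__len__") else counts,
                     dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("abundance counts must be non-negative")
    return arr


def richness(counts: Iterable[float]) -> int:
    """Number of taxa with a strictly positive count."""
    arr = _counts_array(counts)
    return int(np.count_nonzero(arr > 0))


def shannon(counts: Iterable[float]) -> float:
    """Shannon-Wiener diversity H = -sum p_i ln p_i (natural log)."""
    arr = _counts_array(counts)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts: Iterable[float]) -> float:
    """Pielou's evenness J = H / ln S; undefined for fewer than 2 taxa."""
    arr = _counts_array(counts)
    s = richness(arr)
    if s < 2:
        raise ValueError(f"Pielou's J requires >= 2 taxa, found {s}")
    return shannon(arr) / float(np.log(s))


def rank_abundance(
    counts: Mapping[str, float] | pd.Series,
) -> list[tuple[str, float]]:
    """Relative-abundance ranking, descending; ties broken by taxon id."""
    series = pd.Series(counts, dtype=float)
    series = series[series > 0]
    total = series.sum()
    if total <= 0:
        raise ValueError("rank abundance undefined for zero total abundance")
    items = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(k, v / total) for k, v in items]


def default_sizes(total: int, n_points: int = 20) -> np.ndarray:
    """An even grid of subsample sizes from 1 to the full sample."""
    if total < 1:
        raise ValueError("total must be positive")
    return np.unique(np.linspace(1, total, min(n_points, total)).astype(int))


def rarefy_species(
    counts: Iterable[float],
    sizes: Sequence[int] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> RarefactionCurve:
    """Individual-based rarefaction of taxon richness.

    For each size m, m individuals are drawn without replacement from the
    pooled sample, ``n_resamples`` times; the distinct-taxon count is
    summarized by its mean and 2.5/97.5 percentiles.  Invariant to
    permutation of the counts vector.
    """
    arr = _counts_array(counts).astype(int)
    # canonical order: richness depends only on the multiset of counts,
    # so sorting makes the seeded draw invariant to input permutation
    arr = np.sort(arr[arr > 0])[::-1]
    individuals = np.repeat(np.arange(arr.size), arr)
    total = individuals.size
    if total == 0:
        raise ValueError("cannot rarefy an empty sample")
    sizes_arr = (default_sizes(total) if sizes is None
                 else np.asarray(sizes, dtype=int))
    if np.any(sizes_arr < 1) or np.any(sizes_arr > total):
        raise ValueError(
            f"subsample sizes must lie in [1, {total}], got {sizes_arr}"
        )

    rng = np.random.default_rng(seed)
    rich = np.empty((n_resamples, sizes_arr.size), dtype=int)
    for r in range(n_resamples):
        perm = rng.permutation(individuals)
        # first occurrence position of each taxon in this draw order
        _, first = np.unique(perm, return_index=True)
        first.sort()
        rich[r] = np.searchsorted(first, sizes_arr, side="left")
    mean = rich.mean(axis=0)
    # percentile band, widened if needed so it always brackets the mean
    # (discrete richness distributions can put >97.5% of mass at one value)
    lower = np.minimum(np.percentile(rich, 2.5, axis=0), mean)
    upper = np.maximum(np.percentile(rich, 97.5, axis=0), mean)
    return RarefactionCurve(
        sizes=sizes_arr,
        mean_richness=mean,
        lower95=lower,
        upper95=upper,
        n_resamples=n_resamples,
        seed=seed,
    )
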