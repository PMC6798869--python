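"""Insect-herbivory metrics on censused leaves.

Damage frequency is the fraction of identifiable leaves bearing at least
one damage type (DT) of a category (any / specialized / generalized);
a leaf counts once per category no matter how many qualifying DTs it
bears.  DT rarefaction resamples *leaves* — damaged or not — without
replacement, so undamaged field-tally batches dilute the curve exactly
as undamaged leaves dilute the census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .diversity import RarefactionCurve, default_sizes
from .io import CensusTable, DTInfo, LeafRecord, pool_units

CATEGORIES = ("total", "specialized", "generalized")


@dataclass(frozen=True)
class DamageSummary:
    """Per-unit herbivory summary.

    ``spec_gen_ratio`` is None (undefined) when no leaf bears generalized
    damage while at least one bears specialized damage.
    """

    unit_id: str
    n_leaves: int
    freq_total: float
    freq_specialized: float
    freq_generalized: float
    spec_gen_ratio: float | None
    dt_richness_total: int
    dt_richness_specialized: int


def _expand(leaves: Sequence[LeafRecord]) -> list[frozenset[str]]:
    """Tally-expand identifiable leaves into one DT set per leaf."""
    out: list[frozenset[str]] = []
    for rec in leaves:
        if not rec.identified:
            continue
        out.extend([rec.dts] * rec.tally_count)
    return out


def _category_dts(dt_registry: Mapping[str, DTInfo], category: str) -> set[str]:
    if category == "total":
        return set(dt_registry)
    return {d for d, info in dt_registry.items()
            if info.specialization == category}


def damage_frequency(
    leaves: Sequence[LeafRecord],
    dt_registry: Mapping[str, DTInfo],
    category: str = "total",
) -> float:
    """Proportion of identifiable leaves with >= 1 DT of ``category``."""
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")
    expanded = _expand(leaves)
    if not expanded:
        raise ValueError("damage frequency undefined for an empty unit")
    for dts in expanded:
        for dt in dts:
            if dt not in dt_registry:
                raise KeyError(f"damage type {dt!r} absent from registry")
    qualifying = _category_dts(dt_registry, category)
    hits = sum(1 for dts in expanded if dts & qualifying)
    return hits / len(expanded)


def spec_gen_ratio(
    leaves: Sequence[LeafRecord], dt_registry: Mapping[str, DTInfo]
) -> float | None:
    """Ratio of specialized-damaged to generalized-damaged leaves.

    Returns 0 when no leaf has specialized damage, and None (undefined)
    when the generalized denominator is zero but specialized damage occurs.
    """
    expanded = _expand(leaves)
    if not expanded:
        raise ValueError("ratio undefined for an empty unit")
    spec = _category_dts(dt_registry, "specialized")
    gen = _category_dts(dt_registry, "generalized")
    n_spec = sum(1 for dts in expanded if dts & spec)
    n_gen = sum(1 for dts in expanded if dts & gen)
    if n_gen == 0:
        return 0.0 if n_spec == 0 else None
    return n_spec / n_gen


def rarefy_dts(
    leaves: Sequence[LeafRecord],
    dt_registry: Mapping[str, DTInfo],
    dt_filter: str = "all",
    sizes: Sequence[int] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> RarefactionCurve:
    """Leaf-based rarefaction of DT richness.

    Each resample draws m leaves without replacement from all
    identifiable leaves, damaged and undamaged alike; richness is the
    number of distinct DTs (restricted to ``dt_filter`` — 'all' or
    'specialized') on the drawn leaves.
    """
    if dt_filter not in {"all", "specialized"}:
        raise ValueError(f"dt_filter must be 'all' or 'specialized', got {dt_filter!r}")
    expanded = _expand(leaves)
    n = len(expanded)
    if n == 0:
        raise ValueError("cannot rarefy an empty unit")
    keep = (set(dt_registry) if dt_filter == "all"
            else _category_dts(dt_registry, "specialized"))

    observed = sorted({dt for dts in expanded for dt in dts if dt in keep})
    # leaf-index members of each DT
    members = [np.flatnonzero([dt in dts for dts in expanded]) for dt in observed]

    sizes_arr = (default_sizes(n) if sizes is None
                 else np.asarray(sizes, dtype=int))
    if np.any(sizes_arr < 1) or np.any(sizes_arr > n):
        raise ValueError(f"subsample sizes must lie in [1, {n}], got {sizes_arr}")

    rng = np.random.default_rng(seed)
    rich = np.zeros((n_resamples, sizes_arr.size), dtype=int)
    if observed:
        pos = np.empty(n, dtype=int)
        for r in range(n_resamples):
            perm = rng.permutation(n)
            pos[perm] = np.arange(n)  # draw position of each leaf
            first = np.sort([pos[m].min() for m in members])
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


def per_host_curves(
    census: CensusTable,
    unit_id: str,
    min_leaves: int = 20,
    by: str = "level",
    dt_filter: str = "all",
    sizes: Sequence[int] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, RarefactionCurve]:
    """DT rarefaction per plant host within one census unit.

    Only hosts with at least ``min_leaves`` identifiable leaves
    (tally-expanded) in the unit are included; each curve applies
    :func:`rarefy_dts` to that host's leaves alone.
    """
    units = pool_units(census, by=by)
    if unit_id not in units:
        raise KeyError(f"unit {unit_id!r} not present under {by!r} pooling")
    by_host: dict[str, list[LeafRecord]] = {}
    for rec in units[unit_id]:
        if rec.identified:
            by_host.setdefault(rec.morphospecies_id, []).append(rec)

    out: dict[str, RarefactionCurve] = {}
    for host in sorted(by_host):
        recs = by_host[host]
        n = sum(r.tally_count for r in recs)
        if n < min_leaves:
            continue
        host_sizes = sizes if sizes is not None else default_sizes(n)
        host_sizes = np.asarray(host_sizes, dtype=int)
        host_sizes = host_sizes[host_sizes <= n]
        out[host] = rarefy_dts(
            recs, census.dt_registry, dt_filter=dt_filter,
            sizes=host_sizes, n_resamples=n_resamples, seed=seed,
        )
    return out


def damage_summary(
    unit_id: str,
    leaves: Sequence[LeafRecord],
    dt_registry: Mapping[str, DTInfo],
) -> DamageSummary:
    """All scalar herbivory metrics for one unit."""
    expanded = _expand(leaves)
    spec = _category_dts(dt_registry, "specialized")
    observed = {dt for dts in expanded for dt in dts}
    return DamageSummary(
        unit_id=unit_id,
        n_leaves=len(expanded),
        freq_total=damage_frequency(leaves, dt_registry, "total"),
        freq_specialized=damage_frequency(leaves, dt_registry, "specialized"),
        freq_generalized=damage_frequency(leaves, dt_registry, "generalized"),
        spec_gen_ratio=spec_gen_ratio(leaves, dt_registry),
        dt_richness_total=len(observed),
        dt_richness_specialized=len(observed & spec),
    )
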