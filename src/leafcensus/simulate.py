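"""Synthetic leaf-census generator.

Emulates the structure of a field census — one row per leaf with quarry,
morphospecies, Raunkiaer size class and a presence/absence set of insect
damage types (DTs) — with controllable richness, rank-abundance shape,
margin-state mix, size-class mix, per-leaf damage probability and a
weighted DT pool split into generalized and specialized feeding classes.
Every draw is driven by a single integer seed so censuses are exactly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml
from scipy.stats import binomtest

from .io import (
    RAUNKIAER_CLASSES,
    UNKNOWN,
    CensusTable,
    DTInfo,
    LeafRecord,
    MorphospeciesInfo,
)

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_dt_pool(n_generalized: int = 20, n_specialized: int = 14) -> list[DTInfo]:
    """A DT pool with the richness balance typical of damage censuses.

    Generalized DTs are assigned round-robin to hole feeding, margin
    feeding, skeletonization and surface feeding; specialized DTs to
    mining, galling and piercer-and-sucker damage.
    """
    gen_groups = ("hole feeding", "margin feeding", "skeletonization",
                  "surface feeding")
    spec_groups = ("mining", "galling", "piercing and sucking")
    pool = [
        DTInfo(f"DT{i + 1}", gen_groups[i % len(gen_groups)], "generalized")
        for i in range(n_generalized)
    ]
    pool += [
        DTInfo(f"DT{n_generalized + i + 1}", spec_groups[i % len(spec_groups)],
               "specialized")
        for i in range(n_specialized)
    ]
    return pool


@dataclass
class SimulationConfig:
    """Parameters of a synthetic census.

    ``abundance_model`` is ``("geometric", k)`` — species i has relative
    abundance proportional to k**i, the classic geometric rank-abundance
    series — or ``("uniform",)``.  ``p_untoothed`` is the probability a
    species in the pool has an untoothed (entire) leaf margin; the margin
    state is a species-level property fixed at pool creation, as in
    leaf-margin analysis, which scores species rather than leaves.
    ``damage_prob`` is the per-leaf probability of bearing any damage;
    a damaged leaf receives between 1 and ``max_dts_per_leaf`` DTs drawn
    by weight without replacement.
    """

    units: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", 300), ("B", 300), ("C", 300),
                                 ("D", 300), ("E", 300)]
    )
    species_pool_size: int = 40
    abundance_model: tuple = ("geometric", 0.8)
    p_untoothed: float = 0.65
    size_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "leptophyll": 0.02, "nanophyll": 0.08, "microphyll": 0.35,
            "notophyll": 0.30, "mesophyll": 0.20, "macrophyll": 0.05,
        }
    )
    damage_prob: float = 0.20
    dt_pool: list[DTInfo] = field(default_factory=default_dt_pool)
    dt_weights: list[float] | None = None
    max_dts_per_leaf: int = 3
    level_map: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for uid, n in self.units:
            if n < 1:
                raise ConfigError(f"unit {uid!r} has non-positive leaf count {n}")
        if self.species_pool_size < 1:
            raise ConfigError("species_pool_size must be positive")
        model = self.abundance_model[0]
        if model == "geometric":
            k = self.abundance_model[1]
            if not 0 < k < 1:
                raise ConfigError(f"geometric decay must be in (0,1), got {k}")
        elif model != "uniform":
            raise ConfigError(f"unknown abundance model {model!r}")
        for name, p in (("p_untoothed", self.p_untoothed),
                        ("damage_prob", self.damage_prob)):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        bad = set(self.size_class_probs) - set(RAUNKIAER_CLASSES)
        if bad:
            raise ConfigError(f"unknown size classes {sorted(bad)}")
        total = sum(self.size_class_probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigError(f"size_class_probs sum to {total}, expected 1")
        if any(p < 0 for p in self.size_class_probs.values()):
            raise ConfigError("size_class_probs must be non-negative")
        if self.damage_prob > 0 and not self.dt_pool:
            raise ConfigError("dt_pool is empty but damage_prob > 0")
        if self.dt_weights is not None and len(self.dt_weights) != len(self.dt_pool):
            raise ConfigError("dt_weights length must match dt_pool")
        if self.max_dts_per_leaf < 1:
            raise ConfigError("max_dts_per_leaf must be positive")


def _species_probs(config: SimulationConfig) -> np.ndarray:
    s = config.species_pool_size
    if config.abundance_model[0] == "uniform":
        return np.full(s, 1.0 / s)
    k = config.abundance_model[1]
    w = k ** np.arange(s)
    return w / w.sum()


def generate_census(config: SimulationConfig) -> CensusTable:
    """Draw a reproducible synthetic census from ``config``.

    Each leaf draws a morphospecies from the abundance model and a size
    class from ``size_class_probs``; with probability ``damage_prob`` it
    receives 1..max_dts_per_leaf DTs sampled by weight without
    replacement.  Identical configs (including seed) produce identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    probs = _species_probs(config)
    width = len(str(config.species_pool_size))
    species_ids = [f"sp{i + 1:0{width}d}" for i in range(config.species_pool_size)]

    # Species-level margin states, fixed once for the whole pool.
    untoothed = rng.random(config.species_pool_size) < config.p_untoothed
    sreg = {
        sid: MorphospeciesInfo(sid, "untoothed" if u else "toothed")
        for sid, u in zip(species_ids, untoothed)
    }
    dreg = {d.dt_id: d for d in config.dt_pool}
    dt_ids = np.array([d.dt_id for d in config.dt_pool])
    if config.dt_weights is not None:
        dt_w = np.asarray(config.dt_weights, dtype=float)
    else:
        dt_w = np.ones(len(config.dt_pool))
    dt_w = dt_w / dt_w.sum() if len(dt_w) else dt_w

    size_labels = list(config.size_class_probs)
    size_p = np.array([config.size_class_probs[c] for c in size_labels])

    records: list[LeafRecord] = []
    counter = 0
    for unit_id, n in config.units:
        level = (config.level_map or {}).get(unit_id, unit_id)
        sp_idx = rng.choice(config.species_pool_size, size=n, p=probs)
        sz_idx = rng.choice(len(size_labels), size=n, p=size_p)
        damaged = rng.random(n) < config.damage_prob
        for j in range(n):
            counter += 1
            dts: frozenset[str] = frozenset()
            if damaged[j]:
                k = int(rng.integers(1, config.max_dts_per_leaf + 1))
                k = min(k, len(dt_ids))
                chosen = rng.choice(len(dt_ids), size=k, replace=False, p=dt_w)
                dts = frozenset(dt_ids[chosen])
            records.append(
                LeafRecord(
                    specimen_id=f"SYN{counter:06d}",
                    quarry_id=unit_id,
                    level_id=level,
                    morphospecies_id=species_ids[int(sp_idx[j])],
                    size_class=size_labels[int(sz_idx[j])],
                    dts=dts,
                )
            )

    unit_map = {uid: (config.level_map or {}).get(uid, uid)
                for uid, _ in config.units}
    return CensusTable(records=records, species_registry=sreg,
                       dt_registry=dreg, unit_map=unit_map)


def recovery_report(
    census: CensusTable, config: SimulationConfig
) -> dict[str, tuple[float, float, bool]]:
    """Compare configured generator parameters with their empirical values.

    Returns ``{parameter: (configured, estimated, inside_95ci)}`` where
    the interval is the exact Clopper-Pearson binomial 95% CI around the
    empirical proportion (per size class, a marginal binomial interval).
    """
    n_leaves = len(census.records)
    out: dict[str, tuple[float, float, bool]] = {}

    def _binom_entry(name: str, k: int, n: int, p_true: float) -> None:
        est = k / n if n else float("nan")
        if n:
            ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
            inside = ci.low <= p_true <= ci.high
        else:
            inside = False
        out[name] = (p_true, est, inside)

    n_damaged = sum(1 for r in census.records if r.dts)
    _binom_entry("damage_prob", n_damaged, n_leaves, config.damage_prob)

    present = {r.morphospecies_id for r in census.records if r.identified}
    n_unt = sum(
        1 for sid in present
        if census.species_registry[sid].margin_state == "untoothed"
    )
    _binom_entry("p_untoothed", n_unt, len(present), config.p_untoothed)

    known = [r for r in census.records if r.size_class != UNKNOWN]
    for cls, p_true in config.size_class_probs.items():
        k = sum(1 for r in known if r.size_class == cls)
        _binom_entry(f"size_class[{cls}]", k, len(known), p_true)
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if "units" in raw:
        raw["units"] = [tuple(u) for u in raw["units"]]
    if "abundance_model" in raw:
        raw["abundance_model"] = tuple(raw["abundance_model"])
    if "dt_pool" in raw:
        raw["dt_pool"] = [DTInfo(**d) for d in raw["dt_pool"]]
    return SimulationConfig(**raw)
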