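"""Leaf-physiognomy paleoclimate proxies.

Leaf-margin analysis (LMA) estimates mean annual temperature from the
proportion P of dicot morphospecies with untoothed (entire) margins:

    MAT (degC)   = 30.6 * P + 1.14
    sigma (degC) = 30.6 * sqrt(P * (1 - P) / r)

with r the number of margin-scored species in the sample.  Leaf-area
analysis estimates mean annual precipitation from the Raunkiaer
size-class spectrum of the leaves:

    MAP (cm/yr) = exp(0.548 * sum_i a_i * p_i + 0.768)

where p_i is the proportion of leaves in size class i and a_i the
natural log of the class's representative leaf area (mm^2).  The
regression's standard error (0.359) lives on the log scale, so the MAP
uncertainty is asymmetric in linear units:

    plus  = MAP * (e^SE - 1)        minus = MAP * (1 - e^-SE)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import UNKNOWN, LeafRecord, MorphospeciesInfo

MAT_SLOPE = 30.6
MAT_INTERCEPT = 1.14
MAP_SLOPE = 0.548
MAP_INTERCEPT = 0.768
MAP_SE_LN = 0.359


@dataclass(frozen=True)
class SizeClassScheme:
    """Raunkiaer size classes with log representative leaf areas.

    ``a`` maps each class label to the natural log of its representative
    leaf area in mm^2 and must be strictly increasing with class size.
    The default uses the geometric midpoint of the classic class bounds
    (25, 225, 2025, 4500, 18225, 164025 mm^2); calibrations differ in the
    literature, so the scheme is an explicit, overridable input.
    """

    a: dict[str, float] = field(default_factory=lambda: {
        "leptophyll": math.log(math.sqrt(5 * 25)),          # 2.41
        "nanophyll": math.log(math.sqrt(25 * 225)),         # 4.32
        "microphyll": math.log(math.sqrt(225 * 2025)),      # 6.51
        "notophyll": math.log(math.sqrt(2025 * 4500)),      # 8.01
        "mesophyll": math.log(math.sqrt(4500 * 18225)),     # 9.11
        "macrophyll": math.log(math.sqrt(18225 * 164025)),  # 10.91
        "megaphyll": math.log(2.0 * 164025),                # open-ended top
    })

    def __post_init__(self) -> None:
        if len(set(self.a)) != len(self.a):
            raise ValueError("size-class labels must be unique")
        vals = list(self.a.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("log areas must increase with class size")

    @classmethod
    def read(cls, path: str | Path) -> "SizeClassScheme":
        df = pd.read_csv(path)
        return cls(a=dict(zip(df["label"], df["a"].astype(float))))

    def write(self, path: str | Path) -> None:
        pd.DataFrame({"label": list(self.a), "a": list(self.a.values())}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class ClimateEstimate:
    """Paleotemperature and paleoprecipitation for one census unit."""

    mat_C: float
    mat_sigma_C: float
    map_cm: float
    map_plus_cm: float
    map_minus_cm: float
    p_untoothed: float
    r_species: int
    size_class_props: dict[str, float]


def lma_mat(p_untoothed: float, r_species: int) -> tuple[float, float]:
    """Leaf-margin MAT estimate and its binomial standard deviation."""
    if not 0 <= p_untoothed <= 1:
        raise ValueError(f"P must be in [0,1], got {p_untoothed}")
    if r_species < 1:
        raise ValueError(f"r must be a positive species count, got {r_species}")
    mat = MAT_SLOPE * p_untoothed + MAT_INTERCEPT
    sigma = MAT_SLOPE * math.sqrt(p_untoothed * (1 - p_untoothed) / r_species)
    return mat, sigma


def margin_proportion(
    leaves: Sequence[LeafRecord],
    species_registry: Mapping[str, MorphospeciesInfo],
) -> tuple[float, int]:
    """(P, r): untoothed proportion over margin-scored species in a unit.

    Species present only as unidentified leaves, and species whose margin
    state is unknown, never enter P or r.
    """
    present = {rec.morphospecies_id for rec in leaves if rec.identified}
    scored = [sid for sid in present
              if species_registry[sid].margin_state != "unknown"]
    if not scored:
        raise ValueError("no margin-scored species present in the unit")
    untoothed = sum(
        1 for sid in scored
        if species_registry[sid].margin_state == "untoothed"
    )
    return untoothed / len(scored), len(scored)


def size_class_proportions(
    leaves: Sequence[LeafRecord], scheme: SizeClassScheme | None = None
) -> dict[str, float]:
    """Tally-weighted leaf proportions per size class, UNKNOWN excluded."""
    scheme = scheme or SizeClassScheme()
    counts: dict[str, float] = {}
    for rec in leaves:
        if rec.size_class == UNKNOWN:
            continue
        if rec.size_class not in scheme.a:
            raise KeyError(f"size class {rec.size_class!r} absent from scheme")
        counts[rec.size_class] = counts.get(rec.size_class, 0) + rec.tally_count
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no leaves with a known size class in the unit")
    return {c: counts[c] / total for c in scheme.a if c in counts}


def leaf_area_map(
    size_class_props: Mapping[str, float],
    scheme: SizeClassScheme | None = None,
) -> float:
    """Leaf-area MAP estimate in cm/yr from a size-class spectrum."""
    scheme = scheme or SizeClassScheme()
    if not size_class_props:
        raise ValueError("empty size-class spectrum")
    total = sum(size_class_props.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {total}")
    mlna = sum(scheme.a[c] * p for c, p in size_class_props.items())
    return math.exp(MAP_SLOPE * mlna + MAP_INTERCEPT)


def map_error_bounds(
    map_cm: float, se_ln: float = MAP_SE_LN
) -> tuple[float, float]:
    """Asymmetric (plus, minus) MAP bounds from the log-scale SE."""
    if map_cm <= 0:
        raise ValueError(f"MAP must be positive, got {map_cm}")
    plus = map_cm * (math.exp(se_ln) - 1.0)
    minus = map_cm * (1.0 - math.exp(-se_ln))
    return plus, minus


def climate_estimate(
    leaves: Sequence[LeafRecord],
    species_registry: Mapping[str, MorphospeciesInfo],
    scheme: SizeClassScheme | None = None,
) -> ClimateEstimate:
    """Full MAT/MAP reconstruction for one census unit."""
    scheme = scheme or SizeClassScheme()
    p, r = margin_proportion(leaves, species_registry)
    mat, sigma = lma_mat(p, r)
    props = size_class_proportions(leaves, scheme)
    map_cm = leaf_area_map(props, scheme)
    plus, minus = map_error_bounds(map_cm)
    return ClimateEstimate(
        mat_C=mat, mat_sigma_C=sigma, map_cm=map_cm,
        map_plus_cm=plus, map_minus_cm=minus,
        p_untoothed=p, r_species=r, size_class_props=props,
    )
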