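"""Pipeline orchestration: census -> summary tables, curves, ordinations.

Every output file begins with provenance header lines (``# key: value``)
recording the package version, a hash of the run configuration, and the
seed, so any table can be traced back to the run that produced it.
Presentation rounding is kept separate from computation: each summary
table carries full-precision columns plus rounded display columns
(2 decimals for H and J, 1 for climate).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .climate import SizeClassScheme, climate_estimate
from .diversity import pielou, rarefy_species, richness, shannon
from .herbivory import damage_summary, per_host_curves, rarefy_dts
from .io import CensusTable, abundance_matrix, pool_units
from .ordination import distance_matrix, nmds, variable_scores


@dataclass
class RunConfig:
    """Inputs and sampling parameters for one pipeline run."""

    census_path: str | None = None
    species_registry_path: str | None = None
    dt_registry_path: str | None = None
    scheme_path: str | None = None
    unit_map: dict[str, str] = field(default_factory=dict)
    n_resamples: int = 1000
    seed: int = 0
    sizes: list[int] | None = None
    min_leaves_per_host: int = 20
    out_dir: str = "out"
    overwrite: bool = False

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _open_out(path: Path, config: RunConfig):
    if path.exists() and not config.overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    fh = open(path, "w")
    fh.write(f"# leafcensus: {__version__}\n")
    fh.write(f"# config: {config.digest()}\n")
    fh.write(f"# seed: {config.seed}\n")
    return fh


def _unit_summary_row(
    unit_id: str, recs, census: CensusTable, scheme: SizeClassScheme
) -> dict[str, Any]:
    counts = abundance_matrix({unit_id: recs}, kind="species").iloc[0]
    counts = counts[counts > 0]
    s = richness(counts)
    h = shannon(counts) if s >= 1 else math.nan
    j = pielou(counts) if s >= 2 else math.nan
    dmg = damage_summary(unit_id, recs, census.dt_registry)
    row: dict[str, Any] = {
        "unit": unit_id,
        "n_leaves": sum(r.tally_count for r in recs if r.identified),
        "richness": s,
        "shannon_H": h,
        "pielou_J": j,
        "freq_total": dmg.freq_total,
        "freq_specialized": dmg.freq_specialized,
        "freq_generalized": dmg.freq_generalized,
        "spec_gen_ratio": (math.nan if dmg.spec_gen_ratio is None
                           else dmg.spec_gen_ratio),
        "dt_richness": dmg.dt_richness_total,
    }
    try:
        est = climate_estimate(recs, census.species_registry, scheme)
        row.update(
            mat_C=est.mat_C, mat_sigma_C=est.mat_sigma_C, map_cm=est.map_cm,
            map_plus_cm=est.map_plus_cm, map_minus_cm=est.map_minus_cm,
        )
    except (ValueError, KeyError):
        row.update(mat_C=math.nan, mat_sigma_C=math.nan, map_cm=math.nan,
                   map_plus_cm=math.nan, map_minus_cm=math.nan)
    # rounded presentation columns; computation stays full precision
    row["shannon_H_2dp"] = round(row["shannon_H"], 2)
    row["pielou_J_2dp"] = round(row["pielou_J"], 2)
    for c in ("mat_C", "mat_sigma_C", "map_cm", "map_plus_cm", "map_minus_cm"):
        row[f"{c}_1dp"] = round(row[c], 1)
    return row


def summarize(
    census: CensusTable, scheme: SizeClassScheme | None = None
) -> dict[str, pd.DataFrame]:
    """Per-quarry and per-level summary tables (in-memory)."""
    if not census.records:
        raise ValueError("cannot summarize an empty census")
    scheme = scheme or SizeClassScheme()
    out = {}
    for by in ("quarry", "level"):
        units = pool_units(census, by=by)
        rows = [_unit_summary_row(u, recs, census, scheme)
                for u, recs in units.items()]
        out[by] = pd.DataFrame(rows).set_index("unit")
    return out


def run_summarize(census: CensusTable, config: RunConfig,
                  scheme: SizeClassScheme | None = None) -> list[Path]:
    """Write per-quarry and per-level summary tables to the output dir."""
    tables = summarize(census, scheme)
    written = []
    for by, table in tables.items():
        path = Path(config.out_dir) / f"summary_{by}.csv"
        with _open_out(path, config) as fh:
            table.to_csv(fh)
        written.append(path)
    return written


def run_rarefy(census: CensusTable, config: RunConfig, target: str = "flora",
               by: str = "level") -> list[Path]:
    """Write rarefaction curve files for the requested target.

    Targets: ``flora`` (species richness), ``dts`` (all damage types),
    ``dts_specialized``, or ``per_host`` (DT curves per abundant host).
    """
    if target not in {"flora", "dts", "dts_specialized", "per_host"}:
        raise ValueError(f"unknown rarefaction target {target!r}")
    units = pool_units(census, by=by)
    written = []
    for unit_id, recs in units.items():
        if target == "per_host":
            curves = per_host_curves(
                census, unit_id, min_leaves=config.min_leaves_per_host, by=by,
                sizes=config.sizes, n_resamples=config.n_resamples,
                seed=config.seed,
            )
            for host, curve in curves.items():
                path = (Path(config.out_dir)
                        / f"rarefy_per_host_{unit_id}_{host}.csv")
                with _open_out(path, config) as fh:
                    fh.write(f"# filter: all (host {host})\n")
                    curve.to_frame().to_csv(fh, index=False)
                written.append(path)
            continue
        if target == "flora":
            counts = abundance_matrix({unit_id: recs}, kind="species").iloc[0]
            total = int(counts.sum())
            if total == 0:
                continue
            sizes = config.sizes or None
            curve = rarefy_species(counts.to_numpy(), sizes=sizes,
                                   n_resamples=config.n_resamples,
                                   seed=config.seed)
            filt = "species"
        else:
            filt = "specialized" if target == "dts_specialized" else "all"
            curve = rarefy_dts(recs, census.dt_registry, dt_filter=filt,
                               sizes=config.sizes,
                               n_resamples=config.n_resamples,
                               seed=config.seed)
        path = Path(config.out_dir) / f"rarefy_{target}_{unit_id}.csv"
        with _open_out(path, config) as fh:
            fh.write(f"# n_resamples: {config.n_resamples}\n")
            fh.write(f"# filter: {filt}\n")
            curve.to_frame().to_csv(fh, index=False)
        written.append(path)
    return written


def run_ordinate(census: CensusTable, config: RunConfig,
                 matrix_kind: str = "species", by: str = "level",
                 k: int = 2, n_restarts: int = 20) -> tuple[list[Path], float]:
    """NMDS ordination of the unit x species or unit x DT count matrix."""
    units = pool_units(census, by=by)
    mat = abundance_matrix(units, kind=matrix_kind)
    dist = distance_matrix(mat)
    result = nmds(dist, k=k, n_restarts=n_restarts, seed=config.seed)
    vscores = variable_scores(result.site_scores, mat)

    written = []
    for name, table in (("site", result.site_scores), ("variable", vscores)):
        path = Path(config.out_dir) / f"nmds_{matrix_kind}_{name}_scores.csv"
        with _open_out(path, config) as fh:
            fh.write(f"# stress: {result.stress:.6g}\n")
            fh.write(f"# converged: {result.converged}\n")
            table.to_csv(fh)
        written.append(path)
    return written, result.stress
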