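"""Data model and readers/writers for fossil leaf-census tables.

A census is a table with one row per collected leaf, or one row per
field-tallied batch of undamaged leaves of a known morphospecies.  Each
row records the quarry it came from, the stratigraphic level the quarry
belongs to, the morphospecies assignment (possibly :data:`UNIDENTIFIED`),
the Raunkiaer leaf-size class, and the set of insect damage types (DTs)
observed on the leaf.

Sidecar registries carry per-morphospecies leaf-margin states (used by
leaf-margin paleotemperature analysis) and per-DT feeding-group and
specialization classes (used by herbivory metrics).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel morphospecies id for leaves that could not be assigned.
UNIDENTIFIED = "UNIDENTIFIED"

#: Sentinel size class for leaves whose size class was not recorded.
UNKNOWN = "UNKNOWN"

#: Raunkiaer-Webb ordinal leaf-size classes, smallest to largest.
RAUNKIAER_CLASSES = (
    "leptophyll",
    "nanophyll",
    "microphyll",
    "notophyll",
    "mesophyll",
    "macrophyll",
    "megaphyll",
)

MARGIN_STATES = ("toothed", "untoothed", "unknown")
SPECIALIZATIONS = ("generalized", "specialized")

_DT_COLUMN_RE = re.compile(r"^DT\d+$")


class SchemaError(ValueError):
    """A mandatory column is missing or mis-declared."""


class CensusValueError(ValueError):
    """A cell value violates the census coding rules."""


class UnitMappingError(KeyError):
    """A quarry has no stratigraphic-level assignment."""


@dataclass(frozen=True)
class LeafRecord:
    """One censused leaf, or one field-tally batch of undamaged leaves.

    ``tally_count`` is 1 for collected specimens.  Values > 1 are allowed
    only for field-tallied batches of undamaged leaves of a known
    morphospecies, which by construction carry no damage types.
    """

    specimen_id: str
    quarry_id: str
    level_id: str
    morphospecies_id: str
    size_class: str
    dts: frozenset[str] = frozenset()
    tally_count: int = 1

    def __post_init__(self) -> None:
        if self.tally_count < 1:
            raise CensusValueError(
                f"tally_count must be >= 1, got {self.tally_count} "
                f"(specimen {self.specimen_id})"
            )
        if self.tally_count > 1 and self.dts:
            raise CensusValueError(
                f"tally batches must be undamaged; specimen {self.specimen_id} "
                f"has tally_count={self.tally_count} and dts={sorted(self.dts)}"
            )
        if not isinstance(self.dts, frozenset):
            object.__setattr__(self, "dts", frozenset(self.dts))

    @property
    def identified(self) -> bool:
        return self.morphospecies_id != UNIDENTIFIED


@dataclass(frozen=True)
class MorphospeciesInfo:
    """Registry entry for one plant morphospecies."""

    morphospecies_id: str
    margin_state: str = "unknown"

    def __post_init__(self) -> None:
        if self.margin_state not in MARGIN_STATES:
            raise CensusValueError(
                f"margin_state must be one of {MARGIN_STATES}, "
                f"got {self.margin_state!r}"
            )


@dataclass(frozen=True)
class DTInfo:
    """Registry entry for one insect damage type (DT)."""

    dt_id: str
    feeding_group: str = ""
    specialization: str = "generalized"

    def __post_init__(self) -> None:
        if self.specialization not in SPECIALIZATIONS:
            raise CensusValueError(
                f"specialization must be one of {SPECIALIZATIONS}, "
                f"got {self.specialization!r}"
            )


@dataclass
class CensusTable:
    """Validated collection of leaf records plus sidecar registries.

    ``unit_map`` maps each quarry id to its stratigraphic-level id, so
    quarries can be pooled into levels for level-resolution analyses.
    """

    records: list[LeafRecord] = field(default_factory=list)
    species_registry: dict[str, MorphospeciesInfo] = field(default_factory=dict)
    dt_registry: dict[str, DTInfo] = field(default_factory=dict)
    unit_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            if rec.identified and rec.morphospecies_id not in self.species_registry:
                raise CensusValueError(
                    f"morphospecies {rec.morphospecies_id!r} (specimen "
                    f"{rec.specimen_id}) missing from species registry"
                )
            for dt in rec.dts:
                if dt not in self.dt_registry:
                    raise CensusValueError(
                        f"damage type {dt!r} (specimen {rec.specimen_id}) "
                        f"missing from DT registry"
                    )
            if rec.quarry_id not in self.unit_map:
                raise UnitMappingError(
                    f"quarry {rec.quarry_id!r} missing from unit_map"
                )

    @property
    def n_leaves(self) -> int:
        """Total leaf count including field-tally batches."""
        return sum(r.tally_count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CensusTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.species_registry == other.species_registry
            and self.dt_registry == other.dt_registry
            and self.unit_map == other.unit_map
        )


DEFAULT_SCHEMA: dict[str, str] = {
    "specimen_id": "specimen_id",
    "quarry_id": "quarry_id",
    "level_id": "level_id",
    "morphospecies_id": "morphospecies_id",
    "size_class": "size_class",
    "tally_count": "tally_count",
    "dts": "dts",
}

_MANDATORY = ("specimen_id", "quarry_id", "morphospecies_id")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a JSON column-name mapping (canonical field -> file column)."""
    with open(path) as fh:
        mapping = json.load(fh)
    return {**DEFAULT_SCHEMA, **mapping}


def read_census(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    species_registry: Mapping[str, MorphospeciesInfo] | None = None,
    dt_registry: Mapping[str, DTInfo] | None = None,
    unit_map: Mapping[str, str] | None = None,
) -> CensusTable:
    """Read a delimited census file into a validated :class:`CensusTable`.

    Two DT encodings are accepted: wide 0/1 columns named like ``DT12``,
    or a single delimited list column (``;``-separated) named by the
    schema's ``dts`` entry.  CSV vs TSV is chosen from the file extension.

    Registries default to permissive stubs built from the observed ids
    (margin state ``unknown``, specialization ``generalized``); pass real
    registries for margin- or specialization-dependent analyses.
    """
    path = Path(path)
    sch = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)

    for key in _MANDATORY:
        if sch[key] not in df.columns:
            raise SchemaError(
                f"mandatory column {sch[key]!r} (field {key}) absent from {path}"
            )

    dt_cols = [c for c in df.columns if _DT_COLUMN_RE.match(c)]
    list_col = sch["dts"] if sch["dts"] in df.columns else None

    records: list[LeafRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        dts: set[str] = set()
        for c in dt_cols:
            v = str(rowd[c]).strip()
            if v in {"", "0"}:
                continue
            if v != "1":
                raise CensusValueError(
                    f"non-binary value {v!r} in DT column {c} at data row {i}"
                )
            dts.add(c)
        if list_col:
            raw = str(rowd[list_col]).strip()
            if raw:
                dts.update(t.strip() for t in raw.split(";") if t.strip())

        size_raw = str(rowd.get(sch["size_class"], "")).strip().lower()
        if size_raw in RAUNKIAER_CLASSES:
            size = size_raw
        else:
            if size_raw and size_raw != UNKNOWN.lower():
                logger.warning(
                    "unknown size-class label %r at data row %d; recorded as %s",
                    size_raw, i, UNKNOWN,
                )
            size = UNKNOWN

        tally_raw = str(rowd.get(sch["tally_count"], "")).strip()
        tally = int(tally_raw) if tally_raw else 1
        morpho = str(rowd[sch["morphospecies_id"]]).strip() or UNIDENTIFIED
        quarry = str(rowd[sch["quarry_id"]]).strip()
        level = str(rowd.get(sch["level_id"], "")).strip() or quarry

        records.append(
            LeafRecord(
                specimen_id=str(rowd[sch["specimen_id"]]).strip(),
                quarry_id=quarry,
                level_id=level,
                morphospecies_id=morpho,
                size_class=size,
                dts=frozenset(dts),
                tally_count=tally,
            )
        )

    umap = dict(unit_map) if unit_map else {}
    for rec in records:
        umap.setdefault(rec.quarry_id, rec.level_id)

    sreg = dict(species_registry) if species_registry else {}
    for rec in records:
        if rec.identified:
            sreg.setdefault(
                rec.morphospecies_id, MorphospeciesInfo(rec.morphospecies_id)
            )
    dreg = dict(dt_registry) if dt_registry else {}
    for rec in records:
        for dt in rec.dts:
            dreg.setdefault(dt, DTInfo(dt))

    return CensusTable(records=records, species_registry=sreg,
                       dt_registry=dreg, unit_map=umap)


def write_census(census: CensusTable, path: str | Path) -> None:
    """Write a census as delimited text (wide 0/1 DT columns)."""
    path = Path(path)
    all_dts = sorted(census.dt_registry)
    rows = []
    for rec in census.records:
        row = {
            "specimen_id": rec.specimen_id,
            "quarry_id": rec.quarry_id,
            "level_id": rec.level_id,
            "morphospecies_id": rec.morphospecies_id,
            "size_class": rec.size_class,
            "tally_count": rec.tally_count,
        }
        for dt in all_dts:
            row[dt] = 1 if dt in rec.dts else 0
        rows.append(row)
    cols = ["specimen_id", "quarry_id", "level_id", "morphospecies_id",
            "size_class", "tally_count", *all_dts]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False)


def read_species_registry(path: str | Path) -> dict[str, MorphospeciesInfo]:
    """Read a morphospecies registry (columns: morphospecies_id, margin_state)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    out: dict[str, MorphospeciesInfo] = {}
    for _, row in df.iterrows():
        mid = row["morphospecies_id"].strip()
        if mid in out:
            raise CensusValueError(f"duplicate morphospecies id {mid!r}")
        out[mid] = MorphospeciesInfo(
            mid, row.get("margin_state", "unknown").strip() or "unknown"
        )
    return out


def write_species_registry(
    registry: Mapping[str, MorphospeciesInfo], path: str | Path
) -> None:
    path = Path(path)
    pd.DataFrame(
        [{"morphospecies_id": m.morphospecies_id, "margin_state": m.margin_state}
         for m in registry.values()]
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_dt_registry(path: str | Path) -> dict[str, DTInfo]:
    """Read a DT registry (columns: dt_id, feeding_group, specialization)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    out: dict[str, DTInfo] = {}
    for _, row in df.iterrows():
        did = row["dt_id"].strip()
        if did in out:
            raise CensusValueError(f"duplicate DT id {did!r}")
        out[did] = DTInfo(
            did,
            row.get("feeding_group", "").strip(),
            row.get("specialization", "generalized").strip() or "generalized",
        )
    return out


def write_dt_registry(registry: Mapping[str, DTInfo], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        [{"dt_id": d.dt_id, "feeding_group": d.feeding_group,
          "specialization": d.specialization}
         for d in registry.values()]
    ).to_csv(path, sep=_sep_for(path), index=False)


def pool_units(
    census: CensusTable, by: str = "quarry"
) -> dict[str, list[LeafRecord]]:
    """Group records into census units by quarry or stratigraphic level.

    Level pooling is the disjoint union of the level's quarries' records;
    the total tally is conserved.  Unit keys are returned sorted.
    """
    if by not in {"quarry", "level"}:
        raise ValueError(f"by must be 'quarry' or 'level', got {by!r}")
    groups: dict[str, list[LeafRecord]] = {}
    for rec in census.records:
        if rec.quarry_id not in census.unit_map:
            raise UnitMappingError(f"quarry {rec.quarry_id!r} missing from unit_map")
        key = rec.quarry_id if by == "quarry" else census.unit_map[rec.quarry_id]
        groups.setdefault(key, []).append(rec)
    return dict(sorted(groups.items()))


def abundance_matrix(
    units: Mapping[str, Sequence[LeafRecord]], kind: str = "species"
) -> pd.DataFrame:
    """Build a units x variables count matrix.

    ``kind='species'``: cell = summed tally of that morphospecies' leaves
    in the unit, unidentified leaves excluded.  ``kind='dt'``: cell =
    number of leaves in the unit bearing that DT (a leaf with k DTs
    contributes once to each of the k columns).  Rows and columns are
    sorted lexicographically for stable output.
    """
    if not units:
        raise ValueError("at least one unit is required")
    if kind not in {"species", "dt"}:
        raise ValueError(f"kind must be 'species' or 'dt', got {kind!r}")

    cells: dict[str, dict[str, int]] = {u: {} for u in units}
    for unit, recs in units.items():
        row = cells[unit]
        for rec in recs:
            if kind == "species":
                if not rec.identified:
                    continue
                row[rec.morphospecies_id] = (
                    row.get(rec.morphospecies_id, 0) + rec.tally_count
                )
            else:
                for dt in rec.dts:
                    row[dt] = row.get(dt, 0) + 1

    cols = sorted({c for row in cells.values() for c in row})
    mat = pd.DataFrame(0, index=sorted(units), columns=cols, dtype=int)
    for unit, row in cells.items():
        for c, v in row.items():
            mat.loc[unit, c] = v
    return mat
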