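import pytest

from leafcensus import (
    CensusTable,
    DTInfo,
    LeafRecord,
    MorphospeciesInfo,
    SimulationConfig,
    generate_census,
)


def make_record(specimen="s1", quarry="Q1", level="L1", species="spA",
                size="microphyll", dts=(), tally=1):
    return LeafRecord(
        specimen_id=specimen, quarry_id=quarry, level_id=level,
        morphospecies_id=species, size_class=size,
        dts=frozenset(dts), tally_count=tally,
    )


def make_census(records, margin_states=None, dt_specs=None):
    """Build a CensusTable with registries inferred from the records.

    ``margin_states`` maps morphospecies id -> margin state (default
    unknown); ``dt_specs`` maps dt id -> specialization (default
    generalized).
    """
    margin_states = margin_states or {}
    dt_specs = dt_specs or {}
    species = {}
    dts = {}
    unit_map = {}
    for rec in records:
        if rec.identified:
            species.setdefault(
                rec.morphospecies_id,
                MorphospeciesInfo(
                    rec.morphospecies_id,
                    margin_states.get(rec.morphospecies_id, "unknown"),
                ),
            )
        for dt in rec.dts:
            dts.setdefault(dt, DTInfo(dt, "", dt_specs.get(dt, "generalized")))
        unit_map.setdefault(rec.quarry_id, rec.level_id)
    return CensusTable(records=list(records), species_registry=species,
                       dt_registry=dts, unit_map=unit_map)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        units=[("A", 300), ("B", 300), ("C", 300), ("D", 300), ("E", 300)],
        species_pool_size=40,
        abundance_model=("geometric", 0.8),
        p_untoothed=0.65,
        damage_prob=0.20,
        seed=20170915,
    )


@pytest.fixture(scope="session")
def synthetic_census(sim_config):
    return generate_census(sim_config)
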