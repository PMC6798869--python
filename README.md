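# leafcensus

Quantitative analysis of fossil leaf censuses for paleoecologists who
track how plant communities and their insect herbivores change through
a stratigraphic section. A census is a table with one row per collected
dicot leaf (or per field-tallied batch of undamaged leaves): the quarry
it came from, its morphospecies, its Raunkiaer size class, and the
presence/absence of numbered insect damage types (DTs). From such
tables, pooled by quarry or by stratigraphic level, the package
computes:

- **Floral diversity** — species richness S, Shannon–Wiener
  H = −Σ pᵢ ln pᵢ, Pielou's evenness J = H / ln S, and rank-abundance
  curves.
- **Individual-based rarefaction** with seeded Monte-Carlo resampling
  (mean and 2.5/97.5 percentile band), for plant species on specimen
  counts and for DTs on leaves — the leaf-based scheme correctly handles
  leaves with no damage and leaves carrying several DTs, for bulk floras
  and for single abundant host plants (≥ 20 leaves by default).
- **Herbivory metrics** — the percent of leaves with any, specialized
  (mines, galls, piercing) or generalized damage, and the
  specialized:generalized ratio.
- **Leaf-physiognomy paleoclimate proxies** — leaf-margin analysis,
  MAT = 30.6 P + 1.14 (°C) with σ = 30.6 √(P(1−P)/r), where P is the
  proportion of untoothed-margin species among the r margin-scored
  species; and leaf-area analysis,
  MAP = exp(0.548 Σ aᵢpᵢ + 0.768) (cm/yr) with the regression SE of
  0.359 applied on the log scale, which makes the linear-scale error
  bounds asymmetric: +MAP(e^0.359 − 1) / −MAP(1 − e^−0.359).
- **NMDS ordination** of unit × species and unit × DT count matrices
  (Euclidean distances on raw counts), minimizing Kruskal stress-1 with
  monotone regression, best of many restarts, with site scores on
  principal axes and abundance-weighted variable scores.
- A **synthetic census generator**, so the entire pipeline is testable
  with no access to physical collections: geometric or uniform
  rank-abundance, species-level margin states, a weighted DT pool split
  into generalized/specialized classes, all driven by one seed.

## Worked example

Simulate a five-level census (1 500 leaves) and summarize it:

```sh
cat > sim.yaml <<'YAML'
units: [[A, 300], [B, 300], [C, 300], [D, 300], [E, 300]]
species_pool_size: 40
abundance_model: [geometric, 0.8]
p_untoothed: 0.65
damage_prob: 0.2
seed: 7
YAML
leafcensus simulate --config sim.yaml --out census.csv
leafcensus summarize --census census.csv \
    --species-registry census_species.csv --dt-registry census_dts.csv \
    --out-dir out --seed 1
leafcensus ordinate --census census.csv --out-dir out --seed 1
```

The level summary (`out/summary_level.csv`, rounded display columns):

```
      n_leaves  richness  shannon_H_2dp  pielou_J_2dp  freq_total  mat_C_1dp  mat_sigma_C_1dp  map_cm_1dp
unit
A          300        20           2.47          0.82    0.240000       21.0              3.3       132.0
B          300        23           2.52          0.80    0.143333       22.4              2.9       119.4
C          300        22           2.54          0.82    0.190000       22.0              3.0       134.3
D          300        20           2.51          0.84    0.223333       21.0              3.3       126.2
E          300        21           2.35          0.77    0.206667       20.1              3.2       125.9
```

Each row is one stratigraphic level: ~20 morphospecies observed out of
the 40-species pool at 300 leaves, H ≈ 2.5 and J ≈ 0.8 (an even,
moderately diverse flora), total damage frequency near the configured
20 %, and margin/size-based climate estimates around 21 °C and
125 cm/yr. The `ordinate` run reports `stress: 0.000304` — five units
embed essentially perfectly in two dimensions (stress < 0.01).

The same operations are available as library functions
(`leafcensus.shannon`, `rarefy_dts`, `lma_mat`, `nmds`, ...) on plain
pandas/numpy objects; see the module docstrings.

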