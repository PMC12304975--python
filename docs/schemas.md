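# Table schemas

All tables are plain CSV; dates are ISO-8601.

## exudates.csv — syringe incubation records
| column | units / values |
|---|---|
| sample_id | unique id |
| array_id | e.g. A1–A3 (ambient), E1–E3 (elevated) |
| treatment | `ambient` \| `elevated` |
| timepoint | season label (e.g. Aug2020) |
| collection_date | ISO date of the campaign |
| box_id | root box within the array |
| is_blank | True for rootless blank syringes |
| solution_C_ug | µg dissolved oxidizable C recovered (collection + washes pooled) |
| solution_N_ug | µg total dissolved N recovered |
| root_dry_mass_g | g dry root (empty for blanks) |
| root_surface_area_mm2 | mm² (empty for blanks) |
| duration_d | incubation length, days |

## root_traits.csv — scanner exports per root system
sample_id, array_id, treatment, timepoint, total_length_mm, branch_points
(count), dry_mass_g, surface_area_mm2, tissue_C_pct, tissue_N_pct.
Alternative scanner column names map via `derive_traits(column_map=...)`.

## biomass.csv — standing fine-root stock per array census
array_id, treatment, timepoint, census_date, biomass_lt1mm_g_m2,
biomass_1to2mm_g_m2 (g m⁻²; the two diameter classes are summed for areal
exudation).

## bags.csv — ingrowth-bag records
bag_id, array_id, treatment, location_id, duration_class (`3mo`|`6mo`|`12mo`),
install_date, collect_date, ergosterol_ug_per_g (µg ergosterol per g dry
sand), sand_mass_g.

## metabolome_*_features.csv / metabolome_*_samples.csv
Features file: feature_id, mz (Da), rt (min), mode (`positive`|`negative`),
then one abundance column per sample_id. Samples file: sample_id, treatment,
compartment (`root`|`exudate`), root_dry_mass_g (used for normalization).

## truth.json — generator ground truth
true_rr (log response ratio per variable), true_mu (turnover per treatment,
y⁻¹), affected_features (per compartment: feature_id → signed fold),
array_effects (log-scale random effects per variable and array).
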