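"""Cross-validate leakage-based hardiness against visual damage scores.

Fits the adjusted-index logistic (EL) and the quartile visual-damage logistic
(VD) for every genotype, then asks at which damage thresholds the two methods
agree: the 9x9 grid compares LT at p% leakage with LT at q% visual damage
across genotypes (correlation, bias, RMSE), and the LST is the coldest tested
temperature no stem segment failed.

Because visual damage accrues faster (a steeper curve), agreement is best in
the mid-range; the (50, 50) cell beats the extreme corners, which is why LT50
is the conventional comparison point.
"""

import warnings

import numpy as np

from cryoleak import (
    LeakageSeries,
    SimConfig,
    fit_loglogistic,
    lowest_survival_temperature,
    simulate_leakage_experiment,
    simulate_visual_damage,
    standardize_dataset,
    threshold_grid,
)

warnings.filterwarnings("ignore", category=UserWarning)

config = SimConfig(seed=17)
records, _ = simulate_leakage_experiment(config)
el_fits = {
    s.genotype: fit_loglogistic(s, "lim_c0_d100")
    for s in standardize_dataset(records, "I_adj") if s.fit_eligible()
}

vd_records = simulate_visual_damage(config)
groups: dict[tuple[str, str], list] = {}
for r in vd_records:
    groups.setdefault((r.species, r.genotype), []).append(r)
vd_fits = {}
for (sp, g), rs in groups.items():
    s = LeakageSeries(sp, g, "VD", [r.temperature_C for r in rs], [r.damage_pct for r in rs])
    if s.fit_eligible():
        vd_fits[g] = fit_loglogistic(s, "vd_c0_d100")

grid = threshold_grid(el_fits, vd_fits)
i = {int(p): k for k, p in enumerate(grid.el_thresholds)}
print("cell (EL%, VD%) -> correlation, bias °C, RMSE °C")
for p, q in [(50, 50), (20, 80), (10, 90)]:
    print(f"  ({p}, {q}): rho = {grid.correlation[i[p], i[q]]:.2f}, "
          f"bias = {grid.bias[i[p], i[q]]:+.1f}, rmse = {grid.rmse[i[p], i[q]]:.1f}")
masks = grid.masks()
ok = masks["correlation"] & masks["bias"] & masks["rmse"]
print(f"cells passing all three cutoffs (rho>0.55, |bias|<5, rmse<7): {ok.sum()}/81")

by_species: dict[str, list] = {}
for r in vd_records:
    by_species.setdefault(r.species, []).append(r)
lsts = {sp: lowest_survival_temperature(rs) for sp, rs in sorted(by_species.items())}
shown = {sp: v for sp, v in list(lsts.items())[:4]}
print("LST by species (first 4):", {k: f"{v:.0f}" if v is not None else "undef"
                                    for k, v in shown.items()})
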