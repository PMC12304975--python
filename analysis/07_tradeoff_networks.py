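"""Carbon-investment trade-offs: Pearson correlation networks over array
means (|r| >= 0.5), per treatment and pooled, plus slopes of the key
variable pairs and the exact array-level permutation test of the treatment
effect on C exudation.

Output: results/network_{pooled,ambient,elevated}.csv, results/tradeoffs.json
"""

import json

import pandas as pd

from rhizoface.exudation import exudation_rates
from rhizoface.mycorrhiza import production_rate
from rhizoface.pipeline import KEY_PAIRS, NETWORK_VARIABLES, array_mean_table
from rhizoface.root_traits import derive_traits
from rhizoface.stats import array_permutation_test, correlation_network, pairwise_slope

indir = "results/dataset"
rates = exudation_rates(pd.read_csv(f"{indir}/exudates.csv"))
traits = derive_traits(pd.read_csv(f"{indir}/root_traits.csv"))
bags = pd.read_csv(f"{indir}/bags.csv")
production = production_rate(bags[bags["duration_class"] == "3mo"])

tab = array_mean_table({
    "c_exudation": (rates, "C_rate_ug_g_d"),
    "n_exudation": (rates, "N_rate_ug_g_d"),
    "srl": (traits, "srl_m_per_g"),
    "branching": (traits, "branching_per_mm"),
    "ecm_production": (production, "production_ug_g_d"),
})

out = {"slopes": [pairwise_slope(tab, x, y) for x, y in KEY_PAIRS]}
for name, sub in (("pooled", tab), ("ambient", tab[tab["treatment"] == "ambient"]),
                  ("elevated", tab[tab["treatment"] == "elevated"])):
    net = correlation_network(sub[list(NETWORK_VARIABLES)], threshold=0.5)
    net.to_edge_csv(f"results/network_{name}.csv")
    out[f"n_edges_{name}"] = len(net.edges)
    print(f"{name}: {len(net.edges)} edges at |r| >= 0.5")
for s in out["slopes"]:
    print(f"  slope {s['y']} ~ {s['x']}: {s['slope']:+.3f} (r={s['r']:+.2f}, p={s['p']:.3f})")

e = tab.loc[tab["treatment"] == "elevated", "c_exudation"]
a = tab.loc[tab["treatment"] == "ambient", "c_exudation"]
perm = array_permutation_test(e, a)
out["c_exudation_array_permutation_p"] = perm.p_value
print(f"array-level permutation test, C exudation: p = {perm.p_value:.3f} ({perm.note})")

with open("results/tradeoffs.json", "w") as fh:
    json.dump(out, fh, indent=2, sort_keys=True)
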