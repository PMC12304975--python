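"""Root morphology and chemistry: SRL, branching frequency, tissue C:N.

Output: results/root_traits_derived.csv, results/root_traits_summary.csv
"""

from pathlib import Path

import pandas as pd

from rhizoface.root_traits import derive_traits
from rhizoface.stats import skew_kurtosis

traits = derive_traits(pd.read_csv(Path("results/dataset/root_traits.csv")))
traits.to_csv("results/root_traits_derived.csv", index=False)

summary = (
    traits.groupby(["timepoint", "treatment"], sort=False)[
        ["srl_m_per_g", "branching_per_mm", "tissue_cn"]
    ]
    .mean()
    .reset_index()
)
summary.to_csv("results/root_traits_summary.csv", index=False)
print(summary.round(3).to_string(index=False))

skew, kurt = skew_kurtosis(traits["branching_per_mm"])
print(f"branching normality screen: skewness {skew:.2f}, excess kurtosis {kurt:.2f}")
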