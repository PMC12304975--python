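"""Untargeted metabolomics of roots and exudates: ordination, per-ion
treatment tests, accumulation/depletion classification, and shared-ion
matching between compartments.

Output: results/metabolome_{root,exudate}_results.csv,
        results/metabolome_summary.json, results/ordination.svg
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from rhizoface.metabolomics import (
    FeatureMatrix,
    classification_summary,
    normalize_and_scale,
    pca_ordination,
    per_feature_test,
    shared_features,
)

fms = {
    name: FeatureMatrix.from_csv(
        f"results/dataset/metabolome_{name}s_features.csv",
        f"results/dataset/metabolome_{name}s_samples.csv",
    )
    for name in ("root", "exudate")
}

results, summaries = {}, {}
for name, fm in fms.items():
    res = per_feature_test(fm, alpha=0.05)
    res.to_csv(f"results/metabolome_{name}_results.csv", index=False)
    results[name] = res
    summaries[name] = classification_summary(res)
    s = summaries[name]
    print(f"{name}s: {s['n_significant']}/{s['n_features']} ions significant "
          f"({s['pct_significant']:.1f}%): {s['n_accumulated']} accumulated, "
          f"{s['n_depleted']} depleted")

shared = shared_features(fms["root"], fms["exudate"],
                         root_results=results["root"], exudate_results=results["exudate"])
print(f"shared ions between compartments: {shared['n_shared']} "
      f"({shared['n_shared_significant']} significant in at least one compartment)")

fig, axes = plt.subplots(1, 2, figsize=(9, 4))
for ax, (name, fm) in zip(axes, fms.items()):
    transformed, dropped = normalize_and_scale(fm)
    ord_ = pca_ordination(transformed, n_components=2)
    scores = ord_["scores"]
    for trt, color in (("ambient", "tab:blue"), ("elevated", "tab:orange")):
        sub = scores[scores["treatment"] == trt]
        ax.scatter(sub["Dim1"], sub["Dim2"], s=18, color=color, label=trt)
    ax.set_xlabel(f"Dim1 ({ord_['explained_pct'][0]:.1f}%)")
    ax.set_ylabel(f"Dim2 ({ord_['explained_pct'][1]:.1f}%)")
    ax.set_title(f"{name} metabolome")
    ax.legend(frameon=False, fontsize=8)
fig.tight_layout()
fig.savefig("results/ordination.svg")

summaries["shared"] = {
    "n_shared": shared["n_shared"],
    "n_shared_significant": shared["n_shared_significant"],
}
with open("results/metabolome_summary.json", "w") as fh:
    json.dump(summaries, fh, indent=2, sort_keys=True)
print("wrote results/metabolome_summary.json, results/ordination.svg")
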