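"""Generate the synthetic FACE study used by the downstream analyses.

Emulates the field design — 3 elevated and 3 ambient arrays, four seasonal
campaigns, 6 exudation pseudoreplicates and 5 ingrowth-bag locations per
array, staggered 3/6/12-month bags — at the study's effect sizes, and
writes the five input tables plus the ground-truth record.

Output: results/dataset/
"""

from pathlib import Path

from rhizoface.config import DesignSpec, EffectSpec, MetabolomeSpec
from rhizoface.synthetic import generate_dataset, write_dataset

SEED = 20200519  # installation date of the first ingrowth bags

outdir = Path("results/dataset")
tables, truth = generate_dataset(DesignSpec(seed=SEED), EffectSpec(), MetabolomeSpec())
write_dataset(tables, truth, outdir)

ex = tables["exudates"]
print(f"wrote {outdir}/")
print(f"  exudate incubations: {(~ex['is_blank']).sum()} root rows, {ex['is_blank'].sum()} blanks")
print(f"  root trait scans:    {len(tables['root_traits'])}")
print(f"  ingrowth bags:       {len(tables['bags'])}")
print(f"  metabolome:          {tables['metabolome_exudates'].n_features} exudate ions, "
      f"{tables['metabolome_roots'].n_features} root ions")
print(f"  ground-truth RRs:    { {k: round(v, 3) for k, v in truth.true_rr.items()} }")
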