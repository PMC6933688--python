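"""Starting-assay density sweep: how many markers does imputation need?

Masks the purebred test set to each nested commercial-assay density and
imputes to the union marker set against the composite panel.  Accuracy
should rise monotonically with starting density, with the largest jump
leaving the ultra-low-density chip, and the rare-variant penalty shrinking
as density grows.
"""

import pandas as pd

from common import get_study, outpath
from herdimpute import benchmark

study = get_study()
sweep = benchmark.density_sweep(study)

rows = [
    {
        "assay": name,
        "starting_density": run["n_typed"],
        "mean_iqs": round(run["mean_iqs"], 4),
        "mean_iqs_low_maf": round(run["mean_iqs_low_maf"], 4),
        "sd_iqs": round(float(run["va"]["iqs"].std()), 4),
    }
    for name, run in sweep.items()
]
tbl = pd.DataFrame(rows)
tbl.to_csv(outpath("density_sweep.tsv"), sep="\t", index=False)
print(tbl.to_string(index=False))

jumps = tbl["mean_iqs"].diff().dropna()
print(f"\nlargest accuracy jump: {jumps.max():+.4f} "
      f"({tbl['assay'][jumps.idxmax() - 1]} -> {tbl['assay'][jumps.idxmax()]})")
print(f"wrote {outpath('density_sweep.tsv')}")
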