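"""Relate GRM similarity to the reference with individual imputation accuracy.

Computes the standardized GRM over the common-chip markers of all test and
reference samples, takes breed-filtered row means for each test sample,
and joins per-individual imputation accuracy (raw r) from the 50K run.
Breeds with sparse reference representation should show depressed and more
variable accuracy regardless of raw relatedness.
"""

from common import get_study, outpath
from herdimpute import benchmark

study = get_study()
sweep = benchmark.density_sweep(study, ("SNP50",))
ia = sweep["SNP50"]["ia"]
rel = benchmark.relatedness_report(study, ia)
rel.to_csv(outpath("relatedness.tsv"), sep="\t", index=False)

by_breed = rel.groupby("breed").agg(
    n=("sample_id", "size"),
    mean_similarity=("similarity", "mean"),
    mean_r=("r_raw", "mean"),
    min_r=("r_raw", "min"),
)
print(by_breed.round(4).to_string())

corr = rel.dropna(subset=["r_raw"])
for breed, grp in corr.groupby("breed"):
    if len(grp) >= 5 and grp["similarity"].std() > 0 and grp["r_raw"].std() > 0:
        c = grp["similarity"].corr(grp["r_raw"])
        print(f"similarity vs accuracy correlation within {breed}: {c:+.3f}")
print(f"\nwrote {outpath('relatedness.tsv')}")
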