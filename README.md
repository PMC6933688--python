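# herdimpute

Evaluation framework for genotype imputation accuracy in multi-breed
livestock SNP panels.

Commercial cattle genotyping spans assays from a few thousand to ~780K
markers, and research assays add hundreds of thousands of rare, putatively
functional variants. Imputing everything to the union of the two
high-density research chips (the "850K" target) makes low-density data
usable for QTL mapping and as a stepping stone to sequence-level
imputation — but only if the imputation is accurate, and accuracy at rare
variants is exactly where the usual metrics mislead. This package is for
quantitative geneticists who want to benchmark imputation designs
(within-breed vs multi-breed composite reference panels, one-round vs
two-round strategies, starting assay density) with metrics that stay
honest at low minor allele frequency.

Because the underlying animal genotype panels are proprietary, the package
ships a synthetic-data module that emulates their statistical structure:
breed differentiation under the Balding–Nichols model
(p_breed ~ Beta(p(1−F)/F, (1−p)(1−F)/F)), within-breed haplotype sharing
via founder mosaics, crossbred individuals, a common-variant "HD"-like
chip, a rare-shifted "F250"-like chip, nested lower-density chips, and
~0.2% platform genotyping error.

## The statistics

For each variant, with truth and imputed genotypes coded 0/1/2 and their
3×3 contingency table *n<sub>gh</sub>*:

- **Concordance** P₀ = Σ n<sub>gg</sub> / N.
- **IQS** (imputation quality score) = (P₀ − P<sub>c</sub>)/(1 − P<sub>c</sub>),
  where P<sub>c</sub> = Σ<sub>g</sub> row<sub>g</sub>·col<sub>g</sub> / N² is the
  concordance expected from the marginals alone — a per-variant Cohen's
  kappa. A marker imputed all-homozygous at MAF 0.03 can score
  concordance 0.97 and IQS 0.0; IQS is the honest number.
- **Pearson r** per variant and per individual (raw, and centered by
  subtracting 2·MAF per marker), with an explicit undefined sentinel when
  either side is constant.
- **Error taxonomy**: false heterozygotes (AA/BB → AB), false homozygotes
  (AB → AA/BB), complete discordances (AA ↔ BB).
- **Standardized GRM** G<sub>jk</sub> = (1/m) Σ<sub>i</sub>
  (x<sub>ij</sub>−2p<sub>i</sub>)(x<sub>ik</sub>−2p<sub>i</sub>)/(2p<sub>i</sub>(1−p<sub>i</sub>))
  with breed-filtered row means as a reference-representation diagnostic.

Imputation itself is a desk-scale Li–Stephens haplotype-copying HMM
(forward–backward over K reference haplotypes, per chromosome) standing in
for production tools such as Minimac/Eagle.

## Worked example

```python
from herdimpute import benchmark

study = benchmark.build_study(seed=1)        # 5,000 markers, 615 reference samples
sweep = benchmark.density_sweep(study)       # mask -> impute -> score per assay
for name, run in sweep.items():
    print(name, run["n_typed"], round(run["mean_iqs"], 4))
```

prints

```
ULD 34 0.3338
LD 89 0.6552
SNP50 235 0.8322
90K 375 0.8555
GGPHD 666 0.8709
```

— mean per-variant IQS rises monotonically with starting assay density,
with the largest jump when leaving the ultra-low-density chip; at this
scale a 50K-like density captures most of the achievable accuracy. The
composite multi-breed panel beats the within-breed panel for the
mixed-ancestry test group (`benchmark.panel_comparison(study)`: mean IQS
0.833 vs 0.798, paired t = 9.9), and one-round imputation edges two-round
at rare markers exclusive to the common chip
(`benchmark.strategy_comparison(study)`: 0.794 vs 0.787).

The numbered scripts under `analysis/` run the full battery and write
tables to `results/`:

```bash
cd analysis
python 01_simulate_panel.py      # panel + assay MAF spectra
python 02_metric_comparison.py   # concordance vs r vs IQS by MAF bin
python 03_panel_comparison.py    # breed vs composite reference
python 04_strategy_comparison.py # one-round vs two-round
python 05_density_sweep.py       # starting-density sweep
python 06_region_scan.py         # misplaced-marker localization
python 07_relatedness.py         # GRM similarity vs accuracy
```

There is also a CLI (`herdimpute simulate|define-assays|qc|mask|impute|
evaluate|build-panel|grm|compare|run`) for file-based workflows; `herdimpute
run --seed 1 --out exp/` executes the whole pipeline from one config.

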