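"""Desk-scale benchmark study: the end-to-end experiment battery.

Builds one seeded synthetic multi-breed panel and runs the evaluation
battery on it: starting-density sweep across the nested commercial assays,
breed-reference vs composite-reference comparison on admixed individuals,
one-round vs two-round strategy comparison at rare common-chip-exclusive
markers, a marker-misplacement region scan, and GRM relatedness
diagnostics.  The analysis drivers, the acceptance script and the
integration tests all run through these functions so every reported number
is recomputed from scratch.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import similarity_to_reference, standardized_grm
from .lsimpute import HmmParams, ImputationResult, impute_samples
from .maskgen import MaskedTestSet, build_masked_test_set, select_test_individuals
from .metrics import (
    PanelComparison,
    binned_summary,
    compare_panels,
    per_individual_accuracy,
    per_variant_accuracy,
    region_scan,
)
from .refpanel import (
    CompositePanel,
    PanelPair,
    build_breed_panel,
    build_composite_one_round,
    build_panel_pair,
    run_one_round,
    run_two_round,
)
from .simpop import (
    AssayDefinition,
    HaplotypePanel,
    SimConfig,
    default_assay_specs,
    define_assays,
    simulate_panel,
)

NESTED_ASSAYS = ("ULD", "LD", "SNP50", "90K", "GGPHD")


def stage_seed(seed: int, stage: str) -> int:
    """Expand a global seed into a stable per-stage seed."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31)


@dataclass
class Study:
    """One simulated panel plus the shared reference infrastructure."""

    cfg: SimConfig
    seed: int
    panel: HaplotypePanel
    assays: dict[str, AssayDefinition]
    test_ids: list[str]
    reference_ids: list[str]
    reference: HaplotypePanel
    pair: PanelPair
    composite: CompositePanel
    params: HmmParams
    panel_maf: np.ndarray  # panel-wide MAF aligned to panel markers

    def maf_for(self, result: ImputationResult) -> np.ndarray:
        idx = pd.Index(self.panel.marker_map["id"]).get_indexer(
            result.marker_map["id"]
        )
        return self.panel_maf[idx]

    def purebred_test_ids(self) -> list[str]:
        return [s for s in self.test_ids if self.panel.breed_of[s] != "CROSS"]

    def taur_test_ids(self, min_reference_haplotypes: int = 100) -> list[str]:
        """Purebred test samples from adequately represented breeds.

        Mirrors restricting density/strategy analyses to breeds whose
        reference representation is large enough to draw conclusions from;
        sparsely represented breeds are still evaluated by the relatedness
        report.
        """
        ref_haps: dict[str, int] = {}
        for s in self.reference_ids:
            b = self.reference.breed_of[s]
            ref_haps[b] = ref_haps.get(b, 0) + 2
        return [
            s
            for s in self.purebred_test_ids()
            if ref_haps.get(self.panel.breed_of[s], 0) >= min_reference_haplotypes
        ]

    def admixed_test_ids(self) -> list[str]:
        return [s for s in self.test_ids if self.panel.breed_of[s] == "CROSS"]

    def masked(self, test_ids: list[str], assay_name: str) -> MaskedTestSet:
        return build_masked_test_set(
            self.panel,
            test_ids,
            self.assays[assay_name],
            error_rate=self.cfg.genotype_error_rate,
            seed=stage_seed(self.seed, f"mask-{assay_name}"),
        )

    def score(self, masked: MaskedTestSet, result: ImputationResult) -> pd.DataFrame:
        return per_variant_accuracy(masked.truth, result, self.maf_for(result))

    def score_individuals(
        self, masked: MaskedTestSet, result: ImputationResult
    ) -> pd.DataFrame:
        df = per_individual_accuracy(masked.truth, result, self.maf_for(result))
        df["breed"] = [self.panel.breed_of[s] for s in df["sample_id"]]
        return df


def build_study(
    seed: int = 1,
    cfg: SimConfig | None = None,
    params: HmmParams | None = None,
) -> Study:
    """Simulate the panel and build the composite reference once.

    The benchmark uses the whole desk-scale reference for copying (no
    haplotype subsampling), mirroring how production imputation consumes
    its full panel.
    """
    if cfg is None:
        cfg = SimConfig(seed=stage_seed(seed, "simulate"))
    panel = simulate_panel(cfg)
    assays = {
        a.name: a
        for a in define_assays(
            panel, default_assay_specs(panel.n_markers), seed=stage_seed(seed, "assays")
        )
    }
    test_ids, reference_ids = select_test_individuals(
        panel.sample_ids,
        panel.breed_of,
        seed=stage_seed(seed, "select"),
        eligible=panel.test_candidates,
    )
    reference = panel.subset_samples(reference_ids)
    if params is None:
        params = HmmParams(max_reference_haplotypes=2 * reference.n_samples + 2)
    pair = build_panel_pair(
        reference,
        assays["HD"],
        assays["F250"],
        # the breed used for the breed-panel contrast has the most complete
        # dual-assay coverage, as in the real reference composition
        overlap_by_breed={"GEL": 0.35},
        seed=stage_seed(seed, "panel-pair"),
    )
    composite = build_composite_one_round(
        pair, params, seed=stage_seed(seed, "composite")
    )
    panel_maf = panel.to_genotype_matrix().maf()
    return Study(
        cfg=cfg,
        seed=seed,
        panel=panel,
        assays=assays,
        test_ids=test_ids,
        reference_ids=reference_ids,
        reference=reference,
        pair=pair,
        composite=composite,
        params=params,
        panel_maf=panel_maf,
    )


def density_sweep(
    study: Study, assay_names: tuple[str, ...] = NESTED_ASSAYS
) -> dict[str, dict]:
    """Impute the purebred test set from each nested starting assay.

    One-round imputation against the composite panel; returns per-variant
    and per-individual tables plus the binned summary for each density.
    """
    out: dict[str, dict] = {}
    test = study.taur_test_ids()
    for name in assay_names:
        masked = study.masked(test, name)
        res = run_one_round(
            masked, study.composite, study.params,
            seed=stage_seed(study.seed, f"impute-{name}"),
        )
        va = study.score(masked, res)
        ia = study.score_individuals(masked, res)
        out[name] = {
            "assay": name,
            "n_typed": study.assays[name].n_markers,
            "va": va,
            "ia": ia,
            "binned": binned_summary(va),
            "mean_iqs": float(va["iqs"].mean()),
            "mean_iqs_low_maf": float(va.loc[va["maf"] < 0.1, "iqs"].mean()),
        }
    return out


def panel_comparison(study: Study, breed: str = "GEL", start: str = "SNP50") -> dict:
    """Breed-reference vs composite-reference imputation, breed-majority test.

    The test group is every test individual whose majority ancestry is the
    given breed — purebreds plus crossbreds with at least half their genome
    from it, the analogue of an open-herdbook breed dataset with mixed
    ancestry.  The breed panel is the composite restricted to that breed's
    samples, so the composite is a strict haplotype superset of it.
    """
    test = [
        s
        for s in study.test_ids
        if study.panel.admixture.get(s, {}).get(breed, 0.0) >= 0.5
        or study.panel.breed_of[s] == breed
    ]
    if not test:
        raise ValueError(f"no test individuals with majority {breed} ancestry")
    masked = study.masked(test, start)
    breed_panel = build_breed_panel(study.composite.panel, breed)
    res_br = impute_samples(
        masked, breed_panel, study.params, seed=stage_seed(study.seed, "impute-br")
    )
    res_cr = run_one_round(
        masked, study.composite, study.params, seed=stage_seed(study.seed, "impute-cr")
    )
    va_br = study.score(masked, res_br)
    va_cr = study.score(masked, res_cr)
    common = va_br.merge(va_cr[["marker_id"]], on="marker_id")["marker_id"]
    va_br = va_br[va_br["marker_id"].isin(set(common))].reset_index(drop=True)
    va_cr = va_cr[va_cr["marker_id"].isin(set(common))].reset_index(drop=True)
    comp = compare_panels(va_br, va_cr)
    rare = va_br["maf"].to_numpy() < 0.05
    gain = va_cr["iqs"].to_numpy() - va_br["iqs"].to_numpy()
    return {
        "breed": breed,
        "va_br": va_br,
        "va_cr": va_cr,
        "comparison": comp,
        "mean_iqs_br": float(va_br["iqs"].mean()),
        "mean_iqs_cr": float(va_cr["iqs"].mean()),
        "gain_rare": float(gain[rare].mean()) if rare.any() else float("nan"),
        "gain_common": float(gain[~rare].mean()) if (~rare).any() else float("nan"),
    }


def strategy_comparison(study: Study, start: str = "SNP50") -> dict:
    """One-round vs two-round imputation of the purebred test set.

    The headline contrast is at rare markers exclusive to the common
    high-density assay, where the composite's cross-imputed haplotypes are
    the only extra information the one-round strategy has.
    """
    test = study.taur_test_ids()
    masked = study.masked(test, start)
    res_one = run_one_round(
        masked, study.composite, study.params, seed=stage_seed(study.seed, "one-round")
    )
    res_two = run_two_round(
        masked, study.pair, study.params, seed=stage_seed(study.seed, "two-round")
    )
    va_one = study.score(masked, res_one)
    va_two = study.score(masked, res_two)
    b_ids = set(study.assays["F250"].marker_ids)
    a_excl = set(study.assays["HD"].marker_ids) - b_ids
    sub_one = va_one[va_one["marker_id"].isin(a_excl)].set_index("marker_id")
    sub_two = va_two[va_two["marker_id"].isin(a_excl)].set_index("marker_id")
    common = sub_one.index.intersection(sub_two.index)
    sub_one, sub_two = sub_one.loc[common], sub_two.loc[common]
    rare = sub_one["maf"].to_numpy() < 0.05
    return {
        "va_one": va_one,
        "va_two": va_two,
        "mean_iqs_one": float(va_one["iqs"].mean()),
        "mean_iqs_two": float(va_two["iqs"].mean()),
        "rare_a_excl_one": float(sub_one.loc[rare, "iqs"].mean()),
        "rare_a_excl_two": float(sub_two.loc[rare, "iqs"].mean()),
        "n_rare_a_excl": int(rare.sum()),
    }


def _swap_columns(panel: HaplotypePanel, cols_a: np.ndarray, cols_b: np.ndarray) -> HaplotypePanel:
    alleles = panel.alleles.copy()
    alleles[:, cols_a], alleles[:, cols_b] = (
        panel.alleles[:, cols_b],
        panel.alleles[:, cols_a],
    )
    return HaplotypePanel(
        alleles=alleles,
        marker_map=panel.marker_map,
        sample_ids=panel.sample_ids,
        breed_of=panel.breed_of,
        founder_freqs=panel.founder_freqs,
        admixture=panel.admixture,
        test_candidates=panel.test_candidates,
    )


def misplacement_scan(
    study: Study, block_size: int = 30, start: str = "GGPHD", window: int = 50
) -> dict:
    """Region scan on a panel with a deliberately position-shuffled block.

    A block of contiguous withheld markers on chromosome 1 has its genotype
    columns swapped with scattered distant markers on chromosome 2,
    emulating probe sequences mapped to the wrong genomic position; the
    whole study (reference and test) inherits the corruption, exactly as a
    wrong map file would propagate.  The rest of the run is kept clean —
    densest starting assay, no genotyping error, observed-genotype
    reference — so clusters of breaching markers localize the corruption
    rather than background imputation noise.
    """
    panel = study.panel
    assay_ids = set(study.assays[start].marker_ids)
    mm = panel.marker_map
    chr1 = mm[mm["chrom"] == "1"].index.to_numpy()
    withheld1 = np.array([i for i in chr1 if mm.iloc[i]["id"] not in assay_ids])
    # contiguous run of withheld markers near the middle of chromosome 1
    mid = len(withheld1) // 2
    block = withheld1[mid : mid + block_size]
    chr2 = mm[mm["chrom"] == "2"].index.to_numpy()
    withheld2 = np.array([i for i in chr2 if mm.iloc[i]["id"] not in assay_ids])
    rng = np.random.default_rng(stage_seed(study.seed, "misplace"))
    partners = np.sort(rng.choice(withheld2, size=len(block), replace=False))

    corrupted = _swap_columns(panel, block, partners)
    reference = corrupted.subset_samples(study.reference_ids)
    test = study.taur_test_ids()
    masked = build_masked_test_set(
        corrupted, test, study.assays[start], error_rate=0.0,
        seed=stage_seed(study.seed, f"mask-{start}"),
    )
    res = impute_samples(
        masked, reference, study.params,
        seed=stage_seed(study.seed, "impute-misplace"),
    )
    va = per_variant_accuracy(masked.truth, res, study.maf_for(res))
    flagged = region_scan(va, window=window)
    block_ids = mm.iloc[block]["id"].tolist()
    block_pos = (int(mm.iloc[block[0]]["pos"]), int(mm.iloc[block[-1]]["pos"]))
    overlap = flagged[
        (flagged["chrom"] == "1")
        & (flagged["end_pos"] >= block_pos[0])
        & (flagged["start_pos"] <= block_pos[1])
    ]
    return {
        "va": va,
        "flagged": flagged,
        "block_marker_ids": block_ids,
        "block_pos": block_pos,
        "n_flagged": len(flagged),
        "block_flagged": len(overlap) > 0,
    }


def relatedness_report(study: Study, ia: pd.DataFrame | None = None) -> pd.DataFrame:
    """Breed-filtered GRM similarity of each test sample to the reference.

    Frequencies come from the combined test+reference genotypes at the
    common-chip markers (everyone's observed density).  When a
    per-individual accuracy table is supplied, its raw r is joined in so
    similarity can be related to imputation accuracy.
    """
    hd = study.assays["HD"]
    everyone = study.panel.subset_markers(hd.marker_ids).to_genotype_matrix()
    grm = standardized_grm(everyone)
    rows = []
    for sid in study.test_ids:
        breed = max(
            study.panel.admixture.get(sid, {study.panel.breed_of[sid]: 1.0}).items(),
            key=lambda kv: kv[1],
        )[0]
        try:
            sim = similarity_to_reference(
                grm,
                [sid],
                study.reference_ids,
                breed_of=study.panel.breed_of,
                breed=breed,
                admixture=study.panel.admixture,
            )[sid]
        except ValueError:
            sim = float("nan")
        rows.append({"sample_id": sid, "breed": breed, "similarity": sim})
    df = pd.DataFrame(rows)
    if ia is not None:
        df = df.merge(ia[["sample_id", "r_raw", "total_errors"]], on="sample_id", how="left")
    return df
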