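"""End-to-end experiment orchestration with config, manifest and reports.

``run_experiment`` wires the stages together — simulate, QC, define assays,
split test/reference, build panels, impute under the configured strategies,
score, and report — writing every artifact under one output directory.  A
single global seed expands deterministically into per-stage seeds, so
re-running the same config reproduces every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import benchmark
from .benchmark import Study, stage_seed
from .gio import qc_filter, write_phased_vcf, write_sample_metadata, write_vcf
from .grm import write_grm
from .lsimpute import HmmParams, write_imputed_vcf
from .maskgen import write_id_list
from .metrics import binned_summary
from .simpop import (
    AdmixtureSpec,
    BreedSpec,
    SimConfig,
    write_assay_list,
)


@dataclass
class ExperimentConfig:
    """One experiment: simulation, assays, masking, HMM and strategy list."""

    sim: SimConfig = field(default_factory=SimConfig)
    hmm: HmmParams | None = None
    strategies: list[str] = field(
        default_factory=lambda: ["one-round-CR", "two-round-CR", "one-round-BR"]
    )
    breed_reference: str = "GEL"
    start_assay: str = "SNP50"
    max_per_breed: int = 50
    max_breed_fraction: float = 0.5
    seed: int = 1

    def validate(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy required")
        known = {"one-round-CR", "two-round-CR", "one-round-BR"}
        bad = set(self.strategies) - known
        if bad:
            raise ValueError(f"unknown strategies: {sorted(bad)}")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = doc.pop("sim", {})
        breeds = sim_doc.pop("breeds", None)
        admixed = sim_doc.pop("admixed_samples", None)
        sim = SimConfig(**sim_doc)
        if breeds is not None:
            sim.breeds = [BreedSpec(**b) for b in breeds]
        if admixed is not None:
            sim.admixed_samples = [
                AdmixtureSpec(a["name"], tuple((k, v) for k, v in a["proportions"].items()))
                for a in admixed
            ]
        hmm_doc = doc.pop("hmm", None)
        hmm = HmmParams(**hmm_doc) if hmm_doc else None
        return cls(sim=sim, hmm=hmm, **doc)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "sim": asdict(self.sim),
                "hmm": asdict(self.hmm) if self.hmm else None,
                "strategies": self.strategies,
                "breed_reference": self.breed_reference,
                "start_assay": self.start_assay,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """Run every configured strategy end to end; returns the report bundle."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"{time.strftime('%H:%M:%S')}\t{name}\tseed={stage_seed(cfg.seed, name)}")

    try:
        stage("simulate")
        study = benchmark.build_study(seed=cfg.seed, cfg=cfg.sim, params=cfg.hmm)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/build' failed: {exc}") from exc

    write_phased_vcf(out / "panel.vcf", study.panel)
    write_sample_metadata(out / "samples.tsv", study.panel)
    for name, assay in study.assays.items():
        write_assay_list(out / f"assay_{name}.txt", assay)
    write_id_list(out / "test_ids.txt", study.test_ids)
    write_id_list(out / "reference_ids.txt", study.reference_ids)

    stage("qc")
    qc_in = study.panel.to_genotype_matrix()
    _, qc_log = qc_filter(qc_in)
    qc_log.to_csv(out / "qc_log.tsv", sep="\t", index=False)

    test = study.purebred_test_ids()
    masked = study.masked(test, cfg.start_assay)
    write_vcf(out / f"masked_{cfg.start_assay}.vcf", masked.observed)

    bundle: dict = {"strategies": {}}
    for strat in cfg.strategies:
        stage(strat)
        try:
            if strat == "one-round-CR":
                from .refpanel import run_one_round

                res = run_one_round(
                    masked, study.composite, study.params,
                    seed=stage_seed(cfg.seed, strat),
                )
            elif strat == "two-round-CR":
                from .refpanel import run_two_round

                res = run_two_round(
                    masked, study.pair, study.params, seed=stage_seed(cfg.seed, strat)
                )
            else:  # one-round-BR
                from .lsimpute import impute_samples
                from .refpanel import build_breed_panel

                breed_panel = build_breed_panel(study.composite.panel, cfg.breed_reference)
                res = impute_samples(
                    masked, breed_panel, study.params, seed=stage_seed(cfg.seed, strat)
                )
        except Exception as exc:
            raise RuntimeError(f"stage {strat!r} failed: {exc}") from exc
        va = study.score(masked, res)
        ia = study.score_individuals(masked, res)
        write_imputed_vcf(out / f"imputed_{strat}.vcf", res)
        va.drop(columns=[]).to_csv(out / f"per_variant_{strat}.tsv", sep="\t", index=False)
        ia.to_csv(out / f"per_individual_{strat}.tsv", sep="\t", index=False)
        binned_summary(va).to_csv(out / f"binned_{strat}.tsv", sep="\t", index=False)
        bundle["strategies"][strat] = {"va": va, "ia": ia}

    if {"one-round-CR", "one-round-BR"} <= set(bundle["strategies"]):
        from .metrics import compare_panels

        va_cr = bundle["strategies"]["one-round-CR"]["va"]
        va_br = bundle["strategies"]["one-round-BR"]["va"]
        common = set(va_cr["marker_id"]) & set(va_br["marker_id"])
        a = va_br[va_br["marker_id"].isin(common)].reset_index(drop=True)
        b = va_cr[va_cr["marker_id"].isin(common)].reset_index(drop=True)
        comp = compare_panels(a, b)
        comp.to_frame().to_csv(out / "panel_comparison.tsv", sep="\t", index=False)
        bundle["panel_comparison"] = comp

    stage("region-scan")
    from .metrics import region_scan

    first = next(iter(bundle["strategies"].values()))["va"]
    scan = region_scan(first)
    scan.to_csv(out / "region_scan.tsv", sep="\t", index=False)
    bundle["region_scan"] = scan

    stage("grm")
    ia0 = next(iter(bundle["strategies"].values()))["ia"]
    rel = benchmark.relatedness_report(study, ia0)
    rel.to_csv(out / "grm_similarity.tsv", sep="\t", index=False)
    hd_gm = study.panel.subset_markers(study.assays["HD"].marker_ids).to_genotype_matrix()
    from .grm import standardized_grm

    write_grm(out / "grm", standardized_grm(hd_gm))
    bundle["relatedness"] = rel

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in cfg.strategies},
        "n_markers": int(study.panel.n_markers),
        "n_reference_samples": len(study.reference_ids),
        "n_test_samples": len(test),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    bundle["manifest"] = manifest
    bundle["study"] = study
    return bundle


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "herdimpute": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
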