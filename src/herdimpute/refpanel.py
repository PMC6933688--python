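"""Within-breed and multi-breed composite reference panels.

Reference animals are genotyped on the common-variant assay (A), on the
rare-enriched assay (B), or on both (the overlap that bridges the two
marker sets).  A composite "one-round" panel fills each sample's missing
assay by reciprocal cross-imputation, giving a complete panel over the
union marker set that mixes observed and imputed genotypes; the "two-round"
strategy instead imputes test samples sequentially against references that
contain only observed genotypes (first to the A marker set, then the
B-exclusive markers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lsimpute import (
    IMPUTED,
    OBSERVED,
    HmmParams,
    ImputationResult,
    best_guess_from_dosage,
    impute_haplotype_panel,
    impute_samples,
)
from .maskgen import MaskedTestSet
from .simpop import AssayDefinition, HaplotypePanel


@dataclass
class PanelPair:
    """Reference samples split by assay membership over two assays.

    ``panel`` holds the (simulated) haplotypes of all reference samples over
    the full marker set; which entries count as *observed* is defined by the
    assay membership lists.  Samples in both lists form the overlap.
    """

    panel: HaplotypePanel
    assay_a: AssayDefinition
    assay_b: AssayDefinition
    a_samples: list[str]
    b_samples: list[str]

    def __post_init__(self) -> None:
        have = set(self.panel.sample_ids)
        for s in list(self.a_samples) + list(self.b_samples):
            if s not in have:
                raise KeyError(f"sample {s} not in reference panel")
        if set(self.a_samples) | set(self.b_samples) != have:
            raise ValueError("every reference sample must carry at least one assay")

    @property
    def overlap_samples(self) -> list[str]:
        b = set(self.b_samples)
        return [s for s in self.a_samples if s in b]

    def union_marker_ids(self) -> list[str]:
        union = set(self.assay_a.marker_ids) | set(self.assay_b.marker_ids)
        return [m for m in self.panel.marker_map["id"] if m in union]


@dataclass
class CompositePanel:
    """Union-marker reference with per-entry provenance flags."""

    panel: HaplotypePanel
    provenance: np.ndarray  # (n_samples, n_union_markers) OBSERVED/IMPUTED

    def provenance_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.provenance == IMPUTED)
        ids = self.panel.marker_map["id"].to_numpy()
        return pd.DataFrame(
            {
                "sample_id": [self.panel.sample_ids[i] for i in rows],
                "marker_id": ids[cols],
                "flag": "cross-imputed",
            }
        )


def build_breed_panel(reference: HaplotypePanel, breed: str) -> HaplotypePanel:
    """Restriction of the reference to one breed's samples."""
    ids = [s for s in reference.sample_ids if reference.breed_of[s] == breed]
    if not ids:
        raise ValueError(f"no reference samples for breed {breed!r}")
    return reference.subset_samples(ids)


def build_panel_pair(
    reference: HaplotypePanel,
    assay_a: AssayDefinition,
    assay_b: AssayDefinition,
    frac_overlap: float = 0.10,
    frac_a_only: float = 0.25,
    overlap_by_breed: dict[str, float] | None = None,
    seed: int = 0,
) -> PanelPair:
    """Assign reference samples to assay-membership groups, per breed.

    Mirrors the unequal assay coverage of real multi-breed references: a
    small dual-genotyped overlap, a minority genotyped only on the common
    chip, the rest only on the rare-enriched chip.  ``overlap_by_breed``
    overrides the dual-genotyped fraction per breed (breeds differ widely in
    dual-assay coverage).  Samples flagged as test candidates
    (dual-genotyped leftovers) always join the overlap.
    """
    if frac_overlap <= 0:
        raise ValueError("overlap fraction must be positive (bridge requirement)")
    rng = np.random.default_rng(seed)
    by_breed: dict[str, list[str]] = {}
    for s in sorted(reference.sample_ids):
        by_breed.setdefault(reference.breed_of[s], []).append(s)
    a_samples: list[str] = []
    b_samples: list[str] = []
    for breed in sorted(by_breed):
        ids = np.array(by_breed[breed])
        rng.shuffle(ids)
        forced = [s for s in ids if s in reference.test_candidates]
        rest = [s for s in ids if s not in reference.test_candidates]
        n = len(ids)
        fo = (overlap_by_breed or {}).get(breed, frac_overlap)
        n_overlap = max(1, int(round(fo * n))) if n else 0
        overlap = forced + rest[: max(0, n_overlap - len(forced))]
        remaining = rest[max(0, n_overlap - len(forced)):]
        n_a = int(round(frac_a_only * n))
        a_only = remaining[:n_a]
        b_only = remaining[n_a:]
        a_samples.extend(overlap)
        a_samples.extend(a_only)
        b_samples.extend(overlap)
        b_samples.extend(b_only)
    return PanelPair(
        panel=reference,
        assay_a=assay_a,
        assay_b=assay_b,
        a_samples=sorted(a_samples),
        b_samples=sorted(b_samples),
    )


def _hard_call(dose: np.ndarray, major_is_alt: np.ndarray) -> np.ndarray:
    """Haploid posterior -> allele; exact 0.5 goes to the panel major allele."""
    allele = (dose > 0.5).astype(np.int8)
    tie = np.isclose(dose, 0.5)
    if tie.any():
        allele[tie] = np.broadcast_to(major_is_alt, dose.shape)[tie]
    return allele


def build_composite_one_round(
    pp: PanelPair, params: HmmParams, seed: int = 0
) -> CompositePanel:
    """Reciprocal cross-imputation to a complete union-marker panel.

    A-only samples get their B-exclusive markers imputed against the
    B-genotyped haplotypes (typed at the A∩B overlap markers), and vice
    versa.  Imputed entries are hard-called to alleles and flagged
    cross-imputed; observed entries are never altered.
    """
    overlap_samples = pp.overlap_samples
    if not overlap_samples:
        raise ValueError(
            "empty A/B overlap: at least one dual-genotyped sample is needed "
            "to bridge the two assays' marker sets"
        )
    union_ids = pp.union_marker_ids()
    sub = pp.panel.subset_markers(union_ids)
    alleles = sub.alleles.copy()
    prov = np.full((sub.n_samples, sub.n_markers), OBSERVED, dtype=np.uint8)
    idx = sub.marker_index()
    a_ids = [m for m in union_ids if m in set(pp.assay_a.marker_ids)]
    b_ids = [m for m in union_ids if m in set(pp.assay_b.marker_ids)]
    shared = [m for m in a_ids if m in set(b_ids)]
    a_excl = [m for m in a_ids if m not in set(b_ids)]
    b_excl = [m for m in b_ids if m not in set(a_ids)]
    sample_pos = {s: i for i, s in enumerate(sub.sample_ids)}

    def fill(targets: list[str], ref_ids: list[str], ref_marker_ids: list[str],
             fill_ids: list[str], typed_ids: list[str], stage_seed: int) -> None:
        if not targets or not fill_ids:
            return
        ref = pp.panel.subset_samples(ref_ids).subset_markers(ref_marker_ids)
        tgt = sub.subset_samples(targets)
        typed_cols = idx.get_indexer(typed_ids)
        obs = tgt.alleles[:, typed_cols]
        dose = impute_haplotype_panel(obs, typed_ids, ref, params, stage_seed)
        fill_in_ref = ref.marker_index().get_indexer(fill_ids)
        maf_alt = ref.alleles[:, fill_in_ref].mean(axis=0)
        called = _hard_call(dose[:, fill_in_ref], (maf_alt > 0.5).astype(np.int8))
        fill_cols = idx.get_indexer(fill_ids)
        for k, s in enumerate(targets):
            i = sample_pos[s]
            alleles[2 * i, fill_cols] = called[2 * k]
            alleles[2 * i + 1, fill_cols] = called[2 * k + 1]
            prov[i, fill_cols] = IMPUTED

    b_set = set(pp.b_samples)
    a_set = set(pp.a_samples)
    a_only = [s for s in pp.a_samples if s not in b_set]
    b_only = [s for s in pp.b_samples if s not in a_set]
    fill(a_only, pp.b_samples, b_ids, b_excl, shared, seed + 11)
    fill(b_only, pp.a_samples, a_ids, a_excl, shared, seed + 13)

    composite = HaplotypePanel(
        alleles=alleles,
        marker_map=sub.marker_map,
        sample_ids=sub.sample_ids,
        breed_of=sub.breed_of,
        founder_freqs=sub.founder_freqs,
        admixture=sub.admixture,
        test_candidates=sub.test_candidates,
    )
    return CompositePanel(panel=composite, provenance=prov)


def run_one_round(
    test: MaskedTestSet,
    composite: CompositePanel | HaplotypePanel,
    params: HmmParams,
    seed: int = 0,
    phase_mode: str = "truth-phase",
) -> ImputationResult:
    """Single imputation pass against the completed composite panel."""
    panel = composite.panel if isinstance(composite, CompositePanel) else composite
    return impute_samples(test, panel, params, phase_mode=phase_mode, seed=seed)


def run_two_round(
    test: MaskedTestSet,
    pp: PanelPair,
    params: HmmParams,
    seed: int = 0,
) -> ImputationResult:
    """Sequential imputation using observed-genotype references only.

    Step 1 imputes the test samples to the full A marker set against the
    A-genotyped reference; step 2 takes the step-1 haplotypes at the A∩B
    markers as typed input and imputes the B-exclusive markers against the
    B-genotyped reference.  The merged result covers the A∪B marker union.
    """
    if test.observed_haplotypes is None:
        raise ValueError("test set carries no phase information")
    a_ids = pp.assay_a.marker_ids
    b_ids = pp.assay_b.marker_ids
    a_id_set = set(a_ids)
    if not set(test.observed.marker_map["id"]) <= a_id_set:
        raise ValueError("test assay markers must be a subset of assay A")
    shared = [m for m in a_ids if m in set(b_ids)]
    b_excl = [m for m in b_ids if m not in a_id_set]

    ref_a = pp.panel.subset_samples(pp.a_samples).subset_markers(a_ids)
    typed_ids = test.observed.marker_map["id"].tolist()
    hap1 = impute_haplotype_panel(
        test.observed_haplotypes, typed_ids, ref_a, params, seed + 21
    )

    if b_excl:
        ref_b = pp.panel.subset_samples(pp.b_samples).subset_markers(b_ids)
        shared_in_a = ref_a.marker_index().get_indexer(shared)
        maf_alt = ref_a.alleles[:, shared_in_a].mean(axis=0)
        typed2 = _hard_call(hap1[:, shared_in_a], (maf_alt > 0.5).astype(np.int8))
        # step-1 observed markers inside the overlap stay exactly observed
        obs_in_shared = [m for m in typed_ids if m in set(shared)]
        if obs_in_shared:
            pos_in_shared = pd.Index(shared).get_indexer(obs_in_shared)
            pos_in_typed = pd.Index(typed_ids).get_indexer(obs_in_shared)
            typed2[:, pos_in_shared] = test.observed_haplotypes[:, pos_in_typed]
        hap2 = impute_haplotype_panel(typed2, shared, ref_b, params, seed + 22)
        b_excl_in_b = ref_b.marker_index().get_indexer(b_excl)
        hap2_excl = hap2[:, b_excl_in_b]
    else:
        hap2_excl = np.empty((hap1.shape[0], 0))

    union_ids = pp.union_marker_ids()
    uidx = pd.Index(union_ids)
    n = len(test.sample_ids)
    dosage = np.zeros((n, len(union_ids)))
    a_cols = uidx.get_indexer(a_ids)
    dosage[:, a_cols] = hap1[0::2] + hap1[1::2]
    if b_excl:
        dosage[:, uidx.get_indexer(b_excl)] = hap2_excl[0::2] + hap2_excl[1::2]

    provenance = np.full(dosage.shape, IMPUTED, dtype=np.uint8)
    best = best_guess_from_dosage(dosage)
    obs_cols = uidx.get_indexer(typed_ids)
    obs_calls = test.observed.calls
    seen = obs_calls != -1
    dosage[:, obs_cols] = np.where(seen, obs_calls, dosage[:, obs_cols])
    best[:, obs_cols] = np.where(seen, obs_calls, best[:, obs_cols])
    provenance[:, obs_cols] = np.where(seen, OBSERVED, IMPUTED)

    mm = pp.panel.marker_map
    union_map = mm[mm["id"].isin(set(union_ids))].reset_index(drop=True)
    return ImputationResult(
        dosage=dosage,
        best_guess=best,
        provenance=provenance,
        marker_map=union_map,
        sample_ids=list(test.sample_ids),
    )
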