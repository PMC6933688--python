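"""Breed-balanced test-set sampling and genotype masking.

Test individuals are drawn per breed, capped both at an absolute maximum and
at a fraction of the breed, so masking never depletes a breed's reference
representation.  Masking restricts a sample's genotypes to one assay's
markers while retaining the withheld truth for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gio import MISSING, GenotypeMatrix
from .simpop import AssayDefinition, HaplotypePanel


@dataclass
class MaskedTestSet:
    """Observed assay-density genotypes plus the withheld full-density truth.

    ``observed_haplotypes`` carries phase for the observed genotypes
    (2 rows per sample, aligned with ``observed`` markers); it is the
    simulator's truth phase, adjusted wherever a genotyping error changed
    the unphased call.
    """

    observed: GenotypeMatrix
    truth: GenotypeMatrix
    assay: AssayDefinition
    withheld_marker_ids: list[str]
    observed_haplotypes: np.ndarray | None = None
    error_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.observed.sample_ids != self.truth.sample_ids:
            raise ValueError("observed and truth must cover the same samples in order")
        obs = set(self.observed.marker_map["id"])
        tru = set(self.truth.marker_map["id"])
        if not obs <= tru:
            raise ValueError("observed markers must be a subset of truth markers")

    @property
    def sample_ids(self) -> list[str]:
        return self.observed.sample_ids


def select_test_individuals(
    sample_ids: list[str],
    breed_of: dict[str, str],
    max_per_breed: int = 50,
    max_breed_fraction: float = 0.5,
    seed: int = 0,
    eligible: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Seeded per-breed draw of test individuals; the rest become reference.

    Per breed, min(max_per_breed, floor(max_breed_fraction * breed size),
    eligible pool size) individuals are sampled uniformly.  The fraction cap
    is computed on the breed's full size so the reference is never depleted
    below half, while only ``eligible`` samples (default: all) can be drawn
    — the analogue of restricting tests to animals genotyped on both
    high-density research assays.  Ids are sorted before drawing, so the
    split is invariant to input order.
    """
    if not sample_ids:
        raise ValueError("no samples to select from")
    rng = np.random.default_rng(seed)
    by_breed: dict[str, list[str]] = {}
    for s in sorted(sample_ids):
        by_breed.setdefault(breed_of[s], []).append(s)
    test: list[str] = []
    for breed in sorted(by_breed):
        members = by_breed[breed]
        pool = [s for s in members if eligible is None or s in eligible]
        n = min(max_per_breed, int(np.floor(max_breed_fraction * len(members))), len(pool))
        if n > 0:
            test.extend(rng.choice(pool, size=n, replace=False).tolist())
    test_set = set(test)
    reference = [s for s in sorted(sample_ids) if s not in test_set]
    return sorted(test), reference


def mask_to_assay(g: GenotypeMatrix, assay: AssayDefinition) -> MaskedTestSet:
    """Restrict genotypes to an assay's markers, keeping the full truth."""
    idx = g.marker_index().get_indexer(assay.marker_ids)
    if (idx < 0).any():
        bad = [m for m, i in zip(assay.marker_ids, idx) if i < 0]
        raise KeyError(f"assay markers absent from genotype matrix: {bad[:5]}")
    observed = g.subset_markers(assay.marker_ids)
    assay_set = set(assay.marker_ids)
    withheld = [m for m in g.marker_map["id"] if m not in assay_set]
    return MaskedTestSet(
        observed=observed, truth=g, assay=assay, withheld_marker_ids=withheld
    )


def build_masked_test_set(
    panel: HaplotypePanel,
    test_ids: list[str],
    assay: AssayDefinition,
    error_rate: float = 0.0,
    seed: int = 0,
) -> MaskedTestSet:
    """Mask simulated samples to one assay, with optional genotyping error.

    Error is injected over the *full* marker set: the scoring truth is the
    test animals' full-density research-assay genotypes, which carry the
    platform error rate, exactly as treating observed high-density calls as
    correct does.  The masked observed genotypes are the restriction of
    that same error-bearing matrix, so typed markers agree between observed
    and truth.  The observed haplotypes are the simulator's phase at the
    assay markers; where an injected error changed the unphased call, the
    haplotype pair is rewritten to a phase consistent with the erroneous
    call (heterozygote orientation drawn at random).
    """
    from .simpop import AssayDefinition, genotype_with_error

    sub = panel.subset_samples(test_ids)
    full_assay = AssayDefinition("_full", panel.marker_map["id"].tolist())
    truth, err_full = genotype_with_error(sub, full_assay, rate=error_rate, seed=seed)
    masked = mask_to_assay(truth, assay)
    obs_gm = masked.observed
    acols = truth.marker_index().get_indexer(assay.marker_ids)
    err = err_full[:, acols]

    assay_sub = sub.subset_markers(assay.marker_ids)
    haps = assay_sub.alleles.copy()
    if err.any():
        rng = np.random.default_rng(seed + 1)
        rows, cols = np.nonzero(err)
        for i, j in zip(rows, cols):
            c = int(obs_gm.calls[i, j])
            if c == 0:
                a, b = 0, 0
            elif c == 2:
                a, b = 1, 1
            else:
                a, b = (0, 1) if rng.random() < 0.5 else (1, 0)
            haps[2 * i, j] = a
            haps[2 * i + 1, j] = b
    return MaskedTestSet(
        observed=obs_gm,
        truth=truth,
        assay=assay,
        withheld_marker_ids=masked.withheld_marker_ids,
        observed_haplotypes=haps,
        error_mask=err_full,
    )


def write_id_list(path, ids: list[str]) -> None:
    with open(path, "w") as fh:
        for s in ids:
            fh.write(s + "\n")
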