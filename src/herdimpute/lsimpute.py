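"""Haplotype-copying (Li-Stephens) imputation.

Each target haplotype is modelled as an imperfect mosaic of the reference
haplotypes: a hidden Markov chain over K copying states on the grid of typed
markers, with a constant per-interval probability ``s`` of redrawing the
copied haplotype uniformly (so the chain stays with probability
(1-s) + s/K) and an allele-mismatch emission probability ``eps``.  Scaled
forward-backward recursions give per-site copying posteriors; the posterior
alternate-allele dosage at an untyped marker is the copying posterior at the
nearest typed marker to its left applied to the reference alleles at the
untyped marker (markers before the first typed site use the first typed
site's posterior).

This is a desk-scale stand-in for production imputation software
(Minimac/Beagle): no PBWT state reduction, no genetic map, targets are
pre-phased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeMatrix
from .maskgen import MaskedTestSet
from .simpop import HaplotypePanel

OBSERVED = 0
IMPUTED = 1

_CHUNK_ELEMS = 24_000_000  # ~190 MB of float64 posterior per chunk


@dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters.

    switch_rate: per-typed-interval probability of redrawing the copied
        reference haplotype (recombination analogue).
    emission_error: allele mismatch probability (mutation/genotyping-error
        analogue).
    max_reference_haplotypes: cap on reference size; larger panels are
        subsampled (seeded, stratified by breed).
    """

    switch_rate: float = 0.01
    emission_error: float = 0.002
    max_reference_haplotypes: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.switch_rate < 1.0:
            raise ValueError("switch_rate must be in (0,1)")
        if not 0.0 < self.emission_error < 0.5:
            raise ValueError("emission_error must be in (0,0.5)")
        if self.max_reference_haplotypes < 2:
            raise ValueError("reference cap must be at least 2")


@dataclass
class ImputationResult:
    """Posterior dosages and best-guess genotypes with provenance flags."""

    dosage: np.ndarray  # (n_samples, n_markers) expected alt count in [0,2]
    best_guess: np.ndarray  # int8 {0,1,2}
    provenance: np.ndarray  # uint8, OBSERVED or IMPUTED per entry
    marker_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.dosage.min() < -1e-9 or self.dosage.max() > 2 + 1e-9:
            raise ValueError("dosage out of [0,2]")

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def marker_index(self) -> pd.Index:
        return pd.Index(self.marker_map["id"])


def _emission(obs_col: np.ndarray, ref_col: np.ndarray, eps: float) -> np.ndarray:
    """Emission matrix (H, K) for one typed site; missing alleles emit 1."""
    match = obs_col[:, None] == ref_col[None, :]
    e = np.where(match, 1.0 - eps, eps)
    e[obs_col < 0, :] = 1.0
    return e


def forward_backward_posteriors(
    obs: np.ndarray, ref_typed: np.ndarray, switch_rate: float, emission_error: float
) -> np.ndarray:
    """Copying-state posteriors, (H, T, K), for targets ``obs`` (H, T).

    ``ref_typed`` is (K, T).  Scaled recursions: posteriors are normalized
    at every typed site, so there is no underflow even for long grids.
    """
    obs = np.atleast_2d(np.asarray(obs))
    H, T = obs.shape
    K = ref_typed.shape[0]
    if T == 0:
        raise ValueError("target typed at zero markers")
    if K < 2:
        raise ValueError("reference must contain at least 2 haplotypes")
    valid = np.isin(obs, (0, 1, MISSING))
    if not valid.all():
        raise ValueError("target alleles must be in {0,1,missing}")
    s, eps = switch_rate, emission_error

    fwd = np.empty((H, T, K))
    f = np.full((H, K), 1.0 / K) * _emission(obs[:, 0], ref_typed[:, 0], eps)
    f /= f.sum(axis=1, keepdims=True)
    fwd[:, 0] = f
    for t in range(1, T):
        f = _emission(obs[:, t], ref_typed[:, t], eps) * ((1.0 - s) * f + s / K)
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, t] = f

    gamma = np.empty((H, T, K))
    b = np.ones((H, K))
    gamma[:, T - 1] = fwd[:, T - 1]
    for t in range(T - 2, -1, -1):
        eb = _emission(obs[:, t + 1], ref_typed[:, t + 1], eps) * b
        b = (1.0 - s) * eb + (s / K) * eb.sum(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)
        g = fwd[:, t] * b
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    return gamma


def _subsample_reference(
    reference: HaplotypePanel, cap: int, seed: int
) -> HaplotypePanel:
    """Seeded breed-stratified subsampling when the panel exceeds the cap."""
    if 2 * reference.n_samples <= cap:
        return reference
    n_keep = max(1, cap // 2)
    by_breed: dict[str, list[str]] = {}
    for sid in sorted(reference.sample_ids):
        by_breed.setdefault(reference.breed_of[sid], []).append(sid)
    rng = np.random.default_rng(seed)
    total = reference.n_samples
    keep: list[str] = []
    breeds = sorted(by_breed)
    quota = {b: int(np.floor(n_keep * len(by_breed[b]) / total)) for b in breeds}
    short = n_keep - sum(quota.values())
    for b in breeds:  # distribute the rounding remainder deterministically
        if short == 0:
            break
        if quota[b] < len(by_breed[b]):
            quota[b] += 1
            short -= 1
    for b in breeds:
        ids = by_breed[b]
        k = min(quota[b], len(ids))
        if k > 0:
            keep.extend(rng.choice(ids, size=k, replace=False).tolist())
    return reference.subset_samples(sorted(keep))


def impute_haplotype_panel(
    obs_haps: np.ndarray,
    typed_marker_ids: list[str],
    reference: HaplotypePanel,
    params: HmmParams,
    seed: int = 0,
) -> np.ndarray:
    """Haploid posterior alt-allele dosage, (H, n_reference_markers).

    ``obs_haps`` is (H, T) over {0,1,missing} at ``typed_marker_ids``, which
    must all be present in the reference.  Posteriors at typed sites come
    from the forward-backward pass; untyped sites use the left-flank rule.
    """
    reference = _subsample_reference(reference, params.max_reference_haplotypes, seed)
    ref_idx = reference.marker_index()
    typed_cols = ref_idx.get_indexer(typed_marker_ids)
    if (typed_cols < 0).any():
        bad = [m for m, i in zip(typed_marker_ids, typed_cols) if i < 0]
        raise KeyError(f"typed markers absent from reference: {bad[:5]}")
    order = np.argsort(typed_cols)
    typed_cols = typed_cols[order]
    obs_haps = np.atleast_2d(obs_haps)[:, order]

    M = reference.n_markers
    H = obs_haps.shape[0]
    K = reference.alleles.shape[0]
    dose = np.empty((H, M))
    # one independent copying chain per chromosome, as production imputers run
    chrom = reference.marker_map["chrom"].to_numpy()
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        on_c = np.isin(typed_cols, cols)
        if not on_c.any():
            # no typed markers on this chromosome: prior posterior (uniform)
            dose[:, cols] = reference.alleles[:, cols].mean(axis=0)[None, :]
            continue
        _impute_chromosome(
            dose, obs_haps[:, on_c], typed_cols[on_c], cols, reference, params
        )
    np.clip(dose, 0.0, 1.0, out=dose)  # guard float roundoff in the matmuls
    return dose


def _impute_chromosome(
    dose: np.ndarray,
    obs: np.ndarray,
    typed_cols: np.ndarray,
    chrom_cols: np.ndarray,
    reference: HaplotypePanel,
    params: HmmParams,
) -> None:
    """Forward-backward plus left-flank interpolation for one chromosome."""
    H, T = obs.shape
    K = reference.alleles.shape[0]
    ref_all = reference.alleles.astype(np.float64)
    ref_typed = reference.alleles[:, typed_cols]

    left = np.searchsorted(typed_cols, chrom_cols, side="right") - 1
    left = np.clip(left, 0, T - 1)  # pre-first-typed markers use the first site
    untyped_mask = ~np.isin(chrom_cols, typed_cols)
    flank_groups: list[tuple[int, np.ndarray]] = []
    if untyped_mask.any():
        ucols = chrom_cols[untyped_mask]
        ul = left[untyped_mask]
        for t in np.unique(ul):
            flank_groups.append((int(t), ucols[ul == t]))

    chunk = max(1, _CHUNK_ELEMS // max(1, T * K))
    for start in range(0, H, chunk):
        sl = slice(start, min(start + chunk, H))
        gamma = forward_backward_posteriors(
            obs[sl], ref_typed, params.switch_rate, params.emission_error
        )
        dose[sl][:, typed_cols] = np.einsum(
            "htk,kt->ht", gamma, ref_typed.astype(np.float64)
        )
        for t, cols in flank_groups:
            dose[sl][:, cols] = gamma[:, t, :] @ ref_all[:, cols]


def impute_haploid(
    target_alleles: np.ndarray,
    typed_marker_ids: list[str],
    reference: HaplotypePanel,
    params: HmmParams,
    seed: int = 0,
) -> np.ndarray:
    """Posterior alternate-allele probability at every reference marker."""
    return impute_haplotype_panel(
        np.atleast_2d(target_alleles), typed_marker_ids, reference, params, seed
    )[0]


def inject_switch_errors(haps: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Emulate imperfect statistical phasing: flip phase at hets w.p. rate.

    ``haps`` has two consecutive rows per sample; at each heterozygous typed
    site a Bernoulli(rate) draw toggles which physical haplotype each row
    tracks from that site onward (a phase switch error).
    """
    out = haps.copy()
    rng = np.random.default_rng(seed)
    h1, h2 = out[0::2], out[1::2]
    het = h1 != h2
    toggle = het & (rng.random(h1.shape) < rate)
    swapped = np.cumsum(toggle, axis=1) % 2 == 1
    a, b = h1.copy(), h2.copy()
    h1[swapped] = b[swapped]
    h2[swapped] = a[swapped]
    return out


def best_guess_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """Round dosage to {0,1,2}; exact .5 ties go to the heterozygote."""
    bg = np.floor(dosage + 0.5)
    frac = dosage - np.floor(dosage)
    tie = np.isclose(frac, 0.5)
    bg = np.where(tie, 1.0, bg)
    return np.clip(bg, 0, 2).astype(np.int8)


def impute_samples(
    test: MaskedTestSet,
    reference: HaplotypePanel,
    params: HmmParams,
    phase_mode: str = "truth-phase",
    switch_error_rate: float = 0.02,
    seed: int = 0,
) -> ImputationResult:
    """Impute every test sample against a phased reference panel.

    Each of a sample's two haplotypes is threaded through the reference
    independently; the diploid dosage is the sum of the two haploid
    posteriors.  Observed genotypes pass through unchanged with
    provenance=OBSERVED.  ``phase_mode`` is ``truth-phase`` (use the phase
    carried by the test set) or ``switch-error`` (inject phase switch
    errors at heterozygous sites first).
    """
    if test.observed_haplotypes is None:
        raise ValueError("test set carries no phase information")
    haps = test.observed_haplotypes
    if phase_mode == "switch-error":
        haps = inject_switch_errors(haps, switch_error_rate, seed + 7)
    elif phase_mode != "truth-phase":
        raise ValueError(f"unknown phase_mode: {phase_mode}")

    typed_ids = test.observed.marker_map["id"].tolist()
    hap_dose = impute_haplotype_panel(haps, typed_ids, reference, params, seed)
    dosage = hap_dose[0::2] + hap_dose[1::2]
    provenance = np.full(dosage.shape, IMPUTED, dtype=np.uint8)
    best = best_guess_from_dosage(dosage)

    obs_cols = reference.marker_index().get_indexer(typed_ids)
    obs_calls = test.observed.calls
    seen = obs_calls != MISSING
    dosage[:, obs_cols] = np.where(seen, obs_calls, dosage[:, obs_cols])
    best[:, obs_cols] = np.where(seen, obs_calls, best[:, obs_cols])
    provenance[:, obs_cols] = np.where(seen, OBSERVED, IMPUTED)

    return ImputationResult(
        dosage=dosage,
        best_guess=best,
        provenance=provenance,
        marker_map=reference.marker_map.copy(),
        sample_ids=list(test.sample_ids),
    )


def write_imputed_vcf(path, result: ImputationResult) -> None:
    """VCF 4.2 with GT (best guess), DS (dosage, 3 decimals), INFO IMPUTED."""
    from .gio import _vcf_header

    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_vcf_header(result.marker_map, result.sample_ids, with_ds=True))
        mm = result.marker_map
        any_imputed = (result.provenance == IMPUTED).any(axis=0)
        for j in range(result.n_markers):
            row = mm.iloc[j]
            info = "IMPUTED" if any_imputed[j] else "."
            cells = "\t".join(
                f"{gt_code[int(result.best_guess[i, j])]}:{result.dosage[i, j]:.3f}"
                for i in range(len(result.sample_ids))
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t{info}\tGT:DS\t{cells}\n"
            )
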