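"""Synthetic multi-breed phased SNP panels.

Generates the statistical structure that multi-breed imputation studies in
cattle rely on: breed differentiation under the Balding-Nichols model,
within-breed haplotype sharing (linkage disequilibrium) through founder
mosaics, admixed individuals, commercial-assay marker subsets (a common-variant
"HD"-like chip, a rare-enriched "F250"-like chip, and nested lower-density
chips), and symmetric genotyping error.

The generator is deliberately non-genealogical: LD arises from copying long
founder segments rather than from a coalescent process.  That is orders of
magnitude cheaper and produces exactly the haplotype-sharing structure a
copying-model imputer exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix

_ALLELE_PAIRS = (("A", "C"), ("G", "T"), ("C", "A"), ("T", "G"))

#: Filtered marker counts of the commercial assays being emulated, from the
#: lowest-density chip to the two high-density research chips, plus the size
#: of the block shared between the rare-enriched and common research chips.
COMMERCIAL_ASSAY_DENSITIES = {
    "ULD": 6394,
    "LD": 16854,
    "SNP50": 44366,
    "90K": 70581,
    "GGPHD": 125446,
    "F250": 201236,
    "HD": 753715,
}
HD_F250_OVERLAP = 31392


@dataclass(frozen=True)
class BreedSpec:
    """One breed: reference haplotype count, test-candidate count, F_ST."""

    name: str
    n_reference_haplotypes: int
    n_test_individuals: int
    fst: float


@dataclass(frozen=True)
class AdmixtureSpec:
    """A named admixed sample with breed proportions summing to 1."""

    name: str
    proportions: tuple[tuple[str, float], ...]

    def proportion_dict(self) -> dict[str, float]:
        return dict(self.proportions)


def default_breeds() -> list[BreedSpec]:
    # Table-2-like imbalance: one dominant breed (~50% of the reference),
    # one mid-sized, several sparse; indicine-like breeds more diverged.
    return [
        BreedSpec("HOL", 600, 60, 0.10),
        BreedSpec("ANG", 240, 40, 0.08),
        BreedSpec("GEL", 160, 50, 0.10),
        BreedSpec("SIM", 100, 25, 0.09),
        BreedSpec("BRM", 60, 10, 0.15),
        BreedSpec("NDA", 40, 5, 0.15),
    ]


def default_admixed() -> list[AdmixtureSpec]:
    # Crossbreds with a Gelbvieh-like primary component, so a within-breed
    # reference panel is a meaningful (if incomplete) match for them.
    out = []
    for i in range(5):
        out.append(AdmixtureSpec(f"XGA{i:02d}", (("GEL", 0.5), ("ANG", 0.5))))
    for i in range(3):
        out.append(AdmixtureSpec(f"XGH{i:02d}", (("GEL", 0.75), ("HOL", 0.25))))
    for i in range(2):
        out.append(AdmixtureSpec(f"XGB{i:02d}", (("GEL", 0.5), ("BRM", 0.5))))
    return out


@dataclass
class SimConfig:
    """Configuration of one synthetic panel.

    ``n_markers`` is per chromosome.  ``mosaic_switch_rate`` is the
    per-marker probability that a haplotype switches to a freshly drawn
    founder, so 1/rate is the expected founder-segment length in markers.
    ``genotype_error_rate`` is the per-genotype probability of replacement
    with a different genotype (platform error is about 0.2%).
    """

    n_markers: int = 2500
    n_chromosomes: int = 2
    breeds: list[BreedSpec] = field(default_factory=default_breeds)
    n_founders_per_breed: int = 30
    mosaic_switch_rate: float = 0.0005
    admixed_samples: list[AdmixtureSpec] = field(default_factory=default_admixed)
    ancestral_sfs_shape: tuple[float, float] = (0.01, 0.99)
    genotype_error_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers <= 0 or self.n_chromosomes <= 0:
            raise ValueError("marker and chromosome counts must be positive")
        if self.n_founders_per_breed < 2:
            raise ValueError("need at least 2 founders per breed")
        if not 0.0 < self.mosaic_switch_rate < 1.0:
            raise ValueError("mosaic_switch_rate must be in (0,1)")
        if not 0.0 <= self.genotype_error_rate <= 0.05:
            raise ValueError("genotype_error_rate must be in [0, 0.05]")
        lo, hi = self.ancestral_sfs_shape
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral SFS bounds must satisfy 0 < lo < hi < 1")
        if not self.breeds:
            raise ValueError("at least one breed required")
        names = set()
        for b in self.breeds:
            if not 0.0 < b.fst < 1.0:
                raise ValueError(f"fst for breed {b.name} must be in (0,1)")
            if b.n_reference_haplotypes <= 0 or b.n_reference_haplotypes % 2:
                raise ValueError(f"breed {b.name}: reference haplotypes must be positive and even")
            if b.n_test_individuals < 0:
                raise ValueError(f"breed {b.name}: negative test count")
            names.add(b.name)
        for adm in self.admixed_samples:
            props = adm.proportion_dict()
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"admixture proportions for {adm.name} must sum to 1")
            missing = set(props) - names
            if missing:
                raise ValueError(f"admixed sample {adm.name} references unknown breeds {missing}")


@dataclass
class AssayDefinition:
    """A named, ordered (genome-order) subset of the panel's markers."""

    name: str
    marker_ids: list[str]
    rule: str = ""

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class AssaySpec:
    """Recipe for one assay: selection rule and target marker count.

    ``rule`` is one of ``common-evenly-spaced``, ``rare-enriched`` and
    ``nested-subset-of``; the latter two require ``parent``.  For
    ``rare-enriched``, ``overlap_count`` markers are copied from the parent
    (the fixed shared block of the two research chips) and the remainder is
    drawn preferentially below MAF 0.1.
    """

    name: str
    target_count: int
    rule: str
    parent: str | None = None
    overlap_count: int | None = None


@dataclass
class HaplotypePanel:
    """Phased haplotypes (two consecutive rows per sample) with marker map.

    ``alleles`` is (2*n_samples, n_markers) over {0,1}; rows 2i and 2i+1 are
    the two haplotypes of ``sample_ids[i]``.  ``founder_freqs`` keeps the
    per-breed empirical founder allele frequencies the mosaics copy from
    (simulation truth for frequency recovery); ``bn_freqs`` keeps the
    underlying Balding-Nichols draws and ``ancestral_freqs`` the ancestral
    frequencies.  ``test_candidates`` marks samples that are eligible for
    masking (the analogue of animals genotyped on both research chips).
    """

    alleles: np.ndarray
    marker_map: pd.DataFrame
    sample_ids: list[str]
    breed_of: dict[str, str]
    founder_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    admixture: dict[str, dict[str, float]] = field(default_factory=dict)
    test_candidates: set[str] = field(default_factory=set)
    bn_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    ancestral_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be twice the sample count")
        if self.alleles.shape[1] != len(self.marker_map):
            raise ValueError("allele matrix width must match marker map")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def marker_index(self) -> pd.Index:
        return pd.Index(self.marker_map["id"])

    def genotypes(self) -> np.ndarray:
        """Unphased alternate-allele counts, (n_samples, n_markers)."""
        return (self.alleles[0::2] + self.alleles[1::2]).astype(np.int8)

    def maf(self) -> np.ndarray:
        f = self.alleles.mean(axis=0)
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, ids: list[str]) -> "HaplotypePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in panel: {missing[:5]}")
        rows = np.concatenate([[2 * pos[s], 2 * pos[s] + 1] for s in ids]).astype(int)
        return HaplotypePanel(
            alleles=self.alleles[rows],
            marker_map=self.marker_map,
            sample_ids=list(ids),
            breed_of={s: self.breed_of[s] for s in ids},
            founder_freqs=self.founder_freqs,
            admixture={s: self.admixture[s] for s in ids if s in self.admixture},
            test_candidates={s for s in ids if s in self.test_candidates},
            bn_freqs=self.bn_freqs,
            ancestral_freqs=self.ancestral_freqs,
        )

    def subset_markers(self, marker_ids: list[str]) -> "HaplotypePanel":
        idx = self.marker_index().get_indexer(marker_ids)
        if (idx < 0).any():
            bad = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not in panel: {bad[:5]}")
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            marker_map=self.marker_map.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            breed_of=dict(self.breed_of),
            founder_freqs={b: f[idx] for b, f in self.founder_freqs.items()},
            admixture=dict(self.admixture),
            test_candidates=set(self.test_candidates),
            bn_freqs={b: f[idx] for b, f in self.bn_freqs.items()},
            ancestral_freqs=None if self.ancestral_freqs is None else self.ancestral_freqs[idx],
        )

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            calls=self.genotypes(),
            marker_map=self.marker_map.copy(),
            sample_ids=list(self.sample_ids),
            phased=True,
        )


def _make_marker_map(n_markers: int, n_chromosomes: int) -> pd.DataFrame:
    rows = []
    g = 0
    for c in range(1, n_chromosomes + 1):
        for i in range(n_markers):
            ref, alt = _ALLELE_PAIRS[g % len(_ALLELE_PAIRS)]
            rows.append((str(c), (i + 1) * 1000, f"snp{g:06d}", ref, alt))
            g += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founder_stack: np.ndarray,
    founder_probs: np.ndarray,
    n_haps: int,
    switch_rate: float,
    chrom_starts: np.ndarray,
) -> np.ndarray:
    """Left-to-right founder mosaics; founder redrawn with prob switch_rate."""
    n_markers = founder_stack.shape[1]
    switch = rng.random((n_haps, n_markers)) < switch_rate
    switch[:, chrom_starts] = True  # fresh founder at every chromosome start
    cdf = np.cumsum(founder_probs)
    pick = np.searchsorted(cdf, rng.random((n_haps, n_markers)), side="right")
    pick = np.minimum(pick, len(founder_probs) - 1)
    last_switch = np.maximum.accumulate(
        np.where(switch, np.arange(n_markers)[None, :], -1), axis=1
    )
    fid = np.take_along_axis(pick, last_switch, axis=1)
    return founder_stack[fid, np.arange(n_markers)[None, :]]


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Generate a phased multi-breed panel; bit-reproducible given cfg.seed.

    Ancestral frequencies follow a 1/x density on the configured interval
    (inverse-CDF sampling); breed frequencies are Balding-Nichols
    Beta(p(1-F)/F, (1-p)(1-F)/F) draws; haplotypes are founder mosaics.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_markers = cfg.n_markers * cfg.n_chromosomes
    chrom_starts = np.arange(0, n_markers, cfg.n_markers)
    marker_map = _make_marker_map(cfg.n_markers, cfg.n_chromosomes)

    lo, hi = cfg.ancestral_sfs_shape
    p_anc = lo * (hi / lo) ** rng.random(n_markers)

    breed_names = [b.name for b in cfg.breeds]
    bn_freqs: dict[str, np.ndarray] = {}
    founder_freqs: dict[str, np.ndarray] = {}
    founders: dict[str, np.ndarray] = {}
    for b in cfg.breeds:
        shape_a = p_anc * (1.0 - b.fst) / b.fst
        shape_b = (1.0 - p_anc) * (1.0 - b.fst) / b.fst
        p_b = rng.beta(shape_a, shape_b)
        bn_freqs[b.name] = p_b
        founders[b.name] = (
            rng.random((cfg.n_founders_per_breed, n_markers)) < p_b
        ).astype(np.int8)
        founder_freqs[b.name] = founders[b.name].mean(axis=0)

    founder_stack = np.concatenate([founders[n] for n in breed_names], axis=0)
    n_f = cfg.n_founders_per_breed
    block_of = {n: slice(i * n_f, (i + 1) * n_f) for i, n in enumerate(breed_names)}

    hap_blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    breed_of: dict[str, str] = {}
    admixture: dict[str, dict[str, float]] = {}
    test_candidates: set[str] = set()

    for b in cfg.breeds:
        probs = np.zeros(founder_stack.shape[0])
        probs[block_of[b.name]] = 1.0 / n_f
        n_samp = b.n_reference_haplotypes // 2 + b.n_test_individuals
        haps = _mosaic_haplotypes(
            rng, founder_stack, probs, 2 * n_samp, cfg.mosaic_switch_rate, chrom_starts
        )
        hap_blocks.append(haps)
        for k in range(n_samp):
            sid = f"{b.name}{k:03d}"
            sample_ids.append(sid)
            breed_of[sid] = b.name
            admixture[sid] = {b.name: 1.0}
            if k >= b.n_reference_haplotypes // 2:
                test_candidates.add(sid)

    for adm in cfg.admixed_samples:
        props = adm.proportion_dict()
        probs = np.zeros(founder_stack.shape[0])
        for breed, p in props.items():
            probs[block_of[breed]] = p / n_f
        haps = _mosaic_haplotypes(
            rng, founder_stack, probs, 2, cfg.mosaic_switch_rate, chrom_starts
        )
        hap_blocks.append(haps)
        sample_ids.append(adm.name)
        breed_of[adm.name] = "CROSS"
        admixture[adm.name] = props
        test_candidates.add(adm.name)

    return HaplotypePanel(
        alleles=np.concatenate(hap_blocks, axis=0),
        marker_map=marker_map,
        sample_ids=sample_ids,
        breed_of=breed_of,
        founder_freqs=founder_freqs,
        admixture=admixture,
        test_candidates=test_candidates,
        bn_freqs=bn_freqs,
        ancestral_freqs=p_anc,
    )


def scale_assay_counts(counts: list[int], factor: float) -> list[int]:
    """Scale commercial assay densities to a desk-scale panel, rounding."""
    return [round(c * factor) for c in counts]


def default_assay_specs(n_markers_total: int) -> list[AssaySpec]:
    """Assay catalogue preserving the commercial chips' density ratios.

    The common-variant research chip ("HD") covers 80% of the simulated
    markers; everything else is scaled by the same factor relative to its
    real filtered density.
    """
    hd_count = round(0.8 * n_markers_total)
    factor = hd_count / COMMERCIAL_ASSAY_DENSITIES["HD"]
    specs = [AssaySpec("HD", hd_count, "common-evenly-spaced")]
    specs.append(
        AssaySpec(
            "F250",
            max(2, round(factor * COMMERCIAL_ASSAY_DENSITIES["F250"])),
            "rare-enriched",
            parent="HD",
            overlap_count=max(1, round(factor * HD_F250_OVERLAP)),
        )
    )
    for name in ("ULD", "LD", "SNP50", "90K", "GGPHD"):
        specs.append(
            AssaySpec(
                name,
                max(2, round(factor * COMMERCIAL_ASSAY_DENSITIES[name])),
                "nested-subset-of",
                parent="HD",
            )
        )
    return specs


def _evenly_spaced(values: np.ndarray, k: int) -> np.ndarray:
    if k > len(values):
        raise ValueError("cannot pick more markers than available")
    idx = np.linspace(0, len(values), k, endpoint=False).astype(int)
    return values[idx]


def define_assays(
    panel: HaplotypePanel, specs: list[AssaySpec], seed: int = 0
) -> list[AssayDefinition]:
    """Realize assay recipes on a panel.

    ``common-evenly-spaced`` prefers markers with panel MAF >= 0.05 and
    spaces them evenly; ``rare-enriched`` copies a fixed overlap block from
    its parent and samples the rest with 9:1 weight on MAF < 0.1 markers;
    ``nested-subset-of`` is an evenly spaced subset of the parent.
    """
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    ids = panel.marker_map["id"].to_numpy()
    order = {m: i for i, m in enumerate(ids)}
    defined: dict[str, AssayDefinition] = {}
    out: list[AssayDefinition] = []

    for sp in specs:
        if sp.target_count > panel.n_markers:
            raise ValueError(f"assay {sp.name}: target exceeds panel size")
        if sp.rule == "common-evenly-spaced":
            eligible = np.flatnonzero(maf >= 0.05)
            if len(eligible) >= sp.target_count:
                sel = _evenly_spaced(eligible, sp.target_count)
            else:
                rest = np.setdiff1d(np.arange(panel.n_markers), eligible)
                fill = _evenly_spaced(rest, sp.target_count - len(eligible))
                sel = np.sort(np.concatenate([eligible, fill]))
            chosen = ids[np.sort(sel)]
        elif sp.rule == "rare-enriched":
            if sp.parent is None or sp.parent not in defined:
                raise ValueError(f"assay {sp.name}: parent assay undefined")
            parent_ids = np.array(defined[sp.parent].marker_ids)
            n_overlap = sp.overlap_count or 0
            n_overlap = min(n_overlap, sp.target_count, len(parent_ids))
            overlap = _evenly_spaced(parent_ids, n_overlap)
            pool = np.setdiff1d(ids, overlap)
            pool_idx = np.array([order[m] for m in pool])
            w = np.where(maf[pool_idx] < 0.1, 9.0, 1.0)
            extra = rng.choice(
                pool, size=sp.target_count - n_overlap, replace=False, p=w / w.sum()
            )
            chosen = np.concatenate([overlap, extra])
            chosen = chosen[np.argsort([order[m] for m in chosen])]
        elif sp.rule == "nested-subset-of":
            if sp.parent is None or sp.parent not in defined:
                raise ValueError(f"assay {sp.name}: parent assay undefined")
            parent_ids = np.array(defined[sp.parent].marker_ids)
            chosen = _evenly_spaced(parent_ids, sp.target_count)
        else:
            raise ValueError(f"unknown assay rule: {sp.rule}")
        assay = AssayDefinition(sp.name, [str(m) for m in chosen], sp.rule)
        defined[sp.name] = assay
        out.append(assay)
    return out


def genotype_with_error(
    panel: HaplotypePanel,
    assay: AssayDefinition,
    rate: float = 0.002,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Unphased genotypes at an assay's markers with symmetric call error.

    Each genotype is independently replaced, with probability ``rate``, by
    one of the two other genotype classes chosen uniformly.  Returns the
    genotype matrix and the boolean error mask (simulation truth).
    """
    if not 0.0 <= rate <= 0.05:
        raise ValueError("error rate must be in [0, 0.05]")
    sub = panel.subset_markers(assay.marker_ids)
    g = sub.genotypes().copy()
    rng = np.random.default_rng(seed)
    err = rng.random(g.shape) < rate
    shift = 1 + (rng.random(g.shape) < 0.5).astype(np.int8)  # +1 or +2 mod 3
    g[err] = (g[err] + shift[err]) % 3
    gm = GenotypeMatrix(
        calls=g,
        marker_map=sub.marker_map.copy(),
        sample_ids=list(panel.sample_ids),
        phased=False,
    )
    return gm, err


def write_assay_list(path, assay: AssayDefinition) -> None:
    """One marker id per line."""
    with open(path, "w") as fh:
        for m in assay.marker_ids:
            fh.write(m + "\n")


def read_assay_list(path, name: str | None = None) -> AssayDefinition:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return AssayDefinition(name or str(path), ids)
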