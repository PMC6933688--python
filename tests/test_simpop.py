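"""Generator: breed structure, LD, assay design, genotyping error."""

import numpy as np
import pytest

import herdimpute as hi
from herdimpute.simpop import (
    AdmixtureSpec,
    BreedSpec,
    scale_assay_counts,
)

from conftest import tiny_config


def test_simulation_is_deterministic(tiny_panel):
    again = hi.simulate_panel(tiny_config())
    assert np.array_equal(tiny_panel.alleles, again.alleles)
    assert tiny_panel.sample_ids == again.sample_ids
    assert tiny_panel.marker_map.equals(again.marker_map)


def test_panel_structure(tiny_panel):
    assert set(np.unique(tiny_panel.alleles)) <= {0, 1}
    assert tiny_panel.alleles.shape[0] == 2 * tiny_panel.n_samples
    for _, grp in tiny_panel.marker_map.groupby("chrom"):
        assert grp["pos"].is_monotonic_increasing


def test_no_recombination_copies_founders_verbatim():
    """With no switching and negligible drift every haplotype is a founder copy."""
    cfg = tiny_config(
        seed=5,
        breeds=[BreedSpec("A", 40, 0, 0.001)],
        admixed_samples=[],
        mosaic_switch_rate=1e-12,
        n_chromosomes=1,
    )
    panel = hi.simulate_panel(cfg)
    # rebuild the founder pool the generator used: haplotypes must each
    # exactly match at least one founder-frequency-consistent sequence;
    # with switch rate ~0 each haplotype is constant-founder per chromosome,
    # so any two haplotypes are either identical or differ like two
    # independent founders -- identity is all-or-high, never partial-low.
    haps = panel.alleles
    n = haps.shape[0]
    ident = (haps[:, None, :] == haps[None, :, :]).mean(axis=2)
    off_diag = ident[~np.eye(n, dtype=bool)]
    # copies of the same founder agree everywhere
    assert (off_diag > 0.999).sum() > 0
    # no pair agrees at an intermediate level right below 1 (no mosaics)
    assert not ((off_diag > 0.97) & (off_diag < 0.999)).any()


def test_balding_nichols_differentiation_moment():
    """Mean squared breed-frequency difference matches 2*F*p(1-p)."""
    fst = 0.2
    cfg = hi.SimConfig(
        n_markers=10000,
        n_chromosomes=1,
        breeds=[BreedSpec("A", 4, 0, fst), BreedSpec("B", 4, 0, fst)],
        admixed_samples=[],
        seed=17,
    )
    panel = hi.simulate_panel(cfg)
    p_a = panel.ancestral_freqs
    d2 = (panel.bn_freqs["A"] - panel.bn_freqs["B"]) ** 2
    expected = 2.0 * fst * p_a * (1.0 - p_a)
    resid = d2 - expected
    se = resid.std(ddof=1) / np.sqrt(len(resid))
    assert abs(resid.mean()) < 3 * se

    # Monte-Carlo oracle: fresh Beta draws reproduce the same moment
    rng = np.random.default_rng(99)
    a = p_a * (1 - fst) / fst
    b = (1 - p_a) * (1 - fst) / fst
    mc = (rng.beta(a, b) - rng.beta(a, b)) ** 2
    assert abs(mc.mean() - expected.mean()) < 3 * mc.std(ddof=1) / np.sqrt(len(mc))


def test_frequency_recovery_at_large_sample_size():
    cfg = hi.SimConfig(
        n_markers=400,
        n_chromosomes=1,
        breeds=[BreedSpec("A", 2000, 0, 0.1)],
        admixed_samples=[],
        seed=2,
    )
    panel = hi.simulate_panel(cfg)
    emp = panel.alleles.mean(axis=0)
    ff = panel.founder_freqs["A"]
    sel = (ff >= 0.1) & (ff <= 0.9)
    assert sel.any()
    assert np.abs(emp - ff)[sel].max() < 0.05


def test_ld_decays_with_marker_distance():
    cfg = hi.SimConfig(
        n_markers=1000,
        n_chromosomes=1,
        breeds=[BreedSpec("A", 400, 0, 0.1)],
        admixed_samples=[],
        mosaic_switch_rate=0.005,
        seed=8,
    )
    panel = hi.simulate_panel(cfg)
    h = panel.alleles.astype(float)
    f = h.mean(axis=0)
    keep = (f > 0.05) & (f < 0.95)
    h = h[:, keep]
    rng = np.random.default_rng(0)
    bins = [(1, 10), (11, 40), (41, 150), (151, 500)]
    means = []
    for lo, hi_ in bins:
        vals = []
        for _ in range(400):
            i = rng.integers(0, h.shape[1] - hi_)
            j = i + rng.integers(lo, hi_ + 1)
            if j >= h.shape[1]:
                continue
            r = np.corrcoef(h[:, i], h[:, j])[0, 1]
            vals.append(r * r)
        means.append(np.mean(vals))
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_admixed_haplotypes_draw_from_both_breeds():
    cfg = tiny_config(
        seed=21,
        breeds=[BreedSpec("A", 100, 0, 0.15), BreedSpec("B", 100, 0, 0.15)],
        admixed_samples=[AdmixtureSpec("X", (("A", 0.5), ("B", 0.5)))],
        n_markers=2000,
        n_chromosomes=1,
        mosaic_switch_rate=0.01,
    )
    panel = hi.simulate_panel(cfg)
    x = panel.subset_samples(["X"]).alleles.mean(axis=0)
    fa, fb = panel.founder_freqs["A"], panel.founder_freqs["B"]
    # the cross's expected frequency is the breed average, so its alleles
    # should correlate better with the average than with either extreme
    mix = (fa + fb) / 2
    informative = np.abs(fa - fb) > 0.4
    assert informative.sum() > 50
    close_mix = np.abs(x[informative] - mix[informative]).mean()
    close_a = np.abs(x[informative] - fa[informative]).mean()
    assert close_mix < close_a


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------

def test_assay_counts_scaled_from_commercial_densities():
    counts = [6394, 16854, 44366, 70581, 125446]
    assert scale_assay_counts(counts, 0.1) == [639, 1685, 4437, 7058, 12545]


def test_nested_assay_with_full_target_is_identity(tiny_panel, tiny_assays):
    specs = [
        hi.AssaySpec("HD", tiny_assays["HD"].n_markers, "common-evenly-spaced"),
        hi.AssaySpec("HDcopy", tiny_assays["HD"].n_markers, "nested-subset-of", parent="HD"),
    ]
    hd, copy = hi.define_assays(tiny_panel, specs, seed=3)
    assert hd.marker_ids == copy.marker_ids


def test_rare_enriched_assay_shifts_maf_spectrum(tiny_panel, tiny_assays):
    maf = tiny_panel.maf()
    idx = tiny_panel.marker_index()
    m_hd = np.median(maf[idx.get_indexer(tiny_assays["HD"].marker_ids)])
    m_f250 = np.median(maf[idx.get_indexer(tiny_assays["F250"].marker_ids)])
    assert m_f250 < m_hd


def test_rare_assay_dominates_toward_zero(tiny_panel, tiny_assays):
    from scipy.stats import mannwhitneyu

    maf = tiny_panel.maf()
    idx = tiny_panel.marker_index()
    hd = maf[idx.get_indexer(tiny_assays["HD"].marker_ids)]
    f250 = maf[idx.get_indexer(tiny_assays["F250"].marker_ids)]
    stat = mannwhitneyu(f250, hd, alternative="less")
    assert stat.pvalue < 1e-6


def test_nested_assay_requires_parent(tiny_panel):
    with pytest.raises(ValueError, match="parent"):
        hi.define_assays(
            tiny_panel, [hi.AssaySpec("N", 10, "nested-subset-of", parent="missing")]
        )


def test_assays_are_ordered_subsets(tiny_panel, tiny_assays):
    order = {m: i for i, m in enumerate(tiny_panel.marker_map["id"])}
    for assay in tiny_assays.values():
        pos = [order[m] for m in assay.marker_ids]
        assert pos == sorted(pos)
        assert len(set(assay.marker_ids)) == assay.n_markers
    hd = set(tiny_assays["HD"].marker_ids)
    for nested in ("ULD", "LD", "SNP50", "90K", "GGPHD"):
        assert set(tiny_assays[nested].marker_ids) <= hd


# ---------------------------------------------------------------------------
# genotyping error
# ---------------------------------------------------------------------------

def test_zero_error_rate_reproduces_truth(tiny_panel, tiny_assays):
    gm, err = hi.genotype_with_error(tiny_panel, tiny_assays["HD"], rate=0.0, seed=1)
    sub = tiny_panel.subset_markers(tiny_assays["HD"].marker_ids)
    assert np.array_equal(gm.calls, sub.genotypes())
    assert not err.any()


def test_full_error_rate_changes_every_genotype(tiny_panel, tiny_assays):
    gm, err = hi.genotype_with_error(tiny_panel, tiny_assays["ULD"], rate=0.05, seed=1)
    sub = tiny_panel.subset_markers(tiny_assays["ULD"].marker_ids)
    truth = sub.genotypes()
    assert np.array_equal(gm.calls != truth, err)
    assert set(np.unique(gm.calls)) <= {0, 1, 2}


def test_error_fraction_matches_binomial_expectation():
    cfg = tiny_config(seed=31, n_markers=2500, n_chromosomes=2,
                      breeds=[BreedSpec("A", 400, 0, 0.1)], admixed_samples=[])
    panel = hi.simulate_panel(cfg)
    assay = hi.AssayDefinition("all", panel.marker_map["id"].tolist())
    rate = 0.002
    _, err = hi.genotype_with_error(panel, assay, rate=rate, seed=4)
    n = err.size
    assert n >= 1_000_000
    bound = 3 * np.sqrt(rate * (1 - rate) / n)
    assert abs(err.mean() - rate) < bound


def test_error_rate_bounds_enforced(tiny_panel, tiny_assays):
    with pytest.raises(ValueError):
        hi.genotype_with_error(tiny_panel, tiny_assays["ULD"], rate=0.2)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="fst"):
        hi.simulate_panel(tiny_config(breeds=[BreedSpec("A", 10, 0, 1.5)]))
    with pytest.raises(ValueError, match="founders"):
        hi.simulate_panel(tiny_config(n_founders_per_breed=1))
    with pytest.raises(ValueError, match="sum to 1"):
        hi.simulate_panel(
            tiny_config(admixed_samples=[AdmixtureSpec("X", (("A", 0.4), ("B", 0.4)))])
        )
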