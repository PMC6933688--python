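"""Genotype I/O and QC: formats round-trip, filters match their definitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herdimpute as hi
from herdimpute import gio

from conftest import make_matrix


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def test_vcf_round_trip_identity(tmp_path):
    g = make_matrix([[0, 1, 2], [2, -1, 0]])
    path = tmp_path / "x.vcf"
    gio.write_vcf(path, g)
    back = hi.read_genotypes(path, format="vcf")
    assert np.array_equal(back.calls, g.calls)
    assert back.sample_ids == g.sample_ids
    assert back.marker_map["id"].tolist() == g.marker_map["id"].tolist()


def test_vcf_unphased_het_parses_as_one(tmp_path):
    path = tmp_path / "h.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tm0\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
    )
    g = hi.read_genotypes(path, format="vcf")
    assert g.calls[0, 0] == 1
    assert g.phased is False


def test_phased_vcf_round_trips_haplotypes(tmp_path, tiny_panel):
    sub = tiny_panel.subset_samples(tiny_panel.sample_ids[:4]).subset_markers(
        tiny_panel.marker_map["id"][:20].tolist()
    )
    path = tmp_path / "p.vcf"
    gio.write_phased_vcf(path, sub)
    back = gio.read_phased_haplotypes(path)
    assert np.array_equal(back.alleles, sub.alleles)
    g = hi.read_genotypes(path, format="vcf")
    assert g.phased is True


def test_multiallelic_site_rejected(tmp_path):
    path = tmp_path / "m.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tbad\tA\tC,G\t.\tPASS\t.\tGT\t0/1\n"
    )
    with pytest.raises(ValueError, match="bad"):
        hi.read_genotypes(path, format="vcf")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def test_ped_allele_orientation_follows_declared_alleles(tmp_path):
    """'A A, G G, 0 0' with A major at site 1 and G minor at site 2 -> (0,2,missing)."""
    (tmp_path / "t.map").write_text(
        # chrom id cM pos A1(counted/minor) A2(major)
        "1\tm0\t0\t100\tC\tA\n"
        "1\tm1\t0\t200\tG\tT\n"
        "1\tm2\t0\t300\tC\tA\n"
    )
    (tmp_path / "t.ped").write_text("f1 s1 0 0 0 -9 A A G G 0 0\n")
    g = hi.read_genotypes(tmp_path / "t", format="plink-text")
    assert g.calls[0].tolist() == [0, 2, gio.MISSING]


def test_ped_minor_allele_inferred_when_undeclared(tmp_path):
    (tmp_path / "u.map").write_text("1\tm0\t0\t100\n")
    (tmp_path / "u.ped").write_text(
        "f1 s1 0 0 0 -9 A A\n"
        "f2 s2 0 0 0 -9 A G\n"
        "f3 s3 0 0 0 -9 A A\n"
    )
    g = hi.read_genotypes(tmp_path / "u", format="plink-text")
    # G is the minor allele, so counts are copies of G
    assert g.calls[:, 0].tolist() == [0, 1, 0]


def test_plink_round_trip_identity(tmp_path):
    g = make_matrix([[0, 1, 2, -1], [2, 2, 0, 1], [1, -1, -1, 0]])
    gio.write_plink(tmp_path / "rt", g)
    back = hi.read_genotypes(tmp_path / "rt", format="plink-text")
    assert np.array_equal(back.calls, g.calls)
    assert back.sample_ids == g.sample_ids


def test_malformed_ped_names_line(tmp_path):
    (tmp_path / "b.map").write_text("1\tm0\t0\t100\n")
    (tmp_path / "b.ped").write_text("f1 s1 0 0 0 -9 A A\nf2 s2 0 0 0 -9 A\n")
    with pytest.raises(ValueError, match="line 2"):
        hi.read_genotypes(tmp_path / "b", format="plink-text")


@settings(derandomize=True, deadline=None, max_examples=25)
@given(
    data=st.lists(
        st.lists(st.sampled_from([0, 1, 2, -1]), min_size=3, max_size=3),
        min_size=1,
        max_size=6,
    )
)
def test_round_trip_fuzz_both_formats(tmp_path_factory, data):
    arr = np.array(data, dtype=np.int8)
    if (arr == -1).all(axis=0).any():  # all-missing columns are unreadable in PED
        arr[0, (arr == -1).all(axis=0)] = 0
    g = make_matrix(arr)
    d = tmp_path_factory.mktemp("fuzz")
    gio.write_vcf(d / "f.vcf", g)
    assert np.array_equal(hi.read_genotypes(d / "f.vcf", format="vcf").calls, arr)
    gio.write_plink(d / "f", g)
    assert np.array_equal(hi.read_genotypes(d / "f", format="plink-text").calls, arr)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_clean_matrix_unchanged():
    g = make_matrix([[0, 1], [2, 1]])
    out, log = hi.qc_filter(g)
    assert np.array_equal(out.calls, g.calls)
    assert log.empty


def test_qc_removes_marker_below_threshold():
    calls = np.zeros((10, 2), dtype=np.int8)
    calls[:2, 0] = -1  # call rate 0.8 < 0.9
    out, log = hi.qc_filter(make_matrix(calls))
    assert out.marker_map["id"].tolist() == ["m1"]
    assert log.iloc[0].tolist()[:3] == ["m0", "marker", "call_rate"]


def test_qc_boundary_call_rate_is_kept():
    calls = np.zeros((10, 2), dtype=np.int8)
    calls[0, 0] = -1  # call rate exactly 0.9: "lower than 0.90" removes, so keep
    out, _ = hi.qc_filter(make_matrix(calls))
    assert out.n_markers == 2


def test_qc_removes_non_autosomes_first():
    calls = np.zeros((4, 3), dtype=np.int8)
    g = make_matrix(calls, chrom=["1", "X", "2"])
    out, log = hi.qc_filter(g)
    assert out.marker_map["chrom"].tolist() == ["1", "2"]
    assert (log["reason"] == "non-autosomal").sum() == 1


def test_qc_removes_low_call_rate_sample_after_markers():
    calls = np.zeros((10, 10), dtype=np.int8)
    calls[0, :5] = -1  # marker call rates stay at 0.9; sample 0 drops to 0.5
    out, log = hi.qc_filter(make_matrix(calls))
    assert "s0" not in out.sample_ids
    assert set(log["type"]) == {"sample"}


def test_qc_keeps_monomorphic_and_out_of_hwe_markers():
    # no MAF filter, no HWE filter: an all-het marker and a fixed marker stay
    calls = np.array([[1, 0], [1, 0], [1, 0], [1, 0]], dtype=np.int8)
    out, log = hi.qc_filter(make_matrix(calls))
    assert out.n_markers == 2
    assert log.empty


def test_qc_is_idempotent(tiny_panel, tiny_assays):
    gm, _ = hi.genotype_with_error(tiny_panel, tiny_assays["HD"], rate=0.01, seed=9)
    calls = gm.calls.copy()
    calls[np.random.default_rng(0).random(calls.shape) < 0.03] = -1
    g = make_matrix(calls, ids=gm.sample_ids)
    once, _ = hi.qc_filter(g)
    twice, log2 = hi.qc_filter(once)
    assert np.array_equal(once.calls, twice.calls)
    assert log2.empty


def test_qc_errors_when_everything_removed():
    calls = np.full((3, 2), -1, dtype=np.int8)
    with pytest.raises(ValueError):
        hi.qc_filter(make_matrix(calls))


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "column,expected",
    [
        ([0, 0, 0, 0], 0.0),
        ([2, 2, 2, 2], 0.0),  # alternate fixed: minor is the reference allele
        ([0, 1, 1, 2], 0.5),
    ],
)
def test_maf_hand_values(column, expected):
    g = make_matrix(np.array(column, dtype=np.int8)[:, None])
    assert hi.compute_maf(g)[0] == pytest.approx(expected)


def test_maf_ignores_missing_calls():
    g = make_matrix(np.array([[1], [-1], [0], [1]], dtype=np.int8))
    assert hi.compute_maf(g)[0] == pytest.approx(2 / 6)


def test_maf_invariant_to_allele_orientation_swap(tiny_panel, tiny_assays):
    gm, _ = hi.genotype_with_error(tiny_panel, tiny_assays["SNP50"], rate=0.0, seed=0)
    swapped = make_matrix(
        np.where(gm.calls == gio.MISSING, gio.MISSING, 2 - gm.calls),
        ids=gm.sample_ids,
    )
    assert np.allclose(hi.compute_maf(gm), hi.compute_maf(swapped))


def test_maf_errors_on_all_missing_marker():
    g = make_matrix(np.array([[-1, 0], [-1, 1]], dtype=np.int8))
    with pytest.raises(ValueError, match="missing"):
        hi.compute_maf(g)
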