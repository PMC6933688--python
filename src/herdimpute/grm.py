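"""Standardized genomic relationship matrix and reference-similarity scan.

The standardized GRM divides each marker's centered genotype product by
2p(1-p) (GEMMA's "standardized" matrix):

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the m polymorphic markers, with p_i the sample allele frequency.
Missing genotypes are mean-imputed to 2p_i, contributing zero.  Row means
against a (possibly breed-filtered) reference set quantify how well an
individual's genetic background is represented in the panel: larger values
mean more closely related.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeMatrix


@dataclass
class GRMatrix:
    values: np.ndarray
    sample_ids: list[str]
    n_markers_used: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


def standardized_grm(g: GenotypeMatrix) -> GRMatrix:
    """Standardized GRM over the polymorphic markers of ``g``."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    obs = g.calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g.calls, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    poly = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    x = g.calls[:, poly].astype(float)
    pj = p[poly]
    z = (x - 2.0 * pj) / np.sqrt(2.0 * pj * (1.0 - pj))
    z[~obs[:, poly]] = 0.0  # mean-imputed missing entries contribute nothing
    m = int(poly.sum())
    values = z @ z.T / m
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRMatrix(values=values, sample_ids=list(g.sample_ids), n_markers_used=m, freqs=pj)


def similarity_to_reference(
    grm: GRMatrix,
    test_ids: list[str],
    reference_ids: list[str],
    breed_of: dict[str, str] | None = None,
    breed: str | None = None,
    admixture: dict[str, dict[str, float]] | None = None,
    min_proportion: float = 0.5,
) -> pd.Series:
    """Mean relationship of each test sample to the reference members.

    With ``breed`` set, the reference is first filtered to samples of that
    breed (or, when ``admixture`` proportions are supplied, to samples with
    more than ``min_proportion`` ancestry from it).
    """
    if set(test_ids) & set(reference_ids):
        raise ValueError("test and reference id sets must be disjoint")
    refs = list(reference_ids)
    if breed is not None:
        if admixture is not None:
            refs = [
                s for s in refs
                if admixture.get(s, {}).get(breed, 1.0 if breed_of and breed_of.get(s) == breed else 0.0)
                > min_proportion - 1e-12
            ]
        elif breed_of is not None:
            refs = [s for s in refs if breed_of.get(s) == breed]
        else:
            raise ValueError("breed filter requires breed_of or admixture")
    if not refs:
        raise ValueError("empty reference set after breed filtering")
    pos = {s: i for i, s in enumerate(grm.sample_ids)}
    ref_idx = np.array([pos[s] for s in refs])
    vals = {t: float(grm.values[pos[t], ref_idx].mean()) for t in test_ids}
    return pd.Series(vals, name="similarity")


def write_grm(prefix, grm: GRMatrix) -> None:
    """GEMMA-style square text matrix plus a sample id list."""
    np.savetxt(f"{prefix}.cXX.txt", grm.values, fmt="%.10g", delimiter="\t")
    with open(f"{prefix}.samples.txt", "w") as fh:
        for s in grm.sample_ids:
            fh.write(s + "\n")
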