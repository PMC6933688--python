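"""Imputation accuracy statistics.

Per-variant: concordance, IQS (a per-variant Cohen's kappa: concordance
corrected for the chance that an imputed genotype could be guessed from the
contingency-table marginals), Pearson r, and an error taxonomy — false
heterozygotes (homozygous truth imputed heterozygous), false homozygotes
(heterozygous truth imputed homozygous) and complete discordances (opposite
homozygotes).  Per-individual: raw and MAF-centered Pearson r plus error
counts.  Aggregation is by half-open MAF bins (0,0.05], ..., (0.45,0.50],
with monomorphic markers in a dedicated "fixed" bin.

Only entries flagged as imputed (withheld markers) are ever scored.
Undefined correlations (zero variance on either side) are reported as NaN
sentinels and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gio import MISSING, GenotypeMatrix
from .lsimpute import IMPUTED, ImputationResult

CORRECT, FALSE_HET, FALSE_HOM, DISCORDANT = 0, 1, 2, 3
ERROR_LABELS = ("correct", "false_het", "false_hom", "discordant")

MAF_BIN_EDGES = np.round(np.arange(0.0, 0.501, 0.05), 2)


def classify_errors(truth, imputed):
    """Error class per genotype pair; scalars in -> label string out.

    AA/BB imputed as AB is a false heterozygote; AB imputed as AA/BB is a
    false homozygote; AA imputed as BB (or vice versa) is completely
    discordant.
    """
    t = np.asarray(truth)
    i = np.asarray(imputed)
    if ((t < 0) | (i < 0)).any():
        raise ValueError("missing genotypes must be excluded before classification")
    codes = np.full(t.shape, CORRECT, dtype=np.int8)
    codes[(t != i) & (i == 1)] = FALSE_HET
    codes[(t == 1) & (i != 1)] = FALSE_HOM
    codes[np.abs(t.astype(int) - i.astype(int)) == 2] = DISCORDANT
    if np.isscalar(truth) or codes.ndim == 0:
        return ERROR_LABELS[int(codes)]
    return codes


def iqs_from_table(table: np.ndarray) -> float:
    """IQS from a 3x3 truth-by-imputed contingency table.

    P0 = observed concordance, Pc = chance concordance from the marginals;
    IQS = (P0 - Pc) / (1 - Pc).  When both vectors are constant and equal
    (P0 = Pc = 1) the score is defined as 1.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p0 = np.trace(table) / n
    pc = float(table.sum(axis=1) @ table.sum(axis=0)) / n**2
    if np.isclose(pc, 1.0):
        return 1.0 if np.isclose(p0, 1.0) else 0.0
    return float((p0 - pc) / (1.0 - pc))


def concordance_from_table(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    return float(np.trace(table) / table.sum())


def contingency_table(truth, imputed) -> np.ndarray:
    t = np.asarray(truth, dtype=np.int64).ravel()
    i = np.asarray(imputed, dtype=np.int64).ravel()
    keep = (t >= 0) & (i >= 0)
    t, i = t[keep], i[keep]
    if t.size == 0:
        raise ValueError("no pairwise non-missing genotypes")
    return np.bincount(3 * t + i, minlength=9).reshape(3, 3)


def iqs(truth, imputed) -> float:
    """Chance-corrected concordance for one variant; may be negative."""
    return iqs_from_table(contingency_table(truth, imputed))


def pearson_r(x, y, centering: str = "raw", maf=None) -> float:
    """Product-moment correlation; NaN sentinel when either side is constant.

    ``maf-centered`` subtracts twice the per-entry MAF from both vectors
    before correlating (used for per-individual r across markers, where the
    centering constant differs by marker).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x >= 0) & (y >= 0) & ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no pairwise-complete data")
    if centering == "maf-centered":
        if maf is None:
            raise ValueError("maf-centered correlation requires per-entry MAF")
        m = 2.0 * np.asarray(maf, dtype=float)[keep]
        x = x - m
        y = y - m
    elif centering != "raw":
        raise ValueError(f"unknown centering: {centering}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def assign_maf_bins(maf: np.ndarray) -> pd.Series:
    """Half-open bins (0,0.05] ... (0.45,0.50]; MAF=0 -> 'fixed'."""
    maf = np.asarray(maf, dtype=float)
    labels = [
        f"({MAF_BIN_EDGES[i]:.2f},{MAF_BIN_EDGES[i + 1]:.2f}]"
        for i in range(len(MAF_BIN_EDGES) - 1)
    ]
    binned = pd.cut(maf, bins=MAF_BIN_EDGES, labels=labels, include_lowest=False)
    out = binned.astype(object)
    out[maf == 0] = "fixed"
    return pd.Series(out, name="maf_bin")


def _align(truth: GenotypeMatrix, imputed: ImputationResult):
    ids = imputed.marker_map["id"]
    tcols = truth.marker_index().get_indexer(ids)
    if (tcols < 0).any():
        raise KeyError("imputed markers missing from truth matrix")
    if truth.sample_ids != imputed.sample_ids:
        raise ValueError("truth and imputed sample sets must match in order")
    return truth.calls[:, tcols]


def per_variant_accuracy(
    truth: GenotypeMatrix, imputed: ImputationResult, maf: np.ndarray
) -> pd.DataFrame:
    """Per-marker accuracy table over withheld (provenance=imputed) entries.

    ``maf`` is the panel-wide MAF aligned to ``imputed``'s markers (computed
    on the full study panel, not just the test samples).  Markers with no
    scored entries are dropped.
    """
    t = _align(truth, imputed)
    i = imputed.best_guess
    mask = (imputed.provenance == IMPUTED) & (t != MISSING) & (i != MISSING)
    if not mask.any():
        raise ValueError("no withheld entries to score")
    maf = np.asarray(maf, dtype=float)
    if maf.shape[0] != imputed.n_markers:
        raise ValueError("maf must align with imputed markers")

    counts = np.zeros((3, 3, imputed.n_markers), dtype=np.int64)
    for g in range(3):
        tg = (t == g) & mask
        for h in range(3):
            counts[g, h] = (tg & (i == h)).sum(axis=0)
    n_comp = counts.sum(axis=(0, 1))
    n_correct = counts[0, 0] + counts[1, 1] + counts[2, 2]
    n_false_het = counts[0, 1] + counts[2, 1]
    n_false_hom = counts[1, 0] + counts[1, 2]
    n_disc = counts[0, 2] + counts[2, 0]

    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(n_comp > 0, n_correct / n_comp, np.nan)
        row = counts.sum(axis=1)  # truth marginals (3, M)
        col = counts.sum(axis=0)
        pc = (row * col).sum(axis=0) / np.where(n_comp > 0, n_comp, 1) ** 2
        iqs_v = np.where(
            np.isclose(pc, 1.0),
            np.where(np.isclose(conc, 1.0), 1.0, 0.0),
            (conc - pc) / (1.0 - pc),
        )

    # column-wise Pearson r on masked entries
    tm = np.where(mask, t, 0).astype(float)
    im = np.where(mask, i, 0).astype(float)
    n = mask.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mt = tm.sum(axis=0) / n
        mi = im.sum(axis=0) / n
        st = (np.where(mask, (t - mt) ** 2, 0)).sum(axis=0)
        si = (np.where(mask, (i - mi) ** 2, 0)).sum(axis=0)
        cov = (np.where(mask, (t - mt) * (i - mi), 0)).sum(axis=0)
        r = np.where((st > 0) & (si > 0), cov / np.sqrt(st * si), np.nan)

    df = pd.DataFrame(
        {
            "marker_id": imputed.marker_map["id"].to_numpy(),
            "chrom": imputed.marker_map["chrom"].to_numpy(),
            "pos": imputed.marker_map["pos"].to_numpy(),
            "maf": maf,
            "n_compared": n_comp,
            "concordance": conc,
            "iqs": iqs_v,
            "r": r,
            "n_false_het": n_false_het,
            "n_false_hom": n_false_hom,
            "n_discordant": n_disc,
        }
    )
    df["n_errors"] = df[["n_false_het", "n_false_hom", "n_discordant"]].sum(axis=1)
    df["maf_bin"] = assign_maf_bins(maf).to_numpy()
    return df[df["n_compared"] > 0].reset_index(drop=True)


def per_individual_accuracy(
    truth: GenotypeMatrix, imputed: ImputationResult, maf: np.ndarray
) -> pd.DataFrame:
    """Per-sample r (raw and MAF-centered) and error counts."""
    t = _align(truth, imputed)
    i = imputed.best_guess
    mask = (imputed.provenance == IMPUTED) & (t != MISSING) & (i != MISSING)
    if not mask.any():
        raise ValueError("no withheld entries to score")
    maf = np.asarray(maf, dtype=float)
    codes = np.full(t.shape, -1, dtype=np.int8)
    codes[mask] = classify_errors(t[mask], i[mask])

    rows = []
    for k, sid in enumerate(imputed.sample_ids):
        m = mask[k]
        tv, iv = t[k, m].astype(float), i[k, m].astype(float)
        c = codes[k, m]
        r_raw = pearson_r(tv, iv) if tv.size else float("nan")
        r_cent = (
            pearson_r(tv, iv, centering="maf-centered", maf=maf[m]) if tv.size else float("nan")
        )
        rows.append(
            {
                "sample_id": sid,
                "n_compared": int(m.sum()),
                "r_raw": r_raw,
                "r_centered": r_cent,
                "n_false_het": int((c == FALSE_HET).sum()),
                "n_false_hom": int((c == FALSE_HOM).sum()),
                "n_discordant": int((c == DISCORDANT).sum()),
            }
        )
    df = pd.DataFrame(rows)
    df["total_errors"] = df[["n_false_het", "n_false_hom", "n_discordant"]].sum(axis=1)
    return df


def binned_summary(va: pd.DataFrame) -> pd.DataFrame:
    """Mean concordance/r/IQS per MAF bin, with unscorable-r counts."""
    order = ["fixed"] + [
        f"({MAF_BIN_EDGES[i]:.2f},{MAF_BIN_EDGES[i + 1]:.2f}]"
        for i in range(len(MAF_BIN_EDGES) - 1)
    ]
    g = va.groupby("maf_bin", sort=False)
    out = g.agg(
        n_markers=("marker_id", "size"),
        concordance=("concordance", "mean"),
        r=("r", "mean"),
        iqs=("iqs", "mean"),
        iqs_sd=("iqs", "std"),
        n_r_undefined=("r", lambda s: int(s.isna().sum())),
        total_errors=("n_errors", "sum"),
    ).reindex([b for b in order if b in set(va["maf_bin"])])
    return out.reset_index()


def region_scan(
    va: pd.DataFrame,
    iqs_threshold: float = 0.8,
    error_threshold: int = 10,
    window: int = 50,
    flag_fraction: float = 0.2,
) -> pd.DataFrame:
    """Flag genomic windows enriched in poorly imputed markers.

    Markers breach if IQS < iqs_threshold or error count > error_threshold;
    non-overlapping windows of ``window`` markers (per chromosome, position
    order) are flagged when the breaching fraction exceeds
    ``flag_fraction``.
    """
    rows = []
    for chrom, grp in va.groupby("chrom", sort=False):
        grp = grp.sort_values("pos").reset_index(drop=True)
        breach = (grp["iqs"] < iqs_threshold) | (grp["n_errors"] > error_threshold)
        for start in range(0, len(grp), window):
            w = grp.iloc[start : start + window]
            wb = breach.iloc[start : start + window]
            frac = wb.mean()
            if frac > flag_fraction:
                rows.append(
                    {
                        "chrom": chrom,
                        "start_pos": int(w["pos"].iloc[0]),
                        "end_pos": int(w["pos"].iloc[-1]),
                        "n_markers": len(w),
                        "n_breaching": int(wb.sum()),
                        "breach_fraction": float(frac),
                        "breaching_markers": ",".join(w.loc[wb.to_numpy(), "marker_id"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_pos", "end_pos", "n_markers",
            "n_breaching", "breach_fraction", "breaching_markers",
        ],
    )


@dataclass
class PanelComparison:
    """Paired comparison of per-variant IQS between two scenarios (b - a)."""

    n: int
    mean_diff: float
    t_stat: float
    t_pvalue: float
    f_stat: float
    f_pvalue: float
    n_improved: int
    n_worsened: int
    n_unchanged: int
    mean_gain_improved: float
    mean_loss_worsened: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compare_panels(a: pd.DataFrame, b: pd.DataFrame) -> PanelComparison:
    """Paired t (mean IQS difference), variance-ratio F, and change counts.

    ``a`` and ``b`` are per-variant tables over the same markers (e.g. the
    breed-reference and composite-reference scenarios); the difference is
    b - a, so positive means b improved on a.
    """
    if list(a["marker_id"]) != list(b["marker_id"]):
        raise ValueError("panel comparison requires identical marker sets in order")
    x = a["iqs"].to_numpy(dtype=float)
    y = b["iqs"].to_numpy(dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    d = y - x
    n = d.size
    if n < 2:
        raise ValueError("need at least two paired markers")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat = mean_d / (sd_d / np.sqrt(n))
        t_p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    var_x, var_y = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if var_y == 0 or var_x == 0:
        f_stat, f_p = float("nan"), float("nan")
    else:
        f_stat = var_x / var_y
        p_right = float(stats.f.sf(f_stat, n - 1, n - 1))
        f_p = float(min(1.0, 2.0 * min(p_right, 1.0 - p_right)))
    improved = d > 0
    worsened = d < 0
    return PanelComparison(
        n=n,
        mean_diff=mean_d,
        t_stat=float(t_stat),
        t_pvalue=t_p,
        f_stat=f_stat,
        f_pvalue=f_p,
        n_improved=int(improved.sum()),
        n_worsened=int(worsened.sum()),
        n_unchanged=int((d == 0).sum()),
        mean_gain_improved=float(d[improved].mean()) if improved.any() else 0.0,
        mean_loss_worsened=float(np.abs(d[worsened]).mean()) if worsened.any() else 0.0,
    )


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across scenario groups (report helper)."""
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
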