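"""Genotype containers, VCF / PLINK-text I/O and call-rate QC.

Genotypes are alternate-allele counts coded 0, 1, 2 (AA, AB, BB) with -1 for
missing.  VCF reading goes through cyvcf2; writing emits plain VCF 4.2 text.
PLINK PED/MAP files are whitespace-delimited; an extended 6-column MAP
(.bim-style, columns 5-6 = A1/A2 = counted/other allele) makes allele
orientation explicit, and when it is absent the counted allele is inferred
as the minor allele, following PLINK's A1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_AUTOSOME_EXCLUDE = {"X", "Y", "XY", "MT", "M", "0"}


@dataclass
class GenotypeMatrix:
    """Sample-by-marker alternate-allele counts over {0,1,2,missing}."""

    calls: np.ndarray
    marker_map: pd.DataFrame
    sample_ids: list[str]
    phased: bool = False
    _maf: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x markers)")
        if self.calls.shape != (len(self.sample_ids), len(self.marker_map)):
            raise ValueError("calls shape must match sample and marker counts")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2,missing}")
        if self.marker_map["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def marker_index(self) -> pd.Index:
        return pd.Index(self.marker_map["id"])

    def marker_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        if self._maf is None:
            self._maf = compute_maf(self)
        return self._maf

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = self.marker_index().get_indexer(marker_ids)
        if (idx < 0).any():
            bad = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not in matrix: {bad[:5]}")
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            marker_map=self.marker_map.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            phased=self.phased,
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = np.array([pos[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            calls=self.calls[rows],
            marker_map=self.marker_map.copy(),
            sample_ids=list(ids),
            phased=self.phased,
        )


def compute_maf(g: GenotypeMatrix, marker_ids: list[str] | None = None) -> np.ndarray:
    """Minor allele frequency min(f, 1-f) per marker; errors on all-missing."""
    gm = g if marker_ids is None else g.subset_markers(marker_ids)
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = gm.marker_map["id"].to_numpy()[n_obs == 0]
        raise ValueError(f"all calls missing for markers: {bad[:5].tolist()}")
    f = np.where(obs, gm.calls, 0).sum(axis=0) / (2.0 * n_obs)
    return np.minimum(f, 1.0 - f)


def qc_filter(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Call-rate and autosome QC; no MAF filter, no HWE filter.

    Non-autosomal markers are removed first, then markers with call rate
    strictly below ``min_call_rate``, then samples with call rate strictly
    below the threshold computed on the surviving markers.  The comparison
    is strict: a call rate exactly at the threshold is kept.
    """
    if not 0.0 < min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in (0,1]")
    log_rows: list[tuple[str, str, str, float]] = []
    out = g

    if autosomes_only:
        chrom = out.marker_map["chrom"].astype(str)
        is_auto = ~chrom.str.upper().isin(_AUTOSOME_EXCLUDE) & chrom.str.isdigit()
        drop = out.marker_map["id"][~is_auto]
        for m in drop:
            log_rows.append((m, "marker", "non-autosomal", np.nan))
        if (~is_auto).any():
            out = out.subset_markers(out.marker_map["id"][is_auto].tolist())

    rate = out.marker_call_rate()
    low = rate < min_call_rate
    for m, r in zip(out.marker_map["id"][low], rate[low]):
        log_rows.append((m, "marker", "call_rate", float(r)))
    if low.any():
        out = out.subset_markers(out.marker_map["id"][~low].tolist())
    if out.n_markers == 0:
        raise ValueError("no markers survive QC filtering")

    srate = out.sample_call_rate()
    slow = srate < min_call_rate
    for s, r in zip(np.array(out.sample_ids)[slow], srate[slow]):
        log_rows.append((s, "sample", "call_rate", float(r)))
    if slow.any():
        keep = [s for s, bad in zip(out.sample_ids, slow) if not bad]
        out = out.subset_samples(keep)
    if out.n_samples == 0:
        raise ValueError("no samples survive QC filtering")

    log = pd.DataFrame(log_rows, columns=["entity", "type", "reason", "value"])
    return out, log


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(marker_map: pd.DataFrame, sample_ids: list[str], with_ds: bool) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=herdimpute"]
    for c in marker_map["chrom"].astype(str).unique():
        max_pos = int(marker_map.loc[marker_map["chrom"].astype(str) == c, "pos"].max())
        lines.append(f"##contig=<ID={c},length={max_pos + 1000}>")
    if with_ds:
        lines.append('##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Genotypes at this site were imputed">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_ds:
        lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


_GT_UNPHASED = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, g: GenotypeMatrix) -> None:
    """Write unphased (or trivially phased) genotype calls as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(g.marker_map, g.sample_ids, with_ds=False))
        mm = g.marker_map
        for j in range(g.n_markers):
            row = mm.iloc[j]
            gts = "\t".join(_GT_UNPHASED[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phased_vcf(path, panel) -> None:
    """Write a HaplotypePanel as phased VCF (GT with '|' separator)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.marker_map, panel.sample_ids, with_ds=False))
        mm = panel.marker_map
        h1 = panel.alleles[0::2]
        h2 = panel.alleles[1::2]
        for j in range(panel.n_markers):
            row = mm.iloc[j]
            gts = "\t".join(f"{a}|{b}" for a, b in zip(h1[:, j], h2[:, j]))
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_sample_metadata(path, panel) -> None:
    """Sidecar TSV: sample_id, breed, admixture proportions."""
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\tproportions\n")
        for s in panel.sample_ids:
            props = panel.admixture.get(s, {panel.breed_of[s]: 1.0})
            ptxt = ",".join(f"{b}:{p:g}" for b, p in props.items())
            fh.write(f"{s}\t{panel.breed_of[s]}\t{ptxt}\n")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    rows = []
    calls = []
    phased = True
    for rec_no, var in enumerate(v, start=1):
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic site not supported: {var.ID or f'{var.CHROM}:{var.POS}'}"
            )
        try:
            gts = np.asarray(var.genotypes, dtype=object)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{rec_no} in {path}") from exc
        a = np.array([g[0] for g in gts], dtype=int)
        b = np.array([g[1] for g in gts], dtype=int)
        call = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        if not all(bool(g[2]) for g in gts):
            phased = False
        rows.append((str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0]))
        calls.append(call)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    marker_map = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(
        calls=np.array(calls, dtype=np.int8).T,
        marker_map=marker_map,
        sample_ids=samples,
        phased=phased,
    )


def read_phased_haplotypes(path):
    """Read a fully phased VCF into a HaplotypePanel (breed labels unknown)."""
    from cyvcf2 import VCF

    from .simpop import HaplotypePanel

    v = VCF(str(path))
    samples = list(v.samples)
    rows = []
    haps = []
    for rec_no, var in enumerate(v, start=1):
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site in record #{rec_no}")
        gts = var.genotypes
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if g[0] < 0 or g[1] < 0:
                raise ValueError(f"missing haplotype in phased VCF record #{rec_no}")
            if not g[2]:
                raise ValueError(f"unphased genotype in record #{rec_no}")
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        rows.append((str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0]))
        haps.append(col)
    marker_map = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return HaplotypePanel(
        alleles=np.array(haps, dtype=np.int8).T,
        marker_map=marker_map,
        sample_ids=samples,
        breed_of={s: "NA" for s in samples},
    )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def write_plink(prefix, g: GenotypeMatrix) -> None:
    """Write .ped/.map; the MAP carries A1/A2 columns (A1 = counted/alt)."""
    mm = g.marker_map
    with open(f"{prefix}.map", "w") as fh:
        for _, row in mm.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['id']}\t0\t{int(row['pos'])}\t{row['alt']}\t{row['ref']}\n"
            )
    code = {
        MISSING: "0 0",
    }
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(g.n_markers):
                c = int(g.calls[i, j])
                ref, alt = mm.iloc[j]["ref"], mm.iloc[j]["alt"]
                if c == MISSING:
                    fields.append("0 0")
                elif c == 0:
                    fields.append(f"{ref} {ref}")
                elif c == 1:
                    fields.append(f"{ref} {alt}")
                else:
                    fields.append(f"{alt} {alt}")
            fh.write(" ".join(fields) + "\n")


def _read_plink(prefix) -> GenotypeMatrix:
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] == 4:
        mp.columns = ["chrom", "id", "cm", "pos"]
        declared = False
    elif mp.shape[1] == 6:
        mp.columns = ["chrom", "id", "cm", "pos", "a1", "a2"]
        declared = True
    else:
        raise ValueError(f"MAP file must have 4 or 6 columns, found {mp.shape[1]}")
    if mp["id"].duplicated().any():
        raise ValueError("duplicate marker ids in MAP")
    n_markers = len(mp)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"malformed PED line {line_no}: expected {6 + 2 * n_markers} fields, "
                    f"found {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object).reshape(n_markers, 2))
    if not allele_rows:
        raise ValueError(f"no samples in {ped_path}")
    alleles = np.stack(allele_rows)  # (n_samples, n_markers, 2)

    calls = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_markers):
        col = alleles[:, j, :]
        obs_mask = (col != "0").all(axis=1)
        observed = col[obs_mask].ravel()
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"marker {mp['id'][j]}: more than two alleles in PED")
        if declared:
            a1, a2 = mp["a1"][j], mp["a2"][j]
        else:
            if len(uniq) == 0:
                a1, a2 = "0", "0"
            elif len(uniq) == 1:
                a1, a2 = "0", uniq[0]  # monomorphic: counted allele unseen
            else:
                # PLINK convention: A1 = minor; tie broken lexicographically
                order = np.lexsort((uniq, counts))
                a1, a2 = uniq[order[0]], uniq[order[1]]
        a1_list.append(a1)
        a2_list.append(a2)
        calls[obs_mask, j] = (col[obs_mask] == a1).sum(axis=1)
    mm = pd.DataFrame(
        {
            "chrom": mp["chrom"],
            "pos": mp["pos"].astype(int),
            "id": mp["id"],
            "ref": a2_list,
            "alt": a1_list,
        }
    )
    return GenotypeMatrix(calls=calls, marker_map=mm, sample_ids=sample_ids, phased=False)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from ``vcf`` (file path) or ``plink-text`` (prefix)."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink(path)
    raise ValueError(f"unknown format: {format}")
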