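"""File formats, region definitions and configuration I/O.

Genotypes move as PLINK bed/bim/fam or VCF (GT field, hard calls);
phenotypes and design tables as CSV with the documented column names;
scenarios and pipeline configuration as YAML. Dosages are always coded
on the minor allele as observed in the loaded cohort; a file whose coded
allele turns out to be the major one is flipped with a warning, never
silently, and strand-ambiguous (A/T, G/C) SNPs are flagged. Coordinates
are 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix
from .simulate import CohortScenario

__all__ = [
    "RegionDefinition",
    "DEFAULT_REGIONS",
    "select_region_snps",
    "read_genotypes",
    "write_vcf",
    "read_vcf",
    "write_plink",
    "read_plink",
    "read_table",
    "write_table",
    "load_scenario",
    "save_scenario",
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("G", "C"))}


@dataclass(frozen=True)
class RegionDefinition:
    """A candidate-gene interval (1-based inclusive, hg19-style).

    An explicit ``snp_ids`` list, when given, overrides the interval.
    """

    gene: str
    chrom: str
    start: int
    end: int
    snp_ids: tuple = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start must be <= end")


#: The two study regions (hg19): CNTNAP2 exons 13-14 and the NRXN1
#: 5' region (exons 1-4 plus 20 kb upstream).
DEFAULT_REGIONS = (
    RegionDefinition("CNTNAP2", "7", 147_514_390, 147_612_852),
    RegionDefinition("NRXN1", "2", 51_141_501, 51_280_121),
)


def select_region_snps(G: GenotypeMatrix, region: RegionDefinition) -> GenotypeMatrix:
    """Subset to SNPs inside the region (boundaries inclusive) or its id list."""
    if region.snp_ids is not None:
        return G.subset_snp_ids(region.snp_ids)
    chrom = G.snps["chrom"].astype(str).str.removeprefix("chr")
    want_chrom = str(region.chrom).removeprefix("chr")
    pos = G.snps["pos"].to_numpy()
    mask = (chrom == want_chrom).to_numpy() & (pos >= region.start) & (pos <= region.end)
    return G.subset_snps(mask)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Plain-text VCF 4.2 with GT hard calls; ALT is the minor allele."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Candidate gene region">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(G.snps["chrom"].astype(str)))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        # panel order is preserved (round-trips losslessly); callers wanting
        # coordinate-sorted output can sort the SNP table first
        for j in range(G.n_snps):
            row = G.snps.iloc[j]
            gts = "\t".join(gt_map[int(v)] for v in G.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                f"{row['allele_major']}\t{row['allele_minor']}\t.\tPASS\t"
                f"GENE={row['gene']}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF; recode to the minor allele.

    ALT-allele dosages whose cohort frequency exceeds 0.5 are flipped to
    the minor allele with a warning; strand-ambiguous A/T and G/C sites
    are flagged (warning list, never silent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, meta = [], []
    ambiguous, flipped = [], []
    for var in vcf:
        ref = var.REF
        alt = var.ALT[0] if var.ALT else "."
        if frozenset((ref, alt)) in _AMBIGUOUS_PAIRS:
            ambiguous.append(var.ID)
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (cyvcf2 gts012)
        gts = var.gt_types
        dos = np.where(gts == 3, MISSING, np.where(gts == 2, 2, gts)).astype(np.int8)
        called = dos[dos != MISSING]
        freq = called.mean() / 2.0 if len(called) else 0.0
        a_minor, a_major = alt, ref
        if freq > 0.5:
            dos = np.where(dos == MISSING, MISSING, 2 - dos).astype(np.int8)
            a_minor, a_major = ref, alt
            flipped.append(var.ID)
        gene = dict(var.INFO).get("GENE", "")
        dosages.append(dos)
        meta.append((var.ID, var.CHROM, var.POS, gene, a_minor, a_major))
    vcf.close()
    if ambiguous:
        warnings.warn(f"strand-ambiguous (A/T or G/C) SNPs: {ambiguous}")
    if flipped:
        warnings.warn(f"coded allele was the major allele; flipped to minor: {flipped}")
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "gene",
                                       "allele_minor", "allele_major"])
    return GenotypeMatrix(np.array(dosages, dtype=np.int8).T, samples, snps)


# ----------------------------------------------------------------------
# PLINK bed/bim/fam (hand-rolled 2-bit codec)
# ----------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit code -> dosage of allele A1 (bim column 5, conventionally minor)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(G: GenotypeMatrix, prefix, pedigree: pd.DataFrame | None = None) -> None:
    """Write bed/bim/fam; A1 = minor allele, dosages code A1 copies."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "snp_id": G.snps["snp_id"],
            "cm": 0,
            "pos": G.snps["pos"],
            "a1": G.snps["allele_minor"],
            "a2": G.snps["allele_major"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    parents = {}
    if pedigree is not None:
        parents = {
            r.child: (r.father, r.mother) for r in pedigree.itertuples()
        }
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in G.samples:
            pat, mat = parents.get(s, ("0", "0"))
            fh.write(f"{s} {s} {pat} {mat} 0 -9\n")
    n = G.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(G.n_snps):
            buf[:] = 0
            for i, dose in enumerate(G.dosages[:, j]):
                buf[i // 4] |= _BED_ENCODE[int(dose)] << (2 * (i % 4))
            fh.write(buf.tobytes())


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read bed/bim/fam; returns the matrix and the pedigree columns.

    Dosages are recoded to the cohort minor allele when the file's A1
    turns out to be the major allele (reported, not silent).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    samples = list(fam["iid"])
    n, m = len(samples), len(bim)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK bed file")
    body = raw[3:].reshape(m, n_bytes)
    # unpack 2-bit codes, sample-fastest within byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _BED_DECODE[codes].T.copy()  # (n, m), counts of A1

    flipped = []
    a_minor = bim["a1"].to_numpy().copy()
    a_major = bim["a2"].to_numpy().copy()
    for j in range(m):
        col = dosages[:, j]
        called = col[col != MISSING]
        if len(called) and called.mean() / 2.0 > 0.5:
            col[col != MISSING] = 2 - col[col != MISSING]
            a_minor[j], a_major[j] = a_major[j], a_minor[j]
            flipped.append(bim["snp_id"].iloc[j])
    if flipped:
        warnings.warn(f"A1 was the major allele; recoded to minor: {flipped}")
    ambiguous = [
        s for s, x, y in zip(bim["snp_id"], a_minor, a_major)
        if frozenset((x, y)) in _AMBIGUOUS_PAIRS
    ]
    if ambiguous:
        warnings.warn(f"strand-ambiguous (A/T or G/C) SNPs: {ambiguous}")
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "gene": "",
            "allele_minor": a_minor,
            "allele_major": a_major,
        }
    )
    pedigree = fam.loc[(fam["father"] != "0") & (fam["mother"] != "0"),
                       ["iid", "mother", "father"]].rename(columns={"iid": "child"})
    return GenotypeMatrix(dosages, samples, snps), pedigree


def read_genotypes(path, fmt: str | None = None):
    """Dispatch on format: ``"vcf"`` or ``"plink"`` (bed/bim/fam prefix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "plink"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "plink":
        G, _ = read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
        return G
    raise ValueError(f"unknown genotype format: {fmt!r}")


# ----------------------------------------------------------------------
# Tables and configuration
# ----------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_scenario(scenario: CohortScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)


def load_scenario(path) -> CohortScenario:
    with open(path) as fh:
        return CohortScenario.from_dict(yaml.safe_load(fh))
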