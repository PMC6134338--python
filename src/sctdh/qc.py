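"""Genotype quality-control cascade and LD reporting.

Implements the study-style filter cascade, applied in this fixed order:

1. sample call rate (success rate >= 95%),
2. sample heterozygosity (within +/- 2 SD of the mean het rate),
3. SNP Hardy-Weinberg equilibrium (exact conditional test, p >= 1e-6),
4. SNP minor allele frequency (MAF >= 1%),
5. SNP Mendelian inheritance errors in trios (error rate <= 1%, with
   surviving inconsistent genotypes set to missing).

Boundary conventions: call rate and MAF are inclusive (a value exactly at
the threshold passes); the heterozygosity bound is exclusive (strictly
outside +/- k SD is removed). The HWE test is the exact conditional test
on genotype counts, which stays correct at the extreme 1e-6 threshold
where the chi-square approximation does not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCStep",
    "QCReport",
    "QCError",
    "sample_call_rate_filter",
    "heterozygosity_filter",
    "hwe_exact_test",
    "hwe_filter",
    "maf_filter",
    "mendelian_error_filter",
    "pairwise_r2",
    "run_qc",
]

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


class QCError(RuntimeError):
    """Raised when a QC stage leaves nothing to analyse."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


@dataclass
class QCThresholds:
    """Filter thresholds; defaults mirror the study's published cascade."""

    min_sample_call_rate: float = 0.95
    het_sd_bound: float = 2.0
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    mendel_error_max: float = 0.01
    ld_report_r2: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_sample_call_rate <= 1.0):
            raise ValueError("min_sample_call_rate must be a proportion")
        if self.het_sd_bound <= 0:
            raise ValueError("het_sd_bound must be positive")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must be a probability")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.mendel_error_max <= 1.0):
            raise ValueError("mendel_error_max must be a proportion")
        if not (0.0 <= self.ld_report_r2 <= 1.0):
            raise ValueError("ld_report_r2 must be in [0, 1]")


@dataclass
class QCStep:
    """One applied filter: what it removed and why."""

    name: str
    axis: str  # "samples" or "snps"
    n_removed: int
    removed_ids: list
    details: dict = field(default_factory=dict)


@dataclass
class QCReport:
    """Ordered record of the applied cascade."""

    input_shape: tuple
    steps: list = field(default_factory=list)
    output_shape: tuple = None

    def add(self, step: QCStep) -> None:
        self.steps.append(step)

    def removed_count(self, axis: str) -> int:
        return sum(s.n_removed for s in self.steps if s.axis == axis)

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape) if self.output_shape else None,
            "steps": [asdict(s) for s in self.steps],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = [f"QC input: {self.input_shape[0]} samples x {self.input_shape[1]} SNPs"]
        for s in self.steps:
            lines.append(f"  {s.name}: removed {s.n_removed} {s.axis}")
            for key, val in s.details.items():
                lines.append(f"    {key}: {val}")
        if self.output_shape:
            lines.append(
                f"QC output: {self.output_shape[0]} samples x {self.output_shape[1]} SNPs"
            )
        return "\n".join(lines)


def _check_autosomal(G: GenotypeMatrix, allow_nonautosomal: bool) -> None:
    if allow_nonautosomal:
        return
    bad = sorted(set(map(str, G.snps["chrom"])) - _AUTOSOMES)
    if bad:
        raise ValueError(
            f"non-autosomal chromosomes in input: {bad}; this QC cascade "
            "handles autosomes only (pass allow_nonautosomal=True to override)"
        )


# ----------------------------------------------------------------------
# Sample-level filters
# ----------------------------------------------------------------------

def sample_call_rate_filter(G: GenotypeMatrix, thresholds: QCThresholds) -> tuple[GenotypeMatrix, QCStep]:
    """Drop samples with genotype success rate below the threshold (inclusive pass)."""
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    rates = G.sample_call_rate()
    keep = rates >= thresholds.min_sample_call_rate
    removed = [s for s, k in zip(G.samples, keep) if not k]
    step = QCStep(
        "sample_call_rate", "samples", len(removed), removed,
        {"threshold": thresholds.min_sample_call_rate},
    )
    if not keep.any():
        raise QCError("all samples removed by call-rate filter", None)
    return G.subset_samples(keep), step


def heterozygosity_filter(G: GenotypeMatrix, thresholds: QCThresholds) -> tuple[GenotypeMatrix, QCStep]:
    """Drop samples with het rate strictly outside mean +/- k SD of the input set."""
    if G.n_samples < 3:
        raise ValueError("need >= 3 samples for a defined het-rate SD")
    rates = G.sample_het_rate()
    mean, sd = float(np.nanmean(rates)), float(np.nanstd(rates, ddof=1))
    if sd == 0.0:
        warnings.warn("het rates have zero variance; no heterozygosity outliers removed")
        keep = np.ones(G.n_samples, dtype=bool)
    else:
        lo = mean - thresholds.het_sd_bound * sd
        hi = mean + thresholds.het_sd_bound * sd
        keep = (rates >= lo) & (rates <= hi)
    removed = [s for s, k in zip(G.samples, keep) if not k]
    step = QCStep(
        "heterozygosity", "samples", len(removed), removed,
        {"mean": mean, "sd": sd, "sd_bound": thresholds.het_sd_bound},
    )
    if not keep.any():
        raise QCError("all samples removed by heterozygosity filter", None)
    return G.subset_samples(keep), step


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value (no mid-p correction).

    Conditional on the allele counts, the heterozygote count follows the
    exact distribution P(n_Aa | n, n_A) proportional to
    n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa; the p-value sums the probabilities
    of all heterozygote counts at most as probable as the observed one.
    Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes the choice moot
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # feasible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
        + hets * np.log(2.0)
    )
    logp -= gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_A + 1)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(np.flatnonzero(hets == n_Aa)[0])
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_filter(G: GenotypeMatrix, thresholds: QCThresholds,
               sample_ids=None) -> tuple[GenotypeMatrix, QCStep]:
    """Drop SNPs with exact HWE p below the threshold.

    ``sample_ids`` restricts the population used for the test (e.g. one
    twin per pair, excluding trisomy probands whose genotype calling is
    atypical); the filter itself still applies to every sample.
    """
    if sample_ids is not None:
        sub = G.subset_samples(G.sample_positions(sample_ids))
    else:
        sub = G
    keep = np.ones(G.n_snps, dtype=bool)
    pvals = {}
    for j in range(G.n_snps):
        n0, n1, n2 = sub.genotype_counts(j)
        if n0 + n1 + n2 == 0:
            continue
        p = hwe_exact_test(n0, n1, n2)
        pvals[G.snps["snp_id"].iloc[j]] = p
        if p < thresholds.hwe_p_min:
            keep[j] = False
    removed = list(G.snps["snp_id"][~keep])
    step = QCStep(
        "hwe_exact", "snps", len(removed), removed,
        {
            "threshold": thresholds.hwe_p_min,
            "population": "all samples" if sample_ids is None else f"{len(sample_ids)} designated samples",
        },
    )
    return G.subset_snps(keep), step


def maf_filter(G: GenotypeMatrix, thresholds: QCThresholds) -> tuple[GenotypeMatrix, QCStep]:
    """Drop SNPs with MAF below the threshold (exactly-at-threshold passes)."""
    maf = G.maf()
    keep = maf >= thresholds.maf_min
    removed = list(G.snps["snp_id"][~keep])
    step = QCStep("maf", "snps", len(removed), removed, {"threshold": thresholds.maf_min})
    return G.subset_snps(keep), step


# ----------------------------------------------------------------------
# Mendelian errors
# ----------------------------------------------------------------------

def _mendel_consistent(child: int, mother: int, father: int) -> bool:
    """Can the child genotype arise from the parental pair? (biallelic)."""
    transmit = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(
        tm + tf == child for tm in transmit[mother] for tf in transmit[father]
    )


def mendelian_error_filter(G: GenotypeMatrix, pedigree: pd.DataFrame,
                           thresholds: QCThresholds) -> tuple[GenotypeMatrix, QCStep]:
    """Trio-based inheritance-error filter.

    ``pedigree`` needs columns ``child``, ``mother``, ``father`` referring
    to sample ids present in ``G``. Per SNP, the error rate is
    inconsistent / informative trios; SNPs above the threshold are
    dropped, and for surviving SNPs the genotypes of every member of an
    inconsistent trio are set missing. With no usable trios the filter is
    skipped with a warning.
    """
    lookup = {s: i for i, s in enumerate(G.samples)}
    trios = [
        (lookup[r.child], lookup[r.mother], lookup[r.father])
        for r in pedigree.itertuples()
        if r.child in lookup and r.mother in lookup and r.father in lookup
    ]
    if not trios:
        warnings.warn("no complete trios in pedigree; Mendelian-error filter skipped")
        step = QCStep("mendelian_errors", "snps", 0, [], {"skipped": "no trios"})
        return G, step

    d = G.dosages
    n_snps = G.n_snps
    err_rate = np.zeros(n_snps)
    inconsistent = np.zeros((len(trios), n_snps), dtype=bool)
    for t, (ci, mi, fi) in enumerate(trios):
        for j in range(n_snps):
            c, m, f = int(d[ci, j]), int(d[mi, j]), int(d[fi, j])
            if MISSING in (c, m, f):
                continue
            if not _mendel_consistent(c, m, f):
                inconsistent[t, j] = True
    informative = np.zeros(n_snps, dtype=int)
    for j in range(n_snps):
        count = 0
        for (ci, mi, fi) in trios:
            if MISSING not in (int(d[ci, j]), int(d[mi, j]), int(d[fi, j])):
                count += 1
        informative[j] = count
    with np.errstate(invalid="ignore"):
        err_rate = np.where(informative > 0, inconsistent.sum(axis=0) / np.maximum(informative, 1), 0.0)

    keep = err_rate <= thresholds.mendel_error_max
    removed = list(G.snps["snp_id"][~keep])
    out = G.subset_snps(keep)
    # blank surviving inconsistent genotypes (whole trio at the offending SNP)
    surviving_cols = np.flatnonzero(keep)
    n_blanked = 0
    for t, (ci, mi, fi) in enumerate(trios):
        for new_j, old_j in enumerate(surviving_cols):
            if inconsistent[t, old_j]:
                out.dosages[[ci, mi, fi], new_j] = MISSING
                n_blanked += 3
    step = QCStep(
        "mendelian_errors", "snps", len(removed), removed,
        {
            "threshold": thresholds.mendel_error_max,
            "n_trios": len(trios),
            "genotypes_set_missing": n_blanked,
        },
    )
    return out, step


# ----------------------------------------------------------------------
# LD reporting
# ----------------------------------------------------------------------

def pairwise_r2(G: GenotypeMatrix, region=None,
                report_threshold: float = 0.8) -> tuple[pd.DataFrame, int]:
    """Pairwise squared dosage correlations within a region.

    ``region`` is a gene label (restricts to those SNPs) or ``None`` for
    the whole panel. Missing dosages are excluded pairwise; zero-variance
    SNPs give NaN rows/columns. Returns the symmetric r^2 matrix (as a
    labelled DataFrame with unit diagonal) and the number of distinct
    off-diagonal pairs above ``report_threshold``.
    """
    if region is not None:
        G = G.subset_snps((G.snps["gene"] == region).to_numpy())
    if G.n_snps < 2:
        raise ValueError("need at least two SNPs for pairwise r^2")
    d = pd.DataFrame(G.dosages_float(), columns=G.snp_ids)
    corr = d.corr(min_periods=2)  # pairwise-complete Pearson
    r2 = corr ** 2
    np.fill_diagonal(r2.values, 1.0)
    mat = r2.to_numpy()
    iu = np.triu_indices(G.n_snps, k=1)
    above = int(np.nansum(mat[iu] > report_threshold))
    return r2, above


# ----------------------------------------------------------------------
# The cascade
# ----------------------------------------------------------------------

def run_qc(G: GenotypeMatrix, pedigree: pd.DataFrame | None = None,
           thresholds: QCThresholds | None = None,
           hwe_sample_ids=None,
           allow_nonautosomal: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full cascade in the fixed published order.

    Order: sample call rate -> heterozygosity -> HWE -> MAF -> Mendelian.
    Heterozygosity bounds are computed once on the input to that stage
    (not iterated). Raises :class:`QCError` (with the partial report
    attached) if a stage removes everything.
    """
    thresholds = thresholds or QCThresholds()
    _check_autosomal(G, allow_nonautosomal)
    report = QCReport(input_shape=(G.n_samples, G.n_snps))
    try:
        G, step = sample_call_rate_filter(G, thresholds)
        report.add(step)
        G, step = heterozygosity_filter(G, thresholds)
        report.add(step)
        if hwe_sample_ids is not None:
            present = set(G.samples)
            hwe_sample_ids = [s for s in hwe_sample_ids if s in present]
        G, step = hwe_filter(G, thresholds, sample_ids=hwe_sample_ids)
        report.add(step)
        G, step = maf_filter(G, thresholds)
        report.add(step)
        if pedigree is not None:
            G, step = mendelian_error_filter(G, pedigree, thresholds)
            report.add(step)
        if G.n_snps == 0:
            raise QCError("all SNPs removed by QC cascade", report)
    except QCError as err:
        err.report = err.report or report
        raise
    report.output_shape = (G.n_samples, G.n_snps)
    return G, report
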