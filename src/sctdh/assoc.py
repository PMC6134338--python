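"""Exploratory per-SNP and gene-based association tests.

Complements the primary GSCA analysis with:

* per-SNP minor-allele regression (slope of phenotype on minor-allele
  count, with per-dosage group means for figure-style summaries);
* a p-value uniformity diagnostic (KS distance + decile table) for the
  whole SNP collection;
* a rare-variant burden test (cumulative carrier score across a gene,
  regressed on phenotype) for variants with MAF < 0.01;
* a SKAT-style variance-component score test on a weighted genotype
  kernel (MAF window up to 0.5), with the mixture-of-chi-squares p-value
  from the Liu et al. moment-matching approximation (exact Imhof
  characteristic-function inversion optional);
* the Bonferroni threshold for the SNP x phenotype test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .containers import GenotypeMatrix

__all__ = [
    "SnpAssocResult",
    "GeneTestResult",
    "UniformityDiagnostic",
    "snp_regression",
    "snp_scan",
    "pvalue_uniformity_check",
    "burden_test_zeggini",
    "skat_test",
    "bonferroni_threshold",
]


@dataclass
class SnpAssocResult:
    """OLS association of one phenotype with one SNP's minor-allele count."""

    snp_id: str
    phenotype: str
    group: str
    slope: float          # per minor-allele copy, phenotype in its own units
    beta_std: float       # fully standardized slope (= Pearson correlation)
    se: float
    p_value: float
    n: int
    testable: bool
    dosage_means: dict = field(default_factory=dict)  # dosage -> mean phenotype


@dataclass
class GeneTestResult:
    """Gene-based (burden or variance-component) test result."""

    gene: str
    test: str             # "burden" or "skat"
    statistic: float
    p_value: float
    n_variants: int
    maf_window: tuple
    n: int
    testable: bool
    detail: dict = field(default_factory=dict)


@dataclass
class UniformityDiagnostic:
    """KS distance from Uniform(0,1) plus a decile table."""

    ks_statistic: float
    ks_p_value: float
    decile_counts: np.ndarray
    n: int
    note: str


# ----------------------------------------------------------------------
# Per-SNP regression
# ----------------------------------------------------------------------

def snp_regression(dosage: np.ndarray, phenotype: np.ndarray,
                   snp_id: str = "", phenotype_name: str = "",
                   group: str = "all") -> SnpAssocResult:
    """OLS of phenotype on minor-allele count, two-sided t-test p.

    Missing values (NaN or negative dosage) are excluded pairwise.
    Monomorphic SNPs are flagged untestable rather than erroring.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    d = np.where(d < 0, np.nan, d)
    ok = ~(np.isnan(d) | np.isnan(y))
    d, y = d[ok], y[ok]
    n = len(d)
    means = {
        int(k): float(y[d == k].mean()) for k in (0, 1, 2) if np.any(d == k)
    }
    if n < 3 or np.unique(d).size < 2 or np.std(y) == 0:
        return SnpAssocResult(snp_id, phenotype_name, group, np.nan, np.nan,
                              np.nan, np.nan, n, False, means)
    fit = stats.linregress(d, y)
    beta_std = fit.slope * np.std(d) / np.std(y)
    return SnpAssocResult(
        snp_id, phenotype_name, group,
        float(fit.slope), float(beta_std), float(fit.stderr),
        float(fit.pvalue), n, True, means,
    )


def snp_scan(G: GenotypeMatrix, pheno: pd.DataFrame,
             measures=("nonword_repetition", "language_factor", "global_burden"),
             design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy table of snp_regression over every SNP x measure (x group)."""
    pheno = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    pheno = pheno.loc[[s for s in G.samples if s in pheno.index]]
    groups = {"all": np.arange(G.n_samples)}
    if design is not None:
        design = design.set_index("sample_id") if "sample_id" in design.columns else design
        lookup = {s: i for i, s in enumerate(G.samples)}
        groups = {
            str(g): np.array([lookup[s] for s in design.index[design["group"] == g] if s in lookup])
            for g in dict.fromkeys(design["group"])
        }
    d_all = G.dosages_float()
    rows = []
    for gname, idx in groups.items():
        for j, snp_id in enumerate(G.snp_ids):
            for measure in measures:
                res = snp_regression(
                    d_all[idx, j], pheno[measure].to_numpy()[idx],
                    snp_id=snp_id, phenotype_name=measure, group=gname,
                )
                rows.append(
                    {
                        "group": gname, "snp_id": snp_id, "phenotype": measure,
                        "slope": res.slope, "beta_std": res.beta_std,
                        "se": res.se, "p_value": res.p_value, "n": res.n,
                        "testable": res.testable,
                        **{f"mean_dosage_{k}": res.dosage_means.get(k, np.nan) for k in (0, 1, 2)},
                    }
                )
    return pd.DataFrame(rows)


def pvalue_uniformity_check(p_values, dependence_note: str | None = None) -> UniformityDiagnostic:
    """Descriptive check that a p-value collection looks Uniform(0, 1).

    The KS p-value ignores inter-SNP LD and phenotype correlations, so it
    is a descriptive diagnostic, not a calibrated test — the returned
    note says so.
    """
    p = np.asarray([x for x in np.asarray(p_values, dtype=float) if not np.isnan(x)])
    if len(p) < 10:
        raise ValueError("need at least 10 p-values for a uniformity check")
    ks = stats.kstest(p, "uniform")
    counts, _ = np.histogram(p, bins=np.linspace(0.0, 1.0, 11))
    note = dependence_note or (
        "descriptive only: KS calibration assumes independent tests; "
        "inter-SNP LD and phenotype correlations are not corrected for"
    )
    return UniformityDiagnostic(float(ks.statistic), float(ks.pvalue), counts, len(p), note)


# ----------------------------------------------------------------------
# Gene-based tests
# ----------------------------------------------------------------------

def _complete_cases(G_gene: GenotypeMatrix, phenotype: np.ndarray):
    y = np.asarray(phenotype, dtype=float)
    d = G_gene.dosages_float()
    ok = ~np.isnan(y)
    return d[ok], y[ok]


def burden_test_zeggini(G_gene: GenotypeMatrix, phenotype: np.ndarray,
                        maf_max: float = 0.01, coding: str = "proportion") -> GeneTestResult:
    """Rare-variant burden test: carrier score regressed on phenotype.

    The per-sample burden is, by default, the proportion of rare-variant
    sites (MAF strictly below ``maf_max``) at which the sample carries at
    least one minor allele; ``coding="count"`` uses the total minor-allele
    count instead. A constant burden column is flagged untestable.
    """
    if coding not in ("proportion", "count"):
        raise ValueError("coding must be 'proportion' or 'count'")
    gene = str(G_gene.snps["gene"].iloc[0]) if G_gene.n_snps else ""
    maf = G_gene.maf()
    rare = maf < maf_max
    n_var = int(rare.sum())
    if n_var == 0:
        return GeneTestResult(gene, "burden", np.nan, np.nan, 0, (0.0, maf_max),
                              G_gene.n_samples, False, {"reason": "no rare variants"})
    d, y = _complete_cases(G_gene.subset_snps(rare), phenotype)
    carrier = (d >= 1)
    if coding == "proportion":
        with np.errstate(invalid="ignore"):
            burden = np.nanmean(np.where(np.isnan(d), np.nan, carrier), axis=1)
    else:
        burden = np.nansum(d, axis=1)
    ok = ~np.isnan(burden)
    burden, y = burden[ok], y[ok]
    if len(burden) < 3 or np.std(burden) == 0:
        return GeneTestResult(gene, "burden", np.nan, np.nan, n_var, (0.0, maf_max),
                              len(burden), False, {"reason": "constant burden score"})
    fit = stats.linregress(burden, y)
    return GeneTestResult(
        gene, "burden", float(fit.slope / fit.stderr), float(fit.pvalue),
        n_var, (0.0, maf_max), len(burden), True,
        {"slope": float(fit.slope), "se": float(fit.stderr), "coding": coding},
    )


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching p-value for Q ~ sum lam_i chi^2_1."""
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    if c2 <= 0:
        return np.nan
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    t_star = (q - mu_q) / sigma_q
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def _imhof_pvalue(q: float, lam: np.ndarray) -> float:
    """Exact tail probability by Imhof's characteristic-function inversion."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))


def skat_test(G_gene: GenotypeMatrix, phenotype: np.ndarray,
              weights_scheme: str = "beta", maf_max: float = 0.5,
              method: str = "liu") -> GeneTestResult:
    """Variance-component (SKAT-style) score test for a gene's variant set.

    Q = (y - y0_hat)' G W^2 G' (y - y0_hat) under an intercept-only null
    model; the null distribution of Q is the weighted chi-square mixture
    with weights sigma^2 * eigvals(W G' (I - 11'/n) G W). Variant weights
    follow Beta(MAF; 1, 25) by default (up-weighting rare variants) or
    are flat with ``weights_scheme="flat"``. ``method`` selects the Liu
    moment-matching approximation (default) or exact Imhof inversion.
    """
    if weights_scheme not in ("beta", "flat"):
        raise ValueError("weights_scheme must be 'beta' or 'flat'")
    if method not in ("liu", "imhof"):
        raise ValueError("method must be 'liu' or 'imhof'")
    gene = str(G_gene.snps["gene"].iloc[0]) if G_gene.n_snps else ""
    maf = G_gene.maf()
    window = (maf > 0) & (maf <= maf_max)
    n_var = int(window.sum())
    if n_var == 0:
        return GeneTestResult(gene, "skat", np.nan, np.nan, 0, (0.0, maf_max),
                              G_gene.n_samples, False, {"reason": "no variants in MAF window"})
    sub = G_gene.subset_snps(window)
    d, y = _complete_cases(sub, phenotype)
    # mean-impute residual missing dosages (complete-case on phenotype only)
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    n = len(y)
    if n < 3 or np.std(y) == 0:
        return GeneTestResult(gene, "skat", np.nan, np.nan, n_var, (0.0, maf_max),
                              n, False, {"reason": "degenerate phenotype"})
    maf_used = np.minimum(col_mean / 2.0, 1.0 - col_mean / 2.0)
    if weights_scheme == "beta":
        w = stats.beta.pdf(maf_used, 1, 25)
    else:
        w = np.ones(n_var)
    r = y - y.mean()
    sigma2 = float(r @ r) / (n - 1)
    gw = d * w  # G W
    q = float((r @ gw) @ (gw.T @ r))
    gw_c = gw - gw.mean(axis=0)  # projection of columns off the intercept
    lam = np.linalg.eigvalsh(sigma2 * (gw_c.T @ gw_c))
    lam = lam[lam > 1e-10 * max(lam.max(), 1.0)]
    if lam.size == 0:
        return GeneTestResult(gene, "skat", q, np.nan, n_var, (0.0, maf_max),
                              n, False, {"reason": "rank-0 kernel"})
    p = _liu_pvalue(q, lam) if method == "liu" else _imhof_pvalue(q, lam)
    return GeneTestResult(
        gene, "skat", q, float(p), n_var, (0.0, maf_max), n, True,
        {"weights": weights_scheme, "method": method, "n_eigenvalues": int(lam.size)},
    )


def bonferroni_threshold(alpha: float, n_snps: int, n_phenotypes: int) -> tuple[float, str]:
    """Per-test threshold alpha / (n_snps * n_phenotypes).

    Returns the full-precision value and a 2-significant-figure display
    string (0.05 over 47 SNPs x 3 phenotypes prints as 0.00035).
    """
    if n_snps < 1 or n_phenotypes < 1:
        raise ValueError("counts must be >= 1")
    value = alpha / (n_snps * n_phenotypes)
    display = f"{float(f'{value:.1e}'):.10f}".rstrip("0").rstrip(".")
    return value, display
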