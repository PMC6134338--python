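"""Synthetic cohort generator.

Emulates the statistical structure the association analysis assumes, so the
whole pipeline is testable without access to any real genotypes:

* two candidate-gene SNP panels (24 SNPs in a *CNTNAP2*-region block on
  chr7, 23 in an *NRXN1*-region block on chr2) with block LD, including
  high-LD pairs (r^2 > 0.8);
* three correlated quantitative phenotypes loading on one latent
  neurodevelopmental factor, with pairwise correlations matching the
  observed ~0.76 / 0.60 / 0.69 pattern;
* a sex-chromosome-trisomy (SCT) group in which a configurable fraction of
  cases is ascertained through a low phenotype (truncation sampling with a
  target mean shift in SD units);
* twin pairs with MZ/DZ genotype sharing, and one-twin-per-pair
  subsampling into two comparison groups.

Genotypes come from a Gaussian copula applied at the haplotype level: each
individual is the sum of two i.i.d. haplotypes, and each haplotype is a
thresholded multivariate-normal draw. The latent normal correlation for
every SNP pair is calibrated (bivariate-normal orthant probabilities +
root finding) so the realized dosage correlation matches the target
``sign * sqrt(r^2)``. Summing two independent haplotypes guarantees
Hardy-Weinberg equilibrium at generation and makes twin simulation exact:
MZ co-twins share both transmitted haplotypes, DZ co-twins redraw the
transmission from the same simulated parents independently per chromosome
(expected IBD 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "SnpSpec",
    "LdBlockSpec",
    "CohortScenario",
    "SimulatedCohort",
    "GenotypeSimulator",
    "default_panel",
    "default_phenotype_loadings",
    "generate_genotypes",
    "generate_phenotypes",
    "apply_ascertainment",
    "generate_sct_cohort",
    "generate_twin_pairs",
    "split_one_per_pair",
    "generate_cohort",
    "ascertainment_threshold",
]


# ----------------------------------------------------------------------
# Specs
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP in a synthetic panel.

    ``pos`` is a 1-based hg19-style coordinate inside the SNP's region;
    ``maf`` must lie in (0, 0.5].
    """

    snp_id: str
    chrom: str
    pos: int
    maf: float
    gene: str

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass
class LdBlockSpec:
    """Target pairwise LD for a SNP panel.

    ``target_r2`` is the full symmetric matrix of squared dosage
    correlations (unit diagonal, entries in [0, 1]).
    """

    target_r2: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.target_r2, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("target_r2 must be square")
        if not np.allclose(m, m.T):
            raise ValueError("target_r2 must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("target_r2 must have unit diagonal")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("target_r2 entries must be in [0, 1]")
        self.target_r2 = m

    @property
    def n_snps(self) -> int:
        return self.target_r2.shape[0]


@dataclass
class CohortScenario:
    """Study conditions for a simulated cohort.

    Defaults mirror the design of the registered study: 130 SCT cases of
    whom 59 came to light postnatally because of developmental problems,
    185 twin pairs (370 twins), karyotype mix 42 XXX / 43 XXY / 45 XYY,
    an ascertainment shift of 0.9 SD on the language measure, and
    phenotype loadings solving the printed correlation pattern
    0.76 / 0.60 / 0.69 exactly. ``gene_effect`` is the standardized path
    from each gene component to the latent factor (0 under the null);
    ``sct_multiplier`` amplifies it in the SCT group (the double-hit
    injection).
    """

    n_sct: int = 130
    n_twin_pairs: int = 185
    frac_postnatal: float = 59 / 130
    ascertainment_shift: float = 0.9
    karyotype_mix: tuple[float, float, float] = (42 / 130, 43 / 130, 45 / 130)
    zygosity_mix: tuple[float, float] = (1 / 3, 2 / 3)
    phenotype_loadings: tuple[float, float, float] = None  # filled in __post_init__
    gene_effect: float = 0.0
    sct_multiplier: float = 1.0
    ascertain_on: str = "language_factor"  # or "latent"
    battery_loading: float = 0.9
    geno_missing_rate: float = 0.0
    pheno_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype_loadings is None:
            self.phenotype_loadings = default_phenotype_loadings()
        for name, mix in (("karyotype_mix", self.karyotype_mix), ("zygosity_mix", self.zygosity_mix)):
            mix = tuple(float(x) for x in mix)
            if any(x < 0 or x > 1 for x in mix) or abs(sum(mix) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be proportions summing to 1")
        if not (0.0 <= self.frac_postnatal <= 1.0):
            raise ValueError("frac_postnatal must be in [0, 1]")
        if not (-1.0 < self.gene_effect < 1.0):
            raise ValueError("gene_effect must be in (-1, 1)")
        if any(not (-1.0 < lam < 1.0) for lam in self.phenotype_loadings):
            raise ValueError("phenotype loadings must be in (-1, 1)")
        if self.ascertain_on not in ("language_factor", "latent"):
            raise ValueError("ascertain_on must be 'language_factor' or 'latent'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["karyotype_mix"] = list(self.karyotype_mix)
        d["zygosity_mix"] = list(self.zygosity_mix)
        d["phenotype_loadings"] = list(self.phenotype_loadings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortScenario":
        d = dict(d)
        for key in ("karyotype_mix", "zygosity_mix", "phenotype_loadings"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_phenotype_loadings() -> tuple[float, float, float]:
    """Loadings of the three measures on the latent factor.

    Solved in closed form from the target pairwise correlations
    r12 = 0.76, r13 = 0.60, r23 = 0.69 (a one-factor model with three
    indicators is exactly identified): lam_i lam_j = r_ij.
    """
    r12, r13, r23 = 0.76, 0.60, 0.69
    lam1 = np.sqrt(r12 * r13 / r23)
    return (float(lam1), float(r12 / lam1), float(r13 / lam1))


@dataclass
class SimulatedCohort:
    """Bundle of genotypes, phenotypes and design for one simulated study."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    design: pd.DataFrame


# ----------------------------------------------------------------------
# Default two-region panel
# ----------------------------------------------------------------------

_CNTNAP2_REGION = ("7", 147_514_390, 147_612_852)
_NRXN1_REGION = ("2", 51_141_501, 51_280_121)


def default_panel(seed: int = 20210601) -> tuple[list[SnpSpec], LdBlockSpec]:
    """The default 47-SNP two-region panel (24 CNTNAP2 + 23 NRXN1).

    MAFs are drawn once from Uniform(0.08, 0.5) with a fixed seed so the
    panel is a reproducible constant. Each region carries one or more tight
    sub-blocks (r^2 = 0.85) sized so that 6 pairs exceed r^2 = 0.8 in the
    CNTNAP2 region and 8 in the NRXN1 region, over a weak background LD of
    r^2 = 0.04 within each region and independence across regions. Two
    CNTNAP2 SNPs are labelled rs2710102 and rs7794745 so Fig-6-style
    outputs have their usual names; their positions here are synthetic.
    """
    rng = np.random.default_rng(seed)
    specs: list[SnpSpec] = []

    def region_snps(gene, chrom, start, end, n, prefix, named=None):
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=n, replace=False))
        mafs = rng.uniform(0.08, 0.5, size=n)
        out = []
        for i in range(n):
            snp_id = f"{prefix}{i + 1:02d}"
            if named and i in named:
                snp_id = named[i]
            out.append(SnpSpec(snp_id, chrom, int(pos[i]), float(round(mafs[i], 4)), gene))
        return out

    cn = region_snps("CNTNAP2", *_CNTNAP2_REGION, 24, "cn_",
                     named={10: "rs2710102", 17: "rs7794745"})
    nr = region_snps("NRXN1", *_NRXN1_REGION, 23, "nr_")

    # tight sub-blocks share the MAF of their first member so r^2=0.85 is
    # attainable for a thresholded-binary pair
    sub_blocks = {"CNTNAP2": [range(0, 4)], "NRXN1": [range(0, 4), range(4, 6), range(6, 8)]}

    def harmonise(snps, blocks):
        snps = list(snps)
        for block in blocks:
            head = snps[block[0] if isinstance(block, list) else block.start]
            for i in block:
                s = snps[i]
                snps[i] = SnpSpec(s.snp_id, s.chrom, s.pos, head.maf, s.gene)
        return snps

    cn = harmonise(cn, sub_blocks["CNTNAP2"])
    nr = harmonise(nr, sub_blocks["NRXN1"])
    specs = cn + nr

    m = len(specs)
    r2 = np.zeros((m, m))
    offsets = {"CNTNAP2": 0, "NRXN1": 24}
    sizes = {"CNTNAP2": 24, "NRXN1": 23}
    for gene, off in offsets.items():
        size = sizes[gene]
        r2[off:off + size, off:off + size] = 0.04
        for block in sub_blocks[gene]:
            idx = np.array(list(block)) + off
            r2[np.ix_(idx, idx)] = 0.85
    np.fill_diagonal(r2, 1.0)
    return specs, LdBlockSpec(r2)


# ----------------------------------------------------------------------
# Copula calibration
# ----------------------------------------------------------------------

def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X < h, Y < k) for standard bivariate normal, via Owen's T.

    Owen (1956): Phi2(h, k; rho) = (Phi(h) + Phi(k))/2
    - T(h, a_h) - T(k, a_k) - beta, with beta = 1/2 when h and k straddle
    zero. Orders of magnitude faster than generic multivariate CDF code,
    which matters because the copula calibration root-finds through it.
    """
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return stats.norm.cdf(min(h, k))
        return max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0)
    if rho == 0.0:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    # avoid 0/0 in the slope arguments at exactly zero thresholds
    if h == 0.0:
        h = -1e-15
    if k == 0.0:
        k = -1e-15
    r = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    beta = 0.5 if h * k < 0 else 0.0
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - beta
    )
    return float(min(max(val, 0.0), 1.0))


def _binary_corr(p1: float, p2: float, rho: float) -> float:
    """Correlation of two thresholded-normal Bernoulli alleles."""
    c1, c2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = bvn_cdf(c1, c2, rho)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


@lru_cache(maxsize=65536)
def _latent_rho(p1: float, p2: float, target: float) -> float:
    """Latent normal correlation giving allele correlation ``target``.

    Raises if the target exceeds the maximum achievable correlation for
    the given allele frequencies (Frechet bound of the thresholded pair).
    """
    if target == 0.0:
        return 0.0
    hi = _binary_corr(p1, p2, 0.999999)
    if target >= hi:
        if target <= hi + 1e-6 or abs(p1 - p2) < 1e-12:
            return 1.0
        raise ValueError(
            f"target allele correlation {target:.3f} infeasible for "
            f"MAFs ({p1}, {p2}); maximum achievable is {hi:.3f}"
        )
    lo_bound = _binary_corr(p1, p2, -0.999999)
    if target <= lo_bound:
        raise ValueError(
            f"target allele correlation {target:.3f} infeasible for "
            f"MAFs ({p1}, {p2}); minimum achievable is {lo_bound:.3f}"
        )
    return float(optimize.brentq(
        lambda r: _binary_corr(p1, p2, r) - target, -0.999999, 0.999999, xtol=1e-10
    ))


class GenotypeSimulator:
    """Haplotype-copula genotype sampler for a fixed panel + LD target.

    Calibration of the latent correlation matrix happens once at
    construction; sampling is then a Cholesky draw per haplotype.
    """

    def __init__(self, specs: list[SnpSpec], ld: LdBlockSpec):
        if len(specs) == 0:
            raise ValueError("panel must contain at least one SNP")
        if ld.n_snps != len(specs):
            raise ValueError("LD matrix size does not match panel")
        ids = [s.snp_id for s in specs]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique within a panel")
        self.specs = list(specs)
        self.ld = ld
        self._mafs = np.array([s.maf for s in specs])
        self._thresholds = stats.norm.ppf(self._mafs)
        self._latent = self._calibrate()
        self._chol = self._factor(self._latent)

    def _calibrate(self) -> np.ndarray:
        m = len(self.specs)
        target_corr = np.sqrt(self.ld.target_r2)  # positive-sign convention
        latent = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                t = float(target_corr[i, j])
                if t == 0.0:
                    continue
                rho = _latent_rho(float(self._mafs[i]), float(self._mafs[j]), t)
                latent[i, j] = latent[j, i] = rho
        return latent

    @staticmethod
    def _factor(latent: np.ndarray) -> np.ndarray:
        eigval, eigvec = np.linalg.eigh(latent)
        if eigval.min() < -1e-8:
            raise ValueError(
                "calibrated latent correlation matrix is not positive "
                f"semi-definite (min eigenvalue {eigval.min():.3g}); the "
                "requested LD pattern is jointly infeasible"
            )
        eigval = np.clip(eigval, 0.0, None)
        return eigvec * np.sqrt(eigval)  # latent = F F'

    # ------------------------------------------------------------------
    def sample_haplotypes(self, n_hap: int, rng: np.random.Generator) -> np.ndarray:
        """(n_hap, m) boolean array; True = minor allele carried."""
        z = rng.standard_normal((n_hap, self._chol.shape[1])) @ self._chol.T
        return z < self._thresholds

    def sample(self, n: int, rng: np.random.Generator, sample_ids=None) -> GenotypeMatrix:
        """Unrelated individuals: each the sum of two i.i.d. haplotypes."""
        if n < 2:
            raise ValueError("need n >= 2 individuals")
        haps = self.sample_haplotypes(2 * n, rng).astype(np.int8)
        dosages = haps[0::2] + haps[1::2]
        if sample_ids is None:
            sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        return GenotypeMatrix(dosages, list(sample_ids), self.snp_table())

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.specs],
                "chrom": [s.chrom for s in self.specs],
                "pos": [s.pos for s in self.specs],
                "gene": [s.gene for s in self.specs],
                "allele_minor": "A",
                "allele_major": "G",
            }
        )

    def chrom_groups(self) -> dict[str, np.ndarray]:
        """SNP column indices grouped by chromosome (independent transmission)."""
        chroms = np.array([s.chrom for s in self.specs])
        return {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)}


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

_SIMULATOR_CACHE: dict = {}


def get_simulator(specs, ld) -> GenotypeSimulator:
    """Construct (or fetch a cached) calibrated simulator for a panel."""
    key = (tuple(specs), ld.target_r2.tobytes())
    sim = _SIMULATOR_CACHE.get(key)
    if sim is None:
        sim = GenotypeSimulator(specs, ld)
        if len(_SIMULATOR_CACHE) > 32:
            _SIMULATOR_CACHE.clear()
        _SIMULATOR_CACHE[key] = sim
    return sim


def generate_genotypes(specs, ld, n, seed) -> GenotypeMatrix:
    """Sample ``n`` unrelated individuals from the panel's copula model."""
    rng = np.random.default_rng(seed)
    return get_simulator(specs, ld).sample(n, rng)


def _gene_components(G: GenotypeMatrix) -> pd.DataFrame:
    """Standardized equal-weight component per gene region (generative truth)."""
    d = G.dosages_float()
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d), col_mean, d)
    sd = inds.std(axis=0)
    sd[sd == 0] = 1.0
    z = (inds - col_mean) / sd
    out = {}
    for gene in dict.fromkeys(G.snps["gene"]):
        idx = np.flatnonzero((G.snps["gene"] == gene).to_numpy())
        comp = z[:, idx].mean(axis=1)
        csd = comp.std()
        out[gene] = comp / csd if csd > 0 else comp
    return pd.DataFrame(out, index=G.samples)


def generate_phenotypes(G: GenotypeMatrix, scenario: CohortScenario, seed,
                        amplified: bool = False) -> pd.DataFrame:
    """Three observed measures loading on one latent factor.

    latent = sum_g b_g * component_g + residual (unit variance), with
    b_g = gene_effect (times ``sct_multiplier`` when ``amplified``), and
    measure_i = loading_i * latent + noise. Emitted columns:

    * ``nonword_repetition`` — scaled-score metric (10 + 3 z);
    * ``language_factor`` — z-units;
    * ``global_burden`` — z-units, already inverted so LOW = impaired;
    * four language-battery subtests (z-units) generated from the language
      measure with loading ``battery_loading``;
    * ``latent_truth`` and per-gene component columns for simulation
      diagnostics only.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    comps = _gene_components(G)
    b = scenario.gene_effect * (scenario.sct_multiplier if amplified else 1.0)
    effects = {gene: b for gene in comps.columns}
    total_var = sum(v ** 2 for v in effects.values())
    if total_var >= 1.0:
        raise ValueError("gene effects imply latent variance above 1")
    latent = sum(v * comps[g].to_numpy() for g, v in effects.items())
    latent = latent + np.sqrt(1.0 - total_var) * rng.standard_normal(n)

    lam = np.asarray(scenario.phenotype_loadings)
    measures = lam * latent[:, None] + np.sqrt(1.0 - lam ** 2) * rng.standard_normal((n, 3))

    nu = scenario.battery_loading
    battery = nu * measures[:, 1][:, None] + np.sqrt(1.0 - nu ** 2) * rng.standard_normal((n, 4))

    pheno = pd.DataFrame(
        {
            "sample_id": G.samples,
            "nonword_repetition": 10.0 + 3.0 * measures[:, 0],
            "language_factor": measures[:, 1],
            "global_burden": measures[:, 2],
            "verbal_comprehension": battery[:, 0],
            "oromotor_sequences": battery[:, 1],
            "sentence_repetition": battery[:, 2],
            "vocabulary": battery[:, 3],
            "latent_truth": latent,
        }
    )
    for g in comps.columns:
        pheno[f"component_{g}"] = comps[g].to_numpy()
    if scenario.pheno_missing_rate > 0:
        for col in ("nonword_repetition", "language_factor", "global_burden"):
            mask = rng.random(n) < scenario.pheno_missing_rate
            pheno.loc[mask, col] = np.nan
    return pheno


def ascertainment_threshold(shift: float) -> float:
    """Standard-normal truncation point c with E[Y | Y < c] = -shift.

    Solves phi(c)/Phi(c) = shift (the lower-tail inverse Mills ratio).
    A zero shift means no truncation (returns +inf).
    """
    if shift < 0:
        raise ValueError("ascertainment shift must be non-negative")
    if shift == 0:
        return np.inf
    mills = lambda c: np.exp(stats.norm.logpdf(c) - stats.norm.logcdf(c)) - shift
    return float(optimize.brentq(mills, -40.0, 40.0, xtol=1e-12))


def apply_ascertainment(pheno: pd.DataFrame, scenario: CohortScenario, seed) -> tuple[np.ndarray, pd.DataFrame]:
    """Select an SCT group of ``n_sct`` from a candidate pool.

    A fraction ``frac_postnatal`` is drawn by truncation sampling — kept
    only if the ascertainment measure (standardized within the pool) falls
    below the threshold whose truncated mean is ``-ascertainment_shift``
    SD. The remainder is drawn at random from the rest of the pool.
    Returns the selected pool row positions and the design table
    (karyotype / ascertainment labels).
    """
    rng = np.random.default_rng(seed)
    n_pool = len(pheno)
    n_sct = scenario.n_sct
    if n_pool < n_sct:
        raise ValueError("candidate pool smaller than n_sct")
    measure_col = "latent_truth" if scenario.ascertain_on == "latent" else scenario.ascertain_on
    y = pheno[measure_col].to_numpy(dtype=float)
    y_std = (y - np.nanmean(y)) / np.nanstd(y)

    n_post = int(round(scenario.frac_postnatal * n_sct))
    n_pre = n_sct - n_post
    c = ascertainment_threshold(scenario.ascertainment_shift)

    # draw the unascertained subgroup first (a plain random draw), then the
    # ascertained one by truncation from the remainder: removing a random
    # subset leaves the conditional distribution below c unchanged, so the
    # ascertained mean lands at -shift SD exactly in expectation
    order = rng.permutation(n_pool)
    prenatal = order[:n_pre]
    remainder = order[n_pre:]
    below = remainder[y_std[remainder] < c]
    if len(below) < n_post:
        raise ValueError(
            f"candidate pool has only {len(below)} below-threshold cases; "
            f"need {n_post} (enlarge the pool)"
        )
    postnatal = below[:n_post]
    chosen = np.concatenate([postnatal, prenatal])

    karyotypes = rng.choice(["XXX", "XXY", "XYY"], size=n_sct, p=scenario.karyotype_mix)
    design = pd.DataFrame(
        {
            "sample_id": pheno["sample_id"].to_numpy()[chosen],
            "group": "SCT",
            "karyotype": karyotypes,
            "ascertainment": ["postnatal"] * n_post + ["prenatal"] * n_pre,
            "pair_id": "",
            "zygosity": "",
        }
    )
    return chosen, design


def generate_sct_cohort(specs, ld, scenario: CohortScenario, seed) -> SimulatedCohort:
    """SCT group: oversample a candidate pool, then ascertain."""
    ss = np.random.SeedSequence(seed).spawn(3)
    sim = get_simulator(specs, ld)
    c = ascertainment_threshold(scenario.ascertainment_shift)
    accept = stats.norm.cdf(c) if np.isfinite(c) else 1.0
    n_post = int(round(scenario.frac_postnatal * scenario.n_sct))
    pool = max(2 * scenario.n_sct, int(np.ceil(3 * n_post / max(accept, 1e-6))), 4)
    ids = [f"SCTpool{i + 1:05d}" for i in range(pool)]
    G_pool = sim.sample(pool, np.random.default_rng(ss[0]), sample_ids=ids)
    pheno_pool = generate_phenotypes(G_pool, scenario, ss[1], amplified=True)
    chosen, design = apply_ascertainment(pheno_pool, scenario, ss[2])
    G = G_pool.subset_samples(chosen)
    pheno = pheno_pool.iloc[chosen].reset_index(drop=True)
    # relabel from pool ids to cohort ids
    new_ids = [f"SCT{i + 1:04d}" for i in range(len(chosen))]
    G.samples = new_ids
    pheno = pheno.assign(sample_id=new_ids)
    design = design.assign(sample_id=new_ids)
    return SimulatedCohort(G, pheno, design.reset_index(drop=True))


def generate_twin_pairs(specs, ld, scenario: CohortScenario, seed) -> SimulatedCohort:
    """Twin comparison sample: ``n_twin_pairs`` pairs (2 children each).

    Each pair gets four simulated parental haplotypes per SNP panel;
    children inherit one maternal and one paternal haplotype, chosen
    independently per chromosome. MZ co-twins share the same transmission
    (identical genotype rows); DZ co-twins redraw it (expected IBD 1/2).
    """
    if scenario.n_twin_pairs < 1:
        raise ValueError("need at least one twin pair")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    sim = get_simulator(specs, ld)
    n_pairs = scenario.n_twin_pairs
    m = len(sim.specs)

    zygosity = rng.choice(["MZ", "DZ"], size=n_pairs, p=scenario.zygosity_mix)
    # parental haplotypes: (pairs, 4, m) — [mat1, mat2, pat1, pat2]
    parent = sim.sample_haplotypes(4 * n_pairs, rng).reshape(n_pairs, 4, m)
    dosages = np.zeros((2 * n_pairs, m), dtype=np.int8)
    chrom_groups = sim.chrom_groups()
    for p in range(n_pairs):
        child = np.zeros((2, m), dtype=np.int8)
        for cols in chrom_groups.values():
            # independent transmission per chromosome
            cm1, cp1 = rng.integers(0, 2), rng.integers(0, 2)
            if zygosity[p] == "MZ":
                cm2, cp2 = cm1, cp1
            else:
                cm2, cp2 = rng.integers(0, 2), rng.integers(0, 2)
            child[0, cols] = parent[p, cm1, cols].astype(np.int8) + parent[p, 2 + cp1, cols]
            child[1, cols] = parent[p, cm2, cols].astype(np.int8) + parent[p, 2 + cp2, cols]
        dosages[2 * p] = child[0]
        dosages[2 * p + 1] = child[1]

    sample_ids, pair_ids, members = [], [], []
    for p in range(n_pairs):
        for member in ("a", "b"):
            sample_ids.append(f"TW{p + 1:04d}{member}")
            pair_ids.append(f"pair{p + 1:04d}")
    G = GenotypeMatrix(dosages, sample_ids, sim.snp_table())
    pheno = generate_phenotypes(G, scenario, ss[1], amplified=False)
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": "twin",
            "karyotype": "46,XX",
            "ascertainment": "",
            "pair_id": pair_ids,
            "zygosity": np.repeat(zygosity, 2),
        }
    )
    return SimulatedCohort(G, pheno, design)


def split_one_per_pair(design: pd.DataFrame, seed) -> tuple[np.ndarray, np.ndarray]:
    """Split twins into two subsamples with one co-twin of each pair in each.

    Returns two integer row-position arrays into ``design``. Every pair
    must have exactly two members; the split is deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    idx_a, idx_b = [], []
    grouped = design.reset_index(drop=True).groupby("pair_id", sort=True)
    for pair_id, rows in grouped:
        if len(rows) != 2:
            raise ValueError(f"pair {pair_id!r} has {len(rows)} members; expected 2")
        first, second = rows.index.to_numpy()
        if rng.random() < 0.5:
            first, second = second, first
        idx_a.append(first)
        idx_b.append(second)
    return np.array(sorted(idx_a)), np.array(sorted(idx_b))


def _inject_missing(G: GenotypeMatrix, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        mask = rng.random(G.dosages.shape) < rate
        G.dosages[mask] = MISSING


def generate_cohort(scenario: CohortScenario, seed=None, specs=None, ld=None) -> SimulatedCohort:
    """Full study cohort: 130-style SCT group + split twin comparison groups.

    Twins are labelled ``twinA``/``twinB`` by a random one-per-pair split;
    genotypes, phenotypes and design are concatenated over all samples.
    Exactly reproducible given (scenario, seed).
    """
    if seed is None:
        seed = scenario.seed
    if specs is None or ld is None:
        specs, ld = default_panel()
    ss = np.random.SeedSequence(seed).spawn(4)
    ss = [s.generate_state(1)[0] % (2**31) for s in ss]
    sct = generate_sct_cohort(specs, ld, scenario, ss[0])
    twins = generate_twin_pairs(specs, ld, scenario, ss[1])
    idx_a, idx_b = split_one_per_pair(twins.design, ss[2])
    group = twins.design["group"].to_numpy(dtype=object)
    group[idx_a] = "twinA"
    group[idx_b] = "twinB"
    twins.design = twins.design.assign(group=group)

    dosages = np.vstack([sct.genotypes.dosages, twins.genotypes.dosages])
    samples = sct.genotypes.samples + twins.genotypes.samples
    G = GenotypeMatrix(dosages, samples, sct.genotypes.snps.copy())
    _inject_missing(G, scenario.geno_missing_rate, np.random.default_rng(ss[3]))
    pheno = pd.concat([sct.phenotypes, twins.phenotypes], ignore_index=True)
    design = pd.concat([sct.design, twins.design], ignore_index=True)
    return SimulatedCohort(G, pheno, design)
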