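"""Generalized Structured Component Analysis (GSCA) for SNP-set association.

The model mirrors the registered analysis: each candidate-gene SNP block
forms one *component* — an exact weighted sum of its standardized dosages
— and the three phenotype measures form one latent outcome component (the
"Neurodev" factor). The structural part regresses the outcome component
on the gene components:

    gamma_g = Z_g w_g          (unit variance, per gene g)
    eta     = P v              (unit variance)
    eta     = sum_g a_g gamma_g + e

Estimation is alternating least squares on the structural residual sum of
squares f = E[(eta - sum_g a_g gamma_g)^2]:

* path update: a = Phi^{-1} c (OLS of eta on the components);
* weight update for block g: minimize f over w_g subject to the
  unit-variance constraint — the constrained optimum is
  w_g proportional to S_gg^{-1} t_g with t_g the partial cross-covariance
  target, rescaled to unit component variance (sign matched to a_g);
* outcome update: v proportional to S_pp^{-1} (sum_g a_g S_pg w_g), rescaled.

Every sub-step exactly minimizes f over its own block under its own
constraint, so the criterion is monotone non-increasing — asserted on
every fit. All quantities depend on the data only through the
cross-product matrix S = X'X/n, so permutation refits (phenotype rows
permuted as a block against the genotypes, preserving LD and phenotype
intercorrelations) only recompute the genotype-phenotype cross block.

Inference is by permutation: p = (1 + #{|a_perm| >= |a_obs|}) / (B + 1)
per path (two-sided default; one-tailed directional optional), with the
pre-registered sequential alpha levels applied per path in declared order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .containers import GenotypeMatrix

__all__ = [
    "GscaSpec",
    "GscaModel",
    "PermutationResult",
    "Designs",
    "standardize_blocks",
    "fit_gsca",
    "permutation_test",
    "sequential_alpha_decision",
    "run_group_analyses",
]

#: Pre-registered per-path alpha levels, in testing order.
DEFAULT_ALPHAS = (("CNTNAP2", 0.05), ("NRXN1", 0.025))


@dataclass
class GscaSpec:
    """Model topology: named gene blocks -> one outcome factor."""

    gene_blocks: dict[str, list[str]]
    phenotype_block: tuple[str, ...] = ("nonword_repetition", "language_factor", "global_burden")
    alpha_sequence: tuple = DEFAULT_ALPHAS
    convergence_tol: float = 1e-5
    max_iter: int = 1000

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene, ids in self.gene_blocks.items():
            if not ids:
                raise ValueError(f"gene block {gene!r} is empty")
            overlap = seen & set(ids)
            if overlap:
                raise ValueError(f"blocks must be disjoint; shared SNPs: {sorted(overlap)}")
            seen |= set(ids)

    @classmethod
    def from_genotypes(cls, G: GenotypeMatrix, **kwargs) -> "GscaSpec":
        """Blocks from the ``gene`` column of the SNP metadata."""
        blocks = {
            gene: list(G.snps.loc[G.snps["gene"] == gene, "snp_id"])
            for gene in dict.fromkeys(G.snps["gene"])
        }
        return cls(gene_blocks=blocks, **kwargs)


@dataclass
class Designs:
    """Standardized per-block design matrices over the analysis samples."""

    Z: dict[str, np.ndarray]      # gene label -> (n, m_g), columns mean 0 / SD 1
    P: np.ndarray                 # (n, 3)
    sample_ids: list[str]
    snp_ids: dict[str, list[str]]
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class GscaModel:
    """Fitted weights, paths and convergence diagnostics."""

    weights: dict[str, np.ndarray]   # W_g per gene block
    v: np.ndarray                    # phenotype-factor weights
    paths: dict[str, float]          # a_g per gene
    criterion: float                 # structural residual variance
    iterations: int
    converged: bool
    criterion_trace: np.ndarray


@dataclass
class PermutationResult:
    """Observed paths, permutation null draws and p-values."""

    paths_obs: dict[str, float]
    null_draws: dict[str, np.ndarray]
    p_values: dict[str, float]
    B: int
    seed: int
    tails: str
    alpha_sequence: tuple = DEFAULT_ALPHAS


# ----------------------------------------------------------------------
# Designs
# ----------------------------------------------------------------------

def standardize_blocks(G: GenotypeMatrix, pheno: pd.DataFrame,
                       spec: GscaSpec) -> Designs:
    """Build mean-0 / SD-1 design matrices for every block.

    Missing dosages are imputed to the column mean before standardization;
    samples with any missing phenotype measure are excluded (complete-case).
    Zero-variance columns are dropped with a warning.
    """
    pheno = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    common = [s for s in G.samples if s in pheno.index]
    pheno = pheno.loc[common, list(spec.phenotype_block)]
    complete = ~pheno.isna().any(axis=1)
    keep_ids = list(pheno.index[complete])
    if not keep_ids:
        raise ValueError("no samples with complete phenotype data")
    Gsub = G.subset_samples(G.sample_positions(keep_ids))
    P_raw = pheno.loc[keep_ids].to_numpy(dtype=float)

    dropped: list[str] = []

    def _standardize(mat: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
        col_mean = np.nanmean(mat, axis=0)
        filled = np.where(np.isnan(mat), col_mean, mat)
        sd = filled.std(axis=0)
        ok = sd > 0
        for name, good in zip(names, ok):
            if not good:
                dropped.append(name)
        if not ok.all():
            warnings.warn(f"dropping zero-variance columns: {[n for n, g in zip(names, ok) if not g]}")
        z = (filled[:, ok] - col_mean[ok]) / sd[ok]
        return z, [n for n, g in zip(names, ok) if g]

    Z: dict[str, np.ndarray] = {}
    snp_ids: dict[str, list[str]] = {}
    for gene, ids in spec.gene_blocks.items():
        sub = Gsub.subset_snp_ids(ids)
        missing_ids = set(ids) - set(sub.snp_ids)
        if missing_ids:
            raise KeyError(f"block {gene!r}: SNPs not in genotype matrix: {sorted(missing_ids)}")
        z, kept = _standardize(sub.dosages_float(), sub.snp_ids)
        if z.shape[1] == 0:
            raise ValueError(f"gene block {gene!r} has no polymorphic SNPs")
        Z[gene] = z
        snp_ids[gene] = kept

    P, kept_measures = _standardize(P_raw, list(spec.phenotype_block))
    if P.shape[1] < len(spec.phenotype_block):
        raise ValueError("zero-variance phenotype measure; cannot fit outcome factor")
    return Designs(Z=Z, P=P, sample_ids=keep_ids, snp_ids=snp_ids, dropped=dropped)


# ----------------------------------------------------------------------
# ALS in cross-product space
# ----------------------------------------------------------------------

class _SBlocks:
    """Cross-product matrices S = X'X/n with cached Cholesky factors.

    Only the genotype-phenotype block changes under phenotype-row
    permutation, so everything else is computed once.
    """

    def __init__(self, designs: Designs):
        self.genes = list(designs.Z.keys())
        self.n = designs.n
        self.Zall = np.concatenate([designs.Z[g] for g in self.genes], axis=1)
        self.P = designs.P
        sizes = [designs.Z[g].shape[1] for g in self.genes]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.slices = {g: slice(offsets[i], offsets[i + 1]) for i, g in enumerate(self.genes)}
        S_zz_full = self.Zall.T @ self.Zall / self.n
        self.S_gh = {
            (g, h): S_zz_full[self.slices[g], self.slices[h]]
            for g in self.genes for h in self.genes
        }
        self.S_pp = self.P.T @ self.P / self.n
        jitter = 1e-10
        self.chol_gg = {
            g: cho_factor(self.S_gh[(g, g)] + jitter * np.eye(sizes[i]))
            for i, g in enumerate(self.genes)
        }
        self.chol_pp = cho_factor(self.S_pp + jitter * np.eye(self.P.shape[1]))
        self.set_szp(self.Zall.T @ self.P / self.n)

    def set_szp(self, S_zp: np.ndarray) -> None:
        self.S_gp = {g: S_zp[self.slices[g], :] for g in self.genes}

    def permuted_szp(self, perm: np.ndarray) -> np.ndarray:
        return self.Zall.T @ self.P[perm, :] / self.n


def _fit_from_S(S: _SBlocks, tol: float, max_iter: int) -> GscaModel:
    genes = S.genes
    G = len(genes)
    w = {}
    for g in genes:
        m = S.S_gh[(g, g)].shape[0]
        u = np.ones(m)
        w[g] = u / np.sqrt(u @ S.S_gh[(g, g)] @ u)
    v = np.ones(S.S_pp.shape[0])
    v = v / np.sqrt(v @ S.S_pp @ v)
    a = np.zeros(G)

    def paths_and_criterion():
        Phi = np.empty((G, G))
        c = np.empty(G)
        for i, g in enumerate(genes):
            c[i] = w[g] @ S.S_gp[g] @ v
            for j, h in enumerate(genes):
                Phi[i, j] = w[g] @ S.S_gh[(g, h)] @ w[h]
        return Phi, c

    trace = []
    f_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Phi, c = paths_and_criterion()
        a = np.linalg.solve(Phi + 1e-12 * np.eye(G), c)
        # weight update per gene block (constrained least squares)
        for i, g in enumerate(genes):
            if a[i] == 0.0:
                continue
            t = S.S_gp[g] @ v
            for j, h in enumerate(genes):
                if h != g:
                    t = t - a[j] * (S.S_gh[(g, h)] @ w[h])
            u = cho_solve(S.chol_gg[g], t)
            norm = u @ S.S_gh[(g, g)] @ u
            if norm <= 0:
                continue
            u = u / np.sqrt(norm)
            w[g] = u if a[i] > 0 else -u
        # outcome weight update
        m_vec = np.zeros(S.S_pp.shape[0])
        for i, g in enumerate(genes):
            m_vec = m_vec + a[i] * (S.S_gp[g].T @ w[g])
        if np.any(m_vec != 0.0):
            u = cho_solve(S.chol_pp, m_vec)
            norm = u @ S.S_pp @ u
            if norm > 0:
                v = u / np.sqrt(norm)
        # refresh paths for current weights, then evaluate the criterion
        Phi, c = paths_and_criterion()
        a = np.linalg.solve(Phi + 1e-12 * np.eye(G), c)
        f = float(1.0 - 2.0 * a @ c + a @ Phi @ a)
        trace.append(f)
        if f > f_prev + 1e-9:
            raise AssertionError(
                f"ALS criterion increased ({f_prev:.12g} -> {f:.12g}); "
                "this indicates an implementation fault"
            )
        if abs(f_prev - f) < tol:
            converged = True
            f_prev = f
            break
        f_prev = f
    if not converged:
        warnings.warn(f"GSCA did not converge in {max_iter} iterations")

    # sign convention: outcome component positively covaries with its first
    # indicator; each gene component with its first SNP
    if (S.S_pp @ v)[0] < 0:
        v = -v
        a = -a
    for i, g in enumerate(genes):
        if (S.S_gh[(g, g)] @ w[g])[0] < 0:
            w[g] = -w[g]
            a[i] = -a[i]
    return GscaModel(
        weights={g: w[g].copy() for g in genes},
        v=v.copy(),
        paths={g: float(a[i]) for i, g in enumerate(genes)},
        criterion=f_prev,
        iterations=it,
        converged=converged,
        criterion_trace=np.array(trace),
    )


def fit_gsca(spec: GscaSpec, designs: Designs) -> GscaModel:
    """Fit the GSCA model by alternating least squares."""
    n_params = sum(z.shape[1] for z in designs.Z.values()) + designs.P.shape[1] + len(designs.Z)
    if designs.n <= n_params:
        warnings.warn(
            f"n={designs.n} does not exceed the {n_params} estimated weights/paths; "
            "fit may be unstable"
        )
    return _fit_from_S(_SBlocks(designs), spec.convergence_tol, spec.max_iter)


# ----------------------------------------------------------------------
# Permutation inference
# ----------------------------------------------------------------------

def permutation_test(spec: GscaSpec, designs: Designs, B: int = 5000,
                     seed: int = 0, tails: str = "two") -> PermutationResult:
    """Permutation p-values for every gene -> factor path.

    The phenotype block's rows are permuted as a unit against the
    genotype blocks (preserving both LD and the phenotype covariance) and
    the whole model is refitted each time. ``tails``: ``"two"`` compares
    |a|; ``"one"`` counts permuted paths <= observed (directional: the
    registered prediction is that more minor alleles lower the outcome).
    """
    if tails not in ("two", "one"):
        raise ValueError("tails must be 'two' or 'one'")
    if B < 100:
        warnings.warn(f"B={B} permutations gives unstable p-values")
    S = _SBlocks(designs)
    obs = _fit_from_S(S, spec.convergence_tol, spec.max_iter)
    rng = np.random.default_rng(seed)
    genes = S.genes
    draws = {g: np.empty(B) for g in genes}
    for b in range(B):
        perm = rng.permutation(S.n)
        S.set_szp(S.permuted_szp(perm))
        model_b = _fit_from_S(S, spec.convergence_tol, spec.max_iter)
        for g in genes:
            draws[g][b] = model_b.paths[g]
    S.set_szp(S.Zall.T @ S.P / S.n)  # restore

    p = {}
    for g in genes:
        if tails == "two":
            count = int(np.sum(np.abs(draws[g]) >= abs(obs.paths[g])))
        else:
            count = int(np.sum(draws[g] <= obs.paths[g]))
        p[g] = (1 + count) / (B + 1)
    return PermutationResult(
        paths_obs=dict(obs.paths),
        null_draws=draws,
        p_values=p,
        B=B,
        seed=seed,
        tails=tails,
        alpha_sequence=spec.alpha_sequence,
    )


def sequential_alpha_decision(result: PermutationResult,
                              alpha_sequence=None) -> pd.DataFrame:
    """Compare each path to its pre-registered alpha, in declared order."""
    seq = tuple(alpha_sequence or result.alpha_sequence)
    rows = []
    for gene, alpha in seq:
        if gene not in result.p_values:
            raise KeyError(f"no fitted path for {gene!r} (alpha sequence mismatch)")
        p = result.p_values[gene]
        rows.append(
            {"gene": gene, "p_value": p, "alpha": alpha, "significant": bool(p < alpha)}
        )
    missing = set(result.p_values) - {g for g, _ in seq}
    if missing:
        raise KeyError(f"paths without a declared alpha: {sorted(missing)}")
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Group-wise driver
# ----------------------------------------------------------------------

def run_group_analyses(G: GenotypeMatrix, pheno: pd.DataFrame,
                       design: pd.DataFrame, spec: GscaSpec,
                       B: int = 5000, seed: int = 0,
                       karyotype_subgroups: bool = False,
                       min_n: int = 10, tails: str = "two") -> pd.DataFrame:
    """Repeat the GSCA permutation analysis per cohort group.

    With ``karyotype_subgroups=True`` the SCT group is additionally
    subdivided by karyotype, restricted to cases NOT ascertained through
    developmental problems (the prenatal/incidental subset), mirroring the
    registered subgroup analysis. Subgroups below ``min_n`` are skipped
    with a warning. Returns a tidy table (group, gene, n, path, p, alpha,
    significant).
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    tasks: list[tuple[str, list[str]]] = []
    for group in dict.fromkeys(design["group"]):
        ids = list(design.index[design["group"] == group])
        tasks.append((str(group), ids))
    if karyotype_subgroups:
        sct = design[(design["group"] == "SCT") & (design["ascertainment"] != "postnatal")]
        for karyotype in dict.fromkeys(sct["karyotype"]):
            ids = list(sct.index[sct["karyotype"] == karyotype])
            tasks.append((f"SCT:{karyotype}", ids))

    child_seeds = np.random.SeedSequence(seed).spawn(len(tasks))
    rows = []
    for (label, ids), child in zip(tasks, child_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        present = [s for s in ids if s in set(G.samples)]
        if len(present) < min_n:
            warnings.warn(f"group {label!r}: n={len(present)} below floor {min_n}; skipped")
            continue
        designs = standardize_blocks(G.subset_samples(G.sample_positions(present)), pheno, spec)
        if designs.n < min_n:
            warnings.warn(f"group {label!r}: n={designs.n} complete cases below floor {min_n}; skipped")
            continue
        result = permutation_test(spec, designs, B=B, seed=sub_seed, tails=tails)
        verdicts = sequential_alpha_decision(result)
        for _, r in verdicts.iterrows():
            rows.append(
                {
                    "group": label,
                    "gene": r["gene"],
                    "n": designs.n,
                    "path": result.paths_obs[r["gene"]],
                    "p_value": r["p_value"],
                    "alpha": r["alpha"],
                    "significant": r["significant"],
                    "B": B,
                }
            )
    return pd.DataFrame(rows)
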