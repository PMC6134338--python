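"""Construction of the three analysis phenotypes.

The latent outcome factor is built from three measures: a nonword
repetition scaled score (phonological short-term memory, consumed as
supplied), a general language factor derived from four battery subtests
(Verbal Comprehension, Oromotor Sequences, Sentence Repetition,
Vocabulary), and a global neurodevelopmental burden index (supplied, not
reconstructed — its construction from parental report is ad hoc by
design). All three are oriented so that LOW = impaired, and the language
factor is z-standardized against a reference sample (by default the
pooled twin comparison groups).

The language factor is a one-factor maximum-likelihood model fitted on
complete cases, with regression (Thomson) scores; samples missing some
subtests are scored from their observed items via the model-implied
covariance (available-item reweighting), and samples with fewer than two
subtests get no score. If the ML fit fails, the first principal
component is used instead and the fallback is recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "BATTERY_SUBTESTS",
    "LanguageFactorModel",
    "fit_language_factor",
    "orient_and_standardize",
]

#: The four language-battery subtests the factor is derived from.
BATTERY_SUBTESTS = (
    "verbal_comprehension",
    "oromotor_sequences",
    "sentence_repetition",
    "vocabulary",
)

#: Minimum observed subtests for a sample to receive a factor score.
MIN_SUBTESTS = 2


@dataclass
class LanguageFactorModel:
    """Fitted one-factor model: loadings, scores and bookkeeping."""

    loadings: pd.Series
    uniquenesses: pd.Series
    scores: pd.Series              # z-standardized; NaN where unscorable
    n_complete: int
    method: str                    # "ml" or "pca-fallback"
    unscorable: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.round(6).to_dict(),
            "uniquenesses": self.uniquenesses.round(6).to_dict(),
            "n_complete": self.n_complete,
            "method": self.method,
        }


def fit_language_factor(battery: pd.DataFrame,
                        subtests=BATTERY_SUBTESTS) -> LanguageFactorModel:
    """Fit the one-factor language model and score every scorable sample.

    ``battery`` must contain the subtest columns (missingness allowed)
    and is indexed by sample. Requires >= 10 complete cases to fit; all
    loadings are forced to one sign (positive = better language).
    """
    subtests = list(subtests)
    missing_cols = [c for c in subtests if c not in battery.columns]
    if missing_cols:
        raise KeyError(f"battery missing subtests: {missing_cols}")
    X = battery[subtests].to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < 10:
        raise ValueError(f"need >= 10 complete cases to fit loadings, have {n_complete}")

    mu = X[complete].mean(axis=0)
    sd = X[complete].std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance subtest; correlation matrix degenerate")
    Zc = (X[complete] - mu) / sd

    method = "ml"
    try:
        fa = FactorAnalysis(n_components=1, random_state=0)
        fa.fit(Zc)
        lam = fa.components_[0].copy()
        psi = fa.noise_variance_.copy()
        if np.all(np.abs(lam) < 1e-8):
            raise np.linalg.LinAlgError("degenerate ML solution")
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"ML factor fit failed ({err}); falling back to first principal component")
        method = "pca-fallback"
        corr = np.corrcoef(Zc.T)
        eigval, eigvec = np.linalg.eigh(corr)
        pc = eigvec[:, -1]
        lam = pc * np.sqrt(eigval[-1])
        psi = np.clip(1.0 - lam ** 2, 1e-6, None)

    # sign convention: positive loadings = better language
    if lam.sum() < 0:
        lam = -lam
    if np.any(lam < 0):
        warnings.warn("mixed-sign loadings forced positive; check subtest orientation")
        lam = np.abs(lam)

    # regression (Thomson) scoring from observed items, model-implied covariance
    sigma = np.outer(lam, lam) + np.diag(psi)
    Z_all = (X - mu) / sd
    scores = np.full(len(battery), np.nan)
    unscorable = []
    for i in range(len(battery)):
        obs = ~np.isnan(Z_all[i])
        if obs.sum() < MIN_SUBTESTS:
            unscorable.append(battery.index[i])
            continue
        s_oo = sigma[np.ix_(obs, obs)]
        scores[i] = lam[obs] @ np.linalg.pinv(s_oo) @ Z_all[i, obs]
    valid = ~np.isnan(scores)
    scores[valid] = (scores[valid] - scores[valid].mean()) / scores[valid].std()

    idx = battery.index
    return LanguageFactorModel(
        loadings=pd.Series(lam, index=subtests),
        uniquenesses=pd.Series(psi, index=subtests),
        scores=pd.Series(scores, index=idx, name="language_factor"),
        n_complete=n_complete,
        method=method,
        unscorable=unscorable,
    )


def orient_and_standardize(pheno: pd.DataFrame,
                           high_is_impaired=(),
                           reference_ids=None) -> pd.DataFrame:
    """Orient all three measures LOW = impaired and standardize the factor.

    ``high_is_impaired`` lists measures supplied in the opposite
    orientation (e.g. a burden index counting problems); those are
    sign-flipped about their reference mean. The language factor is
    z-standardized against ``reference_ids`` (default: all samples);
    orientation flips preserve all correlations up to sign.
    """
    out = pheno.copy()
    ref = out["sample_id"].isin(set(reference_ids)).to_numpy() if reference_ids is not None \
        else np.ones(len(out), dtype=bool)
    if not ref.any():
        raise ValueError("no reference samples present")
    for col in high_is_impaired:
        vals = out[col].to_numpy(dtype=float)
        out[col] = 2.0 * np.nanmean(vals[ref]) - vals  # reflect about reference mean
    lf = out["language_factor"].to_numpy(dtype=float)
    mu, sd = np.nanmean(lf[ref]), np.nanstd(lf[ref])
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("language factor has zero variance in the reference sample")
    out["language_factor"] = (lf - mu) / sd
    for col in ("nonword_repetition", "global_burden"):
        vals = out[col].to_numpy(dtype=float)
        if np.nanstd(vals[ref]) == 0:
            raise ValueError(f"zero-variance measure: {col}")
    return out
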