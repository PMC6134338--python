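"""Core in-memory containers shared across the pipeline.

The pipeline passes around three tabular objects:

``GenotypeMatrix``
    Hard-call minor-allele dosages (0/1/2, ``MISSING`` = -1) with per-SNP
    metadata. Dosages are always coded on the minor allele as determined in
    the loaded cohort; readers flag coding flips rather than silently
    recoding.

``PhenotypeTable`` / ``CohortDesign``
    Plain :class:`pandas.DataFrame` objects with documented column names
    (see :data:`PHENOTYPE_COLUMNS` and :data:`DESIGN_COLUMNS`). Keeping them
    as DataFrames keeps every downstream statistical call idiomatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing hard-call dosage.
MISSING: int = -1

#: Columns of a phenotype table. ``nonword_repetition`` is on the scaled-score
#: metric (mean 10, SD 3); ``language_factor`` is in z-score units;
#: ``global_burden`` is oriented so that LOW = impaired.
PHENOTYPE_COLUMNS = ("sample_id", "nonword_repetition", "language_factor", "global_burden")

#: Columns of a cohort design table. ``group`` is one of ``SCT``/``twinA``/
#: ``twinB``; ``karyotype`` is ``XXX``/``XXY``/``XYY`` for trisomy cases and
#: ``46,XX``/``46,XY`` otherwise; ``ascertainment`` is ``postnatal`` (came to
#: light through developmental problems) or ``prenatal``; twins carry a
#: ``pair_id`` and ``zygosity`` (``MZ``/``DZ``).
DESIGN_COLUMNS = ("sample_id", "group", "karyotype", "ascertainment", "pair_id", "zygosity")

#: Columns of the SNP metadata frame inside a GenotypeMatrix.
SNP_COLUMNS = ("snp_id", "chrom", "pos", "gene", "allele_minor", "allele_major")


@dataclass
class GenotypeMatrix:
    """Per-sample minor-allele dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array of minor-allele counts;
        ``MISSING`` (-1) marks a failed call.
    samples
        Sample identifiers, one per row.
    snps
        DataFrame with columns :data:`SNP_COLUMNS`, one row per column of
        ``dosages``.
    """

    dosages: np.ndarray
    samples: list[str]
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list does not match dosage rows")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError("snp table does not match dosage columns")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING (-1)")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_id values must be unique within a panel")
        self.snps = self.snps.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    # ------------------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``dosages``."""
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing calls replaced by NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def sample_het_rate(self) -> np.ndarray:
        """Heterozygous fraction among non-missing calls per sample."""
        called = ~self.missing_mask()
        n_called = called.sum(axis=1)
        het = (self.dosages == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, het / n_called, np.nan)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded (minor) allele per SNP, pairwise-complete."""
        d = self.dosages_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (always reported on the minor allele)."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts for SNP column ``j``."""
        col = self.dosages[:, j]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    # ------------------------------------------------------------------
    def subset_samples(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given sample positions / boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        samples = [self.samples[i] for i in index]
        return GenotypeMatrix(self.dosages[index, :].copy(), samples, self.snps.copy())

    def subset_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP positions / boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index].copy(),
            list(self.samples),
            self.snps.iloc[index].reset_index(drop=True),
        )

    def subset_snp_ids(self, snp_ids) -> "GenotypeMatrix":
        wanted = set(snp_ids)
        mask = self.snps["snp_id"].isin(wanted).to_numpy()
        return self.subset_snps(mask)

    def sample_positions(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.samples), self.snps.copy())


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table carries the documented analysis columns."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return pheno


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort design table carries the documented columns."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    return design
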