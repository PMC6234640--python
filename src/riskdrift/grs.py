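"""Genetic risk scores: raw, standardized, and ancestral/derived-corrected.

A raw genetic risk score (GRS) is the unweighted sum of risk-allele
counts over the loci of one disease category.  Standardized scores are
Z-scores against the mean and SD over all individuals pooled across
populations.  The correction compensates for the systematic excess of
ancestral risk alleles (and deficit of derived risk alleles) that
African genomes carry relative to non-African genomes at
European-ascertained disease loci: each ancestral-risk locus count is
shifted down by twice the mean ancestral frequency difference, each
derived-risk locus count shifted up by twice the derived difference,
and the shifted sum is mapped through the *uncorrected* mean/SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import NON_AFRICAN, POPULATIONS, Panel


@dataclass(frozen=True)
class CorrectionConstants:
    """Per-locus count shifts for the African GRS correction.

    ``delta_ancestral`` is twice the mean AFR-minus-non-AFR ancestral
    risk-allele frequency difference (2 × 9.51% = 0.1902);
    ``delta_derived`` is twice the derived difference magnitude
    (2 × 5.41% = 0.1082).
    """

    delta_ancestral: float = 0.1902
    delta_derived: float = 0.1082

    @classmethod
    def from_panel(cls, panel: Panel, disease_table: pd.DataFrame) -> "CorrectionConstants":
        """Recompute the shifts from a panel's own frequency differences."""
        from .popstats import frequency_difference_by_state

        d = frequency_difference_by_state(disease_table, panel)
        return cls(delta_ancestral=2.0 * d.delta_ancestral, delta_derived=2.0 * abs(d.delta_derived))


def _category_loci(disease_table: pd.DataFrame, category: str | None) -> pd.DataFrame:
    if category is None:
        return disease_table
    loci = disease_table[disease_table["category"] == category]
    if loci.empty:
        raise ValueError(f"no loci in category {category!r}")
    return loci


def _risk_counts(genotypes: pd.DataFrame, loci: pd.DataFrame) -> np.ndarray:
    """(n_individuals, n_loci) risk-allele counts; complement for ancestral risk."""
    missing = [i for i in loci["id"] if i not in genotypes.columns]
    if missing:
        raise ValueError(f"loci missing from genotype matrix: {missing[:10]}")
    counts = genotypes[loci["id"].tolist()].to_numpy(dtype=float)
    ancestral = (loci["risk_state"] == "ancestral").to_numpy()
    counts[:, ancestral] = 2.0 - counts[:, ancestral]
    return counts


def raw_grs(genotypes: pd.DataFrame, disease_table: pd.DataFrame, category: str | None = None) -> pd.Series:
    """Per-individual sum of risk-allele counts over a category's loci.

    Counts the derived allele when the risk allele is derived and its
    complement (2 − derived count) when the risk allele is ancestral;
    no effect-size weighting.
    """
    loci = _category_loci(disease_table, category)
    counts = _risk_counts(genotypes, loci)
    return pd.Series(counts.sum(axis=1), index=genotypes.index, name="raw")


def standardize_grs(raw: pd.Series) -> pd.Series:
    """Z-scores of raw GRS against the mean/SD over all individuals pooled.

    A zero SD (all raw scores identical) yields all-zero Z-scores with
    a warning rather than an error.
    """
    if len(raw) < 2:
        raise ValueError("standardization requires at least 2 individuals")
    mean, sd = float(raw.mean()), float(raw.std(ddof=0))
    if sd == 0.0:
        warnings.warn("all raw GRS identical; standardized scores set to 0")
        return pd.Series(np.zeros(len(raw)), index=raw.index, name="z")
    return ((raw - mean) / sd).rename("z")


def corrected_grs(
    genotypes: pd.DataFrame,
    disease_table: pd.DataFrame,
    category: str | None = None,
    constants: CorrectionConstants = CorrectionConstants(),
) -> pd.Series:
    """Corrected raw scores from per-locus effective risk-allele counts.

    Effective count = risk count − delta_ancestral at ancestral-risk
    loci and risk count + delta_derived at derived-risk loci (so a
    homozygote carries 1.8098 effective ancestral or 2.1082 effective
    derived risk alleles under the default constants).
    """
    loci = _category_loci(disease_table, category)
    counts = _risk_counts(genotypes, loci)
    ancestral = (loci["risk_state"] == "ancestral").to_numpy()
    counts[:, ancestral] -= constants.delta_ancestral
    counts[:, ~ancestral] += constants.delta_derived
    return pd.Series(counts.sum(axis=1), index=genotypes.index, name="corrected_raw")


def corrected_african_grs(
    genotypes: pd.DataFrame,
    disease_table: pd.DataFrame,
    category: str | None,
    constants: CorrectionConstants,
    uncorrected_mean: float,
    uncorrected_sd: float,
) -> pd.Series:
    """Corrected standardized scores through the uncorrected Z mapping."""
    corrected = corrected_grs(genotypes, disease_table, category, constants)
    if uncorrected_sd == 0.0:
        warnings.warn("zero uncorrected SD; corrected Z set to 0")
        return pd.Series(np.zeros(len(corrected)), index=corrected.index, name="corrected_z")
    return ((corrected - uncorrected_mean) / uncorrected_sd).rename("corrected_z")


def score_table(
    genotypes: pd.DataFrame,
    disease_table: pd.DataFrame,
    constants: CorrectionConstants = CorrectionConstants(),
    correct_populations: tuple[str, ...] = ("AFR",),
) -> pd.DataFrame:
    """Raw, Z, and corrected scores per individual × disease category.

    The correction is applied only to individuals in
    ``correct_populations`` (African genomes by default); other rows
    carry NaN in the corrected columns.
    """
    if "population" not in genotypes.columns:
        raise ValueError("genotype matrix needs a 'population' column")
    frames = []
    for category in sorted(disease_table["category"].unique()):
        raw = raw_grs(genotypes, disease_table, category)
        z = standardize_grs(raw)
        mean, sd = float(raw.mean()), float(raw.std(ddof=0))
        block = pd.DataFrame(
            {
                "individual": genotypes.index,
                "population": genotypes["population"].to_numpy(),
                "category": category,
                "raw": raw.to_numpy(),
                "z": z.to_numpy(),
            }
        )
        corr_mask = block["population"].isin(correct_populations).to_numpy()
        corrected_raw = np.full(len(block), np.nan)
        corrected_z = np.full(len(block), np.nan)
        if corr_mask.any():
            sub = genotypes.loc[corr_mask]
            craw = corrected_grs(sub, disease_table, category, constants)
            corrected_raw[corr_mask] = craw.to_numpy()
            if sd > 0:
                corrected_z[corr_mask] = (craw.to_numpy() - mean) / sd
            else:
                corrected_z[corr_mask] = 0.0
        block["corrected_raw"] = corrected_raw
        block["corrected_z"] = corrected_z
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def compare_grs_distributions(scores_a, scores_b):
    """Two-sided Mann–Whitney U test between two groups of scores.

    Exact small-sample p-values where scipy supports them (no ties);
    returns the scipy result object with ``statistic`` and ``pvalue``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
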