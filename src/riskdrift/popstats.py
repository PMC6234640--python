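"""Empirical summary statistics for disease-locus frequency tables.

Paired nonparametric tests of African vs pooled non-African risk-allele
frequencies, per-category summaries, mean differences split by the
ancestral/derived state of the risk allele, DAF binning, a
frequency-based allele-age estimate, and the across-category
correlation between frequency bias and ancestral-risk proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DAF_COLUMNS, NON_AFRICAN, POPULATIONS, Panel
from .synthetic import CATEGORIES


def paired_wilcoxon_frequency_test(afr: Sequence[float], non_afr: Sequence[float]):
    """Two-sided paired Wilcoxon signed-rank test on per-locus frequencies.

    Exact null distribution for n ≤ 25 pairs (no ties/zeros), normal
    approximation above — scipy's 'auto' policy.

    Raises
    ------
    ValueError
        If every paired difference is zero (the test is undefined).
    """
    afr = np.asarray(afr, dtype=float)
    non_afr = np.asarray(non_afr, dtype=float)
    if afr.shape != non_afr.shape:
        raise ValueError("paired samples must have equal length")
    d = afr - non_afr
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    return stats.wilcoxon(afr, non_afr, alternative="two-sided", method="auto")


def _joined_risk_frequencies(disease_table: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Disease table joined to the panel, with per-population risk frequencies."""
    pdf = panel.df.set_index("id")
    missing = [i for i in disease_table["id"] if i not in pdf.index]
    if missing:
        raise ValueError(f"disease loci not in panel: {missing[:10]}")
    joined = disease_table.join(pdf.loc[:, list(DAF_COLUMNS)], on="id")
    ancestral = (joined["risk_state"] == "ancestral").to_numpy()
    for p in POPULATIONS:
        daf = joined[f"daf_{p}"].to_numpy(dtype=float)
        joined[f"rf_{p}"] = np.where(ancestral, 1.0 - daf, daf)
    joined["rf_nonafr"] = joined[[f"rf_{p}" for p in NON_AFRICAN]].mean(axis=1)
    joined["daf_mean"] = joined[list(DAF_COLUMNS)].mean(axis=1)
    return joined


@dataclass(frozen=True)
class StateDifferences:
    """Mean AFR − pooled-non-AFR risk-frequency differences, split by risk state."""

    delta_ancestral: float
    delta_derived: float
    frac_higher_afr_ancestral: float
    frac_higher_afr_derived: float
    n_ancestral: int
    n_derived: int
    ties_ancestral: int
    ties_derived: int


def frequency_difference_by_state(disease_table: pd.DataFrame, panel: Panel) -> StateDifferences:
    """Mean risk-frequency difference (AFR − pooled non-AFR) by risk state.

    Also reports the fraction of loci where the African risk frequency
    is strictly higher; ties count as not-higher and are reported.
    """
    joined = _joined_risk_frequencies(disease_table, panel)
    out = {}
    for state in ("ancestral", "derived"):
        sub = joined[joined["risk_state"] == state]
        d = sub["rf_AFR"].to_numpy() - sub["rf_nonafr"].to_numpy()
        out[state] = (
            float(d.mean()) if len(d) else float("nan"),
            float((d > 0).mean()) if len(d) else float("nan"),
            len(d),
            int((d == 0).sum()),
        )
    return StateDifferences(
        delta_ancestral=out["ancestral"][0],
        delta_derived=out["derived"][0],
        frac_higher_afr_ancestral=out["ancestral"][1],
        frac_higher_afr_derived=out["derived"][1],
        n_ancestral=out["ancestral"][2],
        n_derived=out["derived"][2],
        ties_ancestral=out["ancestral"][3],
        ties_derived=out["derived"][3],
    )


def overall_weighted_difference(delta_ancestral: float, delta_derived: float, prop_ancestral: float) -> float:
    """Overall risk-frequency difference as the state-proportion-weighted mean."""
    if not 0.0 <= prop_ancestral <= 1.0:
        raise ValueError("prop_ancestral must be in [0,1]")
    return prop_ancestral * delta_ancestral + (1.0 - prop_ancestral) * delta_derived


def daf_bin_differences(
    disease_table: pd.DataFrame, panel: Panel, bin_width: float = 0.2
) -> pd.DataFrame:
    """Per-DAF-bin mean Δ(AFR − non-AFR) risk frequency, by risk state.

    Each locus is binned by its across-population mean DAF.  The lowest
    bin is closed, [0, bin_width], and subsequent bins are
    (lo, lo + bin_width], so a mean DAF exactly at a boundary falls in
    the lower bin.
    """
    n_bins = round(1.0 / bin_width)
    if not np.isclose(n_bins * bin_width, 1.0):
        raise ValueError("bin_width must divide 1")
    joined = _joined_risk_frequencies(disease_table, panel)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    joined["daf_bin"] = pd.cut(joined["daf_mean"], bins=edges, right=True, include_lowest=True)
    delta = joined["rf_AFR"] - joined["rf_nonafr"]
    out = (
        joined.assign(delta=delta)
        .groupby(["daf_bin", "risk_state"], observed=False)["delta"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "delta_afr_nonafr", "count": "n_loci"})
    )
    out["bin_low"] = [max(float(b.left), 0.0) for b in out["daf_bin"]]
    out["bin_high"] = [float(b.right) for b in out["daf_bin"]]
    return out.drop(columns="daf_bin")


def allele_age(
    p: float,
    N: float = 10_000,
    gen_time: float = 25.0,
    formula: Callable[[float, float], float] | None = None,
) -> float:
    """Expected age in years of a derived allele at frequency p.

    The default estimator is 2·N·p/(1−p) generations, scaled by the
    generation time; at p = 0.2 with N = 10,000 and 25 years per
    generation this gives 125,000 years.  An alternative frequency-age
    formula (taking p and N, returning generations) can be plugged in.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    if formula is None:
        generations = 2.0 * N * p / (1.0 - p)
    else:
        generations = formula(p, N)
    return generations * gen_time


def kimura_ohta_age(p: float, N: float) -> float:
    """Alternative age estimator: −4N·p·ln(p)/(1−p) generations."""
    return -4.0 * N * p * np.log(p) / (1.0 - p)


def category_summaries(disease_table: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Per-category locus counts, mean risk frequencies, Δ, ancestral share, test p."""
    joined = _joined_risk_frequencies(disease_table, panel)
    rows = []
    for category in [c for c in CATEGORIES if c in set(joined["category"])]:
        sub = joined[joined["category"] == category]
        row = {"category": category, "n_loci": len(sub)}
        for p in POPULATIONS:
            row[f"mean_rf_{p}"] = float(sub[f"rf_{p}"].mean())
        d = sub["rf_AFR"].to_numpy() - sub["rf_nonafr"].to_numpy()
        row["delta_afr_nonafr"] = float(d.mean())
        row["prop_ancestral"] = float((sub["risk_state"] == "ancestral").mean())
        if np.any(d != 0):
            row["wilcoxon_p"] = float(
                paired_wilcoxon_frequency_test(sub["rf_AFR"], sub["rf_nonafr"]).pvalue
            )
        else:
            row["wilcoxon_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def category_correlation(summaries: pd.DataFrame) -> float:
    """Squared Pearson correlation between Δ(AFR − non-AFR) and ancestral share.

    Raises
    ------
    ValueError
        With fewer than 3 categories or zero variance in either variable.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 categories")
    x = summaries["prop_ancestral"].to_numpy(dtype=float)
    y = summaries["delta_afr_nonafr"].to_numpy(dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
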