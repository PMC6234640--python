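"""Rejection-sampling simulation of GWAS discovery from a SNP pool.

Each simulated "GWAS catalog" is built by repeatedly drawing a test SNP
uniformly from a platform-filtered pool, looking up its risk-allele
frequency in the study population, drawing a genotype relative risk
from the configured effect-size model, computing analytic case-control
power, and accepting the SNP with probability equal to that power,
until a target number of distinct disease associations is reached.
Accepted loci carry risk-allele frequencies from all five continental
populations, so the bias that ascertainment imposes on non-study
populations can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import NON_AFRICAN, POPULATIONS, Panel
from .power import power_vector

EFFECT_MODELS = ("fixed", "gamma", "gamma_pop_noise", "gamma_shift_eur", "gamma_shift_afr")

STUDY_POPS = POPULATIONS + ("MIX",)

_RF_COLUMNS = tuple(f"rf_{p}" for p in POPULATIONS)
_GRR_COLUMNS = tuple(f"grr_{p}" for p in POPULATIONS)


@dataclass(frozen=True)
class EffectModelParams:
    """Parameters of the locus-specific effect-size distributions.

    Symmetric effects are Gamma(shape, scale) draws shared by all
    populations; per-population noise adds independent N(0, pop_noise_sd)
    to each population's GRR; the shifted variants add ``shift`` to the
    EUR (or AFR) GRR only.  Any GRR below ``floor`` is set to ``floor``
    after noise/shift.
    """

    gamma_shape: float = 1.24
    gamma_scale: float = 0.85
    pop_noise_sd: float = 0.5
    shift: float = 0.5
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one GWAS-discovery simulation.

    Defaults are the canonical discovery scenario: Affymetrix 6.0
    content, a European study cohort of 3500 cases and 3500 controls,
    additive inheritance, prevalence 0.1, genome-wide threshold 1e-5
    and a fixed genotype relative risk of 1.211.
    """

    platform: str = "AFFY6"
    study_pop: str = "EUR"
    risk_state: str = "derived"
    n_cases: int = 3500
    n_controls: int = 3500
    alpha: float = 1e-5
    model: str = "additive"
    prevalence: float = 0.1
    effect_model: str = "fixed"
    fixed_grr: float = 1.211
    effect_params: EffectModelParams = field(default_factory=EffectModelParams)
    n_target: int = 3036
    seed: int = 0
    draw_cap: int = 100_000_000
    batch_size: int = 20_000

    def __post_init__(self) -> None:
        if self.study_pop not in STUDY_POPS:
            raise ValueError(f"study_pop must be one of {STUDY_POPS}")
        if self.risk_state not in ("ancestral", "derived"):
            raise ValueError("risk_state must be 'ancestral' or 'derived'")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")


@dataclass(frozen=True)
class SimReplicate:
    """One simulated GWAS catalog: accepted loci and bookkeeping."""

    config: SimConfig
    loci: pd.DataFrame  # id, risk_state, rf_*, grr_*, power
    attempts: int


def study_population_risk_frequency(record, config: SimConfig) -> float:
    """Risk-allele frequency of one variant in the study population.

    The risk frequency is the derived frequency for derived risk
    alleles and its complement for ancestral risk alleles; the MIX
    cohort uses the unweighted mean over the five populations.
    """
    daf = np.array([record.daf[p] for p in POPULATIONS])
    rf = daf if config.risk_state == "derived" else 1.0 - daf
    if config.study_pop == "MIX":
        return float(rf.mean())
    return float(rf[POPULATIONS.index(config.study_pop)])


def sample_genotype_relative_risk(
    config: SimConfig, rng: np.random.Generator, size: int | None = None
) -> dict[str, float] | np.ndarray:
    """Draw per-population genotype relative risks under the effect model.

    Returns a dict population→GRR for a single draw, or a (size, 5)
    array when ``size`` is given.  Values below the truncation floor are
    set to the floor after any noise or shift.
    """
    n = 1 if size is None else size
    ep = config.effect_params
    if config.effect_model == "fixed":
        g = np.full((n, 5), config.fixed_grr)
    else:
        base = rng.gamma(ep.gamma_shape, ep.gamma_scale, size=n)
        g = np.repeat(base[:, None], 5, axis=1)
        if config.effect_model == "gamma_pop_noise":
            g = g + rng.normal(0.0, ep.pop_noise_sd, size=(n, 5))
        elif config.effect_model == "gamma_shift_eur":
            g[:, POPULATIONS.index("EUR")] += ep.shift
        elif config.effect_model == "gamma_shift_afr":
            g[:, POPULATIONS.index("AFR")] += ep.shift
    g = np.maximum(g, ep.floor)
    if size is None:
        return {p: float(g[0, k]) for k, p in enumerate(POPULATIONS)}
    return g


def _risk_frequency_matrix(panel: Panel, risk_state: str, pool: np.ndarray) -> np.ndarray:
    daf = panel.daf_matrix()[pool]
    return daf if risk_state == "derived" else 1.0 - daf


def rejection_sample_associations(
    panel: Panel, config: SimConfig, rng: np.random.Generator | None = None
) -> SimReplicate:
    """Simulate one GWAS catalog by power-weighted rejection sampling.

    Draws test SNPs uniformly with replacement from the platform pool;
    each draw is accepted with probability equal to its analytic power
    in the study cohort (using the study population's GRR; MIX uses the
    mean GRR).  Already-accepted SNPs are skipped, so the returned set
    is distinct.  ``attempts`` counts every draw up to and including the
    one that completed the set.

    Raises
    ------
    RuntimeError
        If the draw cap is exceeded before ``n_target`` acceptances,
        reporting the realised acceptance rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = np.flatnonzero(panel.platform_mask(config.platform))
    if pool.size == 0:
        raise ValueError(f"no panel records carry platform flag {config.platform!r}")
    rf = _risk_frequency_matrix(panel, config.risk_state, pool)  # (m, 5)
    study_p = rf.mean(axis=1) if config.study_pop == "MIX" else rf[:, POPULATIONS.index(config.study_pop)]
    ids = panel.ids.to_numpy()[pool]

    accepted: dict[int, tuple[np.ndarray, float]] = {}
    attempts = 0
    batch = config.batch_size
    while True:
        if attempts >= config.draw_cap:
            rate = len(accepted) / attempts if attempts else 0.0
            raise RuntimeError(
                f"draw cap {config.draw_cap} exceeded with {len(accepted)}/{config.n_target} "
                f"acceptances (acceptance rate {rate:.3g})"
            )
        idx = rng.integers(0, pool.size, size=batch)
        grr = sample_genotype_relative_risk(config, rng, size=batch)  # (batch, 5)
        if config.study_pop == "MIX":
            g_study = grr.mean(axis=1)
        else:
            g_study = grr[:, POPULATIONS.index(config.study_pop)]
        pw = power_vector(
            study_p[idx], g_study, config.n_cases, config.n_controls,
            config.alpha, config.prevalence, config.model,
        )
        u = rng.random(batch)
        hits = np.flatnonzero(u < pw)
        done_at = None
        for h in hits:
            j = int(idx[h])
            if j in accepted:
                continue
            accepted[j] = (grr[h], float(pw[h]))
            if len(accepted) == config.n_target:
                done_at = int(h)
                break
        if done_at is not None:
            attempts += done_at + 1
            break
        attempts += batch

    order = list(accepted.keys())
    rf_rows = rf[order]
    grr_rows = np.vstack([accepted[j][0] for j in order])
    powers = [accepted[j][1] for j in order]
    loci = pd.DataFrame({"id": ids[order], "risk_state": config.risk_state})
    for k, col in enumerate(_RF_COLUMNS):
        loci[col] = rf_rows[:, k]
    for k, col in enumerate(_GRR_COLUMNS):
        loci[col] = grr_rows[:, k]
    loci["power"] = powers
    return SimReplicate(config=config, loci=loci, attempts=attempts)


def summarize_population_differences(rep: SimReplicate) -> pd.Series:
    """Mean risk-allele frequency per population and AFR-vs-rest contrasts."""
    loci = rep.loci
    means = {f"mean_rf_{p}": float(loci[f"rf_{p}"].mean()) for p in POPULATIONS}
    nonafr = loci[[f"rf_{p}" for p in NON_AFRICAN]].to_numpy().mean(axis=1)
    out = {
        "risk_state": rep.config.risk_state,
        "n_loci": len(loci),
        "attempts": rep.attempts,
        **means,
        "delta_afr_eur": float((loci["rf_AFR"] - loci["rf_EUR"]).mean()),
        "delta_afr_nonafr": float((loci["rf_AFR"].to_numpy() - nonafr).mean()),
    }
    return pd.Series(out)


def replicate_rng(seed: int, i: int) -> np.random.Generator:
    """Deterministic child generator for replicate ``i`` of a run."""
    return np.random.default_rng([seed, i])


def run_replicates(panel: Panel, config: SimConfig, n_reps: int) -> pd.DataFrame:
    """Run independent replicates under child seeds (seed, i).

    Returns one summary row per replicate; aggregate with
    :func:`aggregate_replicates`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for i in range(n_reps):
        rep = rejection_sample_associations(panel, config, rng=replicate_rng(config.seed, i))
        s = summarize_population_differences(rep)
        s["replicate"] = i
        rows.append(s)
    return pd.DataFrame(rows)


def aggregate_replicates(summaries: pd.DataFrame) -> pd.Series:
    """Across-replicate mean and SD of the population contrasts."""
    num = summaries.drop(columns=["risk_state", "replicate"], errors="ignore")
    agg = {}
    for col in num.columns:
        agg[f"{col}_mean"] = float(num[col].mean())
        agg[f"{col}_sd"] = float(num[col].std(ddof=1)) if len(num) > 1 else 0.0
    agg["n_reps"] = len(summaries)
    return pd.Series(agg)


def sweep_sample_sizes(
    panel: Panel,
    config: SimConfig,
    log10_min: float = 3.0,
    log10_max: float = 6.0,
    step: float = 0.1,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Replicate summaries over a log10 grid of equal case/control sizes."""
    if log10_min > log10_max:
        raise ValueError("log10_min must not exceed log10_max")
    n_points = int(round((log10_max - log10_min) / step)) + 1
    grid = log10_min + step * np.arange(n_points)
    rows = []
    for x in grid:
        n = int(round(10**x))
        cfg = replace(config, n_cases=n, n_controls=n)
        agg = aggregate_replicates(run_replicates(panel, cfg, n_reps))
        agg["log10_n"] = float(x)
        agg["n_cases"] = n
        agg["platform"] = config.platform
        agg["risk_state"] = config.risk_state
        rows.append(agg)
    return pd.DataFrame(rows)
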