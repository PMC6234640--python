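"""Analytic case-control power for a single SNP, plus a Monte-Carlo oracle.

The analytic engine follows the one-stage GAS/CaTS design: penetrances
are derived from prevalence, genotype relative risk, inheritance model
and risk-allele frequency under Hardy–Weinberg; expected case and
control allele frequencies follow; power is that of the two-sided
1-degree-of-freedom allelic test under a normal approximation with
null-pooled and alternative-specific variances.  The Monte-Carlo
routine simulates allele-count tables and applies the Pearson
chi-square allele test directly, serving as the independent oracle for
the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MODELS = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class PowerParams:
    """Full parameterisation of one case-control power evaluation."""

    n_cases: int
    n_controls: int
    alpha: float
    prevalence: float
    grr: float
    model: str
    p: float

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.grr < 1.0:
            raise ValueError("genotype relative risk must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("risk allele frequency must be in [0,1]")


def _relative_risks(grr, model: str):
    """Genotype relative risks (r1, r2) for 1 and 2 risk alleles."""
    grr = np.asarray(grr, dtype=float)
    if model == "additive":
        return grr, 2.0 * grr - 1.0
    if model == "dominant":
        return grr, grr
    if model == "recessive":
        return np.ones_like(grr), grr
    raise ValueError(f"model must be one of {MODELS}")


def penetrances_from_model(params: PowerParams) -> tuple[float, float, float]:
    """Solve (f0, f1, f2) from prevalence, GRR, model and allele frequency.

    f0 satisfies K = (1-p)^2 f0 + 2 p (1-p) f1 + p^2 f2 with f1 = r1 f0,
    f2 = r2 f0 under Hardy–Weinberg genotype frequencies.

    Raises
    ------
    ValueError
        If any solved penetrance falls outside [0, 1] (the parameter
        combination is inconsistent with the stated prevalence).
    """
    p, K = params.p, params.prevalence
    r1, r2 = _relative_risks(params.grr, params.model)
    denom = (1 - p) ** 2 + 2 * p * (1 - p) * r1 + p**2 * r2
    f0 = K / denom
    f1, f2 = float(r1 * f0), float(r2 * f0)
    f0 = float(f0)
    for name, f in (("f0", f0), ("f1", f1), ("f2", f2)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(
                f"penetrance {name}={f:.4g} outside [0,1]; parameters inconsistent "
                f"(K={K}, grr={params.grr}, model={params.model}, p={p})"
            )
    return f0, f1, f2


def case_control_allele_frequencies(params: PowerParams) -> tuple[float, float]:
    """Expected risk-allele frequencies among cases and controls."""
    p, K = params.p, params.prevalence
    f0, f1, f2 = penetrances_from_model(params)
    p_case = (p**2 * f2 + p * (1 - p) * f1) / K
    p_control = (p**2 * (1 - f2) + p * (1 - p) * (1 - f1)) / (1 - K)
    return float(p_case), float(p_control)


# Gauss-Hermite nodes/weights for integrating over the estimated pooled
# frequency (probabilists' convention: exact for standard-normal moments)
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _allelic_power(p_case, p_control, n_cases, n_controls, alpha):
    """Normal-approximation power of the two-sided allelic contrast test.

    The allelic chi-square statistic compares the case/control
    frequency contrast against a null variance *estimated* from the
    pooled sample frequency.  Power is computed by integrating the
    normal rejection probability of the contrast over the (normal)
    sampling distribution of that pooled frequency, with the proper
    covariance between contrast and pool — a refinement that keeps the
    closed form within Monte-Carlo error of the simulated test even at
    high power and skewed allele frequencies.
    """
    p_case = np.asarray(p_case, dtype=float)
    p_control = np.asarray(p_control, dtype=float)
    na = 2.0 * np.asarray(n_cases, dtype=float)
    nu = 2.0 * np.asarray(n_controls, dtype=float)
    n_tot = na + nu
    var_c = p_case * (1 - p_case) / na
    var_u = p_control * (1 - p_control) / nu
    delta = p_case - p_control
    pbar = (na * p_case + nu * p_control) / n_tot
    var_m = (na / n_tot) ** 2 * var_c + (nu / n_tot) ** 2 * var_u
    cov = (na / n_tot) * var_c - (nu / n_tot) * var_u
    var1 = var_c + var_u
    z = stats.norm.isf(alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mhat = pbar[..., None] + np.sqrt(var_m)[..., None] * _GH_NODES
        inside = (mhat > 0.0) & (mhat < 1.0)
        mhat = np.clip(mhat, 0.0, 1.0)
        thr = z * np.sqrt(mhat * (1 - mhat) * (1 / na + 1 / nu)[..., None])
        # contrast given the pooled frequency: conditional normal
        beta = np.where(var_m > 0, cov / np.where(var_m > 0, var_m, 1.0), 0.0)
        mu_d = delta[..., None] + beta[..., None] * (mhat - pbar[..., None])
        sd_d = np.sqrt(np.maximum(var1 - beta * cov, 0.0))[..., None]
        p_rej = stats.norm.sf((thr - mu_d) / sd_d) + stats.norm.cdf((-thr - mu_d) / sd_d)
        # a pooled sample frequency of exactly 0 or 1 is monomorphic: no test
        p_rej = np.where(inside, np.clip(p_rej, 0.0, 1.0), 0.0)
        power = np.sum(_GH_WEIGHTS * p_rej, axis=-1)
    # monomorphic in both groups: the test cannot reject
    power = np.where(var1 <= 0, 0.0, power)
    return power


def analytic_power(params: PowerParams) -> float:
    """Power of the two-sided 1-df allelic test at level alpha.

    Returns exactly 0 for monomorphic sites (p = 0 or p = 1), which can
    never yield an association.
    """
    if params.p <= 0.0 or params.p >= 1.0:
        return 0.0
    p_case, p_control = case_control_allele_frequencies(params)
    return float(
        np.clip(
            _allelic_power(p_case, p_control, params.n_cases, params.n_controls, params.alpha),
            0.0,
            1.0,
        )
    )


def power_vector(
    p,
    grr,
    n_cases: int,
    n_controls: int,
    alpha: float,
    prevalence: float,
    model: str,
) -> np.ndarray:
    """Vectorised analytic power over arrays of frequencies and GRRs.

    Used by the rejection sampler, where GRR draws from heavy-tailed
    effect-size distributions can imply penetrances above 1; those are
    saturated at 1 and the prevalence implied by the saturated
    penetrances is used, rather than raising as the scalar API does.
    """
    p = np.asarray(p, dtype=float)
    grr = np.broadcast_to(np.asarray(grr, dtype=float), p.shape)
    r1, r2 = _relative_risks(grr, model)
    denom = (1 - p) ** 2 + 2 * p * (1 - p) * r1 + p**2 * r2
    f0 = np.clip(prevalence / denom, 0.0, 1.0)
    f1 = np.clip(r1 * f0, 0.0, 1.0)
    f2 = np.clip(r2 * f0, 0.0, 1.0)
    K = (1 - p) ** 2 * f0 + 2 * p * (1 - p) * f1 + p**2 * f2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_case = (p**2 * f2 + p * (1 - p) * f1) / K
        p_control = (p**2 * (1 - f2) + p * (1 - p) * (1 - f1)) / (1 - K)
    power = _allelic_power(p_case, p_control, n_cases, n_controls, alpha)
    power = np.where((p <= 0.0) | (p >= 1.0) | (K <= 0.0) | (K >= 1.0), 0.0, power)
    return np.clip(power, 0.0, 1.0)


def monte_carlo_power(params: PowerParams, n_reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo power estimate via simulated allele-count tables.

    Draws case/control risk-allele counts Binomial(2n, p_case) and
    Binomial(2n, p_control) and applies the Pearson chi-square test on
    the 2×2 allele table (no continuity correction); returns the
    fraction of replicates with p-value below alpha.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if params.p <= 0.0 or params.p >= 1.0:
        return 0.0
    p_case, p_control = case_control_allele_frequencies(params)
    rng = np.random.default_rng(seed)
    na, nu = 2 * params.n_cases, 2 * params.n_controls
    x = rng.binomial(na, p_case, size=n_reps).astype(float)
    y = rng.binomial(nu, p_control, size=n_reps).astype(float)
    n = float(na + nu)
    t = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (x * (nu - y) - y * (na - x)) ** 2 / (t * (n - t) * na * nu)
    chi2 = np.where((t == 0) | (t == n), 0.0, chi2)
    crit = stats.chi2.isf(params.alpha, df=1)
    return float(np.mean(chi2 > crit))
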