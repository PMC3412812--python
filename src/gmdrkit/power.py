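"""Case-control power for the Cochran-Armitage trend test.

Follows the Slager-Schaid formulation: case and control genotype
probabilities are obtained by Bayes inversion of a per-allele logistic
penetrance calibrated to a population prevalence under HWE; the trend
statistic's mean and variance under the alternative give analytic power for
the two-sided test.  A vectorized Monte Carlo oracle is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .simulate import hwe_genotype_freqs


@dataclass
class PowerSpec:
    maf: float
    per_allele_or: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    weights: tuple[float, float, float] = (0.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf {self.maf} outside (0, 0.5]")
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def case_control_genotype_freqs(
    maf: float, per_allele_or: float, prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype probabilities in cases and controls.

    Penetrance f_j = expit(a + j log OR) with intercept a calibrated so the
    HWE-weighted prevalence equals ``prevalence``; then
    p_j = g_j f_j / K and q_j = g_j (1 - f_j) / (1 - K).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    g = hwe_genotype_freqs(maf)
    beta = np.log(per_allele_or)
    x = np.arange(3.0)

    def mean_pen(a):
        return float(g @ expit(a + beta * x)) - prevalence

    lo, hi = logit(prevalence) - abs(beta) * 2 - 1, logit(prevalence) + abs(beta) * 2 + 1
    a = optimize.brentq(mean_pen, lo, hi, xtol=1e-12)
    pen = expit(a + beta * x)
    p = g * pen / prevalence
    q = g * (1.0 - pen) / (1.0 - prevalence)
    return p, q


def _trend_moments(p, q, n_cases, n_controls, weights):
    """Mean and variances (null and alternative) of the trend statistic
    U = sum_j x_j (S r_j - R s_j) / N for multinomial genotype counts."""
    x = np.asarray(weights, dtype=float)
    r, s = float(n_cases), float(n_controls)
    n = r + s
    mu_p, mu_q = float(x @ p), float(x @ q)
    m2p, m2q = float((x ** 2) @ p), float((x ** 2) @ q)
    eu = r * s / n * (mu_p - mu_q)
    var_alt = (s ** 2 * r * (m2p - mu_p ** 2) + r ** 2 * s * (m2q - mu_q ** 2)) / n ** 2
    pi = (r * np.asarray(p) + s * np.asarray(q)) / n  # pooled genotype freqs
    var_null = r * s / n * (float((x ** 2) @ pi) - float(x @ pi) ** 2)
    return eu, var_null, var_alt


def armitage_trend_power(spec: PowerSpec, prevalence: float = 0.20) -> float:
    """Analytic two-sided power of the Cochran-Armitage trend test.

    power = Phi((|mu| - z sqrt(V0)) / sqrt(VA)) + Phi((-|mu| - z sqrt(V0)) / sqrt(VA)),
    with mu the trend-statistic mean under the alternative, V0/VA its null and
    alternative variances, and z the 1 - alpha/2 normal quantile.  Equals
    alpha exactly at OR = 1.
    """
    p, q = case_control_genotype_freqs(spec.maf, spec.per_allele_or, prevalence)
    eu, v0, va = _trend_moments(p, q, spec.n_cases, spec.n_controls, spec.weights)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    thresh = z * np.sqrt(v0)
    sd_a = np.sqrt(va)
    return float(
        stats.norm.cdf((abs(eu) - thresh) / sd_a)
        + stats.norm.cdf((-abs(eu) - thresh) / sd_a)
    )


def cochran_armitage_trend(
    case_counts, control_counts, weights=(0.0, 1.0, 2.0)
) -> tuple[float, float]:
    """Cochran-Armitage trend chi-squared (1 df) and p from genotype counts.

    Accepts vectors of length 3 or stacked (n_sims, 3) arrays (vectorized);
    returns arrays in the latter case.
    """
    r_j = np.atleast_2d(np.asarray(case_counts, dtype=float))
    s_j = np.atleast_2d(np.asarray(control_counts, dtype=float))
    x = np.asarray(weights, dtype=float)
    r = r_j.sum(axis=1)
    s = s_j.sum(axis=1)
    n = r + s
    u = (s * (r_j @ x) - r * (s_j @ x)) / n
    n_j = r_j + s_j
    var0 = r * s / n * ((n_j @ (x ** 2)) / n - ((n_j @ x) / n) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var0 > 0, u ** 2 / var0, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    if np.ndim(case_counts) == 1:
        return float(chi2[0]), float(p[0])
    return chi2, p


def simulate_trend_power(
    spec: PowerSpec,
    prevalence: float = 0.20,
    n_sims: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte Carlo rejection rate of the trend test under the spec's
    alternative: genotype counts drawn multinomially in cases and controls."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p, q = case_control_genotype_freqs(spec.maf, spec.per_allele_or, prevalence)
    r_j = rng.multinomial(spec.n_cases, p, size=n_sims)
    s_j = rng.multinomial(spec.n_controls, q, size=n_sims)
    _, pvals = cochran_armitage_trend(r_j, s_j, spec.weights)
    return float((pvals <= spec.alpha).mean())


def expected_genotype_counts(spec: PowerSpec, prevalence: float = 0.20) -> dict:
    """Expected case/control genotype counts under the spec's alternative."""
    p, q = case_control_genotype_freqs(spec.maf, spec.per_allele_or, prevalence)
    return {
        "cases": (spec.n_cases * p).tolist(),
        "controls": (spec.n_controls * q).tolist(),
    }
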