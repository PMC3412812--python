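"""Single-locus and combination association analyses.

Covariate-adjusted logistic regressions under dominant/recessive/allelic
genotype encodings, the risk-allele-count trend model, the 2x2 odds ratio of
high- vs low-risk cell membership, and the multiplicative-interaction
deviation test (product term, Wald and likelihood-ratio p).

The "allelic model" is the log-additive per-allele dose term (genotype coded
0/1/2) in a logistic regression — the only reading of that label under which
covariate-adjusted allelic odds ratios exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, GENOTYPE_MODELS, encode_model
from .mdr import CellPartition

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class TermEstimate:
    term: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float


@dataclass
class GlmResult:
    """Per-term estimates of a fitted association model."""

    terms: dict[str, TermEstimate]
    llf: float
    nobs: int
    focal: str | None = None

    def __getitem__(self, term: str) -> TermEstimate:
        return self.terms[term]

    @property
    def focal_term(self) -> TermEstimate:
        return self.terms[self.focal]


def _fit_logit(y: np.ndarray, X: pd.DataFrame, focal: str) -> GlmResult:
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=50, tol=1e-8)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"logistic fit failed (singular design): {exc}") from None
    if not res.mle_retvals.get("converged", False):
        raise ValueError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} "
            "iterations; likely complete separation"
        )
    if np.abs(res.params).max() > 15:
        raise ValueError("logistic fit diverged (|beta| > 15); complete separation")
    terms = {}
    for name in Xc.columns:
        b = float(res.params[name])
        se = float(res.bse[name])
        terms[name] = TermEstimate(
            term=name, beta=b, se=se, or_=float(np.exp(b)),
            ci95=(float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))),
            p=float(res.pvalues[name]),
        )
    return GlmResult(terms=terms, llf=float(res.llf), nobs=int(res.nobs), focal=focal)


def _covariate_frame(cohort: Cohort, covariate_names) -> pd.DataFrame:
    for c in covariate_names:
        if c not in cohort.covariates.columns:
            raise ValueError(f"covariate {c!r} not in cohort")
    return cohort.covariates[list(covariate_names)].astype(float)


def fit_single_locus_model(
    cohort: Cohort,
    snp: int | str,
    model: str,
    covariate_names: tuple[str, ...] = (),
) -> GlmResult:
    """Adjusted logistic fit of case status on one encoded locus.

    Complete-case on the locus and covariates.  Raises if the encoded
    predictor is constant (e.g. no minor-allele homozygotes under the
    recessive encoding) or the fit separates.
    """
    if isinstance(snp, str):
        snp = cohort.snp_ids.index(snp)
    y = cohort.require_binary()
    x = encode_model(cohort.genotypes[:, snp], model)
    cov = _covariate_frame(cohort, covariate_names)
    keep = ~np.isnan(x)
    if cov.shape[1]:
        keep &= ~cov.isna().any(axis=1).to_numpy()
    x, yk = x[keep], y[keep]
    if np.ptp(x) == 0:
        raise ValueError(
            f"{cohort.snp_ids[snp]}: encoded predictor constant under the "
            f"{model} model (no informative genotypes)"
        )
    X = pd.DataFrame({"genotype": x})
    for c in cov.columns:
        X[c] = cov[c].to_numpy()[keep]
    return _fit_logit(yk, X, focal="genotype")


def declare_risk_direction(
    cohort: Cohort, snp: int, covariate_names: tuple[str, ...] = ()
) -> int:
    """+1 if the minor allele is the risk allele (adjusted allelic OR > 1),
    else -1.  Risk alleles are defined empirically, from the fitted direction."""
    res = fit_single_locus_model(cohort, snp, "allelic", covariate_names)
    return 1 if res.focal_term.or_ > 1.0 else -1


def risk_allele_trend(
    cohort: Cohort,
    loci: tuple[int, int],
    covariate_names: tuple[str, ...] = (),
    directions: tuple[int, int] | None = None,
) -> GlmResult:
    """Logistic fit of case status on the 0-4 count of risk alleles across two
    loci (reference: zero risk alleles).  Risk-allele direction at each locus
    defaults to the adjusted single-locus allelic fit (OR > 1)."""
    y = cohort.require_binary()
    if directions is None:
        directions = tuple(declare_risk_direction(cohort, j, covariate_names) for j in loci)
    counts = np.zeros(cohort.n_subjects)
    keep = np.ones(cohort.n_subjects, dtype=bool)
    for j, d in zip(loci, directions):
        g = cohort.genotypes[:, j].astype(float)
        miss = cohort.genotypes[:, j] == -1
        keep &= ~miss
        counts = counts + (g if d > 0 else 2.0 - g)
    cov = _covariate_frame(cohort, covariate_names)
    if cov.shape[1]:
        keep &= ~cov.isna().any(axis=1).to_numpy()
    counts, yk = counts[keep], y[keep]
    if np.ptp(counts) == 0:
        raise ValueError("risk-allele count is constant across subjects")
    X = pd.DataFrame({"risk_alleles": counts})
    for c in cov.columns:
        X[c] = cov[c].to_numpy()[keep]
    return _fit_logit(yk, X, focal="risk_alleles")


@dataclass
class TwoByTwo:
    """2x2 case/control by exposed/unexposed table with Woolf-CI odds ratio."""

    a: int  # exposed cases
    b: int  # exposed controls
    c: int  # unexposed cases
    d: int  # unexposed controls
    or_: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)
    chi2: float = field(init=False)
    p: float = field(init=False)
    haldane_corrected: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be nonnegative")
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            raise ValueError("2x2 table has an empty margin")
        aa, bb, cc, dd = (float(v) for v in (a, b, c, d))
        if min(a, b, c, d) == 0:  # Haldane-Anscombe continuity correction
            aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
            self.haldane_corrected = True
        self.or_ = aa * dd / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        log_or = np.log(self.or_)
        self.ci95 = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
        chi2, p, _, _ = stats.chi2_contingency(
            np.array([[a, b], [c, d]]), correction=False
        )
        self.chi2, self.p = float(chi2), float(p)


def high_low_risk_or(
    y: np.ndarray | Cohort,
    high: np.ndarray | CellPartition,
    genotypes: np.ndarray | None = None,
) -> TwoByTwo:
    """Odds ratio of case status by high- vs low-risk cell membership.

    Accepts either (case vector, boolean high-risk vector) or
    (cohort, CellPartition) — in the latter case subjects are assigned by the
    partition's labels, EMPTY cells counting as low risk.
    """
    if isinstance(y, Cohort):
        cohort, partition = y, high
        yv = cohort.require_binary()
        hv = partition.predict(cohort.genotypes)
    else:
        yv = np.asarray(y).astype(int)
        hv = np.asarray(high).astype(bool)
    a = int(((yv == 1) & hv).sum())
    b = int(((yv == 0) & hv).sum())
    c = int(((yv == 1) & ~hv).sum())
    d = int(((yv == 0) & ~hv).sum())
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("both HIGH and LOW groups must be nonempty")
    return TwoByTwo(a, b, c, d)


@dataclass
class InteractionTest:
    """Multiplicative-deviation test of a locus pair."""

    full_model: GlmResult
    product_beta: float
    product_or: float
    wald_p: float
    lrt_stat: float
    lrt_p: float


def interaction_deviation_test(
    cohort: Cohort,
    loci: tuple[int, int],
    covariate_names: tuple[str, ...] = (),
    encodings: tuple[str, str] = ("allelic", "allelic"),
) -> InteractionTest:
    """Test deviation from multiplicativity: logistic model with both main
    effects plus their product, reporting the product-term Wald p and the
    1-df likelihood-ratio p against the main-effects model."""
    y = cohort.require_binary()
    for e in encodings:
        if e not in GENOTYPE_MODELS:
            raise ValueError(f"unknown encoding {e!r}")
    x1 = encode_model(cohort.genotypes[:, loci[0]], encodings[0])
    x2 = encode_model(cohort.genotypes[:, loci[1]], encodings[1])
    cov = _covariate_frame(cohort, covariate_names)
    keep = ~np.isnan(x1) & ~np.isnan(x2)
    if cov.shape[1]:
        keep &= ~cov.isna().any(axis=1).to_numpy()
    X_main = pd.DataFrame({"g1": x1[keep], "g2": x2[keep]})
    for c in cov.columns:
        X_main[c] = cov[c].to_numpy()[keep]
    X_full = X_main.copy()
    X_full.insert(2, "g1:g2", x1[keep] * x2[keep])
    reduced = _fit_logit(y[keep], X_main, focal="g2")
    full = _fit_logit(y[keep], X_full, focal="g1:g2")
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    term = full["g1:g2"]
    return InteractionTest(
        full_model=full,
        product_beta=term.beta,
        product_or=term.or_,
        wald_p=term.p,
        lrt_stat=lrt,
        lrt_p=float(stats.chi2.sf(lrt, df=1)),
    )


def association_table(
    cohort: Cohort,
    covariate_sets: dict[str, tuple[str, ...]],
    models: tuple[str, ...] = GENOTYPE_MODELS,
) -> pd.DataFrame:
    """OR [95% CI] (p) per SNP per genetic model per adjustment set.

    Inestimable fits (constant encoded predictor, separation) are reported
    as blank cells, mirroring how such entries are left empty in practice.
    """
    rows = []
    for j, info in enumerate(cohort.snps):
        row = {"snp": info.snp_id, "gene": info.gene}
        for model in models:
            for set_name, covs in covariate_sets.items():
                col = f"{model}_{set_name}"
                try:
                    t = fit_single_locus_model(cohort, j, model, covs).focal_term
                    row[col] = f"{t.or_:.2f} [{t.ci95[0]:.2f}-{t.ci95[1]:.2f}] ({t.p:.3f})"
                except ValueError:
                    row[col] = ""
        rows.append(row)
    return pd.DataFrame(rows)
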