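"""Synthetic case-control and continuous-trait cohort generator.

Generates the data structure the downstream analyses assume: independent
biallelic loci in Hardy-Weinberg proportions at stated minor-allele
frequencies, age/sex (plus smoking/FPG) covariates, marginal genetic effects
on the logit or trait scale, and calibrated two-locus epistasis with exactly
zero marginal single-locus effects.

Pure epistasis is parameterized on the penetrance (probability) scale: the
3x3 genotype-pair penetrance table is ``target + contrast * outer(u, v)``
where ``u`` and ``v`` have zero mean under the HWE genotype weights of their
locus.  Every row/column HWE-weighted average then equals the target
prevalence exactly, so each locus has analytically zero marginal effect and
the population prevalence is the target by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import Cohort, SnpInfo, RAS_LOCI, encode_model

# Study-scale defaults: sample sizes from the motivating case-control design,
# MAFs plausible for the six RAS loci in an East-Asian population, disease
# prevalence typical of adult obesity in that setting.
STUDY_N_CASES = 324
STUDY_N_CONTROLS = 373
STUDY_MAFS = (0.30, 0.39, 0.06, 0.30, 0.10, 0.40)
STUDY_EPISTASIS_PAIR = (3, 5)  # MAS1-like x BDKRB2-like
DEFAULT_PREVALENCE = 0.20
# Penetrance-scale contrast of the default pure-epistasis model; chosen once
# to give a detectable but not trivial two-locus signal at the study sample
# size (see docs/methods.md).
DEFAULT_CONTRAST = 0.085


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """(P(0), P(1), P(2)) minor-allele-count probabilities under HWE."""
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


@dataclass
class SimulationConfig:
    """Sampling design of a simulated cohort.

    ``retrospective`` draws a source population until exactly ``n_cases``
    cases and ``n_controls`` controls are collected (case-control design);
    ``prospective`` keeps a cohort of ``n_total`` with its observed prevalence.
    """

    n_cases: int = STUDY_N_CASES
    n_controls: int = STUDY_N_CONTROLS
    n_total: int | None = None
    mafs: tuple[float, ...] = STUDY_MAFS
    seed: int = 0
    sampling: str = "retrospective"
    max_batches: int = 200

    def __post_init__(self) -> None:
        for m in self.mafs:
            if not 0.0 < m <= 0.5:
                raise ValueError(f"maf {m} outside (0, 0.5]")
        if self.sampling not in ("retrospective", "prospective"):
            raise ValueError(f"unknown sampling {self.sampling!r}")
        if self.sampling == "prospective" and not self.n_total:
            raise ValueError("prospective sampling requires n_total")


@dataclass
class PenetranceSpec:
    """Generative phenotype model.

    Binary traits: logit P(case) = baseline_logit + sum of per-locus model
    encodings times their betas + covariate terms; if an epistasis table is
    present, ``logit(table[g_i, g_j])`` replaces the baseline for the pair
    (the table holds penetrances and absorbs the baseline).

    Continuous traits: mean = baseline_value + genetic and covariate terms
    (+ the epistasis table read as additive mean offsets), plus Gaussian
    noise with ``noise_sd``.
    """

    baseline_logit: float
    per_locus_betas: dict[int, tuple[float, str]] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)
    epistasis_loci: tuple[int, int] | None = None
    epistasis_table: np.ndarray | None = None
    trait_kind: str = "binary"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.epistasis_table is not None:
            self.epistasis_table = np.asarray(self.epistasis_table, dtype=float)
            if self.epistasis_table.shape != (3, 3):
                raise ValueError("epistasis_table must be 3x3")
            if self.epistasis_loci is None or len(self.epistasis_loci) != 2:
                raise ValueError("epistasis_table requires exactly two epistasis_loci")
            if self.trait_kind == "binary" and not (
                (self.epistasis_table > 0).all() and (self.epistasis_table < 1).all()
            ):
                raise ValueError("binary epistasis penetrances must lie in (0, 1)")

    def to_json(self) -> str:
        d = asdict(self)
        if d["epistasis_table"] is not None:
            d["epistasis_table"] = self.epistasis_table.tolist()
        d["per_locus_betas"] = {str(k): list(v) for k, v in self.per_locus_betas.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PenetranceSpec":
        d = json.loads(text)
        d["per_locus_betas"] = {int(k): (v[0], v[1]) for k, v in d["per_locus_betas"].items()}
        if d["epistasis_table"] is not None:
            d["epistasis_table"] = np.array(d["epistasis_table"])
        if d["epistasis_loci"] is not None:
            d["epistasis_loci"] = tuple(d["epistasis_loci"])
        return cls(**d)


def _pattern_vector(pattern: str, maf: float) -> np.ndarray:
    """Zero-HWE-mean contrast vector over genotype codes, max |entry| = 1."""
    f = hwe_genotype_freqs(maf)
    if pattern == "xor":
        # heterozygote-vs-homozygote contrast
        u = np.array([1.0, -(f[0] + f[2]) / f[1], 1.0])
    elif pattern == "checkerboard":
        # centered additive dose contrast
        u = np.arange(3.0) - 2.0 * maf
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return u / np.abs(u).max()


def build_epistasis_penetrance(
    pair_maf: tuple[float, float],
    target_prevalence: float,
    contrast: float,
    pattern: str = "xor",
    custom_table: np.ndarray | None = None,
    loci: tuple[int, int] = STUDY_EPISTASIS_PAIR,
    trait_kind: str = "binary",
    noise_sd: float = 1.0,
) -> PenetranceSpec:
    """Two-locus pure-epistasis penetrance spec calibrated to a prevalence.

    For ``xor``/``checkerboard`` the 3x3 table is ``target + contrast *
    outer(u1, u2)`` with zero-HWE-mean unit-max vectors u, so the population
    prevalence equals ``target_prevalence`` exactly and both loci have
    analytically zero marginal penetrance effect.  ``custom_table`` (a 3x3
    deviation matrix) is recentred additively to hit the target prevalence
    but makes no zero-marginal guarantee.  Raises if any penetrance would
    leave (0, 1) for a binary trait.
    """
    if trait_kind == "binary" and not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    if contrast < 0:
        raise ValueError("contrast must be nonnegative")
    m1, m2 = pair_maf
    f1, f2 = hwe_genotype_freqs(m1), hwe_genotype_freqs(m2)
    if custom_table is not None:
        delta = np.asarray(custom_table, dtype=float) * contrast
        delta = delta - f1 @ delta @ f2  # recentre to the target prevalence
    else:
        u1 = _pattern_vector(pattern, m1)
        u2 = _pattern_vector(pattern, m2)
        delta = contrast * np.outer(u1, u2)
    table = target_prevalence + delta
    if trait_kind == "binary" and not ((table > 0).all() and (table < 1).all()):
        raise ValueError(
            f"infeasible contrast {contrast}: penetrances span "
            f"[{table.min():.4f}, {table.max():.4f}], must lie in (0, 1)"
        )
    if trait_kind == "continuous":
        table = delta  # additive mean offsets around the baseline
    return PenetranceSpec(
        baseline_logit=float(logit(target_prevalence)) if trait_kind == "binary"
        else float(target_prevalence),
        epistasis_loci=tuple(loci),
        epistasis_table=table,
        trait_kind=trait_kind,
        noise_sd=noise_sd,
    )


def marginal_penetrances(table: np.ndarray, pair_maf: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype marginal penetrance of each locus, HWE-averaging the other."""
    f1, f2 = (hwe_genotype_freqs(m) for m in pair_maf)
    return np.asarray(table) @ f2, np.asarray(table).T @ f1


def analytic_prevalence(spec: PenetranceSpec, mafs: tuple[float, ...]) -> float:
    """Population prevalence of a binary genetic-only spec by HWE-weighted sum.

    Enumerates all genotype combinations of the loci the spec involves;
    requires zero covariate effects (otherwise the prevalence depends on the
    covariate distribution and is not a finite sum).
    """
    if spec.trait_kind != "binary":
        raise ValueError("analytic prevalence defined for binary traits only")
    if any(b != 0 for b in spec.covariate_betas.values()):
        raise ValueError("analytic prevalence requires zero covariate effects")
    loci = sorted(set(spec.per_locus_betas) | set(spec.epistasis_loci or ()))
    if not loci:
        return float(expit(spec.baseline_logit))
    freqs = [hwe_genotype_freqs(mafs[j]) for j in loci]
    total = 0.0
    for combo in np.ndindex(*([3] * len(loci))):
        weight = float(np.prod([freqs[i][g] for i, g in enumerate(combo)]))
        geno_row = np.zeros((1, max(loci) + 1), dtype=int)
        for i, j in enumerate(loci):
            geno_row[0, j] = combo[i]
        total += weight * float(penetrance(spec, geno_row, None)[0])
    return total


def simulate_genotypes(config: SimulationConfig, n: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """HWE genotypes at the config's MAFs; independent loci, codes 0/1/2."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n is None:
        n = config.n_total or (config.n_cases + config.n_controls)
    return _draw_genotypes(config.mafs, n, rng)


def _draw_genotypes(mafs, n, rng) -> np.ndarray:
    cols = []
    for m in mafs:
        if not 0.0 < m <= 0.5:
            raise ValueError(f"maf {m} outside (0, 0.5]")
        cdf = np.cumsum(hwe_genotype_freqs(m))
        cols.append(np.searchsorted(cdf, rng.random(n), side="right"))
    return np.column_stack(cols).astype(np.int64)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age/sex/smoking/FPG covariates at magnitudes typical of the design."""
    return pd.DataFrame(
        {
            "age": rng.normal(56.0, 10.0, n),
            "sex": (rng.random(n) < 0.55).astype(float),
            "smoking": (rng.random(n) < 0.20).astype(float),
            "fpg": np.clip(rng.normal(6.7, 2.4, n), 2.5, None),
        }
    )


def penetrance(spec: PenetranceSpec, genotypes: np.ndarray,
               covariates: pd.DataFrame | None) -> np.ndarray:
    """Per-subject P(case) (binary) or trait mean (continuous)."""
    n = genotypes.shape[0]
    if spec.trait_kind == "binary" and spec.epistasis_table is not None:
        i, j = spec.epistasis_loci
        lp = logit(spec.epistasis_table[genotypes[:, i], genotypes[:, j]])
    else:
        lp = np.full(n, spec.baseline_logit)
        if spec.epistasis_table is not None:
            i, j = spec.epistasis_loci
            lp = lp + spec.epistasis_table[genotypes[:, i], genotypes[:, j]]
    for snp_idx, (beta, model) in spec.per_locus_betas.items():
        lp = lp + beta * encode_model(genotypes[:, snp_idx], model)
    for name, beta in spec.covariate_betas.items():
        if beta == 0.0:
            continue
        if covariates is None or name not in covariates:
            raise ValueError(f"covariate {name!r} required by spec but absent")
        lp = lp + beta * covariates[name].to_numpy()
    return expit(lp) if spec.trait_kind == "binary" else lp


def simulate_phenotypes(
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    spec: PenetranceSpec,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    snps: list[SnpInfo] | None = None,
) -> Cohort:
    """Assign phenotypes to subjects; retrospective mode tops up to the
    requested case/control counts by drawing further source-population
    batches from the config's MAFs.
    """
    rng = np.random.default_rng(None if config is None else config.seed) if rng is None else rng
    if genotypes.shape[0] != len(covariates):
        raise ValueError("genotype and covariate row counts differ")

    def draw(G, cov):
        mu = penetrance(spec, G, cov)
        if spec.trait_kind == "binary":
            return (rng.random(len(mu)) < mu).astype(float)
        return mu + rng.normal(0.0, spec.noise_sd, len(mu))

    y = draw(genotypes, covariates)
    if config is None or config.sampling == "prospective":
        ids = [f"S{i}" for i in range(len(y))]
        return Cohort(ids, genotypes, y, covariates.reset_index(drop=True), snps or [],
                      spec.trait_kind)

    if spec.trait_kind != "binary":
        raise ValueError("retrospective sampling requires a binary trait")
    G, cov = genotypes, covariates
    batch = max(genotypes.shape[0], 1000)
    for _ in range(config.max_batches):
        if (y == 1).sum() >= config.n_cases and (y == 0).sum() >= config.n_controls:
            break
        Gb = _draw_genotypes(config.mafs, batch, rng)
        cb = simulate_covariates(batch, rng)
        yb = draw(Gb, cb)
        G = np.vstack([G, Gb])
        cov = pd.concat([cov, cb], ignore_index=True)
        y = np.concatenate([y, yb])
    else:
        raise RuntimeError(
            f"could not reach {config.n_cases} cases / {config.n_controls} controls "
            f"after {config.max_batches} batches (got {(y == 1).sum()} cases, "
            f"{(y == 0).sum()} controls); check the spec's baseline risk"
        )
    keep = np.concatenate(
        [np.flatnonzero(y == 1)[: config.n_cases], np.flatnonzero(y == 0)[: config.n_controls]]
    )
    ids = [f"S{i}" for i in range(len(keep))]
    return Cohort(ids, G[keep], y[keep], cov.iloc[keep].reset_index(drop=True),
                  snps or [], "binary")


def simulate_cohort(
    spec: PenetranceSpec,
    config: SimulationConfig,
    snps: list[SnpInfo] | None = None,
) -> Cohort:
    """Full generator: genotypes + covariates + phenotypes under one master seed.

    Child RNG streams for genotypes, covariates and phenotypes are derived
    deterministically from ``config.seed``, so each stage is reproducible in
    isolation and the whole cohort is byte-identical under a fixed seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_c, rng_p = (np.random.default_rng(s) for s in ss.spawn(3))
    if config.sampling == "prospective":
        n0 = config.n_total
    else:
        # initial batch sized by expected yield; retrospective top-up follows
        n0 = max(2 * (config.n_cases + config.n_controls), 1000)
    G = _draw_genotypes(config.mafs, n0, rng_g)
    cov = simulate_covariates(n0, rng_c)
    return simulate_phenotypes(G, cov, spec, config, rng_p, snps=snps)


def study_spec(
    contrast: float = DEFAULT_CONTRAST,
    prevalence: float = DEFAULT_PREVALENCE,
    pattern: str = "xor",
    pair: tuple[int, int] = STUDY_EPISTASIS_PAIR,
    mafs: tuple[float, ...] = STUDY_MAFS,
) -> PenetranceSpec:
    """Default study-condition generating model: pure two-locus epistasis."""
    return build_epistasis_penetrance(
        (mafs[pair[0]], mafs[pair[1]]), prevalence, contrast, pattern=pattern, loci=pair
    )


def study_cohort(seed: int, contrast: float = DEFAULT_CONTRAST, **spec_kwargs) -> Cohort:
    """A study-sized synthetic cohort: 324 cases / 373 controls, six loci,
    pure two-locus epistasis at the default contrast, age/sex covariates."""
    spec = study_spec(contrast=contrast, **spec_kwargs)
    config = SimulationConfig(seed=seed)
    return simulate_cohort(spec, config, snps=[SnpInfo(s.snp_id, s.gene) for s in RAS_LOCI])


def null_cohort(seed: int, prevalence: float = DEFAULT_PREVALENCE) -> Cohort:
    """Same design with no genetic effects at all (permutation/null checks)."""
    spec = PenetranceSpec(baseline_logit=float(logit(prevalence)))
    config = SimulationConfig(seed=seed)
    return simulate_cohort(spec, config, snps=[SnpInfo(s.snp_id, s.gene) for s in RAS_LOCI])
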