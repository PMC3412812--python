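"""End-to-end study pipeline: simulate or load a cohort, QC, MDR and GMDR
searches, association tables, combination OR, interaction test, trend power.

All stages run under one master seed; every report is plain JSON/TSV with
sorted keys and no absolute paths or timestamps, so re-running an identical
config reproduces each report byte-identically (wall-times go to run.log).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    Cohort,
    load_cohort,
    load_report,
    write_cohort_csv,
)
from .gmdr import run_gmdr_search
from .mdr import run_mdr_search, tabulate_and_classify
from .models import (
    association_table,
    high_low_risk_or,
    interaction_deviation_test,
)
from .power import PowerSpec, armitage_trend_power
from .simulate import (
    DEFAULT_CONTRAST,
    DEFAULT_PREVALENCE,
    STUDY_EPISTASIS_PAIR,
    STUDY_MAFS,
    SimulationConfig,
    build_epistasis_penetrance,
    simulate_cohort,
)

logger = logging.getLogger("gmdrkit.pipeline")


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    input_path: str | None = None
    input_format: str = "csv"
    simulation: dict | None = None
    trait_kind: str = "binary"
    covariates_primary: tuple[str, ...] = ("age", "sex")
    covariates_extended: tuple[str, ...] = ("age", "sex", "fpg", "smoking")
    k_min: int = 1
    k_max: int = 6
    folds: int = 10
    permutations: int = 1000
    seed: int = 0
    outdir: str = "gmdr_run"

    def __post_init__(self) -> None:
        if self.input_path is None and self.simulation is None:
            self.simulation = {}
        self.covariates_primary = tuple(self.covariates_primary)
        self.covariates_extended = tuple(self.covariates_extended)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _simulate_from_config(cfg: RunConfig) -> tuple[Cohort, dict]:
    sim = dict(cfg.simulation or {})
    params = {
        "n_cases": sim.get("n_cases", 324),
        "n_controls": sim.get("n_controls", 373),
        "mafs": tuple(sim.get("mafs", STUDY_MAFS)),
        "pattern": sim.get("pattern", "xor"),
        "contrast": sim.get("contrast", DEFAULT_CONTRAST),
        "prevalence": sim.get("prevalence", DEFAULT_PREVALENCE),
        "pair": tuple(sim.get("pair", STUDY_EPISTASIS_PAIR)),
        "seed": cfg.seed,
    }
    spec = build_epistasis_penetrance(
        (params["mafs"][params["pair"][0]], params["mafs"][params["pair"][1]]),
        params["prevalence"],
        params["contrast"],
        pattern=params["pattern"],
        loci=params["pair"],
    )
    config = SimulationConfig(
        n_cases=params["n_cases"],
        n_controls=params["n_controls"],
        mafs=params["mafs"],
        seed=params["seed"],
    )
    snps = None
    if len(params["mafs"]) == 6:
        from .cohort import RAS_LOCI, SnpInfo

        snps = [SnpInfo(s.snp_id, s.gene) for s in RAS_LOCI]
    return simulate_cohort(spec, config, snps=snps), params


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Emits hwe_report.json, mdr_report.json, gmdr_report.json,
    assoc_table.tsv, combination_or.json, interaction_test.json, power.json
    and manifest.json.  A stage failure aborts with the stage name after
    writing a partial manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k not in ("outdir", "input_path")},  # no paths in reports
        "stages_completed": [],
        "outputs": [],
    }
    stage = "setup"

    def done(name: str, path: Path | None, t0: float) -> None:
        manifest["stages_completed"].append(name)
        if path is not None:
            manifest["outputs"].append(path.name)
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    try:
        stage = "cohort"
        t0 = time.perf_counter()
        if config.input_path:
            covs = tuple(dict.fromkeys(config.covariates_primary + config.covariates_extended))
            cohort = load_cohort(config.input_path, config.input_format,
                                 config.trait_kind, covs)
            sim_params = None
        else:
            cohort, sim_params = _simulate_from_config(config)
            write_cohort_csv(cohort, out / "cohort.csv")
            manifest["outputs"].append("cohort.csv")
            manifest["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in sim_params.items()
            }
        done("cohort", None, t0)

        stage = "hwe"
        t0 = time.perf_counter()
        _dump(load_report(cohort), out / "hwe_report.json")
        done("hwe", out / "hwe_report.json", t0)

        stage = "mdr"
        t0 = time.perf_counter()
        reports, best = run_mdr_search(
            cohort, config.k_min, config.k_max, config.folds,
            seed=config.seed, permutations=config.permutations,
        )
        snp_ids = cohort.snp_ids
        _dump(
            {
                "per_k": [r.to_dict(snp_ids) for r in reports],
                "best": best.to_dict(snp_ids),
            },
            out / "mdr_report.json",
        )
        done("mdr", out / "mdr_report.json", t0)

        stage = "gmdr"
        t0 = time.perf_counter()
        g_reports, g_best = run_gmdr_search(
            cohort, config.covariates_primary, config.k_min, config.k_max,
            config.folds, seed=config.seed, permutations=config.permutations,
        )
        _dump(
            {
                "covariates": list(config.covariates_primary),
                "per_k": [r.to_dict(snp_ids) for r in g_reports],
                "best": g_best.to_dict(snp_ids),
            },
            out / "gmdr_report.json",
        )
        done("gmdr", out / "gmdr_report.json", t0)

        stage = "assoc"
        t0 = time.perf_counter()
        table = association_table(
            cohort,
            {"primary": config.covariates_primary, "extended": config.covariates_extended},
        )
        table.to_csv(out / "assoc_table.tsv", sep="\t", index=False)
        done("assoc", out / "assoc_table.tsv", t0)

        pair_report = next((r for r in g_reports if r.k == 2), None)
        pair = pair_report.chosen_model if pair_report else None

        stage = "combination_or"
        t0 = time.perf_counter()
        if pair is not None:
            y = cohort.require_binary()
            resub = tabulate_and_classify(cohort.genotypes, y, pair)
            tt = high_low_risk_or(cohort, resub)
            fw = _fold_wise_or(cohort, pair, config.folds, config.seed)
            _dump(
                {
                    "pair": [snp_ids[i] for i in pair],
                    "resubstituted": _twobytwo_dict(tt) | {"note": "optimistic: labels reuse all data"},
                    "fold_wise": _twobytwo_dict(fw),
                },
                out / "combination_or.json",
            )
            done("combination_or", out / "combination_or.json", t0)

        stage = "interaction_test"
        t0 = time.perf_counter()
        if pair is not None:
            it = interaction_deviation_test(cohort, pair, config.covariates_primary)
            _dump(
                {
                    "pair": [snp_ids[i] for i in pair],
                    "product_or": it.product_or,
                    "wald_p": it.wald_p,
                    "lrt_stat": it.lrt_stat,
                    "lrt_p": it.lrt_p,
                },
                out / "interaction_test.json",
            )
            done("interaction_test", out / "interaction_test.json", t0)

        stage = "power"
        t0 = time.perf_counter()
        n_case = int(cohort.phenotype.sum()) if cohort.trait_kind == "binary" else cohort.n_subjects
        n_ctrl = cohort.n_subjects - n_case
        power_rows = []
        for j, info in enumerate(cohort.snps):
            from .cohort import allele_frequencies

            try:
                maf, _ = allele_frequencies(cohort, j)
            except ValueError:
                continue
            if maf <= 0:
                continue
            for or_ in (1.3, 1.5):
                spec = PowerSpec(min(maf, 0.5), or_, max(n_case, 1), max(n_ctrl, 1))
                power_rows.append(
                    {"snp": info.snp_id, "maf": round(maf, 4), "or": or_,
                     "power": round(armitage_trend_power(spec, DEFAULT_PREVALENCE), 4)}
                )
        _dump({"alpha": 0.05, "prevalence": DEFAULT_PREVALENCE, "grid": power_rows},
              out / "power.json")
        done("power", out / "power.json", t0)
    except Exception:
        manifest["failed_stage"] = stage
        _dump(manifest, out / "manifest.json")
        logger.removeHandler(log_handler)
        log_handler.close()
        raise
    _dump(manifest, out / "manifest.json")
    logger.removeHandler(log_handler)
    log_handler.close()
    return out


def _twobytwo_dict(tt) -> dict:
    return {
        "a_high_cases": tt.a,
        "b_high_controls": tt.b,
        "c_low_cases": tt.c,
        "d_low_controls": tt.d,
        "or": round(tt.or_, 4),
        "ci95": [round(tt.ci95[0], 4), round(tt.ci95[1], 4)],
        "chi2": round(tt.chi2, 4),
        "p": round(tt.p, 6),
        "haldane_corrected": tt.haldane_corrected,
    }


def _fold_wise_or(cohort: Cohort, pair, folds: int, seed: int | None):
    """2x2 OR with HIGH/LOW labels learned on training folds only (each
    subject classified by the partition fit without them)."""
    from .mdr import stratified_fold_ids

    y = cohort.require_binary()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    fid = stratified_fold_ids(y, cohort.genotypes, folds, rng)
    pred = np.zeros(cohort.n_subjects, dtype=bool)
    for f in range(folds):
        tr = fid != f
        part = tabulate_and_classify(cohort.genotypes[tr], y[tr], pair)
        pred[fid == f] = part.predict(cohort.genotypes[fid == f])
    return high_low_risk_or(y, pred)
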