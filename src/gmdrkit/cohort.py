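"""Cohort data model, file IO, genotype encodings, allele frequencies and HWE QC.

Genotypes are stored as minor-allele counts (0, 1, 2) with :data:`MISSING`
(-1) for missing calls.  The minor allele is defined empirically from the
loaded data (ties at frequency 0.5 are broken lexicographically, the smaller
allele character becoming the minor allele), so loading the same file always
yields the same coding regardless of external annotation.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

GENOTYPE_MODELS = ("dominant", "recessive", "allelic")


@dataclass
class SnpInfo:
    """Metadata for one biallelic locus.

    An insertion/deletion polymorphism (e.g. ACE I/D) is represented the same
    way, with 'I' and 'D' as the two allele characters.
    """

    snp_id: str
    gene: str | None = None
    allele_minor: str = "a"
    allele_major: str = "A"
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.allele_minor == self.allele_major:
            raise ValueError(
                f"{self.snp_id}: minor and major allele are both {self.allele_minor!r}"
            )


#: The six renin-angiotensin-system loci used as default simulation metadata.
RAS_LOCI = (
    SnpInfo("rs699", gene="AGT"),
    SnpInfo("ACE_ID", gene="ACE", allele_minor="D", allele_major="I"),
    SnpInfo("rs5186", gene="AGTR1"),
    SnpInfo("rs220721", gene="MAS1"),
    SnpInfo("rs1799983", gene="NOS3"),
    SnpInfo("rs1799722", gene="BDKRB2"),
)


@dataclass
class Cohort:
    """Aligned per-subject genotypes, phenotype and covariates.

    Parameters
    ----------
    subject_ids : list of str
    genotypes : (n_subjects, n_snps) int array of minor-allele counts,
        values in {0, 1, 2, MISSING}.
    phenotype : length-n vector; binary {0=control, 1=case} or continuous
        (e.g. BMI in kg/m^2) according to ``trait_kind``.
    covariates : DataFrame with one row per subject (may have zero columns).
    snps : per-locus metadata.
    trait_kind : "binary" or "continuous".
    """

    subject_ids: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame
    snps: list[SnpInfo] = field(default_factory=list)
    trait_kind: str = "binary"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.subject_ids)
        if self.genotypes.shape[0] != n or len(self.phenotype) != n:
            raise ValueError("subject_ids, genotypes and phenotype disagree on n")
        if len(self.covariates) != n:
            raise ValueError("covariates row count does not match subjects")
        if self.trait_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype code {self.genotypes[tuple(bad)]} at subject {bad[0]}, "
                f"snp {bad[1]} is not in {{0,1,2,{MISSING}}}"
            )
        if not self.snps:
            self.snps = [SnpInfo(f"snp{j}") for j in range(self.genotypes.shape[1])]
        if len(self.snps) != self.genotypes.shape[1]:
            raise ValueError("snps metadata does not match genotype columns")
        if self.trait_kind == "binary":
            vals = set(np.unique(self.phenotype))
            if not vals <= {0.0, 1.0}:
                raise ValueError(
                    f"binary phenotype must be coded 0/1, found values {sorted(vals)}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def require_binary(self) -> np.ndarray:
        if self.trait_kind != "binary":
            raise ValueError("operation requires a binary (case/control) phenotype")
        y = self.phenotype.astype(int)
        if y.min() == y.max():
            raise ValueError("binary phenotype must contain both cases and controls")
        return y


def genotype_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) from minor-allele-count codes, ignoring missing."""
    codes = np.asarray(codes)
    codes = codes[codes != MISSING]
    return int((codes == 0).sum()), int((codes == 1).sum()), int((codes == 2).sum())


def allele_frequencies(
    cohort: Cohort, snp_index: int, subset: str = "all"
) -> tuple[float, tuple[int, int, int]]:
    """Minor-allele frequency and genotype counts for one locus.

    ``subset`` is one of "all", "cases", "controls" (the latter two require a
    binary trait).  Missing genotypes are dropped; raises if nothing is left.
    """
    codes = cohort.genotypes[:, snp_index]
    if subset != "all":
        y = cohort.require_binary()
        codes = codes[y == (1 if subset == "cases" else 0)]
    counts = genotype_counts(codes)
    total = sum(counts)
    if total == 0:
        raise ValueError(f"all genotypes missing for snp {snp_index} in {subset}")
    maf = (counts[1] + 2 * counts[2]) / (2 * total)
    return maf, counts


@dataclass
class HweResult:
    """Pearson goodness-of-fit test of genotype counts against HWE proportions."""

    chi2: float
    df: int
    p_value: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    monomorphic: bool = False


def hwe_chi2(counts: tuple[int, int, int]) -> HweResult:
    """Hardy-Weinberg chi-squared test (1 df, no continuity correction).

    ``counts`` is (n_AA, n_Aa, n_aa).  With allele frequency
    p = (2 n_AA + n_Aa) / 2N the expected counts are (p^2 N, 2p(1-p) N,
    (1-p)^2 N).  A monomorphic locus (p in {0, 1}) fits HWE trivially and is
    returned flagged with chi2 = 0, p = 1.
    """
    n_aa_maj, n_het, n_aa_min = counts
    n = n_aa_maj + n_het + n_aa_min
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa_maj + n_het) / (2 * n)
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if p == 0.0 or p == 1.0:
        obs_exp = ((n, 0.0, 0.0) if p == 1.0 else (0.0, 0.0, n))
        return HweResult(0.0, 1, 1.0, counts, obs_exp, monomorphic=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(float(chi2), 1, p_value, counts, expected)


def encode_model(codes: np.ndarray, model: str) -> np.ndarray:
    """Encode minor-allele counts under a genetic model.

    dominant: 0,1,2 -> 0,1,1 ; recessive -> 0,0,1 ; allelic (log-additive
    per-allele dose) -> 0,1,2.  Missing codes propagate as NaN.
    """
    if model not in GENOTYPE_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; expected one of {GENOTYPE_MODELS}")
    codes = np.asarray(codes)
    out = codes.astype(float)
    out[codes == MISSING] = np.nan
    if model == "dominant":
        out[codes == 2] = 1.0
    elif model == "recessive":
        out[codes == 1] = 0.0
        out[codes == 2] = 1.0
    return out


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------


def _recode_column(raw: list[str], snp_id: str, line_offset: int = 2):
    """Turn a column of allele-pair strings or 0/1/2 integers into minor-allele
    counts plus allele metadata.  Returns (codes, SnpInfo)."""
    allele_counts: Counter[str] = Counter()
    parsed: list[tuple[str, str] | int | None] = []
    for i, val in enumerate(raw):
        v = str(val).strip()
        if v in ("NA", "00", "0 0", "", "nan"):
            parsed.append(None)
            continue
        if v in ("0", "1", "2"):
            parsed.append(int(v))
            continue
        if len(v) == 2 and v.isalpha():
            a, b = v[0], v[1]  # allele characters are case-sensitive
            parsed.append((a, b))
            allele_counts[a] += 1
            allele_counts[b] += 1
            continue
        raise ValueError(
            f"malformed genotype {val!r} at line {i + line_offset}, column {snp_id!r}"
        )
    has_pairs = any(isinstance(p, tuple) for p in parsed)
    has_ints = any(isinstance(p, int) for p in parsed)
    if has_pairs and has_ints:
        raise ValueError(f"column {snp_id!r} mixes allele pairs and integer codes")
    if has_pairs:
        alleles = sorted(allele_counts)  # lexicographic tie-break
        if len(alleles) > 2:
            raise ValueError(f"column {snp_id!r} has >2 alleles: {alleles}")
        if len(alleles) == 1:
            warnings.warn(f"snp {snp_id!r} is monomorphic", stacklevel=3)
            minor, major = alleles[0], alleles[0]
            # degenerate: keep a placeholder major allele distinct from minor
            major = "N" if minor != "N" else "M"
        else:
            a0, a1 = alleles
            minor, major = (a0, a1) if allele_counts[a0] <= allele_counts[a1] else (a1, a0)
        codes = np.full(len(parsed), MISSING, dtype=np.int64)
        for i, p in enumerate(parsed):
            if isinstance(p, tuple):
                codes[i] = (p[0] == minor) + (p[1] == minor)
        info = SnpInfo(snp_id, allele_minor=minor, allele_major=major)
    else:
        codes = np.array([MISSING if p is None else p for p in parsed], dtype=np.int64)
        obs = codes[codes != MISSING]
        if obs.size and obs.mean() > 1.0:  # coded allele is the major one: flip
            codes[codes != MISSING] = 2 - codes[codes != MISSING]
        info = SnpInfo(snp_id)
        if obs.size and len(np.unique(obs)) == 1:
            warnings.warn(f"snp {snp_id!r} is monomorphic", stacklevel=3)
    obs = codes[codes != MISSING]
    if obs.size:
        info.maf = float(obs.sum() / (2 * obs.size))
    return codes, info


def load_cohort(
    path: str,
    format: str = "csv",
    trait_kind: str = "binary",
    covariate_names: tuple[str, ...] = (),
) -> Cohort:
    """Read a cohort from CSV or minimal PLINK .ped/.map.

    CSV layout: header ``subject_id, phenotype, <covariate...>, <snp_id...>``;
    genotypes as allele pairs ("AG") or integers 0/1/2; missing is "NA"/"00".
    For ``plink_pedmap`` pass the .ped path (the .map is found by extension);
    PLINK phenotype 1=control / 2=case is re-coded to 0/1.
    """
    if format == "csv":
        return _load_csv(path, trait_kind, covariate_names)
    if format == "plink_pedmap":
        return _load_pedmap(path, trait_kind, covariate_names)
    raise ValueError(f"unknown format {format!r}")


def _load_csv(path, trait_kind, covariate_names):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["subject_id", "phenotype", *covariate_names]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    snp_cols = [c for c in df.columns if c not in required]
    subject_ids = df["subject_id"].tolist()
    try:
        phenotype = df["phenotype"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric phenotype: {exc}") from None
    covariates = pd.DataFrame(
        {c: pd.to_numeric(df[c]) for c in covariate_names},
        index=pd.RangeIndex(len(df)),
    )
    genos, infos = [], []
    for col in snp_cols:
        codes, info = _recode_column(df[col].tolist(), col)
        genos.append(codes)
        infos.append(info)
    genotypes = (
        np.column_stack(genos) if genos else np.zeros((len(df), 0), dtype=np.int64)
    )
    return Cohort(subject_ids, genotypes, phenotype, covariates, infos, trait_kind)


def _load_pedmap(ped_path, trait_kind, covariate_names):
    ped_path = str(ped_path)
    map_path = ped_path[: -len(".ped")] + ".map" if ped_path.endswith(".ped") else ped_path + ".map"
    snp_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f".map line {lineno}: expected 4 fields, got {len(parts)}")
            snp_ids.append(parts[1])
    subject_ids, phenos, sexes, rows = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ValueError(
                    f".ped line {lineno}: expected {6 + 2 * len(snp_ids)} fields, got {len(parts)}"
                )
            subject_ids.append(parts[1])
            sexes.append(parts[4])
            phenos.append(parts[5])
            rows.append(parts[6:])
    if trait_kind == "binary":
        pheno_map = {"1": 0.0, "2": 1.0}
        try:
            phenotype = np.array([pheno_map[p] for p in phenos])
        except KeyError as exc:
            raise ValueError(f"PLINK binary phenotype must be 1/2, found {exc}") from None
    else:
        phenotype = np.array([float(p) for p in phenos])
    genos, infos = [], []
    for j, snp_id in enumerate(snp_ids):
        raw = []
        for row in rows:
            a, b = row[2 * j], row[2 * j + 1]
            raw.append("00" if a == "0" or b == "0" else a + b)
        codes, info = _recode_column(raw, snp_id)
        genos.append(codes)
        infos.append(info)
    genotypes = np.column_stack(genos) if genos else np.zeros((len(rows), 0), dtype=np.int64)
    cov = {}
    if "sex" in covariate_names:
        cov["sex"] = [max(float(s) - 1.0, 0.0) for s in sexes]
    covariates = pd.DataFrame(cov, index=pd.RangeIndex(len(rows)))
    return Cohort(subject_ids, genotypes, phenotype, covariates, infos, trait_kind)


def write_cohort_csv(cohort: Cohort, path: str) -> None:
    """Write a cohort as the CSV dialect accepted by :func:`load_cohort`.

    Genotypes are written as allele pairs using each locus's allele
    characters, so a write/load round trip reproduces the integer codes.
    """
    df = pd.DataFrame({"subject_id": cohort.subject_ids})
    pheno = cohort.phenotype
    df["phenotype"] = pheno.astype(int) if cohort.trait_kind == "binary" else pheno
    for c in cohort.covariates.columns:
        df[c] = cohort.covariates[c].to_numpy()
    for j, info in enumerate(cohort.snps):
        mn, mj = info.allele_minor, info.allele_major
        # code k -> k copies of the minor allele, written in sorted order
        rep = {0: "".join(sorted(mj + mj)), 1: "".join(sorted(mn + mj)),
               2: "".join(sorted(mn + mn)), MISSING: "NA"}
        df[info.snp_id] = [rep[int(g)] for g in cohort.genotypes[:, j]]
    df.to_csv(path, index=False)


def load_report(cohort: Cohort) -> dict:
    """Per-SNP QC report: MAF, missingness, and HWE in controls (binary traits)."""
    report = {"n_subjects": cohort.n_subjects, "snps": {}}
    binary = cohort.trait_kind == "binary"
    for j, info in enumerate(cohort.snps):
        codes = cohort.genotypes[:, j]
        missing = float((codes == MISSING).mean())
        entry = {"gene": info.gene, "missingness": missing}
        try:
            maf, counts = allele_frequencies(cohort, j, "all")
            entry["maf"] = maf
            entry["genotype_counts"] = counts
        except ValueError:
            entry["maf"] = None
        if binary and entry.get("maf") is not None:
            _, ctrl_counts = allele_frequencies(cohort, j, "controls")
            hwe = hwe_chi2(ctrl_counts)
            entry["hwe_controls"] = {
                "chi2": hwe.chi2,
                "p_value": hwe.p_value,
                "monomorphic": hwe.monomorphic,
            }
        report["snps"][info.snp_id] = entry
    return report


def write_load_report(cohort: Cohort, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(load_report(cohort), fh, indent=2)
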