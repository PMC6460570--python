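"""Synthetic cohort generator with planted variant x drug -> ADE effects.

Emulates the joint data a population-biobank pharmacogenomics study works
from: a diploid genotype matrix with a realistic minor-allele-frequency
spectrum, ATC-coded prescription records, ICD10-coded diagnosis records
(adverse-drug-effect codes plus unrelated background codes), self-reported
ADEs, and a covariate table.  Effects are planted as log-odds-ratios in the
logistic model that generates ADE status among prescribed persons, and every
planted effect is recorded in a truth table so downstream estimators can be
tested for parameter recovery.  Identical seeds give byte-identical output
files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import load_ade_codes
from .variants import MAF_BINS, GenotypeMatrix

# Pool of ATC level-4 chemical subgroups used to label synthetic drugs.
ATC4_POOL = [
    "M01AC", "N02AX", "N06AB", "C10AA", "A10BA", "N06AA", "C08DA", "A02BC",
    "N03AF", "C03CA", "G04BD", "N06AX", "N05AH", "J01CA", "R06AE", "B01AC",
    "C07AB", "M01AE", "N02BE", "A02BA", "C09AA", "N05BA", "J01MA", "R03AC",
    "L04AX", "H02AB", "A07EC", "D07AC", "S01ED", "M05BA",
]

EHR_WINDOW = (np.datetime64("2004-01-01"), np.datetime64("2015-08-31"))

# Background (non-ADE) ICD10 codes so phenotype extraction has chaff to drop.
BACKGROUND_CODES = ["I10", "J06.9", "M54.5", "E11.9", "K21.0", "F41.1"]

# Covariate coefficients in the ADE-generating logistic model (centred
# covariates, so the intercept stays close to logit(base_ade_rate)).
COV_BETAS = {"sex": 0.10, "age_c": 0.010, "bmi_c": 0.020,
             "PC1": 0.05, "PC2": 0.05, "PC3": 0.05, "PC4": 0.05,
             "platform_wgs": 0.05}


@dataclass
class PlantedEffect:
    """A causal variant x drug-group effect on ADE risk.

    ``log_odds_ratio`` enters the generating logistic model multiplied by
    dosage (additive) or by the carrier indicator.  When ``group`` is set,
    ADE events attributable to the genotype term draw their ICD10 code from
    that diagnostic group only, which lets group-refinement logic be tested.
    """

    variant_id: str
    atc4_group: str
    log_odds_ratio: float
    model: str = "additive"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("additive", "carrier"):
            raise ValueError(f"model must be additive or carrier, got {self.model!r}")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``maf_spectrum`` gives mixture weights over the five MAF bins
    (<0.05%, 0.05-0.5%, 0.5-1%, 1-5%, >=5%), lowest bin first; the default
    reproduces the spectrum observed for pharmacogene variants in a deeply
    sequenced European population sample.  ``variant_mafs`` pins named
    variants to exact frequencies (used when planting effects at a known MAF).
    """

    n_persons: int = 5000
    n_variants: int = 100
    maf_spectrum: tuple[float, ...] = (0.552, 0.217, 0.034, 0.072, 0.125)
    n_drugs: int = 5
    prescription_rate: float = 0.25
    base_ade_rate: float = 0.05
    background_dx_rate: float = 0.01
    self_report_rate: float = 0.005
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    variant_mafs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_variants < 1:
            raise ValueError("n_persons and n_variants must be positive")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be positive")
        w = np.asarray(self.maf_spectrum, dtype=float)
        if len(w) != len(MAF_BINS) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("maf_spectrum must be 5 non-negative weights summing to 1")
        for name, p in [("prescription_rate", self.prescription_rate),
                        ("base_ade_rate", self.base_ade_rate),
                        ("background_dx_rate", self.background_dx_rate),
                        ("self_report_rate", self.self_report_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")


@dataclass
class SyntheticCohort:
    """Generated tables plus the truth record of planted effects."""

    genotypes: GenotypeMatrix
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    self_reports: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "genotypes.vcf",
            "prescriptions": out / "prescriptions.tsv",
            "diagnoses": out / "diagnoses.tsv",
            "self_reports": out / "self_reports.tsv",
            "covariates": out / "covariates.tsv",
            "truth": out / "truth.json",
        }
        self.genotypes.to_vcf(paths["vcf"])
        self.prescriptions.to_csv(paths["prescriptions"], sep="\t", index=False)
        self.diagnoses.to_csv(paths["diagnoses"], sep="\t", index=False)
        self.self_reports.to_csv(paths["self_reports"], sep="\t", index=False)
        self.covariates.to_csv(paths["covariates"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _draw_mafs(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-variant MAFs from the binned spectrum (uniform within bin)."""
    bins = rng.choice(len(MAF_BINS), size=spec.n_variants, p=spec.maf_spectrum)
    lo = np.array([b[1] for b in MAF_BINS])
    hi = np.array([min(b[2], 0.5) for b in MAF_BINS])
    mafs = rng.uniform(lo[bins], hi[bins])
    # a floor keeps every variant polymorphic in expectation
    floor = min(1.0 / (4 * spec.n_persons), 0.5)
    return np.clip(mafs, floor, 0.5)


def _covariate_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    persons = [f"P{i:06d}" for i in range(n)]
    return pd.DataFrame({
        "person_id": persons,
        "sex": rng.integers(0, 2, n),
        "age": rng.uniform(18, 90, n).round(1),
        "BMI": rng.normal(26, 4, n).round(2),
        "PC1": rng.normal(0, 1, n).round(4),
        "PC2": rng.normal(0, 1, n).round(4),
        "PC3": rng.normal(0, 1, n).round(4),
        "PC4": rng.normal(0, 1, n).round(4),
        "platform": rng.choice(["WGS", "chip"], n, p=[0.14, 0.86]),
    })


def _covariate_lp(cov: pd.DataFrame) -> np.ndarray:
    return (COV_BETAS["sex"] * cov["sex"].to_numpy()
            + COV_BETAS["age_c"] * (cov["age"].to_numpy() - 54.0)
            + COV_BETAS["bmi_c"] * (cov["BMI"].to_numpy() - 26.0)
            + sum(COV_BETAS[f"PC{k}"] * cov[f"PC{k}"].to_numpy() for k in range(1, 5))
            + COV_BETAS["platform_wgs"] * (cov["platform"] == "WGS").to_numpy())


def _random_dates(n: int, rng: np.random.Generator) -> np.ndarray:
    span = int((EHR_WINDOW[1] - EHR_WINDOW[0]) / np.timedelta64(1, "D"))
    return EHR_WINDOW[0] + rng.integers(0, span + 1, n).astype("timedelta64[D]")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one synthetic cohort from ``spec``.

    Genotypes are in Hardy-Weinberg proportions at their drawn MAFs.  Among
    persons prescribed a drug group, ADE status follows
    ``logit P(ADE) = logit(base_ade_rate) + covariate terms + sum planted
    beta * genotype`` with the sum over effects planted on that group.
    """
    rng = np.random.default_rng(spec.seed)

    # genotypes -----------------------------------------------------------
    variant_ids = [f"v{i:05d}" for i in range(spec.n_variants)]
    mafs = _draw_mafs(spec, rng)
    for vid, m in spec.variant_mafs.items():
        if vid not in variant_ids:
            raise ValueError(f"variant_mafs names unknown variant {vid!r}")
        if not 0 < m <= 0.5:
            raise ValueError(f"pinned MAF for {vid} must be in (0, 0.5]")
        mafs[variant_ids.index(vid)] = m
    dosages = rng.binomial(2, mafs[:, None], size=(spec.n_variants, spec.n_persons))
    bases = ["A", "C", "G", "T"]
    ref_idx = rng.integers(0, 4, spec.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, spec.n_variants)) % 4
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": np.sort(rng.choice(np.arange(1, 50_000_000), spec.n_variants,
                                  replace=False)),
        "id": variant_ids,
        "ref": [bases[i] for i in ref_idx],
        "alt": [bases[i] for i in alt_idx],
    })
    covariates = _covariate_table(spec.n_persons, rng)
    persons = covariates["person_id"].to_numpy()
    genotypes = GenotypeMatrix(list(persons), variants, dosages)

    # prescriptions -------------------------------------------------------
    if spec.n_drugs <= len(ATC4_POOL):
        drug_groups = ATC4_POOL[: spec.n_drugs]
    else:
        extra = [f"X{i:02d}AA" for i in range(spec.n_drugs - len(ATC4_POOL))]
        drug_groups = ATC4_POOL + extra
    for eff in spec.planted_effects:
        if eff.variant_id not in variant_ids:
            raise ValueError(f"planted effect on unknown variant {eff.variant_id!r}")
        if eff.atc4_group not in drug_groups:
            raise ValueError(
                f"planted effect on drug group {eff.atc4_group!r} absent from cohort")

    prescribed = rng.random((spec.n_persons, spec.n_drugs)) < spec.prescription_rate
    rx_rows = []
    for j, grp in enumerate(drug_groups):
        idx = np.flatnonzero(prescribed[:, j])
        n_fill = rng.integers(1, 4, idx.size)  # 1-3 refills each
        rep = np.repeat(idx, n_fill)
        codes = [f"{grp}{k:02d}" for k in rng.integers(1, 10, rep.size)]
        rx_rows.append(pd.DataFrame({
            "person_id": persons[rep], "atc": codes,
            "date": _random_dates(rep.size, rng),
        }))
    prescriptions = pd.concat(rx_rows, ignore_index=True)

    # ADE events among prescribed persons --------------------------------
    codelist = load_ade_codes()
    all_codes = sorted(codelist.codes)
    cov_lp = _covariate_lp(covariates)
    base_lp = np.log(spec.base_ade_rate / (1 - spec.base_ade_rate)) if spec.base_ade_rate > 0 else -np.inf
    dx_rows = []
    effects_by_drug: dict[str, list[PlantedEffect]] = {}
    for eff in spec.planted_effects:
        effects_by_drug.setdefault(eff.atc4_group, []).append(eff)
    for j, grp in enumerate(drug_groups):
        idx = np.flatnonzero(prescribed[:, j])
        lp0 = base_lp + cov_lp[idx]
        lp1 = lp0.copy()
        tagged_group = None
        for eff in effects_by_drug.get(grp, []):
            g = dosages[variant_ids.index(eff.variant_id), idx].astype(float)
            if eff.model == "carrier":
                g = (g >= 1).astype(float)
            lp1 = lp1 + eff.log_odds_ratio * g
            if eff.group is not None:
                tagged_group = eff.group
        u = rng.random(idx.size)
        p0 = 1 / (1 + np.exp(-lp0))
        p1 = 1 / (1 + np.exp(-lp1))
        event = u < p1
        attributable = event & (u >= p0)  # would not have occurred at baseline
        n_ev = int(event.sum())
        if n_ev == 0:
            continue
        if tagged_group is not None:
            grp_codes = sorted(codelist.codes_in_group(tagged_group))
            codes = np.array(rng.choice(all_codes, n_ev), dtype=object)
            codes[attributable[event]] = rng.choice(grp_codes, int(attributable.sum()))
        else:
            codes = rng.choice(all_codes, n_ev)
        dx_rows.append(pd.DataFrame({
            "person_id": persons[idx[event]],
            "icd10": codes,
            "date": _random_dates(n_ev, rng),
            "physician_confirmed": True,
            "source": "ehr",
        }))

    # background diagnoses: ADE-coded but drug-independent, plus chaff ----
    bg = rng.random(spec.n_persons) < spec.background_dx_rate
    if bg.any():
        nbg = int(bg.sum())
        dx_rows.append(pd.DataFrame({
            "person_id": persons[bg],
            "icd10": rng.choice(all_codes, nbg),
            "date": _random_dates(nbg, rng),
            "physician_confirmed": rng.random(nbg) < 0.5,
            "source": "ehr",
        }))
    chaff = rng.random(spec.n_persons) < 0.05
    if chaff.any():
        nc = int(chaff.sum())
        dx_rows.append(pd.DataFrame({
            "person_id": persons[chaff],
            "icd10": rng.choice(BACKGROUND_CODES, nc),
            "date": _random_dates(nc, rng),
            "physician_confirmed": False,
            "source": "ehr",
        }))
    diagnoses = (pd.concat(dx_rows, ignore_index=True) if dx_rows
                 else pd.DataFrame(columns=["person_id", "icd10", "date",
                                            "physician_confirmed", "source"]))
    diagnoses = diagnoses.sort_values(["person_id", "date", "icd10"],
                                      kind="stable").reset_index(drop=True)

    sr = rng.random(spec.n_persons) < spec.self_report_rate
    self_reports = pd.DataFrame({
        "person_id": persons[sr],
        "reaction": "self-reported adverse drug reaction",
        "date": _random_dates(int(sr.sum()), rng),
    })

    truth = {
        "seed": spec.seed,
        "spec": {k: v for k, v in dataclasses.asdict(spec).items()
                 if k not in ("planted_effects",)},
        "drug_groups": drug_groups,
        "drawn_mafs": dict(zip(variant_ids, np.round(mafs, 6))),
        "planted_effects": [dataclasses.asdict(e) for e in spec.planted_effects],
    }
    return SyntheticCohort(genotypes, prescriptions, diagnoses, self_reports,
                           covariates, truth)


def ld_bounds(maf_a: float, maf_b: float) -> float:
    """Maximum attainable genotype r-squared for two alleles at given MAFs."""
    pa, pb = maf_a, maf_b
    d_max = min(pa, pb) - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    return d_max**2 / denom


def generate_ld_pair(
    n: int,
    maf_a: float,
    maf_b: float,
    r2_target: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors whose genotype correlation-squared targets ``r2_target``.

    Haplotypes are drawn from the two-locus distribution with
    ``D = r * sqrt(pa qa pb qb)`` and paired at random (Hardy-Weinberg), so
    the expected genotype r-squared equals the haplotype r-squared.
    """
    if not 0.0 <= r2_target <= 1.0:
        raise ValueError("r2_target must be in [0, 1]")
    for m in (maf_a, maf_b):
        if not 0 < m <= 0.5:
            raise ValueError("MAFs must be in (0, 0.5]")
    r2_max = ld_bounds(maf_a, maf_b)
    if r2_target > r2_max + 1e-12:
        raise ValueError(
            f"r2_target {r2_target} infeasible for MAFs {maf_a}/{maf_b}; "
            f"maximum attainable r2 is {r2_max:.4f}")
    rng = np.random.default_rng(seed)
    pa, pb = maf_a, maf_b
    d = np.sqrt(r2_target * pa * (1 - pa) * pb * (1 - pb))
    p11 = pa * pb + d
    probs = np.array([p11, pa - p11, pb - p11, 1 - pa - pb + p11])
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    # haplotype classes: (1,1), (1,0), (0,1), (0,0)
    hap = rng.choice(4, size=(n, 2), p=probs)
    a = (np.isin(hap, (0, 1))).sum(axis=1).astype(np.int8)
    b = (np.isin(hap, (0, 2))).sum(axis=1).astype(np.int8)
    return a, b
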