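"""Variant-drug-ADE association statistics.

Two estimators are exposed: the crude 2x2 odds ratio with Woolf's
log-method confidence interval, and a covariate-adjusted logistic model
(maximum likelihood via Newton/IRLS, Wald tests) for the genotype term under
additive (0/1/2 dosage) or carrier (0/1) coding.  On top of these sit the
two scans the study design calls for -- the candidate scan over curated
gene-drug pairs with its inclusion filters, and the genome-wide scan over
common variants per drug cohort -- plus conditional adjustment for known
variants and the drug-independent check used to rule out confounding by the
underlying disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohorts import DrugCohort, GeneDrugMap
from .phenotype import PhenotypeResult
from .variants import MISSING, GenotypeMatrix

Z975 = 1.959963984540054  # Phi^-1(0.975)

#: Covariates used in discovery-stage fits.
DISCOVERY_COVARIATES = ("BMI", "sex", "age", "PC1", "PC2", "PC3", "PC4", "platform")
#: Reduced covariate set used in the replication stage.
REPLICATION_COVARIATES = ("age", "BMI", "sex")


@dataclass(frozen=True)
class TwoByTwo:
    """ADE x carrier contingency counts.

    a = ADE & carrier, b = ADE & non-carrier,
    c = no-ADE & carrier, d = no-ADE & non-carrier.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_vectors(cls, y: np.ndarray, carrier: np.ndarray) -> "TwoByTwo":
        y = np.asarray(y).astype(bool)
        carrier = np.asarray(carrier).astype(bool)
        return cls(int((y & carrier).sum()), int((y & ~carrier).sum()),
                   int((~y & carrier).sum()), int((~y & ~carrier).sum()))


@dataclass
class OddsRatio:
    or_: float
    ci95: tuple[float, float]
    p: float
    status: str = "ok"


def crude_or(t: TwoByTwo, haldane: bool = False) -> OddsRatio:
    """Crude odds ratio (a*d)/(b*c) with Woolf's log-method 95% CI.

    A zero cell yields status ``zero_cell`` unless the Haldane-Anscombe
    correction (+0.5 to every cell) is explicitly enabled.  The p-value is
    the two-sided Wald test on the log odds ratio.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not haldane:
            return OddsRatio(np.nan, (np.nan, np.nan), np.nan, "zero_cell")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - Z975 * se), np.exp(np.log(or_) + Z975 * se)
    z = np.log(or_) / se
    p = 2 * stats.norm.sf(abs(z))
    return OddsRatio(or_, (lo, hi), p)


@dataclass
class AssociationResult:
    """One variant/allele x drug (or diagnostic-group) association."""

    variant_or_allele: str
    drug_or_group: str
    n: int = 0
    two_by_two: TwoByTwo | None = None
    beta: float = np.nan
    se: float = np.nan
    or_: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    p: float = np.nan
    conditional_p: float | None = None
    status: str = "ok"

    def as_dict(self) -> dict:
        t = self.two_by_two
        return {
            "variant": self.variant_or_allele, "cohort": self.drug_or_group,
            "n": self.n,
            "a": t.a if t else np.nan, "b": t.b if t else np.nan,
            "c": t.c if t else np.nan, "d": t.d if t else np.nan,
            "beta": self.beta, "se": self.se, "OR": self.or_,
            "lo": self.ci95[0], "hi": self.ci95[1], "p": self.p,
            "conditional_p": self.conditional_p, "status": self.status,
        }


def results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def design_matrix(
    covariates: pd.DataFrame | None,
    persons: Sequence[str],
    columns: Sequence[str] = DISCOVERY_COVARIATES,
) -> np.ndarray | None:
    """Numeric covariate block aligned to ``persons`` (no intercept).

    ``sex`` is passed through as 0/1; ``platform`` becomes a 0/1 indicator
    for WGS.  Returns None when ``covariates`` is None.
    """
    if covariates is None:
        return None
    cov = covariates.set_index("person_id").loc[list(persons)]
    cols = []
    for name in columns:
        if name == "platform":
            cols.append((cov["platform"] == "WGS").to_numpy(float))
        else:
            cols.append(cov[name].to_numpy(float))
    return np.column_stack(cols)


def fit_logistic(
    y: np.ndarray,
    g: np.ndarray,
    X: np.ndarray | None = None,
    coding: str = "additive",
    variant: str = "?",
    cohort: str = "?",
    extra: np.ndarray | None = None,
) -> AssociationResult:
    """Adjusted logistic association of ADE status with genotype.

    ``g`` is a dosage vector (0/1/2, -1 or NaN = missing); persons with a
    missing genotype are dropped from the fit.  ``coding='carrier'``
    collapses dosage to a 0/1 indicator.  ``extra`` appends further
    adjustment columns (used for conditional analysis).  Wald beta/SE/p are
    reported for the genotype term; a diverging genotype coefficient
    (|beta| > 15) or a failed Newton fit is flagged ``separated`` /
    ``nonconverged``.
    """
    if coding not in ("additive", "carrier"):
        raise ValueError(f"unknown coding {coding!r}")
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~np.isnan(g) & (g != MISSING)
    y, g = y[keep], g[keep]
    X = X[keep] if X is not None else None
    extra = extra[keep] if extra is not None else None
    if coding == "carrier":
        g = (g >= 1).astype(float)
    carrier = g >= 1
    tab = TwoByTwo.from_vectors(y, carrier) if len(y) else None

    res = AssociationResult(variant, cohort, n=len(y), two_by_two=tab)
    if y.sum() < 2 or (1 - y).sum() < 2:
        res.status = "skipped:lt_2_cases_or_controls"
        return res
    if np.ptp(g) == 0:
        res.status = "skipped:no_carriers"
        return res
    blocks = [np.ones(len(y)), g]
    if X is not None:
        blocks.append(X)
    if extra is not None:
        blocks.append(np.atleast_2d(extra.T).T)
    design = np.column_stack(blocks)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        res.status = "collinear"
        return res
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-10, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning):
            res.status = "separated"
            return res
        except Exception:
            res.status = "nonconverged"
            return res
    beta, se = fit.params[1], fit.bse[1]
    if not np.isfinite(beta) or abs(beta) > 15 or not np.isfinite(se):
        res.status = "separated"
        return res
    if not fit.mle_retvals.get("converged", True):
        res.status = "nonconverged"
        return res
    res.beta, res.se = float(beta), float(se)
    res.or_ = float(np.exp(beta))
    res.ci95 = (float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se)))
    res.p = float(2 * stats.norm.sf(abs(beta / se)))
    return res


def conditional_test(
    y: np.ndarray,
    g_index: np.ndarray,
    g_known: Sequence[np.ndarray],
    X: np.ndarray | None = None,
    coding: str = "additive",
) -> tuple[float, str]:
    """Wald p of the index variant after adjusting for known variants.

    Returns ``(p, status)``; a conditioning variant perfectly collinear with
    the index (r^2 = 1) yields status ``collinear``.
    """
    if not g_known:
        raise ValueError("need at least one conditioning variant")
    gi = np.asarray(g_index, dtype=float)
    cond = np.column_stack([np.asarray(gk, dtype=float) for gk in g_known])
    for k in range(cond.shape[1]):
        gk = cond[:, k]
        if np.ptp(gi) > 0 and np.ptp(gk) > 0:
            r = np.corrcoef(gi, gk)[0, 1]
            if abs(r) > 1 - 1e-10:
                return np.nan, "collinear"
    res = fit_logistic(y, gi, X, coding=coding, extra=cond)
    return res.p, res.status


@dataclass
class CandidateScan:
    """Results and filter accounting of the candidate-variant scan."""

    results: list[AssociationResult] = field(default_factory=list)
    tally: dict[str, int] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return results_frame(self.results)

    @property
    def significant(self) -> list[AssociationResult]:
        return [r for r in self.results if r.status == "ok" and r.p < 0.05]


def candidate_scan(
    genotypes: GenotypeMatrix,
    variant_genes: dict[str, str],
    gene_drug_map: GeneDrugMap,
    cohorts: list[DrugCohort],
    phenotypes: PhenotypeResult,
    covariates: pd.DataFrame | None,
    min_participants: int = 500,
    coding: str = "additive",
    alpha: float = 0.05,
) -> CandidateScan:
    """Test every candidate variant against every drug linked to its gene.

    Linkage is at gene level: a variant is paired with each ATC-4 group
    associated with *any* variant of its gene in the map.  Pairs are skipped
    (with the reason tallied) when the variant is absent from the genotype
    matrix, the drug group has no cohort, fewer than ``min_participants``
    prescribed persons are available, no prescribed person carries the
    variant, or no prescribed person has an ADE.
    """
    by_group = {c.atc4_group: c for c in cohorts}
    ade = phenotypes.cases
    scan = CandidateScan()

    def tally(reason: str) -> None:
        scan.tally[reason] = scan.tally.get(reason, 0) + 1

    for vid in sorted(variant_genes):
        gene = variant_genes[vid]
        for group in sorted(gene_drug_map.drugs_for_gene(gene)):
            res = AssociationResult(vid, group)
            if vid not in genotypes:
                res.status = "skipped:variant_absent"
            elif group not in by_group:
                res.status = "skipped:no_prescriptions"
            else:
                cohort = by_group[group]
                persons = sorted(cohort.persons)
                dosage = pd.Series(genotypes.row(vid), index=genotypes.samples)
                g = dosage.loc[persons].to_numpy(float)
                called = g != MISSING
                if int(called.sum()) < min_participants:
                    res.status = f"skipped:lt_{min_participants}"
                elif not (g[called] >= 1).any():
                    res.status = "skipped:no_carriers"
                elif not (cohort.cases & set(persons)):
                    res.status = "skipped:no_ade"
                else:
                    y = np.array([p in ade for p in persons], dtype=float)
                    X = design_matrix(covariates, persons)
                    res = fit_logistic(y, g, X, coding=coding,
                                       variant=vid, cohort=group)
            if res.status != "ok":
                tally(res.status)
            else:
                tally("ok")
            scan.results.append(res)
    return scan


def genome_scan(
    genotypes: GenotypeMatrix,
    cohorts: list[DrugCohort],
    covariates: pd.DataFrame | None,
    maf_min: float = 0.01,
    p_suggestive: float = 1e-6,
) -> pd.DataFrame:
    """Additive genome-wide scan of common variants within each drug cohort.

    Tests every variant with cohort-wide MAF >= ``maf_min`` for ADE-status
    association among the cohort's prescribed persons; the returned frame
    carries a ``suggestive`` flag for p < ``p_suggestive``.  Cohorts lacking
    both cases and controls are skipped with a warning.
    """
    mafs = genotypes.maf()
    eligible = np.flatnonzero(mafs >= maf_min)
    frames = []
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    for cohort in cohorts:
        persons = sorted(cohort.persons)
        if not cohort.cases or not cohort.controls:
            warnings.warn(f"cohort {cohort.atc4_group} lacks cases or controls; skipped")
            continue
        cols = np.array([sample_index[p] for p in persons])
        y = np.array([p in cohort.cases for p in persons], dtype=float)
        X = design_matrix(covariates, persons)
        rows = []
        for i in eligible:
            vid = genotypes.variants["id"].iloc[i]
            res = fit_logistic(y, genotypes.dosages[i, cols], X,
                               coding="additive", variant=vid,
                               cohort=cohort.atc4_group)
            rows.append(res.as_dict())
        frame = pd.DataFrame(rows)
        frame["suggestive"] = (frame["status"] == "ok") & (frame["p"] < p_suggestive)
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def drug_independent_test(
    genotypes: GenotypeMatrix,
    variant_id: str,
    group: str,
    group_members: dict[str, set[str]],
    covariates: pd.DataFrame | None,
    coding: str = "additive",
) -> AssociationResult:
    """Association of a variant with one diagnostic group, ignoring drug intake.

    Cases are persons with any ADE in ``group``; controls are persons with no
    ADE at all (persons with ADEs only in other groups are excluded).
    ``group_members`` maps each person to their set of diagnostic groups
    (empty set = no ADE).
    """
    cases = sorted(p for p, gs in group_members.items() if group in gs)
    controls = sorted(p for p, gs in group_members.items() if not gs)
    if not cases:
        raise ValueError(f"diagnostic group {group!r} has no cases")
    persons = cases + controls
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    dosage = pd.Series(genotypes.row(variant_id), index=genotypes.samples)
    g = dosage.loc[persons].to_numpy(float)
    X = design_matrix(covariates, persons)
    return fit_logistic(y, g, X, coding=coding, variant=variant_id, cohort=group)
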