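"""Diagnostic-group refinement, Bonferroni gating and sum-of-z meta-analysis.

Genome-wide hits are refined by refitting within their drug cohort against
each of the 12 diagnostic groups (cases = persons with ADEs in that group,
controls = persons with no ADE at all) and keeping the group with the lowest
p-value.  Replication p-values are gated by Bonferroni correction, and
discovery and replication evidence is combined with the unweighted sum-of-z
(Stouffer) method: z_i = Phi^-1(1 - p_i) signed by effect direction,
z = sum(z_i) / sqrt(k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationResult, design_matrix, fit_logistic
from .cohorts import DrugCohort
from .variants import GenotypeMatrix


@dataclass
class RefinedHit:
    """A suggestive hit re-tested per diagnostic group."""

    variant: str
    cohort: str
    best_group: str
    p_discovery: float
    direction: int  # sign of beta in the best-group fit
    per_group: dict[str, AssociationResult]


@dataclass
class MetaResult:
    variant: str
    z_per_cohort: list[float]
    z_combined: float
    p_one_sided: float
    p_two_sided: float

    @property
    def k(self) -> int:
        return len(self.z_per_cohort)


def refine_by_group(
    variant_id: str,
    cohort: DrugCohort,
    group_members: dict[str, set[str]],
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    groups: Sequence[str] | None = None,
    coding: str = "additive",
) -> RefinedHit:
    """Find the diagnostic group minimizing the association p within a cohort.

    For each group, cases are cohort persons with an ADE in that group and
    controls are cohort persons with no ADE; persons with ADEs only in other
    groups are excluded from that group's fit.  Groups with fewer than two
    cases are skipped.  Ties are broken by larger case count, then
    lexicographic group id.
    """
    if groups is None:
        groups = sorted({g for gs in group_members.values() for g in gs})
    dosage = pd.Series(genotypes.row(variant_id), index=genotypes.samples)
    per_group: dict[str, AssociationResult] = {}
    candidates = []  # (p, -n_cases, group)
    cohort_persons = set(cohort.persons)
    controls = sorted(p for p in cohort_persons if not group_members.get(p, set()))
    for group in groups:
        cases = sorted(p for p in cohort_persons if group in group_members.get(p, set()))
        if len(cases) < 2:
            continue
        persons = cases + controls
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
        X = design_matrix(covariates, persons)
        res = fit_logistic(y, dosage.loc[persons].to_numpy(float), X,
                           coding=coding, variant=variant_id, cohort=group)
        per_group[group] = res
        if res.status == "ok":
            candidates.append((res.p, -len(cases), group))
    if not candidates:
        raise ValueError(f"no diagnostic group with a valid fit for {variant_id}")
    candidates.sort()
    _, _, best = candidates[0]
    best_res = per_group[best]
    return RefinedHit(variant_id, cohort.atc4_group, best,
                      best_res.p, int(np.sign(best_res.beta)) or 1, per_group)


def bonferroni_gate(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Pass flags at the Bonferroni-corrected threshold alpha / m."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    m = len(p_values)
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return [p < alpha / m for p in p_values]


def one_sided(p_two_sided: float, direction: int) -> tuple[float, int]:
    """Directional one-sided p from a two-sided p and the effect sign."""
    if not 0 < p_two_sided < 1:
        raise ValueError(f"two-sided p must be in (0, 1), got {p_two_sided}")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    return p_two_sided / 2, direction


def sum_of_z(
    p_values: Sequence[float],
    directions: Sequence[int] | None = None,
    variant: str = "?",
    two_sided_inputs: bool = False,
) -> MetaResult:
    """Unweighted Stouffer combination of per-cohort p-values.

    By default ``p_values`` are one-sided; with ``two_sided_inputs`` they are
    two-sided and halved using ``directions``.  Each study contributes
    ``z_i = Phi^-1(1 - p_i) * sign_i``; the combined statistic is
    ``sum(z_i)/sqrt(k)``, reported with both one- and two-sided p-values.
    """
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    if directions is None:
        directions = [1] * len(p_values)
    if len(directions) != len(p_values):
        raise ValueError("p_values and directions differ in length")
    zs = []
    for p, s in zip(p_values, directions):
        if s not in (-1, 1):
            raise ValueError("directions must be +1 or -1")
        if two_sided_inputs:
            p, s = one_sided(p, s)
        if not 0 < p < 1:
            raise ValueError(f"p-values must be in (0, 1), got {p}")
        zs.append(float(stats.norm.isf(p)) * s)
    z = sum(zs) / np.sqrt(len(zs))
    return MetaResult(variant, zs, float(z),
                      float(stats.norm.sf(z)),
                      float(2 * stats.norm.sf(abs(z))))


def meta_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant": r.variant, "k": r.k, "z": r.z_combined,
        "p_one": r.p_one_sided, "p_two": r.p_two_sided,
    } for r in results])
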