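"""Drug-exposure cohorts and gene-drug-ADE linkage.

Prescriptions are grouped at ATC level 4 (the five-character prefix of the
WHO Anatomical Therapeutic Chemical code, e.g. ``M01AC`` = oxicams).  A
cohort is the set of distinct persons with any prescription in one such
group, split into cases (ADE phenotype) and controls.  A PharmGKB-style
gene-drug map links variants to the drugs whose cohorts they are tested in;
linkage is at gene level, so a variant is tested against every drug
associated with any variant of its gene.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import PhenotypeResult
from .variants import MISSING, GenotypeMatrix

ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")
PHARMGKB_LEVELS = {"1A", "1B", "2A", "2B", "3", "4"}
HIGH_CONFIDENCE_LEVELS = {"1A", "1B", "2A", "2B"}


def atc4(code: str) -> str:
    """ATC level-4 prefix (first 5 characters); rejects malformed codes."""
    code = str(code).strip().upper()
    if not ATC_RE.match(code):
        raise ValueError(f"malformed ATC code {code!r}")
    return code[:5]


@dataclass
class DrugCohort:
    """Persons prescribed any drug in one ATC-4 group, labelled case/control."""

    atc4_group: str
    persons: frozenset[str]
    cases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cases <= self.persons:
            raise ValueError("cases must be a subset of cohort persons")

    @property
    def controls(self) -> frozenset[str]:
        return self.persons - self.cases

    @property
    def n_prescribed(self) -> int:
        return len(self.persons)


@dataclass
class GeneDrugMap:
    """Rows of (gene, variant id, drug ATC, PharmGKB level of evidence)."""

    table: pd.DataFrame  # columns gene, variant_id, atc, level

    def __post_init__(self) -> None:
        required = {"gene", "variant_id", "atc", "level"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"gene-drug map needs columns {sorted(required)}")
        bad = set(self.table["level"].astype(str)) - PHARMGKB_LEVELS
        if bad:
            raise ValueError(f"levels outside PharmGKB vocabulary: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneDrugMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def high_confidence(self) -> "GeneDrugMap":
        return GeneDrugMap(
            self.table[self.table["level"].isin(HIGH_CONFIDENCE_LEVELS)].reset_index(drop=True))

    def drugs_for_gene(self, gene: str) -> set[str]:
        """ATC-4 groups of every drug linked to any variant in ``gene``."""
        rows = self.table[self.table["gene"] == gene]
        return {atc4(a) for a in rows["atc"]}

    def gene_of(self, variant_id: str) -> str | None:
        rows = self.table[self.table["variant_id"] == variant_id]
        return None if rows.empty else str(rows["gene"].iloc[0])


def build_cohorts(
    prescriptions: pd.DataFrame,
    phenotypes: PhenotypeResult,
    min_prescribed: int = 1000,
) -> list[DrugCohort]:
    """One cohort per ATC-4 group with at least ``min_prescribed`` persons.

    Persons are counted once per group regardless of refills; persons with an
    ADE phenotype are the cases.  Returns cohorts sorted by group code.
    """
    if prescriptions.empty:
        return []
    rx = prescriptions[["person_id", "atc"]].copy()
    rx["group"] = [atc4(a) for a in rx["atc"]]
    cases = phenotypes.cases
    cohorts = []
    for group, sub in rx.groupby("group"):
        persons = frozenset(sub["person_id"].astype(str))
        if len(persons) < min_prescribed:
            continue
        cohorts.append(DrugCohort(group, persons, frozenset(persons & cases)))
    return sorted(cohorts, key=lambda c: c.atc4_group)


def assign_allele_carriers(
    genotypes: GenotypeMatrix, allele_def: list[str]
) -> pd.Series:
    """Carrier flag per person for a (possibly multi-SNV) allele definition.

    A person carries the allele iff any defining variant has dosage >= 1;
    a person missing at every defining site gets a missing flag (NA).
    """
    if not allele_def:
        raise ValueError("allele definition must name at least one variant")
    rows = np.vstack([genotypes.row(v) for v in allele_def])
    any_carrier = (rows >= 1).any(axis=0)
    all_missing = (rows == MISSING).all(axis=0)
    flags = pd.Series(any_carrier.astype(float), index=genotypes.samples, name="carrier")
    flags[all_missing] = np.nan
    return flags


def triad_overlap(
    carriers: dict[str, pd.Series],
    cohorts: list[DrugCohort],
    phenotypes: PhenotypeResult,
    gene_drug_map: GeneDrugMap,
    min_n: int = 10,
) -> pd.DataFrame:
    """Gene -> drug -> ADE co-occurrence counts (the Sankey flow table).

    For every (gene, ATC-4 drug group) pair in the map with an available
    cohort, counts persons with (i) a qualifying variant in the gene,
    (ii) a prescription in the group, (iii) an ADE, and the three-way
    intersection.  Rows below ``min_n`` in the three-way count are kept but
    flagged ``suppressed`` for plot export.
    """
    by_group = {c.atc4_group: c for c in cohorts}
    ade = phenotypes.cases
    rows = []
    for gene in sorted(set(gene_drug_map.table["gene"])):
        flags = carriers.get(gene)
        if flags is None:
            continue
        carrier_set = set(flags.index[flags == 1])
        for group in sorted(gene_drug_map.drugs_for_gene(gene)):
            cohort = by_group.get(group)
            if cohort is None:
                continue
            prescribed = set(cohort.persons)
            three = carrier_set & prescribed & ade
            rows.append({
                "gene": gene, "atc4_group": group,
                "n_carrier": len(carrier_set),
                "n_prescribed": len(prescribed),
                "n_ade": len(ade),
                "n_carrier_prescribed": len(carrier_set & prescribed),
                "n_all_three": len(three),
                "suppressed": len(three) < min_n,
            })
    return pd.DataFrame(rows, columns=[
        "gene", "atc4_group", "n_carrier", "n_prescribed", "n_ade",
        "n_carrier_prescribed", "n_all_three", "suppressed"])


def sankey_export(flows: pd.DataFrame, path: str | Path) -> None:
    """Write a nodes/links JSON of the unsuppressed flows for Sankey plotting."""
    shown = flows[~flows["suppressed"]]
    genes = sorted(set(shown["gene"]))
    drugs = sorted(set(shown["atc4_group"]))
    nodes = [{"name": g} for g in genes] + [{"name": d} for d in drugs] + [{"name": "ADE"}]
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: len(genes) + i for i, d in enumerate(drugs)}
    ade_node = len(genes) + len(drugs)
    links = []
    for row in shown.itertuples(index=False):
        links.append({"source": gi[row.gene], "target": di[row.atc4_group],
                      "value": int(row.n_carrier_prescribed)})
        links.append({"source": di[row.atc4_group], "target": ade_node,
                      "value": int(row.n_all_three)})
    with open(path, "w") as fh:
        json.dump({"nodes": nodes, "links": links}, fh, indent=2)
        fh.write("\n")
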