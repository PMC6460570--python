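"""Pipeline configuration, input validation and end-to-end orchestration.

The full analysis runs as simulate -> phenotype -> link -> candidate scan ->
genome-wide scan -> replicate/meta, writing each stage's tables under one
run directory together with a provenance manifest (package version, seed,
config echo, SHA-256 of every written file).  Reruns with the same
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import candidate_scan, genome_scan, results_frame
from .cohorts import ATC_RE, GeneDrugMap, build_cohorts
from .meta import bonferroni_gate, meta_frame, refine_by_group, sum_of_z
from .phenotype import ICD10_RE, extract_ades, group_ades, load_ade_codes
from .simulate import CohortSpec, PlantedEffect, generate_cohort
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and switches for one pipeline run.

    Defaults mirror the study design: drug cohorts need >= 1000 prescribed
    persons for the genome-wide scan and >= 500 interrogable persons for a
    candidate test; genome-wide tests run on variants with MAF >= 1% and
    hits pass to replication below the suggestive 1e-6 level; replication is
    gated by Bonferroni-corrected alpha = 0.05.
    """

    min_prescribed: int = 1000
    min_participants: int = 500
    maf_min: float = 0.01
    p_suggestive: float = 1e-6
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "pharmscan_run"
    cohort: CohortSpec | None = None
    replication_cohort: CohortSpec | None = None
    ade_codes_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_prescribed", "min_participants", "maf_min",
                     "p_suggestive", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("cohort", "replication_cohort"):
            if key in raw and raw[key] is not None:
                spec = dict(raw[key])
                effects = [PlantedEffect(**e) for e in spec.pop("planted_effects", [])]
                raw[key] = CohortSpec(planted_effects=effects, **spec)
        return cls(**raw)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    vcf: str | Path | None = None,
    prescriptions: str | Path | None = None,
    diagnoses: str | Path | None = None,
    covariates: str | Path | None = None,
) -> ValidationReport:
    """Structural checks on the pipeline's input files (report-only)."""
    rep = ValidationReport()
    if vcf is not None:
        p = Path(vcf)
        if not p.exists():
            rep.errors.append(f"VCF not found: {p}")
        else:
            head = p.read_text().splitlines()
            if not head or not head[0].startswith("##fileformat=VCF"):
                rep.errors.append(f"{p}: missing ##fileformat=VCF header")
            body = [ln for ln in head if ln and not ln.startswith("#")]
            if body:
                fields = body[0].split("\t")
                if len(fields) < 10 or "GT" not in fields[8].split(":"):
                    rep.errors.append(f"{p}: records lack a GT FORMAT field")
    if prescriptions is not None:
        rx = pd.read_csv(prescriptions, sep="\t", dtype=str)
        missing = {"person_id", "atc", "date"} - set(rx.columns)
        if missing:
            rep.errors.append(f"prescriptions: missing columns {sorted(missing)}")
        else:
            bad = [a for a in rx["atc"].unique() if not ATC_RE.match(str(a))]
            if bad:
                rep.errors.append(
                    f"prescriptions: {len(bad)} ATC codes violate the ATC grammar "
                    f"(e.g. {bad[:3]})")
    if diagnoses is not None:
        dx = pd.read_csv(diagnoses, sep="\t", dtype=str)
        missing = {"person_id", "icd10"} - set(dx.columns)
        if missing:
            rep.errors.append(f"diagnoses: missing columns {sorted(missing)}")
        else:
            bad = [c for c in dx["icd10"].unique() if not ICD10_RE.match(str(c))]
            if bad:
                rep.warnings.append(
                    f"diagnoses: {len(bad)} ICD10 codes malformed (e.g. {bad[:3]}); "
                    "these records will be skipped")
    if covariates is not None:
        cov = pd.read_csv(covariates, sep="\t")
        needed = {"person_id", "sex", "age", "BMI", "PC1", "PC2", "PC3", "PC4",
                  "platform"}
        missing = needed - set(cov.columns)
        if missing:
            rep.errors.append(f"covariates: missing columns {sorted(missing)}")
        elif cov["person_id"].duplicated().any():
            rep.errors.append("covariates: duplicate person ids")
    return rep


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic-cohort pipeline; returns the run directory.

    Stage order: simulate, phenotype, link, candidate scan, genome-wide scan,
    replicate.  Any stage failure aborts with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stages: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - rethrown with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stages.append(name)
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        spec = config.cohort or CohortSpec(seed=config.seed)
        spec = dataclasses.replace(spec, seed=config.seed)
        cohort = generate_cohort(spec)
        written.update(cohort.write(out / "simulate"))
        state["cohort"] = cohort
        state["spec"] = spec

    @stage("phenotype")
    def _phenotype():
        codelist = load_ade_codes(config.ade_codes_path)
        c = state["cohort"]
        phen = extract_ades(c.diagnoses, c.self_reports, codelist,
                            persons=list(c.covariates["person_id"]))
        phen.frame().to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        written["phenotypes"] = out / "phenotypes.tsv"
        state["codelist"] = codelist
        state["phenotypes"] = phen
        state["groups"] = group_ades(phen, codelist)

    @stage("link")
    def _link():
        c = state["cohort"]
        cohorts = build_cohorts(c.prescriptions, state["phenotypes"],
                                min_prescribed=config.min_prescribed)
        state["cohorts"] = cohorts
        frame = pd.DataFrame([{
            "atc4_group": co.atc4_group, "n_prescribed": co.n_prescribed,
            "n_cases": len(co.cases), "n_controls": len(co.controls),
        } for co in cohorts])
        frame.to_csv(out / "cohorts.tsv", sep="\t", index=False)
        written["cohorts"] = out / "cohorts.tsv"

    @stage("candidate_scan")
    def _candidate():
        c = state["cohort"]
        # synthetic gene-drug map: planted (variant, drug) pairs plus the
        # first few variants mapped to each drug group as background
        rows = []
        for eff in state["spec"].planted_effects:
            rows.append({"gene": f"GENE_{eff.variant_id}", "variant_id": eff.variant_id,
                         "atc": eff.atc4_group + "01", "level": "1A"})
        vids = list(c.genotypes.variants["id"][:10])
        for i, vid in enumerate(vids):
            grp = state["cohorts"][i % max(1, len(state["cohorts"]))].atc4_group \
                if state["cohorts"] else "M01AC"
            rows.append({"gene": f"GENE_{vid}", "variant_id": vid,
                         "atc": grp + "01", "level": "2A"})
        gdmap = GeneDrugMap(pd.DataFrame(rows).drop_duplicates())
        variant_genes = {r["variant_id"]: r["gene"] for r in rows}
        scan = candidate_scan(c.genotypes, variant_genes, gdmap, state["cohorts"],
                              state["phenotypes"], c.covariates,
                              min_participants=config.min_participants)
        scan.frame().to_csv(out / "candidate_scan.tsv", sep="\t", index=False)
        written["candidate_scan"] = out / "candidate_scan.tsv"
        with open(out / "candidate_tally.json", "w") as fh:
            json.dump(scan.tally, fh, indent=2, sort_keys=True)
        written["candidate_tally"] = out / "candidate_tally.json"
        state["candidate"] = scan

    @stage("genome_scan")
    def _gwas():
        c = state["cohort"]
        frame = genome_scan(c.genotypes, state["cohorts"], c.covariates,
                            maf_min=config.maf_min,
                            p_suggestive=config.p_suggestive)
        frame.to_csv(out / "genome_scan.tsv", sep="\t", index=False)
        written["genome_scan"] = out / "genome_scan.tsv"
        state["gwas"] = frame

    @stage("replicate")
    def _replicate():
        gwas = state["gwas"]
        hits = gwas[gwas.get("suggestive", False) == True] if len(gwas) else gwas  # noqa: E712
        c = state["cohort"]
        by_group = {co.atc4_group: co for co in state["cohorts"]}
        rep_spec = config.replication_cohort
        metas, refined_rows = [], []
        if len(hits) and rep_spec is not None:
            rep_cohort = generate_cohort(
                dataclasses.replace(rep_spec, seed=config.seed + 1))
            rep_codelist = state["codelist"]
            rep_phen = extract_ades(rep_cohort.diagnoses, rep_cohort.self_reports,
                                    rep_codelist,
                                    persons=list(rep_cohort.covariates["person_id"]))
            rep_groups = group_ades(rep_phen, rep_codelist)
            rep_cohorts = {co.atc4_group: co for co in build_cohorts(
                rep_cohort.prescriptions, rep_phen, min_prescribed=1)}
            disc_groups = state["groups"]
            for row in hits.itertuples(index=False):
                cohort = by_group.get(row.cohort)
                if cohort is None:
                    continue
                refined = refine_by_group(row.variant, cohort, disc_groups,
                                          c.genotypes, c.covariates)
                refined_rows.append({
                    "variant": refined.variant, "cohort": refined.cohort,
                    "best_group": refined.best_group,
                    "p_discovery": refined.p_discovery,
                    "direction": refined.direction,
                })
                rep_co = rep_cohorts.get(row.cohort)
                if rep_co is None or row.variant not in rep_cohort.genotypes:
                    continue
                rep_refined = refine_by_group(
                    row.variant, rep_co, rep_groups, rep_cohort.genotypes,
                    rep_cohort.covariates,
                    groups=[refined.best_group])
                metas.append(sum_of_z(
                    [refined.p_discovery, rep_refined.p_discovery],
                    [refined.direction, rep_refined.direction],
                    variant=row.variant, two_sided_inputs=True))
        pd.DataFrame(refined_rows).to_csv(out / "refined_hits.tsv", sep="\t",
                                          index=False)
        written["refined_hits"] = out / "refined_hits.tsv"
        mf = meta_frame(metas)
        if len(metas):
            mf["bonferroni_pass"] = bonferroni_gate(
                list(mf["p_two"]), alpha=config.alpha)
        mf.to_csv(out / "meta.tsv", sep="\t", index=False)
        written["meta"] = out / "meta.tsv"

    manifest = {
        "package": "pharmscan",
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if not isinstance(v, dict)},
        "outputs": {name: {"path": str(p.relative_to(out)),
                           "sha256": sha256_file(p)}
                    for name, p in sorted(written.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out
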