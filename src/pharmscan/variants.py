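"""Genotype containers and per-variant frequency statistics.

The central in-memory object is :class:`GenotypeMatrix`, a person x variant
dosage store read from (or written to) diploid VCF 4.2.  Dosages are coded
0/1/2 copies of the ALT allele with -1 for missing calls.  Frequency
statistics follow the usual population-genetics conventions: the allele
count ``AC`` counts copies of the *minor* allele among non-missing calls and
``MAF = AC / (2 * n_nonmissing)``, so ``MAF <= 0.5`` always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Minor-allele-frequency bins used for variant spectra (half-open,
#: lower-inclusive; the top bin is closed at 0.5).
MAF_BINS: list[tuple[str, float, float]] = [
    ("MAF<0.05%", 0.0, 0.0005),
    ("0.05%<=MAF<0.5%", 0.0005, 0.005),
    ("0.5%<=MAF<1%", 0.005, 0.01),
    ("1%<=MAF<5%", 0.01, 0.05),
    ("MAF>=5%", 0.05, 0.5000001),
]


def maf_bin(maf: float) -> str:
    """Assign a MAF to its spectrum bin (lower bound inclusive)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    for label, lo, hi in MAF_BINS:
        if lo <= maf < hi:
            return label
    return MAF_BINS[-1][0]


class VariantStats(NamedTuple):
    ac: int
    maf: float
    call_rate: float
    bin: str
    ac_label: str | None  # "AC=1" / "AC=2" for singletons and doubletons


@dataclass
class VariantRecord:
    """A single bi-allelic variant with per-person dosages."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str = "."
    ancestral_allele: str | None = None
    dosages: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_stats(dosages: np.ndarray) -> VariantStats:
    """AC, MAF, call rate and MAF bin for one dosage vector.

    Raises ``ValueError`` when every genotype is missing.
    """
    d = np.asarray(dosages)
    called = d != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("all genotypes missing; statistics undefined")
    alt_count = int(d[called].sum())
    ac = min(alt_count, 2 * n - alt_count)  # minor allele copies
    maf = ac / (2 * n)
    ac_label = {1: "AC=1", 2: "AC=2"}.get(ac)
    return VariantStats(ac, maf, n / d.size, maf_bin(maf), ac_label)


def tag_novelty(
    variant: VariantRecord,
    known_keys: set[tuple[str, int, str, str]],
    known_ids: set[str] = frozenset(),
) -> str:
    """Tag a variant ``novel`` or ``known`` against a catalogue.

    A variant is novel only when both its (chrom, pos, ref, alt) key and its
    identifier are absent from the catalogue; an rsID hit alone suffices to
    mark it known.
    """
    if variant.key in known_keys:
        return "known"
    if variant.id not in (".", "", None) and variant.id in known_ids:
        return "known"
    return "novel"


class GenotypeMatrix:
    """Person x variant dosage matrix backed by a variant table.

    ``dosages`` has shape (n_variants, n_persons), dtype int8, with
    :data:`MISSING` (-1) for no-calls.
    """

    def __init__(self, samples: Sequence[str], variants: pd.DataFrame, dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        required = {"chrom", "pos", "id", "ref", "alt"}
        if not required.issubset(variants.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        self.samples = list(samples)
        self.variants = variants.reset_index(drop=True)
        self.dosages = dosages
        self._index = {vid: i for i, vid in enumerate(self.variants["id"])}

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def record(self, variant_id: str) -> VariantRecord:
        i = self._index[variant_id]
        v = self.variants.iloc[i]
        return VariantRecord(
            chrom=str(v["chrom"]), pos=int(v["pos"]), ref=str(v["ref"]),
            alt=str(v["alt"]), id=str(v["id"]),
            ancestral_allele=v.get("aa") if "aa" in self.variants.columns else None,
            dosages=self.dosages[i],
        )

    def stats(self, variant_id: str) -> VariantStats:
        return variant_stats(self.row(variant_id))

    def maf(self) -> np.ndarray:
        """Vector of minor-allele frequencies over all variants."""
        d = self.dosages
        called = d != MISSING
        n = called.sum(axis=1)
        if (n == 0).any():
            raise ValueError("variant with all genotypes missing")
        alt = np.where(called, d, 0).sum(axis=1)
        af = alt / (2 * n)
        return np.minimum(af, 1 - af)

    # -- VCF I/O -----------------------------------------------------------

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeMatrix":
        """Load diploid GT calls from a VCF 4.x file via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows, dosage_rows = [], []
        for var in vcf:
            aa = var.INFO.get("AA")
            rows.append({
                "chrom": var.CHROM, "pos": var.POS,
                "id": var.ID or ".", "ref": var.REF, "alt": var.ALT[0],
                "aa": aa,
            })
            gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3=unknown
            gt[gt == 3] = MISSING
            dosage_rows.append(gt)
        vcf.close()
        if not rows:
            raise ValueError(f"no variants in {path}")
        variants = pd.DataFrame(rows)
        if variants["aa"].isna().all():
            variants = variants.drop(columns=["aa"])
        return cls(samples, variants, np.vstack(dosage_rows))

    def to_vcf(self, path: str) -> None:
        """Write the matrix as minimal diploid VCF 4.2 (GT only, unphased)."""
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            has_aa = "aa" in self.variants.columns
            order = np.lexsort((self.variants["pos"].to_numpy(),
                                self.variants["chrom"].to_numpy()))
            for i in order:
                v = self.variants.iloc[i]
                info = f"AA={v['aa']}" if has_aa and pd.notna(v.get("aa")) else "."
                gts = "\t".join(gt_code[int(x)] for x in self.dosages[i])
                fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t"
                         f"{v['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n")
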