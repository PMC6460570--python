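"""Rule-based functional classification of pharmacogene variants.

Loss-of-function (LoF) follows the standard rule set: stop-gain SNVs,
frameshift indels in coding sequence, and variants in the two intronic bases
flanking an exon (the essential splice donor/acceptor dinucleotides).  Two
exclusions apply to LoF candidates: variants whose alternate allele is the
ancestral allele, and variants in the 3'-most 5% of the spliced transcript,
which typically escape nonsense-mediated decay.  Coding SNVs that change the
encoded amino acid without creating a stop are missense; LoF takes
precedence.  Variants in the 5-kb window upstream of the transcription start
site that fall inside a scored transcription-factor binding site are
classified ``promoter_tfbs``.

Coordinates are 1-based closed throughout; the transcript model carries
genomic exon and CDS intervals on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .motif import PWM, MotifHit, revcomp, scan_sequence
from .variants import VariantRecord

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

LAST_FRACTION_CUT = 0.95  # 3'-most 5% of the spliced transcript excluded
PROMOTER_WINDOW = 5000

LOF_CATEGORIES = ("stop_gain", "frameshift", "essential_splice")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genomic contig."""

    gene: str
    chrom: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]]  # 1-based closed, ascending, non-overlapping
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for lo, hi in ivs:
                if lo > hi or lo < 1:
                    raise ValueError(f"malformed {name} interval ({lo}, {hi})")
            for (a, b), (c, _) in zip(ivs, ivs[1:]):
                if c <= b:
                    raise ValueError(f"{name} intervals must be sorted and disjoint")
        for lo, hi in self.cds:
            if not any(elo <= lo and hi <= ehi for elo, ehi in self.exons):
                raise ValueError("CDS interval not contained in an exon")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")

    @property
    def tss(self) -> int:
        """Transcription start: 5' end of the transcript on its strand."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.cds)

    def _offset_in(self, intervals: list[tuple[int, int]], pos: int) -> int | None:
        """5'->3' offset of a genomic position within concatenated intervals."""
        off = 0
        ordered = intervals if self.strand == "+" else intervals[::-1]
        for lo, hi in ordered:
            if lo <= pos <= hi:
                return off + (pos - lo if self.strand == "+" else hi - pos)
            off += hi - lo + 1
        return None

    def spliced_offset(self, pos: int) -> int | None:
        return self._offset_in(self.exons, pos)

    def cds_offset(self, pos: int) -> int | None:
        return self._offset_in(self.cds, pos)

    def transcript_fraction(self, pos: int) -> float | None:
        """Position along the spliced transcript in (0, 1], 5'->3'."""
        off = self.spliced_offset(pos)
        if off is None:
            return None
        return (off + 1) / self.spliced_length

    def splice_sites(self) -> set[int]:
        """Genomic positions of the 2 intronic bases flanking each exon."""
        sites: set[int] = set()
        for (_, hi), (lo2, _) in zip(self.exons, self.exons[1:]):
            sites.update((hi + 1, hi + 2))      # intron start
            sites.update((lo2 - 2, lo2 - 1))    # intron end
        return sites

    def overlaps(self, pos: int) -> bool:
        return self.exons[0][0] - 2 <= pos <= self.exons[-1][1] + 2

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in 5'->3' transcript order."""
        chunks = []
        ordered = self.cds if self.strand == "+" else self.cds[::-1]
        for lo, hi in ordered:
            arr = np.arange(lo, hi + 1)
            chunks.append(arr if self.strand == "+" else arr[::-1])
        return np.concatenate(chunks)

    def promoter_interval(self, contig_length: int | None = None) -> tuple[int, int]:
        """5-kb upstream window (1-based closed), clipped at the contig start/end."""
        if self.strand == "+":
            lo, hi = max(1, self.tss - PROMOTER_WINDOW), self.tss - 1
        else:
            lo, hi = self.tss + 1, self.tss + PROMOTER_WINDOW
            if contig_length is not None:
                hi = min(hi, contig_length)
        if lo > hi:
            raise ValueError("empty promoter window (TSS at contig edge)")
        return lo, hi


@dataclass
class FunctionalCall:
    variant_id: str
    gene: str
    category: str  # stop_gain | frameshift | essential_splice | missense | promoter_tfbs | none
    excluded_reason: str | None = None  # ancestral_allele | last_5_percent

    def __post_init__(self) -> None:
        if self.excluded_reason is not None and self.category != "none":
            raise ValueError("excluded variants must carry category 'none'")

    @property
    def is_lof(self) -> bool:
        return self.category in LOF_CATEGORIES


def _base(refseq, pos: int) -> str:
    return str(refseq[pos - 1]).upper()


def _codon_change(v: VariantRecord, t: TranscriptModel, refseq) -> tuple[str, str] | None:
    """(old_aa, new_aa) for a coding SNV, else None."""
    off = t.cds_offset(v.pos)
    if off is None or not v.is_snv:
        return None
    positions = t.cds_genomic_positions()
    codon_idx = off // 3
    codon_pos = positions[3 * codon_idx:3 * codon_idx + 3]
    bases = [_base(refseq, int(p)) for p in codon_pos]
    if t.strand == "-":
        bases = [revcomp(b) for b in bases]
    ref_base, alt_base = v.ref.upper(), v.alt.upper()
    if t.strand == "-":
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
    slot = off % 3
    if bases[slot] != ref_base:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos}: genome has {bases[slot]}, "
            f"variant REF is {ref_base} (transcript strand)")
    old = CODON_TABLE["".join(bases)]
    bases[slot] = alt_base
    new = CODON_TABLE["".join(bases)]
    return old, new


def _affected_span(v: VariantRecord) -> tuple[int, int]:
    """Genomic span of bases changed by the variant (1-based closed)."""
    if len(v.ref) == len(v.alt) == 1:
        return v.pos, v.pos
    # VCF indel convention: first base is the shared anchor
    return v.pos + 1, v.pos + max(len(v.ref), len(v.alt)) - 1


def classify_lof(v: VariantRecord, t: TranscriptModel, refseq) -> FunctionalCall:
    """Loss-of-function call for one variant against one transcript.

    Returns category ``none`` for variants outside the transcript or not
    matching any LoF rule; LoF candidates whose ALT equals the ancestral
    allele or that sit beyond 95% of the spliced transcript are excluded
    (category ``none`` plus the reason).
    """
    none = FunctionalCall(v.id, t.gene, "none")
    if not t.overlaps(v.pos):
        return none
    category = None
    span_lo, span_hi = _affected_span(v)
    splice = t.splice_sites()
    if any(p in splice for p in range(span_lo, span_hi + 1)) or v.pos in splice:
        category = "essential_splice"
    elif v.is_snv:
        change = _codon_change(v, t, refseq)
        if change is not None:
            old, new = change
            if new == "*" and old != "*":
                category = "stop_gain"
    else:
        shift = abs(len(v.ref) - len(v.alt))
        in_cds = any(t.cds_offset(p) is not None for p in range(span_lo, span_hi + 1))
        if in_cds and shift % 3 != 0:
            category = "frameshift"
    if category is None:
        return none
    if v.ancestral_allele is not None and v.alt.upper() == v.ancestral_allele.upper():
        return FunctionalCall(v.id, t.gene, "none", "ancestral_allele")
    frac = t.transcript_fraction(v.pos)
    if frac is None:  # splice variant: use the nearest exonic base
        exon_edges = [p for lo, hi in t.exons for p in (lo, hi)]
        nearest = min(exon_edges, key=lambda p: abs(p - v.pos))
        frac = t.transcript_fraction(nearest)
    if frac is not None and frac > LAST_FRACTION_CUT:
        return FunctionalCall(v.id, t.gene, "none", "last_5_percent")
    return FunctionalCall(v.id, t.gene, category)


def classify_missense(v: VariantRecord, t: TranscriptModel, refseq) -> FunctionalCall:
    """Missense call; LoF takes precedence and non-coding SNVs return none."""
    lof = classify_lof(v, t, refseq)
    if lof.category != "none" or lof.excluded_reason is not None:
        return lof
    if not v.is_snv:
        return FunctionalCall(v.id, t.gene, "none")
    change = _codon_change(v, t, refseq)
    if change is None:
        return FunctionalCall(v.id, t.gene, "none")
    old, new = change
    if old != new and new != "*" and old != "*":
        return FunctionalCall(v.id, t.gene, "missense")
    return FunctionalCall(v.id, t.gene, "none")


def classify_variant(
    v: VariantRecord,
    t: TranscriptModel,
    refseq,
    promoter_hits: list[MotifHit] | None = None,
    pwm_lengths: dict[str, int] | None = None,
    contig_length: int | None = None,
) -> FunctionalCall:
    """Full classification: LoF, then missense, then promoter TFBS overlap.

    ``promoter_hits`` are motif hits on the forward genomic strand of the
    5-kb upstream window (offsets 0-based from the window start).
    """
    call = classify_missense(v, t, refseq)
    if call.category != "none" or call.excluded_reason is not None:
        return call
    if promoter_hits:
        lo, hi = t.promoter_interval(contig_length)
        if lo <= v.pos <= hi:
            off = v.pos - lo
            for h in promoter_hits:
                length = (pwm_lengths or {}).get(h.pwm, 1)
                if h.offset <= off < h.offset + length:
                    return FunctionalCall(v.id, t.gene, "promoter_tfbs")
    return call


def promoter_scan(
    t: TranscriptModel,
    refseq,
    pwms: list[PWM],
    mss_cut: float,
    css_cut: float,
) -> list[MotifHit]:
    """Scan the transcript's 5-kb upstream window on the genomic sequence."""
    lo, hi = t.promoter_interval(len(refseq))
    window = str(refseq[lo - 1:hi]).upper()
    return scan_sequence(window, pwms, mss_cut=mss_cut, css_cut=css_cut)


def read_transcripts_gff3(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models from GFF3 (gene/mRNA/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        gene = mrna.attributes.get("gene", mrna.attributes.get("Parent", [mrna.id]))[0]
        exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = [(mrna.start, mrna.end)]
        out.append(TranscriptModel(gene=gene, chrom=mrna.seqid, strand=mrna.strand,
                                   exons=exons, cds=cds))
    return out
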