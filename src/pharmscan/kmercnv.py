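"""Copy-number estimation of a segmental-duplication gene region from k-mers.

Read mapping is unreliable inside segmental duplications, so gene copy
number is estimated directly from read k-mer counts: a panel of diagnostic
k-mers unique to the target region is compared against a panel from a
copy-number-2 control region, and

    CN = 2 * median(diagnostic k-mer count) / median(control k-mer count).

All k-mers are canonical (the lexicographic minimum of a k-mer and its
reverse complement), making the estimate strand-invariant.  Counts below 10%
of the control median are treated as absent (sequencing-error tolerance).
A toy uniform read simulator is included for validation on synthetic
genomes with known planted copy numbers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .motif import revcomp

DEFAULT_K = 25
ERROR_FLOOR_FRACTION = 0.10


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            yield canonical(kmer)


@dataclass(frozen=True)
class KmerPanel:
    """Diagnostic and control canonical k-mer sets for one target region."""

    k: int
    kmers: frozenset[str]
    control_kmers: frozenset[str]

    def __post_init__(self) -> None:
        if self.kmers & self.control_kmers:
            raise ValueError("diagnostic and control panels must be disjoint")


@dataclass
class CnvEstimate:
    person_id: str
    cn: float

    @property
    def cn_rounded(self) -> int:
        return int(round(self.cn))


def build_panel(
    reference: dict[str, str],
    region: tuple[str, int, int],
    control: tuple[str, int, int],
    k: int = DEFAULT_K,
) -> KmerPanel:
    """Select region-diagnostic k-mers occurring exactly once genome-wide.

    ``reference`` maps contig name to sequence; ``region`` and ``control``
    are (contig, start, end) in 1-based closed coordinates.  K-mers shared
    between the two panels are assigned to neither (disjointness), and an
    empty diagnostic panel raises with advice to increase k.
    """
    if region == control:
        raise ValueError("control region must differ from the target region")
    genome_counts: Counter[str] = Counter()
    for seq in reference.values():
        genome_counts.update(iter_kmers(seq, k))

    def unique_in(interval: tuple[str, int, int]) -> set[str]:
        chrom, start, end = interval
        if chrom not in reference:
            raise KeyError(f"contig {chrom!r} not in reference")
        if not 1 <= start <= end <= len(reference[chrom]):
            raise ValueError(f"interval {interval} outside contig bounds")
        if end - start + 1 < k:
            raise ValueError(f"interval {interval} shorter than k={k}")
        sub = reference[chrom][start - 1:end]
        return {km for km in iter_kmers(sub, k) if genome_counts[km] == 1}

    diag = unique_in(region)
    ctrl = unique_in(control)
    shared = diag & ctrl
    diag -= shared
    ctrl -= shared
    if not diag:
        raise ValueError(
            "no region-diagnostic k-mers (region likely duplicated elsewhere); "
            "try a larger k")
    if not ctrl:
        raise ValueError("no unique control k-mers; choose another control region")
    return KmerPanel(k, frozenset(diag), frozenset(ctrl))


def count_panel_kmers(reads: Iterable[str], panel: KmerPanel) -> tuple[Counter, Counter]:
    """Occurrences of each panel k-mer across a read set (canonical form)."""
    diag: Counter[str] = Counter()
    ctrl: Counter[str] = Counter()
    for read in reads:
        for km in iter_kmers(read, panel.k):
            if km in panel.kmers:
                diag[km] += 1
            elif km in panel.control_kmers:
                ctrl[km] += 1
    return diag, ctrl


def estimate_cn(
    reads: Iterable[str],
    panel: KmerPanel,
    person_id: str = "sample",
) -> CnvEstimate:
    """Median-ratio copy-number estimate from a read set.

    Raises when the control median is zero (insufficient coverage).  Counts
    below 10% of the control median are zeroed before taking the diagnostic
    median, so sequencing-error k-mers do not inflate a deleted region.
    """
    diag_counts, ctrl_counts = count_panel_kmers(reads, panel)
    ctrl = np.array([ctrl_counts.get(km, 0) for km in sorted(panel.control_kmers)])
    ctrl_median = float(np.median(ctrl))
    if ctrl_median == 0:
        raise ValueError("control k-mer median is zero; coverage insufficient")
    diag = np.array([diag_counts.get(km, 0) for km in sorted(panel.kmers)], dtype=float)
    diag[diag < ERROR_FLOOR_FRACTION * ctrl_median] = 0.0
    cn = 2.0 * float(np.median(diag)) / ctrl_median
    return CnvEstimate(person_id, cn)


def correlate_estimates(cnv_a: Sequence[float], cnv_b: Sequence[float]) -> float:
    """Squared Pearson correlation between two paired CN call sets."""
    a = np.asarray(cnv_a, dtype=float)
    b = np.asarray(cnv_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-d vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 paired estimates")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a CN vector; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r**2)


def simulate_reads(
    haplotypes: Sequence[str],
    coverage: float,
    read_length: int = 100,
    seed: int = 0,
) -> list[str]:
    """Uniform error-free reads from a set of haplotype sequences.

    ``coverage`` is per haplotype set (diploid coverage when two haplotypes
    are passed); reads are drawn from either strand.
    """
    rng = np.random.default_rng(seed)
    total = sum(len(h) for h in haplotypes)
    # read bases = coverage x haploid genome length, so a locus present on
    # both haplotypes of a diploid pair is covered `coverage` times
    n_reads = int(round(coverage * total / (read_length * 2)))
    reads = []
    lengths = np.array([len(h) for h in haplotypes], dtype=float)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(haplotypes), size=n_reads, p=probs)
    for idx in picks:
        h = haplotypes[idx]
        if len(h) < read_length:
            continue
        start = rng.integers(0, len(h) - read_length + 1)
        read = h[start:start + read_length]
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(read)
    return reads


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a (possibly gzipped) FASTQ file."""
    from Bio import SeqIO

    p = Path(path)
    if p.suffix == ".gz":
        import gzip

        with gzip.open(p, "rt") as fh:
            return [str(r.seq) for r in SeqIO.parse(fh, "fastq")]
    with open(p) as fh:
        return [str(r.seq) for r in SeqIO.parse(fh, "fastq")]


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
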