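"""Position-weight-matrix scanning of promoter sequence, Match-style.

Windows of sequence are scored against a nucleotide frequency matrix with
the information-weighted similarity of the Match method:

    score = (Current - Min) / (Max - Min)
    Current = sum_i I(i) * f(i, b_i)
    I(i)    = sum_b f(i, b) * ln(4 f(i, b))      (0 ln 0 := 0)

where ``Min``/``Max`` substitute the per-position minimum/maximum frequency.
Scores lie in [0, 1]; 1 means the window is the matrix consensus.  Two
scores gate a hit: the matrix similarity (mss) over the full matrix and the
core similarity (css) over the 5 consecutive positions of highest summed
information content (leftmost on ties).  Both strands are scanned; windows
containing N are skipped.  A matrix with zero information at every position
scores every window 1.0 by convention (Max == Min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MSS_CUT = 0.95
DEFAULT_CSS_CUT = 0.90
CORE_LENGTH = 5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_content(freqs: np.ndarray) -> np.ndarray:
    """Per-position information I(i) = sum_b f ln(4 f), with 0 ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4 * freqs), 0.0)
    return terms.sum(axis=1)


@dataclass
class PWM:
    """A nucleotide frequency matrix with its high-information core."""

    name: str
    freqs: np.ndarray  # (length, 4) rows over A,C,G,T; rows sum to 1
    core_start: int = field(init=False)
    core_length: int = field(init=False, default=CORE_LENGTH)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("frequency matrix must have shape (length, 4)")
        rowsum = self.freqs.sum(axis=1)
        if (rowsum <= 0).any():
            raise ValueError("every matrix position needs positive counts")
        self.freqs = self.freqs / rowsum[:, None]
        self.core_length = min(CORE_LENGTH, len(self))
        info = self.information
        sums = np.convolve(info, np.ones(self.core_length), mode="valid")
        self.core_start = int(np.argmax(sums))  # argmax is leftmost on ties

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def information(self) -> np.ndarray:
        return information_content(self.freqs)

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray) -> "PWM":
        return cls(name, np.asarray(counts, dtype=float))

    @classmethod
    def from_biopython(cls, motif) -> "PWM":
        counts = np.column_stack([motif.counts[b] for b in BASES])
        return cls(motif.name or motif.get("AC", "motif"), counts)

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.freqs[::-1, ::-1])

    def score(self, window: str, start: int = 0, length: int | None = None) -> float:
        """Match similarity of ``window`` over matrix positions [start, start+length)."""
        if length is None:
            length = len(self)
        if len(window) != len(self):
            raise ValueError("window length must equal matrix length")
        idx = np.fromiter((_BASE_INDEX[b] for b in window), dtype=int, count=len(window))
        info = self.information[start:start + length]
        f = self.freqs[start:start + length]
        current = (info * f[np.arange(length), idx[start:start + length]]).sum()
        lo = (info * f.min(axis=1)).sum()
        hi = (info * f.max(axis=1)).sum()
        if hi - lo == 0:
            return 1.0
        return float((current - lo) / (hi - lo))

    def mss(self, window: str) -> float:
        return self.score(window)

    def css(self, window: str) -> float:
        return self.score(window, self.core_start, self.core_length)


def load_transfac(path: str) -> list[PWM]:
    """Read a TRANSFAC-format matrix library (DE/PO records) via Bio.motifs."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "TRANSFAC")
    return [PWM.from_biopython(m) for m in records]


class MotifHit(NamedTuple):
    pwm: str
    offset: int  # 0-based window start on the forward strand
    strand: str  # "+" | "-"
    css: float
    mss: float


def scan_sequence(
    seq: str,
    pwms: Iterable[PWM],
    mss_cut: float = DEFAULT_MSS_CUT,
    css_cut: float = DEFAULT_CSS_CUT,
) -> list[MotifHit]:
    """All windows on either strand with css >= css_cut and mss >= mss_cut.

    A minus-strand hit at offset j means the reverse complement of
    ``seq[j:j+L]`` matches the matrix; sequence shorter than a matrix yields
    no hits for it.
    """
    for cut in (mss_cut, css_cut):
        if not 0.0 <= cut <= 1.0:
            raise ValueError("similarity cut-offs must be in [0, 1]")
    seq = seq.upper()
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = len(pwm)
        for j in range(len(seq) - L + 1):
            window = seq[j:j + L]
            if "N" in window:
                continue
            for strand in ("+", "-"):
                oriented = window if strand == "+" else revcomp(window)
                css = pwm.css(oriented)
                if css < css_cut:
                    continue
                mss = pwm.mss(oriented)
                if mss >= mss_cut:
                    hits.append(MotifHit(pwm.name, j, strand, float(css), float(mss)))
    hits.sort(key=lambda h: (h.offset, h.pwm, h.strand))
    return hits


def filter_hits_by_mask(
    hits: list[MotifHit],
    pwm_lengths: dict[str, int],
    mask: list[tuple[int, int]],
) -> list[MotifHit]:
    """Keep hits overlapping any masked interval (0-based half-open offsets).

    Models restriction of motif hits to regions with ChIP-seq evidence.
    """
    out = []
    for h in hits:
        lo, hi = h.offset, h.offset + pwm_lengths[h.pwm]
        if any(lo < end and start < hi for start, end in mask):
            out.append(h)
    return out
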