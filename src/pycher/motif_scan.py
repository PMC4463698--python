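"""Position-weight-matrix scanning of cher sequences.

Scoring follows the classic information-weighted similarity scheme used by
TRANSFAC-style matrix search tools.  Each matrix position i carries an
information weight I(i) = sum_B f(i,B) ln(4 f(i,B)) (natural log, with
0 ln 0 := 0); for a sequence window s the score is

    Current = sum_i I(i) f(i, s_i)
    MSS     = (Current - Min) / (Max - Min)

where Min/Max use the per-position minimum/maximum frequency.  The core
similarity score (CSS) applies the same formula restricted to the core:
the five consecutive positions with the largest summed information
(leftmost window on ties).  Scanning applies the two-stage filter of the
Match algorithm — a window must pass the CSS cutoff first, then the MSS
cutoff — on both strands; windows containing an ambiguous base (N) are
skipped.  Hit positions are 1-based first bases of the motif footprint on
the plus strand regardless of hit strand.

TRANSFAC's proprietary minFP/minSum cutoff profiles are not bundled;
cutoffs are user-supplied, with permissive defaults (CSS 0.75, MSS 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cher_calling import Cher
from .errors import ValidationError

CORE_LENGTH = 5
DEFAULT_CSS_CUTOFF = 0.75
DEFAULT_MSS_CUTOFF = 0.80

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _information_vector(freqs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
    return terms.sum(axis=1)


@dataclass
class PWM:
    """A frequency matrix with its information vector and 5-base core.

    ``freqs`` has shape (L, 4) over the alphabet ACGT, each row summing
    to 1.  ``core_start`` (0-based) locates the length-5 window with the
    largest summed information, leftmost on ties.
    """

    matrix_id: str
    freqs: np.ndarray
    css_cutoff: float = DEFAULT_CSS_CUTOFF
    mss_cutoff: float = DEFAULT_MSS_CUTOFF
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValidationError(f"{self.matrix_id}: freqs must have shape (L, 4)")
        if len(self.freqs) < CORE_LENGTH:
            raise ValidationError(f"{self.matrix_id}: matrix length must be >= {CORE_LENGTH}")
        if np.any(self.freqs < 0):
            raise ValidationError(f"{self.matrix_id}: negative frequency")
        sums = self.freqs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(f"{self.matrix_id}: position frequencies must sum to 1")
        if not 0.0 <= self.css_cutoff <= 1.0 or not 0.0 <= self.mss_cutoff <= 1.0:
            raise ValidationError(f"{self.matrix_id}: cutoffs must be in [0, 1]")
        self.info = _information_vector(self.freqs)
        window_info = np.convolve(self.info, np.ones(CORE_LENGTH), mode="valid")
        self.core_start = int(np.argmax(window_info))  # argmax takes the leftmost maximum

    @property
    def length(self) -> int:
        return len(self.freqs)

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + CORE_LENGTH)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.freqs, axis=1))

    @classmethod
    def from_counts(
        cls,
        matrix_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.0,
        css_cutoff: float = DEFAULT_CSS_CUTOFF,
        mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValidationError(f"{matrix_id}: counts must have shape (L, 4)")
        counts = counts + pseudocount
        sums = counts.sum(axis=1)
        if np.any(sums <= 0):
            raise ValidationError(f"{matrix_id}: position with zero total count")
        return cls(matrix_id, counts / sums[:, None], css_cutoff=css_cutoff, mss_cutoff=mss_cutoff)


def load_pwms(
    path,
    dialect: str,
    pseudocount: float = 0.0,
    css_cutoff: float = DEFAULT_CSS_CUTOFF,
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
) -> list[PWM]:
    """Load one or more matrices from a TRANSFAC or JASPAR flat text file."""
    from Bio import motifs as bio_motifs

    dialect = dialect.lower()
    if dialect not in ("transfac", "jaspar"):
        raise ValidationError(f"unknown PWM dialect {dialect!r}")
    with open(path) as fh:
        records = bio_motifs.parse(fh, dialect)
        out = []
        for m in records:
            counts = np.array([[m.counts[b][i] for b in _ALPHABET] for i in range(m.length)])
            matrix_id = m.get("AC") if dialect == "transfac" else (m.matrix_id or m.name)
            if not matrix_id:
                matrix_id = m.name or "PWM"
            out.append(
                PWM.from_counts(
                    str(matrix_id), counts, pseudocount=pseudocount,
                    css_cutoff=css_cutoff, mss_cutoff=mss_cutoff,
                )
            )
    if not out:
        raise ValidationError(f"{path}: no matrices found")
    return out


def load_pwm(path, dialect: str, **kwargs) -> PWM:
    """Load a single matrix (the first in the file)."""
    return load_pwms(path, dialect, **kwargs)[0]


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def _similarity(freqs: np.ndarray, info: np.ndarray, codes: np.ndarray) -> float:
    if np.any(codes > 3):
        raise ValidationError("sequence contains an ambiguous base")
    weighted = freqs * info[:, None]
    current = float(weighted[np.arange(len(freqs)), codes].sum())
    lo = float((info * freqs.min(axis=1)).sum())
    hi = float((info * freqs.max(axis=1)).sum())
    if hi == lo:
        raise ValidationError("degenerate matrix: Max equals Min")
    return (current - lo) / (hi - lo)


def matrix_similarity(pwm: PWM, seq: str) -> float:
    """Matrix similarity score of a window of matrix length, in [0, 1]."""
    if len(seq) != pwm.length:
        raise ValidationError(f"sequence length {len(seq)} != matrix length {pwm.length}")
    return _similarity(pwm.freqs, pwm.info, _encode(seq))


def core_similarity(pwm: PWM, seq: str) -> float:
    """Core similarity score: same formula over the 5-base core window."""
    if len(seq) != pwm.length:
        raise ValidationError(f"sequence length {len(seq)} != matrix length {pwm.length}")
    sl = slice(pwm.core_start, pwm.core_start + CORE_LENGTH)
    return _similarity(pwm.freqs[sl], pwm.info[sl], _encode(seq)[sl])


@dataclass(frozen=True)
class MotifHit:
    matrix_id: str
    seq_id: str
    position: int  # 1-based plus-strand start of the motif footprint
    strand: int  # +1 / -1
    mss: float
    css: float
    matched_sequence: str


def _window_scores(freqs: np.ndarray, info: np.ndarray, codes: np.ndarray):
    """Vectorized Current scores and N-mask for every window of len(freqs)."""
    L = len(freqs)
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    has_n = (windows > 3).any(axis=1)
    safe = np.where(windows > 3, 0, windows)
    weighted = freqs * info[:, None]
    current = weighted[np.arange(L), safe].sum(axis=1)
    return current, has_n


def _scan_one_strand(pwm: PWM, codes: np.ndarray) -> list[tuple[int, float, float]]:
    """(window index, mss, css) for windows passing the two-stage filter."""
    L = pwm.length
    sl = slice(pwm.core_start, pwm.core_start + CORE_LENGTH)
    core_freqs, core_info = pwm.freqs[sl], pwm.info[sl]

    core_lo = float((core_info * core_freqs.min(axis=1)).sum())
    core_hi = float((core_info * core_freqs.max(axis=1)).sum())
    full_lo = float((pwm.info * pwm.freqs.min(axis=1)).sum())
    full_hi = float((pwm.info * pwm.freqs.max(axis=1)).sum())
    if core_hi == core_lo or full_hi == full_lo:
        raise ValidationError(f"{pwm.matrix_id}: degenerate matrix: Max equals Min")

    full_cur, full_n = _window_scores(pwm.freqs, pwm.info, codes)
    if full_cur.size == 0:
        return []
    core_cur, core_n = _window_scores(core_freqs, core_info, codes[pwm.core_start :])
    core_cur = core_cur[: len(full_cur)]
    has_n = full_n  # footprint contains an N anywhere -> skip the window

    css = (core_cur - core_lo) / (core_hi - core_lo)
    mss = (full_cur - full_lo) / (full_hi - full_lo)
    keep = ~has_n & (css >= pwm.css_cutoff) & (mss >= pwm.mss_cutoff)
    return [(int(i), float(mss[i]), float(css[i])) for i in np.flatnonzero(keep)]


def scan_sequence(pwm: PWM, seq: str, seq_id: str = "") -> list[MotifHit]:
    """Scan both strands of a sequence; returns hits sorted by position.

    Minus-strand hits are found by scanning the reverse complement and
    reporting the plus-strand start coordinate of the footprint;
    ``matched_sequence`` is the motif-oriented (scanned) sequence.
    """
    seq = seq.upper()
    n, L = len(seq), pwm.length
    hits = []
    for idx, mss, css in _scan_one_strand(pwm, _encode(seq)):
        hits.append(MotifHit(pwm.matrix_id, seq_id, idx + 1, +1, mss, css, seq[idx : idx + L]))
    rc = revcomp(seq)
    for idx, mss, css in _scan_one_strand(pwm, _encode(rc)):
        plus_start = n - idx - L + 1  # 1-based plus-strand start of the footprint
        hits.append(MotifHit(pwm.matrix_id, seq_id, plus_start, -1, mss, css, rc[idx : idx + L]))
    hits.sort(key=lambda h: (h.position, -h.strand))
    return hits


def scan_chers(
    pwms: list[PWM],
    cher_sequences: dict[str, str],
    cutoff_profile: dict[str, tuple[float, float]] | None = None,
) -> list[MotifHit]:
    """Scan every cher sequence with every matrix.

    ``cutoff_profile`` optionally maps matrix_id -> (css_cutoff,
    mss_cutoff), overriding the cutoffs stored on each matrix.
    """
    from dataclasses import replace as dc_replace

    hits = []
    for pwm in pwms:
        if cutoff_profile and pwm.matrix_id in cutoff_profile:
            css, mss = cutoff_profile[pwm.matrix_id]
            pwm = dc_replace(pwm, css_cutoff=css, mss_cutoff=mss)
        for cher_id in sorted(cher_sequences):
            hits.extend(scan_sequence(pwm, cher_sequences[cher_id], seq_id=cher_id))
    return hits


def fetch_cher_sequences(fasta_path, chers: list[Cher]) -> dict[str, str]:
    """Extract uppercase cher sequences from a genome FASTA (1-based inclusive)."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    out = {}
    for c in chers:
        if c.chrom not in genome:
            raise ValidationError(f"{c.cher_id}: chromosome {c.chrom} not in FASTA")
        out[c.cher_id] = str(genome[c.chrom][c.start - 1 : c.end]).upper()
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def hits_to_table(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "matrix_id": [h.matrix_id for h in hits],
            "seq_id": [h.seq_id for h in hits],
            "position": [h.position for h in hits],
            "strand": ["+" if h.strand == +1 else "-" for h in hits],
            "mss": [h.mss for h in hits],
            "css": [h.css for h in hits],
            "matched_sequence": [h.matched_sequence for h in hits],
        }
    )
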