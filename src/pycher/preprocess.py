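"""Normalization and smoothing of tiling-array log ratios.

Two steps, in this order:

1. **Tukey-biweight scale normalization** — a robust one-step location
   estimate of the log2 ratios is subtracted from every probe, centring
   the array so that unenriched probes sit near zero.  The biweight
   down-weights outliers (enriched probes) via the (1 - u^2)^2 weight.
2. **Running-median smoothing** — each probe's value is replaced by the
   median of all probes within a centered window (900 bp total span by
   default).  Positions whose window holds fewer than ``min_probes``
   reporters get a missing value and are excluded from region calling,
   which prevents single-probe spikes from seeding enriched regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_data import Probe
from .errors import ValidationError

TUKEY_C = 5.0
TUKEY_EPS = 1e-4


def tukey_biweight_location(values, c: float = TUKEY_C, eps: float = TUKEY_EPS) -> float:
    """One-step Tukey-biweight location estimate.

    u = (x - median) / (c * MAD + eps); weights w = (1 - u^2)^2 for |u| < 1
    and 0 otherwise; returns sum(w x) / sum(w).  When every weight is zero
    (degenerate MAD) the median is returned.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("tukey_biweight_location requires at least one finite value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    sw = w.sum()
    if sw == 0.0:
        return med
    return float(np.sum(w * x) / sw)


@dataclass
class NormalizationResult:
    """Centred log ratios plus the location estimate that was removed."""

    location_estimate: float
    normalized: pd.Series


def normalize(log_ratios: pd.Series, c: float = TUKEY_C, eps: float = TUKEY_EPS) -> NormalizationResult:
    """Subtract the Tukey-biweight location from every log ratio."""
    series = pd.Series(log_ratios, dtype=float)
    location = tukey_biweight_location(series.to_numpy(), c=c, eps=eps)
    return NormalizationResult(location_estimate=location, normalized=series - location)


@dataclass
class SmoothedTrack:
    """Per-probe smoothed enrichment values on one chromosome.

    ``values`` are aligned with ``positions``; NaN marks positions whose
    window held fewer than ``min_probes`` probes.  ``probe_ids`` is
    optional bookkeeping for exports.
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    half_window: int = 450
    min_probes: int = 7
    probe_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError(f"track {self.chrom}: positions must be strictly increasing")

    @property
    def n_probes(self) -> int:
        return int(self.positions.size)


def running_median(positions, values, half_window: int = 450, min_probes: int = 7) -> np.ndarray:
    """Centered running median over a bp window.

    The smoothed value at probe position p is the median of the values of
    all probes with |pos - p| <= half_window (the probe itself included).
    Positions whose window contains fewer than ``min_probes`` probes are
    NaN.  Median of an even count is the mean of the two central values.
    """
    pos = np.asarray(positions, dtype=np.int64)
    vals = np.asarray(values, dtype=float)
    if pos.shape != vals.shape:
        raise ValidationError("positions and values must have equal length")
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValidationError("positions must be strictly increasing and sorted")
    n = pos.size
    out = np.full(n, np.nan)
    if n == 0:
        return out
    lo = np.searchsorted(pos, pos - half_window, side="left")
    hi = np.searchsorted(pos, pos + half_window, side="right")
    widths = hi - lo
    # group windows by width so each group is one vectorized median call
    for width in np.unique(widths):
        if width < min_probes:
            continue
        idx = np.flatnonzero(widths == width)
        windows = vals[lo[idx][:, None] + np.arange(width)]
        out[idx] = np.median(windows, axis=1)
    return out


def smooth_probes(
    probes: list[Probe],
    normalized: pd.Series,
    half_window: int = 450,
    min_probes: int = 7,
) -> dict[str, SmoothedTrack]:
    """Run the running median per chromosome over normalized probe ratios.

    Probes without a normalized value are skipped.  Returns one
    :class:`SmoothedTrack` per chromosome, keyed by chromosome name.
    """
    rows = [
        (p.chrom, p.start, p.probe_id, float(normalized[p.probe_id]))
        for p in probes
        if p.probe_id in normalized.index and np.isfinite(normalized[p.probe_id])
    ]
    tracks: dict[str, SmoothedTrack] = {}
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    for chrom, chrom_rows in by_chrom.items():
        chrom_rows.sort(key=lambda r: r[1])
        pos = np.array([r[1] for r in chrom_rows], dtype=np.int64)
        vals = np.array([r[3] for r in chrom_rows], dtype=float)
        smoothed = running_median(pos, vals, half_window=half_window, min_probes=min_probes)
        tracks[chrom] = SmoothedTrack(
            chrom=chrom,
            positions=pos,
            values=smoothed,
            half_window=half_window,
            min_probes=min_probes,
            probe_ids=[r[2] for r in chrom_rows],
        )
    return tracks


def track_to_bedgraph(track: SmoothedTrack, span: int = 1) -> str:
    """bedGraph export (0-based half-open) of non-missing smoothed values."""
    lines = []
    for p, v in zip(track.positions, track.values):
        if np.isfinite(v):
            lines.append(f"{track.chrom}\t{p - 1}\t{p - 1 + span}\t{v:.6g}")
    return "\n".join(lines) + ("\n" if lines else "")
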