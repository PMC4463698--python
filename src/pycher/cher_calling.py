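"""ChIP-enriched region (cher) identification from smoothed tracks.

A cher is a maximal stretch of at least ``min_probes`` consecutive probes
whose smoothed value strictly exceeds an enrichment threshold y0; stretches
on the same chromosome separated by less than ``merge_gap`` bp are merged
into one region.  The threshold is the 99th-quantile rule: y0 is the 99th
percentile of the maximum smoothed levels of "potential chers" (candidate
runs above a permissive floor), so that roughly the top 1% of candidate
regions are promoted.  Setting ``floor_quantile=None`` switches to the
simpler reading where y0 is the 99th percentile of all smoothed values.

Each cher carries a score, the sum over its above-threshold probes of
(smoothed value - y0), and the maximum smoothed level in the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import SmoothedTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    """Parameters of the quantile threshold rule."""

    quantile: float = 0.99
    floor_quantile: float | None = 0.5
    min_probes: int = 7
    min_candidates: int = 10  # below this, fall back to the all-values quantile

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValidationError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.floor_quantile is not None and not 0.0 < self.floor_quantile < self.quantile:
            raise ValidationError(
                f"floor_quantile must satisfy 0 < floor < quantile, got {self.floor_quantile}"
            )
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")


@dataclass(frozen=True)
class ThresholdResult:
    y0: float
    n_candidates: int
    used_fallback: bool
    spec: ThresholdSpec


@dataclass
class Cher:
    """A called ChIP-enriched region.

    ``start``/``end`` are the 1-based positions of the first and last probe
    of the region; ``n_probes`` counts the above-threshold probes only
    (merging may span a short below-threshold gap).
    """

    cher_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    max_peak: float
    score: float
    antibody: str = ""
    pool: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.cher_id}: start > end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _finite_runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (i0, i1 inclusive) of consecutive finite values > threshold.

    Missing (NaN) values break a run.
    """
    mask = np.isfinite(values) & (values > threshold)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def candidate_runs(track: SmoothedTrack, floor: float, min_probes: int = 7) -> list[tuple[int, int]]:
    """Candidate regions: runs of >= min_probes consecutive probes above the floor."""
    return [r for r in _finite_runs_above(track.values, floor) if r[1] - r[0] + 1 >= min_probes]


def compute_threshold(
    tracks: SmoothedTrack | list[SmoothedTrack] | dict,
    spec: ThresholdSpec = ThresholdSpec(),
) -> ThresholdResult:
    """Compute the enrichment threshold y0 over one or more smoothed tracks.

    With a floor quantile set, candidate runs above the floor are
    enumerated and y0 is the requested quantile of their maximum smoothed
    levels (linear-interpolation percentile).  With fewer than
    ``spec.min_candidates`` candidates, or with ``floor_quantile=None``,
    y0 is the requested quantile of all non-missing smoothed values.
    """
    if isinstance(tracks, SmoothedTrack):
        tracks = [tracks]
    elif isinstance(tracks, dict):
        tracks = list(tracks.values())
    all_values = np.concatenate([t.values for t in tracks]) if tracks else np.array([])
    finite = all_values[np.isfinite(all_values)]
    if finite.size == 0:
        raise ValidationError("compute_threshold: all smoothed values are missing")
    if finite.size < 100:
        raise ValidationError(
            f"compute_threshold requires >= 100 non-missing smoothed values, got {finite.size}"
        )
    if spec.floor_quantile is None:
        y0 = float(np.percentile(finite, spec.quantile * 100.0))
        return ThresholdResult(y0=y0, n_candidates=0, used_fallback=False, spec=spec)
    floor = float(np.percentile(finite, spec.floor_quantile * 100.0))
    maxima = []
    for track in tracks:
        for i0, i1 in candidate_runs(track, floor, spec.min_probes):
            maxima.append(float(np.nanmax(track.values[i0 : i1 + 1])))
    if len(maxima) < spec.min_candidates:
        logger.warning(
            "compute_threshold: only %d candidate runs (< %d); falling back to "
            "the %.0fth percentile of all smoothed values",
            len(maxima), spec.min_candidates, spec.quantile * 100,
        )
        y0 = float(np.percentile(finite, spec.quantile * 100.0))
        return ThresholdResult(y0=y0, n_candidates=len(maxima), used_fallback=True, spec=spec)
    y0 = float(np.percentile(np.array(maxima), spec.quantile * 100.0))
    return ThresholdResult(y0=y0, n_candidates=len(maxima), used_fallback=False, spec=spec)


def call_chers(
    track: SmoothedTrack,
    y0: float,
    min_probes: int = 7,
    merge_gap: int = 450,
    antibody: str = "",
    pool: str = "",
    id_prefix: str = "cher",
) -> list[Cher]:
    """Call chers on one chromosome track.

    (i) find maximal runs of consecutive probes with smoothed value > y0
    (strictly; ties at y0 are not enriched); (ii) discard runs with fewer
    than ``min_probes`` probes; (iii) merge surviving runs whose bp gap
    (first probe of the next minus last probe of the previous) is less
    than ``merge_gap``; (iv) emit one region per merged group with
    start/end at the first/last probe position.
    """
    if not np.isfinite(y0):
        raise ValidationError("call_chers: y0 must be finite")
    runs = [
        r for r in _finite_runs_above(track.values, y0) if r[1] - r[0] + 1 >= min_probes
    ]
    merged: list[list[tuple[int, int]]] = []
    for run in runs:
        if merged and track.positions[run[0]] - track.positions[merged[-1][-1][1]] < merge_gap:
            merged[-1].append(run)
        else:
            merged.append([run])
    chers = []
    for k, group in enumerate(merged, start=1):
        member_idx = np.concatenate([np.arange(i0, i1 + 1) for i0, i1 in group])
        member_vals = track.values[member_idx]
        score = float(np.sum(member_vals - y0))
        max_peak = float(np.max(member_vals))
        chers.append(
            Cher(
                cher_id=f"{id_prefix}_{track.chrom}_{k}",
                chrom=track.chrom,
                start=int(track.positions[group[0][0]]),
                end=int(track.positions[group[-1][1]]),
                n_probes=int(member_idx.size),
                max_peak=max_peak,
                score=score,
                antibody=antibody,
                pool=pool,
            )
        )
    return chers


def call_chers_all(
    tracks: dict[str, SmoothedTrack],
    y0: float,
    min_probes: int = 7,
    merge_gap: int = 450,
    antibody: str = "",
    pool: str = "",
) -> list[Cher]:
    """Call chers on every chromosome, sorted by (chrom, start)."""
    out: list[Cher] = []
    for chrom in sorted(tracks):
        out.extend(
            call_chers(
                tracks[chrom], y0,
                min_probes=min_probes, merge_gap=merge_gap,
                antibody=antibody, pool=pool,
            )
        )
    return out


def score_cher(cher: Cher, track: SmoothedTrack, y0: float) -> tuple[float, float]:
    """Recompute (score, max_peak) for a region over a track.

    The score sums (smoothed - y0) over the region's above-threshold
    probes; max_peak is the maximum smoothed value over all non-missing
    probes in the span.
    """
    in_span = (track.positions >= cher.start) & (track.positions <= cher.end)
    vals = track.values[in_span]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"{cher.cher_id}: no probes with values in region span")
    members = vals[vals > y0]
    score = float(np.sum(members - y0)) if members.size else 0.0
    return score, float(np.max(vals))


def chers_to_table(chers: list[Cher]) -> pd.DataFrame:
    """Full-precision TSV-ready table (Chr, CHER Start, CHER End, Max Peak, Score...)."""
    return pd.DataFrame(
        {
            "cher_id": [c.cher_id for c in chers],
            "chrom": [c.chrom for c in chers],
            "cher_start": [c.start for c in chers],
            "cher_end": [c.end for c in chers],
            "n_probes": [c.n_probes for c in chers],
            "max_peak": [c.max_peak for c in chers],
            "score": [c.score for c in chers],
            "antibody": [c.antibody for c in chers],
            "pool": [c.pool for c in chers],
        }
    )


def chers_to_bed(chers: list[Cher]) -> str:
    """BED6 export; score = cher score x 100 clamped to [0, 1000]."""
    lines = []
    for c in chers:
        score = int(min(1000, max(0, round(c.score * 100))))
        lines.append(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cher_id}\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
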