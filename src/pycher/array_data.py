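"""Tiling-array probe tables and two-channel intensities.

A ChIP-chip experiment hybridizes immunoprecipitated DNA (Cy5, "IP") and
total input DNA (Cy3, "input") to a promoter tiling array.  This module
reads probe positions and per-channel fluorescence intensities, computes
the per-probe log2 IP/input ratio, and removes reporters that map to more
than one genomic location (non-specific probes).

Coordinates are 1-based inclusive throughout the package; BED exports
convert to 0-based half-open on the way out.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

PROBE_COLUMNS = ["probe_id", "chrom", "start", "length", "n_genomic_hits"]


@dataclass(frozen=True)
class Probe:
    """One tiling reporter with its genomic target location.

    ``n_genomic_hits`` counts how many genomic loci the reporter sequence
    maps to; only probes with a single hit are kept for analysis.
    """

    probe_id: str
    chrom: str
    start: int  # 1-based inclusive
    length: int  # bp
    n_genomic_hits: int = 1

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValidationError("probe_id must be non-empty")
        if self.start < 1:
            raise ValidationError(
                f"probe {self.probe_id}: start must be >= 1 (1-based), got {self.start}"
            )
        if self.length < 1:
            raise ValidationError(f"probe {self.probe_id}: length must be >= 1")
        if self.n_genomic_hits < 1:
            raise ValidationError(f"probe {self.probe_id}: n_genomic_hits must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1

    @property
    def midpoint(self) -> float:
        return self.start + (self.length - 1) / 2.0


@dataclass
class ArrayDataset:
    """Probes plus two-channel intensities for one antibody/pool experiment.

    ``intensities`` is indexed by probe_id with columns ``ip_signal``,
    ``input_signal`` and ``log_ratio``.
    """

    probes: list[Probe]
    intensities: pd.DataFrame
    antibody: str = ""
    pool: str = ""

    def __post_init__(self) -> None:
        known = {p.probe_id for p in self.probes}
        unknown = set(self.intensities.index) - known
        if unknown:
            raise ValidationError(
                f"{len(unknown)} intensity rows reference unknown probes "
                f"(e.g. {sorted(unknown)[:3]})"
            )


def read_probe_table(path) -> list[Probe]:
    """Read a tab-separated probe table.

    Expected header columns: probe_id, chrom, start, length and optionally
    n_genomic_hits (default 1).  Rows that duplicate an earlier row exactly
    collapse to one; rows that reuse a (probe_id, chrom, start) key with
    different content are rejected.  Returns probes sorted by (chrom, start).
    """
    probes: dict[tuple, Probe] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        required = ["probe_id", "chrom", "start", "length"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        col = {name: header.index(name) for name in header}
        has_hits = "n_genomic_hits" in col
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                probe = Probe(
                    probe_id=row[col["probe_id"]].strip(),
                    chrom=row[col["chrom"]].strip(),
                    start=int(row[col["start"]]),
                    length=int(row[col["length"]]),
                    n_genomic_hits=int(row[col["n_genomic_hits"]]) if has_hits else 1,
                )
            except ValidationError:
                raise
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            key = (probe.probe_id, probe.chrom, probe.start)
            if key in probes:
                if probes[key] != probe:
                    raise ValidationError(
                        f"{path}: line {lineno}: conflicting duplicate for probe key {key}"
                    )
                continue
            probes[key] = probe
    return sorted(probes.values(), key=lambda p: (p.chrom, p.start, p.probe_id))


def write_probe_table(probes: list[Probe], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROBE_COLUMNS)
        for p in probes:
            writer.writerow([p.probe_id, p.chrom, p.start, p.length, p.n_genomic_hits])


def apply_coordinate_map(probes: list[Probe], mapping: dict[int, int] | str) -> tuple[list[Probe], int]:
    """Lift probe start coordinates through an old->new position table.

    ``mapping`` is either a dict or the path of a two-column TSV
    (old_start, new_start), applied per probe start.  Probes without a
    mapping are dropped; the second return value counts them.
    """
    if not isinstance(mapping, dict):
        table = pd.read_csv(mapping, sep="\t", header=None, names=["old", "new"])
        mapping = dict(zip(table["old"].astype(int), table["new"].astype(int)))
    kept, dropped = [], 0
    for p in probes:
        if p.start in mapping:
            kept.append(replace(p, start=int(mapping[p.start])))
        else:
            dropped += 1
    return kept, dropped


def read_intensity_table(path) -> pd.Series:
    """Read a two-column TSV (probe_id, signal) into a Series."""
    table = pd.read_csv(path, sep="\t")
    if not {"probe_id", "signal"}.issubset(table.columns):
        raise ParseError(f"{path}: expected columns probe_id, signal")
    return pd.Series(table["signal"].to_numpy(float), index=table["probe_id"], name="signal")


def compute_log_ratios(ip: pd.Series, input_: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Compute per-probe log2(IP/input) ratios.

    Probes missing either channel are dropped and counted in the report.
    Non-positive signals on shared probes raise a :class:`ValidationError`
    naming the probe.
    """
    ip = pd.Series(ip)
    input_ = pd.Series(input_)
    shared = ip.index.intersection(input_.index)
    dropped = len(ip.index.symmetric_difference(input_.index))
    ip_v = ip.loc[shared].to_numpy(float)
    in_v = input_.loc[shared].to_numpy(float)
    bad = (ip_v <= 0) | (in_v <= 0) | ~np.isfinite(ip_v) | ~np.isfinite(in_v)
    if bad.any():
        first = shared[int(np.flatnonzero(bad)[0])]
        raise ValidationError(f"non-positive or non-finite signal for probe {first}")
    frame = pd.DataFrame(
        {
            "ip_signal": ip_v,
            "input_signal": in_v,
            # log2(ip) - log2(input): exactly antisymmetric under channel swap
            "log_ratio": np.log2(ip_v) - np.log2(in_v),
        },
        index=shared,
    )
    frame.index.name = "probe_id"
    report = {"n_shared": len(shared), "n_dropped_missing_channel": dropped}
    return frame, report


def filter_unique_probes(probes: list[Probe]) -> tuple[list[Probe], int, float]:
    """Keep only uniquely mapping probes (n_genomic_hits == 1).

    Returns (kept, removed_count, removed_fraction); the fraction is 0 for
    empty input.
    """
    kept = [p for p in probes if p.n_genomic_hits == 1]
    removed = len(probes) - len(kept)
    fraction = removed / len(probes) if probes else 0.0
    return kept, removed, fraction


def probes_to_bed(probes: list[Probe], log_ratios: pd.Series | None = None) -> str:
    """BED6 export of probe positions.

    BED is 0-based half-open; the score column is log_ratio x 1000 clamped
    to [0, 1000] (full precision lives in the TSV exports, not in BED).
    """
    lines = []
    for p in probes:
        if log_ratios is not None and p.probe_id in log_ratios.index:
            score = int(min(1000, max(0, round(float(log_ratios[p.probe_id]) * 1000))))
        else:
            score = 0
        lines.append(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.probe_id}\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
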