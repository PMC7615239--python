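"""narrowPeak / BED peak records and the significance post-filter.

Peaks arrive from a caller such as MACS3 (narrowPeak = ENCODE BED6+4).
Peak calling itself is upstream of this package; here peaks are parsed,
validated, and put through the downstream significance filter that keeps
only highly significant peaks (Q-value <= 1e-10 by default, i.e.
-log10 Q >= 10, threshold inclusive) before consensus building.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomeAssembly, GInterval, sort_key, validate_bounds

STRANDS = {"+", "-", "."}

#: default -log10(Q) cutoff: Q <= 1e-10
DEFAULT_MIN_NEGLOG10_Q = 10.0


class PeakParseError(ValueError):
    pass


class MissingQValueError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record.

    ``summit_offset`` is the summit position relative to ``region.start``,
    or -1 for "unknown" (plain BED input); ``p`` and ``q`` are -log10
    transformed, with -1 meaning missing per narrowPeak convention.
    """

    region: GInterval
    name: str = "."
    score: int = 0
    strand: str = "."
    signal: float = 0.0
    p: float = -1.0
    q: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"peak {self.name!r}: bad strand {self.strand!r}")
        if not (-1 <= self.summit_offset < len(self.region)):
            raise ValueError(
                f"peak {self.name!r}: summit offset {self.summit_offset} outside "
                f"peak of length {len(self.region)}"
            )
        for label, v in (("p", self.p), ("q", self.q)):
            if v < 0 and v != -1:
                raise ValueError(f"peak {self.name!r}: negative -log10 {label}-value {v}")


@dataclass
class PeakSet:
    """A replicate-labelled collection of peaks, kept position-sorted."""

    peaks: list[Peak]
    factor: str = ""
    condition: str = ""
    replicate: str = ""
    assembly: GenomeAssembly | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: sort_key(self.assembly)(p.region))
        if self.assembly is not None:
            for p in self.peaks:
                validate_bounds(p.region, self.assembly, f"peak {p.name!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "PeakSet":
        return PeakSet(
            list(peaks),
            factor=self.factor,
            condition=self.condition,
            replicate=self.replicate,
            assembly=self.assembly,
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_narrowpeak(
    path: str | Path,
    factor: str = "",
    condition: str = "",
    replicate: str = "",
    assembly: GenomeAssembly | None = None,
) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file into a PeakSet.

    Lines must carry >= 10 tab-separated columns; the 10th is the summit
    offset from the peak start.  Files may be gzip-compressed.  Malformed
    lines raise :class:`PeakParseError` with the line number.
    """
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise PeakParseError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(cols)}"
                )
            try:
                region = GInterval(cols[0], int(cols[1]), int(cols[2]))
                peak = Peak(
                    region=region,
                    name=cols[3],
                    score=int(cols[4]),
                    strand=cols[5],
                    signal=float(cols[6]),
                    p=float(cols[7]),
                    q=float(cols[8]),
                    summit_offset=int(cols[9]),
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return PeakSet(peaks, factor=factor, condition=condition, replicate=replicate, assembly=assembly)


def format_narrowpeak_line(p: Peak) -> str:
    def num(x: float) -> str:
        return f"{x:g}"

    return "\t".join(
        [
            p.region.chrom,
            str(p.region.start),
            str(p.region.end),
            p.name,
            str(p.score),
            p.strand,
            num(p.signal),
            num(p.p),
            num(p.q),
            str(p.summit_offset),
        ]
    )


def write_narrowpeak(ps: PeakSet | Sequence[Peak], path: str | Path) -> None:
    peaks = ps.peaks if isinstance(ps, PeakSet) else ps
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(format_narrowpeak_line(p) + "\n")


def filter_by_q(ps: PeakSet, min_neglog10_q: float = DEFAULT_MIN_NEGLOG10_Q) -> PeakSet:
    """Keep peaks with -log10(Q) >= threshold (inclusive); order preserved.

    At the default of 10 this retains peaks with Q <= 1e-10.  Peaks with
    missing Q (-1) are rejected: the filter requires called Q-values.
    """
    for p in ps:
        if p.q == -1:
            raise MissingQValueError(
                f"peak {p.name!r} has no Q-value (-1); supply peaks with called "
                "Q-values (e.g. MACS3 narrowPeak output) before filtering"
            )
    return ps.with_peaks(p for p in ps if p.q >= min_neglog10_q)


def summit_position(p: Peak) -> tuple[str, int]:
    """Absolute summit coordinate (chrom, bp).

    Falls back to the integer midpoint floor((start+end)/2) when the summit
    offset is unknown (-1), so plain BED peaks remain usable.
    """
    if p.summit_offset >= 0:
        return p.region.chrom, p.region.start + p.summit_offset
    return p.region.chrom, (p.region.start + p.region.end) // 2
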