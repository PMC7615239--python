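"""Gene models: GFF3 parsing, strand-aware TSS/TTS, assignment windows.

Gene-level records only — transcript/exon structure is out of scope
because peaks are assigned to genes, not isoforms.  GFF3 coordinates
(1-based, inclusive) are converted to the package's 0-based half-open
convention on read and back on write.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomeAssembly, GInterval, sort_key, validate_bounds


class GFF3ParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    region: GInterval
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")


@dataclass
class GeneSet:
    """Position-sorted genes bound to an assembly."""

    genes: list[GeneModel]
    assembly: GenomeAssembly | None = None

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise GFF3ParseError(f"duplicate gene IDs: {sorted(dupes)}")
        self.genes = sorted(self.genes, key=lambda g: sort_key(self.assembly)(g.region))
        if self.assembly is not None:
            for g in self.genes:
                validate_bounds(g.region, self.assembly, f"gene {g.gene_id!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3_genes(
    path: str | Path,
    feature_type: str = "gene",
    assembly: GenomeAssembly | None = None,
) -> GeneSet:
    """Read gene-level records from a GFF3 file.

    Only rows whose type column equals ``feature_type`` become genes; any
    child features (mRNA, exon, ...) are ignored.  Each record must carry
    an ``ID`` attribute and a definite strand.  1-based inclusive spans
    become 0-based half-open.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != feature_type:
                continue
            try:
                attrs = _parse_attributes(cols[8])
            except ValueError as exc:
                raise GFF3ParseError(f"{path}:{lineno}: {exc}") from exc
            if "ID" not in attrs:
                raise GFF3ParseError(f"{path}:{lineno}: {feature_type} record lacks ID attribute")
            strand = cols[6]
            if strand not in ("+", "-"):
                raise GFF3ParseError(
                    f"{path}:{lineno}: gene {attrs['ID']!r} has strand {strand!r}; "
                    "a definite + or - strand is required"
                )
            start1, end1 = int(cols[3]), int(cols[4])
            if start1 < 1 or end1 < start1:
                raise GFF3ParseError(f"{path}:{lineno}: bad span {start1}..{end1}")
            genes.append(GeneModel(attrs["ID"], GInterval(cols[0], start1 - 1, end1), strand))
    return GeneSet(genes, assembly=assembly)


def write_gff3_genes(gs: GeneSet, path: str | Path, source: str = "chipmeta") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in gs:
            fh.write(
                "\t".join(
                    [
                        g.region.chrom,
                        source,
                        "gene",
                        str(g.region.start + 1),
                        str(g.region.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_bed6_genes(gs: GeneSet, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in gs:
            fh.write(
                f"{g.region.chrom}\t{g.region.start}\t{g.region.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_bed6_genes(path: str | Path, assembly: GenomeAssembly | None = None) -> GeneSet:
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise GFF3ParseError(f"{path}:{lineno}: BED6 needs 6 columns")
            genes.append(GeneModel(cols[3], GInterval(cols[0], int(cols[1]), int(cols[2])), cols[5]))
    return GeneSet(genes, assembly=assembly)


def tss_tts(g: GeneModel) -> tuple[int, int]:
    """Strand-aware (TSS, TTS) base positions.

    On + the TSS is the first base of the span and the TTS the last; on -
    they swap.  Both always lie inside the gene region.
    """
    if g.strand == "+":
        return g.region.start, g.region.end - 1
    return g.region.end - 1, g.region.start


def assignment_window(
    g: GeneModel,
    flank: int = 1000,
    assembly: GenomeAssembly | None = None,
) -> GInterval:
    """The summit-assignment window: gene body extended by ``flank`` bp.

    Because the upstream-of-TSS and downstream-of-TTS flanks are equal the
    window is strand-independent: [start - flank, end + flank), clipped to
    chromosome bounds when an assembly is given.  A summit exactly
    ``flank`` bp upstream of the TSS is inside (inclusive boundary).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(0, g.region.start - flank)
    end = g.region.end + flank
    if assembly is not None:
        end = min(end, assembly.length(g.region.chrom))
    return GInterval(g.region.chrom, start, end)
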