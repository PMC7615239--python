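"""Config-driven orchestration: filter -> consensus -> assign -> overlap -> metagene.

A run is a pure function of (input files, config): outputs are written with
fixed formatting and iteration order, so re-running on identical inputs is
bit-identical.  The manifest records a config hash and per-stage record
counts (no timestamps, no absolute paths).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotation import GeneSet, read_gff3_genes
from .assign import assign_peaks, assignments_to_tsv, target_gene_table
from .consensus import build_consensus, consensus_to_bed
from .cooccupancy import multiway_cooccupancy, pairwise_overlap_matrix
from .intervals import GenomeAssembly
from .metagene import (
    mean_profile,
    merge_tracks,
    metagene_matrix,
    read_bedgraph,
    rpgc_normalize,
)
from .peaks import filter_by_q, read_narrowpeak, write_narrowpeak

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SampleFile:
    factor: str
    condition: str
    replicate: str
    path: Path


@dataclass
class RunConfig:
    genome: Path
    annotation: Path
    peaks: list[SampleFile]
    coverage: list[SampleFile] = field(default_factory=list)
    outdir: Path = Path("chipmeta_out")
    min_neglog10_q: float = 10.0
    min_support: int = 2
    flank: int = 1000
    metagene_flank: int = 1000
    body_bins: int = 100
    flank_bins: int = 20

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        def samples(key: str) -> list[SampleFile]:
            out = []
            for row in raw.get(key, []):
                out.append(
                    SampleFile(
                        factor=row["factor"],
                        condition=row["condition"],
                        replicate=row.get("replicate", "rep1"),
                        path=resolve(row["path"]),
                    )
                )
            return out

        thresholds = raw.get("thresholds", {})
        cfg = cls(
            genome=resolve(raw["genome"]),
            annotation=resolve(raw["annotation"]),
            peaks=samples("peaks"),
            coverage=samples("coverage"),
            outdir=resolve(raw.get("outdir", "chipmeta_out")),
            min_neglog10_q=float(thresholds.get("min_neglog10_q", 10.0)),
            min_support=int(thresholds.get("min_support", 2)),
            flank=int(thresholds.get("flank", 1000)),
            metagene_flank=int(thresholds.get("metagene_flank", 1000)),
            body_bins=int(thresholds.get("body_bins", 100)),
            flank_bins=int(thresholds.get("flank_bins", 20)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.peaks:
            raise ValueError("config lists no peak files")
        missing = [
            str(s.path)
            for s in [*self.peaks, *self.coverage]
            if not Path(s.path).exists()
        ] + [str(p) for p in (self.genome, self.annotation) if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def hash(self) -> str:
        payload = {
            "genome": self.genome.name,
            "annotation": self.annotation.name,
            "peaks": [
                [s.factor, s.condition, s.replicate, s.path.name] for s in self.peaks
            ],
            "coverage": [
                [s.factor, s.condition, s.replicate, s.path.name] for s in self.coverage
            ],
            "min_neglog10_q": self.min_neglog10_q,
            "min_support": self.min_support,
            "flank": self.flank,
            "metagene_flank": self.metagene_flank,
            "body_bins": self.body_bins,
            "flank_bins": self.flank_bins,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            pairs.append((name, int(length)))
    return GenomeAssembly.from_pairs(pairs)


def _groups(samples: Sequence[SampleFile]) -> list[tuple[str, str]]:
    """(factor, condition) pairs in first-appearance order."""
    seen: list[tuple[str, str]] = []
    for s in samples:
        key = (s.factor, s.condition)
        if key not in seen:
            seen.append(key)
    return seen


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Stage order mirrors the analysis: significance filter, replicate
    consensus, summit-to-gene assignment, target table, co-occupancy
    matrices per condition, and (when coverage is supplied) replicate-
    merged RPGC metagene profiles.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    stale.write_text("run in progress; outputs incomplete\n")
    counts: dict[str, int] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineStageError(f"stage {name}: {exc}") from exc

        return deco

    @stage("load")
    def loaded():
        assembly = read_chrom_sizes(cfg.genome)
        genes = read_gff3_genes(cfg.annotation, assembly=assembly)
        return assembly, genes

    assembly, genes = loaded
    counts["genes"] = len(genes)

    @stage("filter")
    def filtered():
        res = {}
        for s in cfg.peaks:
            ps = read_narrowpeak(
                s.path,
                factor=s.factor,
                condition=s.condition,
                replicate=s.replicate,
                assembly=assembly,
            )
            kept = filter_by_q(ps, cfg.min_neglog10_q)
            write_narrowpeak(
                kept, out / f"filtered_{s.factor}_{s.condition}_{s.replicate}.narrowPeak"
            )
            res.setdefault((s.factor, s.condition), []).append(kept)
        return res

    counts["filtered_peaks"] = sum(len(ps) for reps in filtered.values() for ps in reps)

    @stage("consensus")
    def consensus():
        res = {}
        for key in _groups(cfg.peaks):
            cps = build_consensus(filtered[key], min_support=cfg.min_support, assembly=assembly)
            consensus_to_bed(cps, out / f"consensus_{key[0]}_{key[1]}.bed")
            res[key] = cps
        return res

    counts["consensus_peaks"] = sum(len(v) for v in consensus.values())

    @stage("assign")
    def assigned():
        res = {}
        for (factor, condition), cps in consensus.items():
            a = assign_peaks(cps, genes, flank=cfg.flank)
            assignments_to_tsv(a, out / f"assignments_{factor}_{condition}.tsv")
            res[(factor, condition)] = a
        return res

    @stage("table")
    def table():
        df = target_gene_table(assigned)
        df.to_csv(out / "target_gene_table.tsv", sep="\t", index=False)
        return df

    counts["target_genes"] = int(table["n_genes"].sum())

    @stage("overlap")
    def overlap_done():
        conditions = []
        for _, c in _groups(cfg.peaks):
            if c not in conditions:
                conditions.append(c)
        n = 0
        for condition in conditions:
            keys = [k for k in consensus if k[1] == condition]
            if len(keys) < 2:
                continue
            sets = [consensus[k] for k in keys]
            labels = [k[0] for k in keys]
            mat = pairwise_overlap_matrix(sets, labels=labels)
            mat.to_tsv(out / f"overlap_matrix_{condition}.tsv")
            combos = multiway_cooccupancy(sets, labels=labels, reference=0)
            combos.to_csv(out / f"cooccupancy_{condition}.tsv", sep="\t", index=False)
            n += 1
        return n

    counts["overlap_matrices"] = overlap_done

    @stage("metagene")
    def metagene_done():
        if not cfg.coverage:
            log.info("no coverage files in config; metagene stage skipped")
            return 0
        n = 0
        for key in _groups(cfg.coverage):
            files = [s for s in cfg.coverage if (s.factor, s.condition) == key]
            raw = merge_tracks([read_bedgraph(s.path, assembly=assembly) for s in files])
            track = rpgc_normalize(raw, assembly=assembly)
            matrix, _ = metagene_matrix(
                track,
                genes,
                flank=cfg.metagene_flank,
                body_bins=cfg.body_bins,
                flank_bins=cfg.flank_bins,
            )
            profile = mean_profile(matrix, flank_bins=cfg.flank_bins, body_bins=cfg.body_bins)
            profile.to_tsv(out / f"metagene_{key[0]}_{key[1]}.tsv")
            n += 1
        return n

    counts["metagene_profiles"] = metagene_done

    manifest = {
        "package": "chipmeta",
        "version": __version__,
        "config_hash": cfg.hash(),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    stale.unlink()
    return out
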