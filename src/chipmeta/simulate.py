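"""Synthetic genomes, annotations, replicate peak sets and coverage tracks.

The generator plants a known truth — latent binding sites per factor and
condition — and realizes noisy observables from it, so every downstream
stage (filtering, consensus, assignment, co-occupancy, metagene) can be
checked against planted values:

* genes are placed non-overlapping with a guaranteed spacing, so summit-
  to-gene assignment is unambiguous by construction;
* each latent site anchors at a gene TSS, slightly downstream of a gene
  TTS, or in safe intergenic space, drawn from a positional mixture — the
  TSS-heavy mixture with a minor TTS mode mirrors how PRC2-accessory
  binding distributes along transcription units;
* inter-factor sharing: a fraction pi of a non-reference factor's sites
  are jittered copies of reference-factor sites; the remaining sites are
  drawn from anchors the reference factor does not use, so the planted
  overlap fraction is exactly pi and measured co-occupancy deviates from
  100*pi by binomial noise only;
* each replicate realizes each site independently with probability r
  (reproducibility), so consensus recovery follows a Binomial(R, r) tail;
* -log10 Q values are drawn so a configurable fraction of peaks falls
  below the significance cutoff;
* coverage is a uniform background plus Gaussian bumps at realized
  summits; matched input controls carry background only.

One pseudorandom stream per run, seeded from the config: the same seed
reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet, tss_tts, write_gff3_genes
from .intervals import GenomeAssembly, GInterval, merge_intervals
from .peaks import Peak, PeakSet, summit_position, write_narrowpeak


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a compact two-chromosome genome with vernalization-
    style conditions: a nonvernalized state (``NV``) with few sites and a
    post-cold state (``6WT0``) where the same factors occupy many more
    sites.  ``sharing`` is the probability that a site of a non-reference
    factor coincides with a reference-factor site; ``reproducibility`` is
    the probability that a given replicate yields a peak at a site.
    """

    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (800, 2500)
    gene_spacing: int = 4000
    factors: tuple[str, ...] = ("VEL1", "VIN3", "VRN5")
    conditions: tuple[str, ...] = ("NV", "6WT0")
    n_sites: Mapping[str, int] | int = field(
        default_factory=lambda: {"NV": 120, "6WT0": 250}
    )
    n_replicates: int = 3
    sharing: float = 0.8
    reproducibility: float = 0.8
    peak_width: tuple[int, int] = (200, 500)
    p_tss: float = 0.6
    p_tts: float = 0.25
    p_intergenic: float = 0.15
    jitter_sigma: float = 100.0
    tts_offset: int = 200
    copy_jitter_sigma: float = 50.0
    q_range: tuple[float, float] = (10.5, 40.0)
    weak_q_fraction: float = 0.2
    weak_q_range: tuple[float, float] = (2.0, 10.0)
    background: float = 1.0
    enrichment_amplitude: float = 8.0
    enrichment_sigma: float = 200.0
    coverage_step: int = 10

    def __post_init__(self) -> None:
        probs = (self.p_tss, self.p_tts, self.p_intergenic)
        if any(not (0.0 <= p <= 1.0) for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("p_tss + p_tts + p_intergenic must be 1 with each in [0,1]")
        for name in ("sharing", "reproducibility", "weak_q_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("gene_length", "peak_width", "q_range", "weak_q_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.n_chroms < 1 or self.chrom_length < 1 or self.n_genes < 1:
            raise ValueError("n_chroms, chrom_length, n_genes must be positive")

    def sites_for(self, condition: str) -> int:
        if isinstance(self.n_sites, int):
            return self.n_sites
        return self.n_sites[condition]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, GeneSet]:
    """Place non-overlapping genes with at least ``gene_spacing`` bp between them."""
    rng = rng or np.random.default_rng(cfg.seed)
    assembly = GenomeAssembly.from_pairs(
        (f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chroms)
    )
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for ci, (chrom, clen) in enumerate(assembly.chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1, size=n)
        required = int(lengths.sum()) + (n + 1) * cfg.gene_spacing
        if required > clen:
            raise ValueError(
                f"cannot place {n} genes of total {int(lengths.sum())} bp with "
                f"{cfg.gene_spacing} bp spacing on a {clen} bp chromosome; "
                "reduce n_genes/gene_length or increase chrom_length"
            )
        extra = clen - required
        gaps = cfg.gene_spacing + rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(lengths[k])
            pos = end
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{gid:05d}", GInterval(chrom, start, end), strand))
    return assembly, GeneSet(genes, assembly=assembly)


def _safe_intergenic_regions(
    assembly: GenomeAssembly, genes: GeneSet, clearance: int
) -> list[GInterval]:
    """Intergenic intervals at least ``clearance`` bp from every gene body."""
    blocked = merge_intervals(
        [
            GInterval(
                g.region.chrom,
                max(0, g.region.start - clearance),
                min(assembly.length(g.region.chrom), g.region.end + clearance),
            )
            for g in genes
        ],
        assembly=assembly,
    )
    by_chrom: dict[str, list[GInterval]] = {}
    for b in blocked:
        by_chrom.setdefault(b.chrom, []).append(b)
    free: list[GInterval] = []
    for chrom, clen in assembly.chroms:
        pos = 0
        for b in by_chrom.get(chrom, []):
            if b.start > pos:
                free.append(GInterval(chrom, pos, b.start))
            pos = b.end
        if pos < clen:
            free.append(GInterval(chrom, pos, clen))
    return free


@dataclass(frozen=True)
class PlantedSite:
    site_id: str
    factor: str
    condition: str
    chrom: str
    summit: int
    gene_id: str | None  # owning gene for TSS/TTS-anchored sites
    mode: str  # tss | tts | intergenic
    shared_with_reference: bool


def _clamp(x: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, x))


def _draw_reference_sites(
    cfg: SimulationConfig,
    condition: str,
    assembly: GenomeAssembly,
    genes: GeneSet,
    rng: np.random.Generator,
) -> list[PlantedSite]:
    n = cfg.sites_for(condition)
    modes = rng.choice(
        ["tss", "tts", "intergenic"], size=n, p=[cfg.p_tss, cfg.p_tts, cfg.p_intergenic]
    )
    n_genic = int(np.sum(modes != "intergenic"))
    if n_genic > len(genes):
        raise ValueError(
            f"{n_genic} genic sites requested but only {len(genes)} genes available; "
            "increase n_genes or reduce n_sites"
        )
    anchor_idx = rng.choice(len(genes), size=n_genic, replace=False)
    free = _safe_intergenic_regions(assembly, genes, clearance=1000 + cfg.peak_width[1])
    free_lens = np.array([len(f) for f in free], dtype=np.float64)
    sites: list[PlantedSite] = []
    gi = 0
    factor = cfg.factors[0]
    for k, mode in enumerate(modes):
        if mode == "intergenic":
            if not free:
                raise ValueError("no safe intergenic space; increase gene_spacing")
            region = free[rng.choice(len(free), p=free_lens / free_lens.sum())]
            chrom = region.chrom
            summit = int(rng.integers(region.start, region.end))
            gene_id = None
        else:
            g = genes.genes[anchor_idx[gi]]
            gi += 1
            chrom = g.region.chrom
            tss, tts = tss_tts(g)
            jit = int(round(rng.normal(0.0, cfg.jitter_sigma)))
            if mode == "tss":
                summit = tss + jit
            else:
                sign = 1 if g.strand == "+" else -1
                summit = tts + sign * cfg.tts_offset + jit
            summit = _clamp(summit, 0, assembly.length(chrom) - 1)
            gene_id = g.gene_id
        sites.append(
            PlantedSite(
                site_id=f"{factor}_{condition}_s{k:04d}",
                factor=factor,
                condition=condition,
                chrom=chrom,
                summit=summit,
                gene_id=gene_id,
                mode=str(mode),
                shared_with_reference=False,
            )
        )
    return sites


def _draw_dependent_sites(
    cfg: SimulationConfig,
    factor: str,
    condition: str,
    reference: list[PlantedSite],
    assembly: GenomeAssembly,
    genes: GeneSet,
    rng: np.random.Generator,
) -> list[PlantedSite]:
    """Sites of a non-reference factor: Bernoulli(pi) copies of reference sites,
    the rest drawn from anchors the reference factor does not occupy."""
    n = cfg.sites_for(condition)
    shared_flags = rng.random(n) < cfg.sharing
    n_shared = int(shared_flags.sum())
    if n_shared > len(reference):
        raise ValueError("more shared sites requested than reference sites exist")
    copy_idx = rng.choice(len(reference), size=n_shared, replace=False)

    ref_gene_ids = {s.gene_id for s in reference if s.gene_id is not None}
    fresh_genes = [g for g in genes if g.gene_id not in ref_gene_ids]
    ref_summits_by_chrom: dict[str, list[int]] = {}
    for s in reference:
        ref_summits_by_chrom.setdefault(s.chrom, []).append(s.summit)

    n_fresh = n - n_shared
    fresh_modes = rng.choice(
        ["tss", "tts", "intergenic"],
        size=n_fresh,
        p=[cfg.p_tss, cfg.p_tts, cfg.p_intergenic],
    )
    n_genic = int(np.sum(fresh_modes != "intergenic"))
    if n_genic > len(fresh_genes):
        raise ValueError(
            f"factor {factor}: {n_genic} fresh genic sites but only {len(fresh_genes)} "
            "genes unoccupied by the reference factor; increase n_genes"
        )
    fresh_anchor_idx = rng.choice(len(fresh_genes), size=n_genic, replace=False)
    free = _safe_intergenic_regions(assembly, genes, clearance=1000 + cfg.peak_width[1])
    free_lens = np.array([len(f) for f in free], dtype=np.float64)

    sites: list[PlantedSite] = []
    ci = 0
    gi = 0
    fi = 0
    min_sep = 2 * cfg.peak_width[1]
    for k in range(n):
        if shared_flags[k]:
            src = reference[copy_idx[ci]]
            ci += 1
            jit = int(round(rng.normal(0.0, cfg.copy_jitter_sigma)))
            summit = _clamp(src.summit + jit, 0, assembly.length(src.chrom) - 1)
            sites.append(
                PlantedSite(
                    site_id=f"{factor}_{condition}_s{k:04d}",
                    factor=factor,
                    condition=condition,
                    chrom=src.chrom,
                    summit=summit,
                    gene_id=src.gene_id,
                    mode=src.mode,
                    shared_with_reference=True,
                )
            )
            continue
        mode = fresh_modes[fi]
        fi += 1
        if mode == "intergenic":
            if not free:
                raise ValueError("no safe intergenic space; increase gene_spacing")
            # keep clear of reference intergenic sites so the planted
            # sharing fraction stays exact
            for _ in range(100):
                region = free[rng.choice(len(free), p=free_lens / free_lens.sum())]
                chrom = region.chrom
                summit = int(rng.integers(region.start, region.end))
                near = ref_summits_by_chrom.get(chrom, [])
                if all(abs(summit - r) >= min_sep for r in near):
                    break
            else:
                raise ValueError("could not place a non-shared intergenic site")
            gene_id = None
        else:
            g = fresh_genes[fresh_anchor_idx[gi]]
            gi += 1
            chrom = g.region.chrom
            tss, tts = tss_tts(g)
            jit = int(round(rng.normal(0.0, cfg.jitter_sigma)))
            if mode == "tss":
                summit = tss + jit
            else:
                sign = 1 if g.strand == "+" else -1
                summit = tts + sign * cfg.tts_offset + jit
            summit = _clamp(summit, 0, assembly.length(chrom) - 1)
            gene_id = g.gene_id
        sites.append(
            PlantedSite(
                site_id=f"{factor}_{condition}_s{k:04d}",
                factor=factor,
                condition=condition,
                chrom=chrom,
                summit=summit,
                gene_id=gene_id,
                mode=str(mode),
                shared_with_reference=False,
            )
        )
    return sites


def simulate_peaks(
    cfg: SimulationConfig,
    assembly: GenomeAssembly,
    genes: GeneSet,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], list[PeakSet]], pd.DataFrame]:
    """Latent sites per factor/condition, realized as replicate PeakSets.

    Returns (replicate PeakSets keyed by (factor, condition), truth table).
    The truth table has one row per planted site with its position, owning
    gene (NA for intergenic), mode and sharing flag.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    all_sites: dict[tuple[str, str], list[PlantedSite]] = {}
    for condition in cfg.conditions:
        reference = _draw_reference_sites(cfg, condition, assembly, genes, rng)
        all_sites[(cfg.factors[0], condition)] = reference
        for factor in cfg.factors[1:]:
            all_sites[(factor, condition)] = _draw_dependent_sites(
                cfg, factor, condition, reference, assembly, genes, rng
            )

    peaksets: dict[tuple[str, str], list[PeakSet]] = {}
    for (factor, condition), sites in all_sites.items():
        reps: list[PeakSet] = []
        for r in range(1, cfg.n_replicates + 1):
            peaks: list[Peak] = []
            for s in sites:
                if rng.random() >= cfg.reproducibility:
                    continue
                width = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
                clen = assembly.length(s.chrom)
                start = _clamp(s.summit - width // 2, 0, clen - width)
                end = start + width
                if rng.random() < cfg.weak_q_fraction:
                    q = float(rng.uniform(*cfg.weak_q_range))
                else:
                    q = float(rng.uniform(*cfg.q_range))
                p = q + float(rng.uniform(0.0, 5.0))
                peaks.append(
                    Peak(
                        region=GInterval(s.chrom, start, end),
                        name=f"{s.site_id}_rep{r}",
                        score=min(1000, int(10 * q)),
                        strand=".",
                        signal=round(q / 2.0, 3),
                        p=round(p, 3),
                        q=round(q, 3),
                        summit_offset=s.summit - start,
                    )
                )
            reps.append(
                PeakSet(
                    peaks,
                    factor=factor,
                    condition=condition,
                    replicate=f"rep{r}",
                    assembly=assembly,
                )
            )
        peaksets[(factor, condition)] = reps

    truth = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "factor": s.factor,
                "condition": s.condition,
                "chrom": s.chrom,
                "summit": s.summit,
                "gene_id": s.gene_id if s.gene_id is not None else "NA",
                "mode": s.mode,
                "shared_with_reference": int(s.shared_with_reference),
            }
            for sites in all_sites.values()
            for s in sites
        ],
        columns=[
            "site_id",
            "factor",
            "condition",
            "chrom",
            "summit",
            "gene_id",
            "mode",
            "shared_with_reference",
        ],
    )
    return peaksets, truth


def gaussian_bump_track(
    assembly: GenomeAssembly,
    summits: Sequence[tuple[str, int]],
    background: float,
    amplitude: float,
    sigma: float,
    step: int,
) -> "CoverageTrack":
    """Uniform background plus Gaussian enrichment bumps at summit positions.

    Bumps are discretized at ``step`` bp resolution out to 4 sigma; the rest
    of the genome is a single background step per chromosome.
    """
    from .metagene import CoverageTrack

    reach = int(np.ceil(4.0 * sigma))
    by_chrom: dict[str, list[int]] = {c: [] for c, _ in assembly.chroms}
    for chrom, summit in summits:
        by_chrom[chrom].append(summit)
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, clen in assembly.chroms:
        mus = np.array(sorted(by_chrom[chrom]), dtype=np.float64)
        windows = (
            merge_intervals(
                [
                    GInterval(chrom, max(0, int(m) - reach), min(clen, int(m) + reach))
                    for m in mus
                ]
            )
            if len(mus)
            else []
        )
        s_list: list[np.ndarray] = []
        e_list: list[np.ndarray] = []
        v_list: list[np.ndarray] = []
        pos = 0
        for w in windows:
            if w.start > pos:
                s_list.append(np.array([pos]))
                e_list.append(np.array([w.start]))
                v_list.append(np.array([background]))
            edges = np.arange(w.start, w.end + step, step, dtype=np.int64)
            edges[-1] = min(edges[-1], clen)
            edges = edges[edges <= w.end] if edges[-1] > w.end else edges
            if edges[-1] < w.end:
                edges = np.append(edges, w.end)
            starts = edges[:-1]
            ends = edges[1:]
            mids = (starts + ends) / 2.0
            vals = np.full(len(mids), background, dtype=np.float64)
            for m in mus:
                if w.start - reach <= m <= w.end + reach:
                    vals += amplitude * np.exp(-((mids - m) ** 2) / (2.0 * sigma**2))
            s_list.append(starts)
            e_list.append(ends)
            v_list.append(np.round(vals, 6))
            pos = w.end
        if pos < clen:
            s_list.append(np.array([pos]))
            e_list.append(np.array([clen]))
            v_list.append(np.array([background]))
        steps[chrom] = (
            np.concatenate(s_list).astype(np.int64),
            np.concatenate(e_list).astype(np.int64),
            np.concatenate(v_list).astype(np.float64),
        )
    return CoverageTrack(steps, normalization="raw", assembly=assembly)


def simulate_coverage(
    cfg: SimulationConfig,
    assembly: GenomeAssembly,
    peaksets: dict[tuple[str, str], list[PeakSet]],
) -> tuple[dict[tuple[str, str, str], "CoverageTrack"], dict[tuple[str, str], "CoverageTrack"]]:
    """Per-replicate coverage tracks plus matched input controls.

    Each replicate's track carries Gaussian bumps at its realized peak
    summits over a uniform background; the input control for each
    factor/condition is background only.
    """
    tracks: dict[tuple[str, str, str], "CoverageTrack"] = {}
    inputs: dict[tuple[str, str], "CoverageTrack"] = {}
    for (factor, condition), reps in peaksets.items():
        for ps in reps:
            summits = [summit_position(p) for p in ps]
            tracks[(factor, condition, ps.replicate)] = gaussian_bump_track(
                assembly,
                summits,
                cfg.background,
                cfg.enrichment_amplitude,
                cfg.enrichment_sigma,
                cfg.coverage_step,
            )
        inputs[(factor, condition)] = gaussian_bump_track(
            assembly, [], cfg.background, cfg.enrichment_amplitude,
            cfg.enrichment_sigma, cfg.coverage_step,
        )
    return tracks, inputs


def write_fixture(cfg: SimulationConfig, outdir: str | Path, coverage: bool = True) -> Path:
    """Generate and write a complete fixture directory.

    Contents: genome.tsv (chrom sizes), genes.gff3, one narrowPeak per
    factor/condition/replicate, per-sample and input bedGraphs (optional),
    truth.tsv.  Deterministic: same config, same bytes.
    """
    from .metagene import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    assembly, genes = simulate_annotation(cfg, rng)
    with open(outdir / "genome.tsv", "w") as fh:
        for name, length in assembly.chroms:
            fh.write(f"{name}\t{length}\n")
    write_gff3_genes(genes, outdir / "genes.gff3", source="chipmeta-sim")
    peaksets, truth = simulate_peaks(cfg, assembly, genes, rng)
    for (factor, condition), reps in peaksets.items():
        for ps in reps:
            write_narrowpeak(ps, outdir / f"{factor}_{condition}_{ps.replicate}.narrowPeak")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if coverage:
        tracks, inputs = simulate_coverage(cfg, assembly, peaksets)
        for (factor, condition, rep), tr in tracks.items():
            write_bedgraph(tr, outdir / f"{factor}_{condition}_{rep}.bedgraph")
        for (factor, condition), tr in inputs.items():
            write_bedgraph(tr, outdir / f"{factor}_{condition}_input.bedgraph")
    return outdir
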