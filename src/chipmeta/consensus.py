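"""Consensus peaks: clusters of replicate peaks supported by >= 2 replicates.

Replicate peak sets of one factor/condition are pooled and clustered by
transitive overlap (merge semantics: touching or overlapping peaks join
one cluster).  A cluster becomes a consensus peak when its members span at
least ``min_support`` distinct replicates — the "present in at least two
replicates" rule.  The consensus region is the union span of the cluster;
its summit is taken from the member peak with the highest -log10 Q
(leftmost summit on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import GenomeAssembly, GInterval, sort_key
from .peaks import Peak, PeakSet, summit_position

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusPeak:
    region: GInterval
    support: int  # distinct replicates contributing >= 1 peak
    members: tuple[tuple[str, int], ...]  # (replicate id, peak index within that replicate)
    summit: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.region.start <= self.summit < self.region.end):
            raise ValueError(f"consensus {self.name!r}: summit {self.summit} outside region")


def build_consensus(
    replicates: Sequence[PeakSet],
    min_support: int = 2,
    assembly: GenomeAssembly | None = None,
) -> list[ConsensusPeak]:
    """Cluster pooled replicate peaks and keep clusters spanning >= min_support replicates.

    All PeakSets must share one factor and condition (replicate labels must
    differ).  Two peaks from the same replicate in a cluster count once
    toward support.  With ``min_support=1`` the emitted regions reduce to a
    plain merge of the pooled peaks.
    """
    if not replicates:
        return []
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    factors = {ps.factor for ps in replicates}
    conditions = {ps.condition for ps in replicates}
    if len(factors) > 1 or len(conditions) > 1:
        raise ValueError(
            f"replicates must share one factor/condition, got factors={sorted(factors)} "
            f"conditions={sorted(conditions)}"
        )
    rep_ids = [ps.replicate or str(i + 1) for i, ps in enumerate(replicates)]
    if len(set(rep_ids)) != len(rep_ids):
        raise ValueError(f"replicate labels must be distinct, got {rep_ids}")
    if min_support == 1 and len(replicates) > 1:
        log.warning("min_support=1: consensus requires no replicate agreement")
    if assembly is None:
        assembly = next((ps.assembly for ps in replicates if ps.assembly is not None), None)

    pooled: list[tuple[Peak, str, int]] = []
    for rid, ps in zip(rep_ids, replicates):
        for idx, p in enumerate(ps):
            pooled.append((p, rid, idx))
    if not pooled:
        return []
    key = sort_key(assembly)
    pooled.sort(key=lambda t: key(t[0].region))

    clusters: list[list[tuple[Peak, str, int]]] = []
    cur: list[tuple[Peak, str, int]] = [pooled[0]]
    cur_chrom, cur_end = pooled[0][0].region.chrom, pooled[0][0].region.end
    for item in pooled[1:]:
        r = item[0].region
        if r.chrom == cur_chrom and r.start <= cur_end:
            cur.append(item)
            cur_end = max(cur_end, r.end)
        else:
            clusters.append(cur)
            cur = [item]
            cur_chrom, cur_end = r.chrom, r.end
    clusters.append(cur)

    out: list[ConsensusPeak] = []
    factor = replicates[0].factor
    condition = replicates[0].condition
    k = 0
    for cluster in clusters:
        support = len({rid for _, rid, _ in cluster})
        if support < min_support:
            continue
        start = min(p.region.start for p, _, _ in cluster)
        end = max(p.region.end for p, _, _ in cluster)
        chrom = cluster[0][0].region.chrom
        # summit from the member with the highest q; leftmost summit on ties
        best = max(
            cluster,
            key=lambda t: (t[0].q, -summit_position(t[0])[1]),
        )
        summit = summit_position(best[0])[1]
        k += 1
        name = f"consensus_{factor or 'peak'}_{condition or 'all'}_{k}"
        out.append(
            ConsensusPeak(
                region=GInterval(chrom, start, end),
                support=support,
                members=tuple((rid, idx) for _, rid, idx in cluster),
                summit=summit,
                name=name,
            )
        )
    return out


def consensus_to_bed(cps: Sequence[ConsensusPeak], path: str | Path) -> None:
    """Write consensus peaks as BED6+1 (support in column 7, summit encoded in score slot 0)."""
    with open(path, "w") as fh:
        for cp in cps:
            fh.write(
                f"{cp.region.chrom}\t{cp.region.start}\t{cp.region.end}\t"
                f"{cp.name}\t0\t.\t{cp.support}\n"
            )


def consensus_from_bed(path: str | Path) -> list[ConsensusPeak]:
    """Read back BED6+1 consensus peaks (members are not round-tripped; summit = midpoint)."""
    out: list[ConsensusPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path}:{lineno}: consensus BED needs 7 columns")
            region = GInterval(cols[0], int(cols[1]), int(cols[2]))
            out.append(
                ConsensusPeak(
                    region=region,
                    support=int(cols[6]),
                    members=(),
                    summit=(region.start + region.end) // 2,
                    name=cols[3],
                )
            )
    return out
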