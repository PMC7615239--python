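"""Summit-to-gene assignment and target-gene tables.

A consensus peak is assigned to a gene when its summit falls within the
gene's assignment window (gene body extended by 1 kb on both sides, i.e.
1 kb upstream of the TSS through 1 kb downstream of the TTS).  When
several genes are candidates the one closest to the summit wins, with
distance measured from the summit to the gene body (0 inside; otherwise
distance to the nearer of the first and last body base).  A peak with no
gene within the flank stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import GeneSet, assignment_window
from .consensus import ConsensusPeak


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_name: str
    chrom: str
    summit: int
    gene_id: str | None  # None iff no candidate gene
    distance: int | None  # 0 if summit inside the gene body
    n_candidates: int


def _body_distance(summit: int, start: int, end: int) -> int:
    if start <= summit < end:
        return 0
    return min(abs(summit - start), abs(summit - (end - 1)))


def assign_peaks(
    cps: Sequence[ConsensusPeak],
    genes: GeneSet,
    flank: int = 1000,
) -> list[PeakGeneAssignment]:
    """Assign each consensus peak to at most one gene by the summit rule.

    Candidates are genes whose assignment window contains the summit;
    among candidates the minimal summit-to-body distance wins, ties going
    to the lexicographically smallest gene_id.  Assignment is invariant to
    gene input order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_chrom: dict[str, list] = {}
    for g in genes:
        w = assignment_window(g, flank=flank, assembly=genes.assembly)
        by_chrom.setdefault(g.region.chrom, []).append((w.start, w.end, g))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[0], t[1], t[2].gene_id))

    out: list[PeakGeneAssignment] = []
    for cp in cps:
        chrom, summit = cp.region.chrom, cp.summit
        best_gene = None
        best_key = None
        n_cand = 0
        for wstart, wend, g in by_chrom.get(chrom, ()):
            if wstart <= summit < wend:
                n_cand += 1
                d = _body_distance(summit, g.region.start, g.region.end)
                key = (d, g.gene_id)
                if best_key is None or key < best_key:
                    best_key = key
                    best_gene = g
        if best_gene is None:
            out.append(PeakGeneAssignment(cp.name, chrom, summit, None, None, 0))
        else:
            out.append(
                PeakGeneAssignment(cp.name, chrom, summit, best_gene.gene_id, best_key[0], n_cand)
            )
    return out


def target_gene_table(
    assignments_by_group: dict[tuple[str, str], Sequence[PeakGeneAssignment]],
) -> pd.DataFrame:
    """Per (factor, condition): number of peaks and number of distinct target genes.

    A gene hit by several peaks counts once; an unassigned peak contributes
    to the peak count only.
    """
    rows = []
    for (factor, condition), assigns in assignments_by_group.items():
        genes = {a.gene_id for a in assigns if a.gene_id is not None}
        rows.append(
            {
                "factor": factor,
                "condition": condition,
                "n_peaks": len(assigns),
                "n_genes": len(genes),
            }
        )
    return pd.DataFrame(rows, columns=["factor", "condition", "n_peaks", "n_genes"])


def assignments_to_tsv(assignments: Sequence[PeakGeneAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tsummit\tgene_id\tdistance\tn_candidates\n")
        for a in assignments:
            gene = a.gene_id if a.gene_id is not None else "NA"
            dist = str(a.distance) if a.distance is not None else "NA"
            fh.write(f"{a.peak_name}\t{a.chrom}\t{a.summit}\t{gene}\t{dist}\t{a.n_candidates}\n")


def assigned_gene_ids(assignments: Sequence[PeakGeneAssignment]) -> set[str]:
    return {a.gene_id for a in assignments if a.gene_id is not None}
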