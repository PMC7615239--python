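"""Co-occupancy statistics between peak sets and gene-set comparisons.

Overlap between binding profiles of different factors is summarised
peak-level, not base-pair-level: pct[i][j] is the percentage of set i's
peaks that share >= 1 bp with at least one peak of set j (so the matrix is
asymmetric in general).  Multi-way co-occupancy counts, for a reference
factor, how many of its peaks are covered by each subset of the other
factors.  Gene-set overlap compares assigned target-gene lists against
external gene lists (e.g. H3K27me3 / H2AK121ub targets), optionally with a
hypergeometric enrichment p-value when a gene universe is supplied.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import GInterval, overlaps_any
from .consensus import ConsensusPeak


def _regions(peaks: Sequence) -> list[GInterval]:
    out = []
    for p in peaks:
        if isinstance(p, GInterval):
            out.append(p)
        else:
            out.append(p.region)
    return out


@dataclass
class OverlapMatrix:
    labels: list[str]
    pct: np.ndarray  # NaN marks empty-set rows/columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pct, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write("set\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, df.values):
                cells = ["NA" if math.isnan(v) else f"{v:.1f}" for v in row]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


def pairwise_overlap_matrix(
    sets: Sequence[Sequence[ConsensusPeak | GInterval]],
    labels: Sequence[str] | None = None,
) -> OverlapMatrix:
    """pct[i][j] = 100 * fraction of set i's peaks overlapped by >= 1 peak of set j.

    Percentages are reported to one decimal place.  Rows and columns of
    empty sets are NaN ("NA" on write), never 0.
    """
    n = len(sets)
    if labels is None:
        labels = [f"set{i}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("one label per set required")
    regions = [_regions(s) for s in sets]
    pct = np.full((n, n), np.nan)
    for i in range(n):
        if not regions[i]:
            continue
        for j in range(n):
            if not regions[j]:
                continue
            flags = overlaps_any(regions[i], regions[j])
            pct[i, j] = round(100.0 * sum(flags) / len(flags), 1)
    return OverlapMatrix(labels=labels, pct=pct)


def multiway_cooccupancy(
    sets: Sequence[Sequence[ConsensusPeak | GInterval]],
    labels: Sequence[str] | None = None,
    reference: int = 0,
) -> pd.DataFrame:
    """Counts of reference-set peaks overlapped by each subset of the other sets.

    Returns 2^(k-1) rows (one per combination of the non-reference sets,
    including the empty combination); the counts sum to the size of the
    reference set.
    """
    n = len(sets)
    if n < 2:
        raise ValueError("need >= 2 sets")
    if labels is None:
        labels = [f"set{i}" for i in range(n)]
    labels = list(labels)
    others = [i for i in range(n) if i != reference]
    ref_regions = _regions(sets[reference])
    flags = {i: overlaps_any(ref_regions, _regions(sets[i])) for i in others}

    counts: dict[tuple[str, ...], int] = {}
    for combo_size in range(len(others) + 1):
        for combo in itertools.combinations(others, combo_size):
            counts[tuple(labels[i] for i in combo)] = 0
    for k in range(len(ref_regions)):
        hit = tuple(labels[i] for i in others if flags[i][k])
        counts[hit] += 1
    rows = [
        {"combination": "+".join(combo) if combo else "(none)", "count": c}
        for combo, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["combination", "count"])
    df.attrs["reference"] = labels[reference]
    return df


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_ids(
    ids: Iterable[str],
    uppercase: bool = True,
    strip_version: bool = True,
) -> set[str]:
    """Canonicalise gene IDs (case fold, strip trailing .N version suffixes)."""
    out = set()
    for i in ids:
        i = i.strip()
        if not i:
            continue
        if strip_version:
            i = _VERSION_SUFFIX.sub("", i)
        if uppercase:
            i = i.upper()
        out.add(i)
    return out


@dataclass(frozen=True)
class GeneSetOverlap:
    n_a: int
    n_b: int
    n_intersection: int
    pct_a_in_b: float
    p_hypergeom: float | None  # upper-tail enrichment p; None without a universe


def gene_set_overlap(
    a: Iterable[str],
    b: Iterable[str],
    universe: Iterable[str] | None = None,
    normalize: bool = False,
) -> GeneSetOverlap:
    """Exact overlap arithmetic between two gene-ID sets.

    ``pct_a_in_b`` is 100 * |a ∩ b| / |a|.  When a universe is supplied the
    upper-tail hypergeometric p-value for the intersection size is added
    (an extra beyond the raw percentages; flagged as such downstream).
    Both sets must be subsets of the universe.
    """
    sa = normalize_gene_ids(a) if normalize else set(a)
    sb = normalize_gene_ids(b) if normalize else set(b)
    inter = sa & sb
    pct = round(100.0 * len(inter) / len(sa), 1) if sa else float("nan")
    p = None
    if universe is not None:
        su = normalize_gene_ids(universe) if normalize else set(universe)
        offenders = sorted(sa - su) + sorted(sb - su)
        if offenders:
            raise ValueError(f"gene IDs not in universe: {offenders[:10]}")
        # P(X >= |inter|), X ~ Hypergeom(N=|U|, K=|b|, n=|a|)
        p = float(hypergeom.sf(len(inter) - 1, len(su), len(sb), len(sa)))
    return GeneSetOverlap(len(sa), len(sb), len(inter), pct, p)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and #-comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out
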