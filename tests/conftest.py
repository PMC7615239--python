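import numpy as np
import pytest

from chipmeta import GenomeAssembly, GInterval


@pytest.fixture
def asm10k():
    return GenomeAssembly.from_pairs([("chr1", 10_000)])


@pytest.fixture
def asm2():
    return GenomeAssembly.from_pairs([("chr1", 10_000), ("chr2", 8_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chrom="chr1", length=10_000, max_len=400):
    starts = rng.integers(0, length - max_len, size=n)
    lens = rng.integers(1, max_len, size=n)
    return [GInterval(chrom, int(s), int(s + l)) for s, l in zip(starts, lens)]


# ---- independent brute-force oracles -------------------------------------

def brute_merge(intervals, min_gap=0):
    """Quadratic pairwise merge to fixpoint."""
    items = [[iv.chrom, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= min_gap:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(GInterval(c, s, e) for c, s, e in items)


def brute_overlaps_any(queries, subjects):
    return [
        any(
            q.chrom == s.chrom and q.start < s.end and s.start < q.end
            for s in subjects
        )
        for q in queries
    ]


def brute_closest(chrom, pos, features, ids=None):
    best = None
    for i, f in enumerate(features):
        if f.chrom != chrom:
            continue
        d = 0 if f.start <= pos < f.end else min(abs(pos - f.start), abs(pos - (f.end - 1)))
        tie = ids[i] if ids is not None else (f.start, f.end, i)
        if best is None or (d, tie) < (best[0], best[1]):
            best = (d, tie, i)
    if best is None:
        return None, None
    return best[2], best[0]
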