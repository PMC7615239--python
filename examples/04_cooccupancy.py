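"""Co-occupancy between factors and gene-set comparisons.

The pairwise matrix reports, per ordered pair, the percentage of one
factor's peaks overlapped (>= 1 bp) by the other's — asymmetric by design.
The multi-way table partitions the reference factor's peaks by which
combinations of the other factors co-occupy them.
"""

from pathlib import Path

from chipmeta import (
    SimulationConfig,
    build_consensus,
    filter_by_q,
    gene_set_overlap,
    multiway_cooccupancy,
    pairwise_overlap_matrix,
    read_narrowpeak,
    write_fixture,
)

cfg = SimulationConfig(seed=7, n_genes=120, chrom_length=500_000, n_sites={"NV": 30, "6WT0": 80})
fx = write_fixture(cfg, Path("scratch/example_fixture"), coverage=False)

cons = {}
for factor in cfg.factors:
    reps = [
        filter_by_q(read_narrowpeak(fx / f"{factor}_6WT0_rep{r}.narrowPeak",
                                    factor=factor, condition="6WT0", replicate=f"rep{r}"))
        for r in (1, 2, 3)
    ]
    cons[factor] = build_consensus(reps, min_support=2)

mat = pairwise_overlap_matrix(list(cons.values()), labels=list(cons))
print(mat.to_frame().round(1))
# Row VIN3, column VEL1 = % of VIN3 peaks co-occupied by VEL1; the planted
# sharing of 0.8 reappears here, shrunk by imperfect replicate recovery.

combos = multiway_cooccupancy(list(cons.values()), labels=list(cons), reference=0)
print(combos.to_string(index=False))

a = {"G00001", "G00002", "G00003", "G00004"}
b = {"G00003", "G00004", "G00005"}
r = gene_set_overlap(a, b, universe={f"G{i:05d}" for i in range(1, 121)})
print(f"gene sets: |a|={r.n_a} |b|={r.n_b} shared={r.n_intersection} "
      f"({r.pct_a_in_b}% of a), hypergeometric p={r.p_hypergeom:.3g}")
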