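"""Significance filtering and replicate-consensus peaks.

Reads the replicate narrowPeak files of one factor/condition, keeps highly
significant peaks (Q <= 1e-10, i.e. -log10 Q >= 10), and builds consensus
peaks supported by at least two replicates.
"""

from pathlib import Path

from chipmeta import SimulationConfig, build_consensus, filter_by_q, read_narrowpeak, write_fixture

fx = write_fixture(
    SimulationConfig(seed=7, n_genes=120, chrom_length=500_000, n_sites={"NV": 30, "6WT0": 80}),
    Path("scratch/example_fixture"),
    coverage=False,
)

reps = []
for r in (1, 2, 3):
    ps = read_narrowpeak(
        fx / f"VRN5_6WT0_rep{r}.narrowPeak", factor="VRN5", condition="6WT0", replicate=f"rep{r}"
    )
    kept = filter_by_q(ps)  # inclusive: -log10 Q >= 10
    print(f"rep{r}: {len(kept)}/{len(ps)} peaks pass the Q filter")
    reps.append(kept)

cps = build_consensus(reps, min_support=2)
print(f"{len(cps)} consensus peaks present in >= 2 of {len(reps)} replicates")
print("first:", cps[0].name, cps[0].region, "support", cps[0].support, "summit", cps[0].summit)
# Each consensus region is the union span of a cluster of transitively
# overlapping replicate peaks; its summit comes from the member with the
# highest -log10 Q.
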