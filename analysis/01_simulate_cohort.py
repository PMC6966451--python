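#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/data/: per-tissue TAD map BEDs, a chrom.sizes table,
a gene x tissue expression count TSV, a SEG-style CNV file, a clinical
survival TSV, and a truth.json recording which TADs were spiked for CNV
recurrence, which carry survival effects, and which were split/fused in
the simulated cancer genome.
"""

import json
from pathlib import Path

import numpy as np

from tadprog import cnv, genome_io, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2024

ENRICHED_IDX = (5, 18, 33, 47, 61, 72, 85, 96)  # base-map TAD indices, spiked 3x
ENRICHED = {i: 3.0 for i in ENRICHED_IDX}
CAUSAL_IDX = (5, 33, 61)  # subset of the enriched TADs that also drive survival
CAUSAL = {ENRICHED_IDX.index(i): np.log(2) for i in CAUSAL_IDX}
SPLIT_IDS = [7, 21, 40]
FUSE_GROUPS = [[25, 26], [55, 56]]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # causal_tads indexes columns of the survival feature table, which is
    # built below from the enriched-TAD columns in ENRICHED_IDX order
    cfg = simulate.SimulationConfig(seed=SEED, enriched_tads=ENRICHED,
                                    causal_tads=CAUSAL, n_patients=300)

    with open(OUT / "chrom.sizes", "w") as fh:
        for chrom, size in cfg.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    maps, base = simulate.simulate_tad_maps(cfg)
    genome_io.write_tad_map(base, OUT / "base_map.bed")
    for m in maps:
        genome_io.write_tad_map(m, OUT / f"tads_{m.sample_id}.bed")
    print(f"base map: {len(base)} TADs; {len(maps)} tissue maps "
          f"(jitter sd {cfg.boundary_jitter_sd/1000:.0f} kb)")

    tree = simulate.default_clade_tree(cfg.n_tissues)
    expr = simulate.simulate_expression(tree, cfg.n_genes, cfg)
    expr.to_csv(OUT / "expression_counts.tsv", sep="\t")

    cancer = simulate.derive_cancer_map(base, SPLIT_IDS, FUSE_GROUPS)
    genome_io.write_tad_map(cancer, OUT / "cancer_map.bed")

    segs = simulate.simulate_cnvs(cfg, base)
    with open(OUT / "cnvs.seg", "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnum_probes\tsegment_mean\n")
        for s in segs:
            fh.write(f"{s.patient_id}\t{s.interval.chrom}\t{s.interval.start}\t"
                     f"{s.interval.end}\t{s.num_probes}\t{s.segment_mean:.4f}\n")
    n_pass = len(cnv.filter_cnvs(segs))
    print(f"CNVs: {len(segs)} segments for {cfg.n_patients} patients "
          f"({n_pass} pass the size/segment-mean/probe filters)")

    filt = cnv.filter_cnvs(segs)
    mat = cnv.overlap_matrix(filt, base)
    feature_cols = [mat.columns[i] for i in ENRICHED_IDX]
    X = mat[feature_cols].copy()
    recs = simulate.simulate_survival(X, cfg, seed=SEED + 2)
    with open(OUT / "clinical.tsv", "w") as fh:
        fh.write("patient_id\tcancer_type\tdays\tvital_status\tage\tsex\n")
        for r in recs:
            status = "dead" if r.event else "alive"
            fh.write(f"{r.patient_id}\t{r.cancer_type}\t{r.time:.1f}\t{status}\t"
                     f"{r.age:.1f}\t{r.sex}\n")
    print(f"clinical table: {len(recs)} patients, "
          f"{np.mean([r.event for r in recs]):.0%} deceased")

    ids = list(mat.columns)
    truth = {
        "seed": SEED,
        "enriched_tads": {ids[i]: f for i, f in ENRICHED.items()},
        "causal_tads": {ids[i]: float(np.log(2)) for i in CAUSAL_IDX},
        "split_tads": [ids[i] for i in SPLIT_IDS],
        "fused_groups": [[ids[i] for i in g] for g in FUSE_GROUPS],
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote inputs + truth.json to {OUT}")


if __name__ == "__main__":
    main()
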