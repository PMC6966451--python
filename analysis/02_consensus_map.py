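#!/usr/bin/env python
"""Build the consensus TAD map from the simulated tissue maps.

Reads the tissue TAD maps and expression counts from results/data/,
derives tissue weights from the expression dendrogram, computes windowed
conservation/boundary scores, and merges them into consensus TADs.
Writes consensus.bed (TAD/TBR/disorganized regions), tissue_weights.tsv,
dendrogram.nwk, similarity_matrix.tsv and a size summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tadprog import consensus, genome_io, tissue_weights as tw

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sizes = genome_io.read_chrom_sizes(DATA / "chrom.sizes")
    maps = [
        genome_io.read_tad_map(p, p.stem.replace("tads_", ""), "normal",
                               chrom_sizes=sizes)
        for p in sorted(DATA.glob("tads_tissue_*.bed"))
    ]
    per_map, med_of_med = genome_io.tad_map_summary(maps)
    per_map.to_csv(OUT / "tad_map_summary.tsv", sep="\t", index=False)
    print(f"{len(maps)} tissue maps; median-of-medians TAD size "
          f"{med_of_med['normal']/1e6:.2f} Mb")

    sims = pd.DataFrame(
        [[consensus.map_similarity(a, b) if a is not b else 1.0 for b in maps]
         for a in maps],
        index=[m.sample_id for m in maps], columns=[m.sample_id for m in maps],
    )
    sims.to_csv(OUT / "similarity_matrix.tsv", sep="\t")
    off_diag = sims.values[~np.eye(len(maps), dtype=bool)]
    print(f"pairwise map similarity: median {np.median(off_diag):.3f}")

    expr = pd.read_csv(DATA / "expression_counts.tsv", sep="\t", index_col=0)
    transformed = tw.transform_counts(expr)
    variable = tw.select_variable_genes(transformed, 2000)
    dend = tw.build_dendrogram(variable)
    (OUT / "dendrogram.nwk").write_text(tw.to_newick(dend) + "\n")
    weights = tw.leaf_weights(dend)
    weights.rename("weight").to_csv(OUT / "tissue_weights.tsv", sep="\t")
    map_weights = tw.assign_map_weights(weights, maps)
    print(f"tissue weights: min {weights.min():.3f}, max {weights.max():.3f}")

    track = consensus.window_scores(maps, map_weights.values, sizes)
    seg = consensus.build_consensus(track)
    seg.to_bed(OUT / "consensus.bed")
    counts = seg.regions["label"].value_counts()
    tads = seg.tads()
    print(f"consensus: {counts.get('TAD', 0)} TADs "
          f"(median {float((tads['end']-tads['start']).median())/1e6:.2f} Mb), "
          f"{counts.get('TBR', 0)} TBRs, "
          f"{counts.get('disorganized', 0)} disorganized regions")

    base = genome_io.read_tad_map(DATA / "base_map.bed", "base", "normal")
    print(f"similarity of ground-truth map to consensus: "
          f"{consensus.map_similarity(base, seg.to_tad_map()):.3f}")


if __name__ == "__main__":
    main()
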