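#!/usr/bin/env python
"""Classify normal consensus TADs against the simulated cancer genome.

Labels each normal-consensus TAD constitutive / perturbed / ambiguous by
best-overlap fractions against the cancer TAD map, extracts split and
fused subsets, checks them against the simulation's ground truth, and
computes CNV-density meta-profiles (scale-regions over TAD bodies,
reference-point around TBR centers). Writes classification.tsv and the
two profile TSVs.
"""

import json
from pathlib import Path

import pandas as pd

from tadprog import compare, cnv, genome_io
from tadprog.consensus import ConsensusSegmentation

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    regions = pd.read_csv(OUT / "consensus.bed", sep="\t",
                          names=["chrom", "start", "end", "label"])
    normal = ConsensusSegmentation(regions)
    cancer = genome_io.read_tad_map(DATA / "cancer_map.bed", "cancer", "cancer")

    cls = compare.classify_tads(normal, cancer)
    split, fused, groups = compare.detect_split_fused(cls, normal, cancer)
    cls["split"] = cls["tad"].isin(split)
    cls["fused"] = cls["tad"].isin(fused)
    cls.to_csv(OUT / "classification.tsv", sep="\t", index=False)
    counts = cls["label"].value_counts()
    print(f"classification: {counts.get('constitutive', 0)} constitutive, "
          f"{counts.get('perturbed', 0)} perturbed, "
          f"{counts.get('ambiguous', 0)} ambiguous")
    print(f"{len(split)} split TADs, {len(fused)} fused TADs in {len(groups)} groups")

    truth = json.loads((DATA / "truth.json").read_text())
    truth_split = set(truth["split_tads"])
    truth_fused = {t for g in truth["fused_groups"] for t in g}
    match = lambda got, want: sum(  # noqa: E731
        any(_near(g, w) for w in want) for g in got)
    print(f"ground truth recovered: {match(split, truth_split)}/{len(truth_split)} "
          f"split, {match(fused, truth_fused)}/{len(truth_fused)} fused")

    segs = cnv.filter_cnvs(genome_io.read_seg_file(DATA / "cnvs.seg",
                                                   barcode_chars=None))
    coverage = compare.patient_coverage_intervals(segs)
    perturbed = cls[cls["label"] == "perturbed"][["chrom", "start", "end"]]
    profiled = perturbed if len(perturbed) >= 3 else normal.tads()
    prof = compare.scaled_profile(profiled, coverage,
                                  body=2_000_000, flank=1_000_000, bin_size=10_000)
    prof.bins.to_csv(OUT / "cnv_profile_scaled.tsv", sep="\t", index=False)
    body = prof.bins[prof.bins["position_class"] == "body"]["value"]
    flank = prof.bins[prof.bins["position_class"] != "body"]["value"]
    print(f"CNV density (patients/bp): body median {body.median():.1f}, "
          f"flank median {flank.median():.1f} over {prof.n_regions} TADs")

    tbrs = normal.by_label("TBR")
    ref = compare.reference_point_profile(tbrs, coverage,
                                          flank=200_000, bin_size=5_000)
    ref.bins.to_csv(OUT / "cnv_profile_tbr.tsv", sep="\t", index=False)
    print(f"TBR-centered profile written for {ref.n_regions} TBRs")


def _near(a: str, b: str, tol: int = 50_000) -> bool:
    ca, ra = a.split(":")
    cb, rb = b.split(":")
    if ca != cb:
        return False
    sa, ea = map(int, ra.split("-"))
    sb, eb = map(int, rb.split("-"))
    return abs(sa - sb) <= tol and abs(ea - eb) <= tol


if __name__ == "__main__":
    main()
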