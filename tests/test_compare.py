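import numpy as np
import pandas as pd
import pytest

from tadprog import compare
from tadprog.genome_io import CNVSegment, GenomicInterval
from tadprog.simulate import SimulationConfig, derive_cancer_map, simulate_base_map

from conftest import make_map


class TestClassifyTads:
    def test_identical_maps_all_constitutive(self, toy_map):
        out = compare.classify_tads(toy_map, toy_map)
        assert (out["label"] == "constitutive").all()
        assert (out["f_N"] == 1.0).all() and (out["f_C"] == 1.0).all()
        assert out["reciprocal"].all()

    def test_low_forward_fraction_is_perturbed(self):
        normal = make_map([("chr1", 0, 1_000_000)])
        cancer = make_map([("chr1", 0, 600_000)], condition="cancer")
        out = compare.classify_tads(normal, cancer)
        assert out.loc[0, "f_N"] == pytest.approx(0.6)
        assert out.loc[0, "label"] == "perturbed"

    def test_intermediate_reciprocal_is_ambiguous(self):
        # f_N = 0.85, f_C = 0.9: neither constitutive nor perturbed
        normal = make_map([("chr1", 100_000, 1_100_000)])
        cancer = make_map([("chr1", 155_556, 1_100_000 + 94_444)], condition="cancer")
        out = compare.classify_tads(normal, cancer)
        assert 0.8 < out.loc[0, "f_N"] < 0.95
        assert 0.8 < out.loc[0, "f_C"] < 0.95
        assert out.loc[0, "label"] == "ambiguous"

    def test_unmatched_normal_tad_is_perturbed(self):
        normal = make_map([("chr1", 0, 1_000_000)])
        cancer = make_map([("chr2", 0, 1_000_000)], condition="cancer")
        out = compare.classify_tads(normal, cancer)
        assert out.loc[0, "f_N"] == 0.0
        assert out.loc[0, "label"] == "perturbed"

    def test_labels_partition(self):
        cfg = SimulationConfig(seed=3)
        base = simulate_base_map(cfg)
        cancer = derive_cancer_map(base, split_indices=[2, 5], fuse_groups=[[10, 11]])
        out = compare.classify_tads(base, cancer)
        counts = out["label"].value_counts()
        assert counts.sum() == len(out)
        assert set(counts.index) <= {"constitutive", "perturbed", "ambiguous"}

    def test_lowering_reciprocal_threshold_grows_constitutive(self):
        cfg = SimulationConfig(seed=8)
        base = simulate_base_map(cfg)
        cancer = derive_cancer_map(
            base, split_indices=[1, 4, 7],
            fuse_groups=[[12, 13]],
        )
        # add mild jitter so some overlaps land between 0.80 and 0.95
        iv = cancer.intervals.copy()
        iv["start"] = iv["start"] + 30_000
        cancer = make_map(iv.values.tolist(), "cancer_jit", "cancer")
        n_strict = (compare.classify_tads(base, cancer, c_thresh=0.95)["label"]
                    == "constitutive").sum()
        n_loose = (compare.classify_tads(base, cancer, c_thresh=0.80)["label"]
                   == "constitutive").sum()
        assert n_loose >= n_strict
        # and tightening the perturbed bound shrinks the perturbed set
        p_07 = (compare.classify_tads(base, cancer, p_thresh=0.7)["label"]
                == "perturbed").sum()
        p_05 = (compare.classify_tads(base, cancer, p_thresh=0.5)["label"]
                == "perturbed").sum()
        assert p_05 <= p_07


class TestSplitFused:
    def test_clean_split_detected(self):
        normal = make_map([("chr1", 0, 1_000_000)])
        cancer = make_map([("chr1", 0, 500_000), ("chr1", 500_000, 1_000_000)],
                          condition="cancer")
        cls = compare.classify_tads(normal, cancer)
        split, fused, groups = compare.detect_split_fused(cls, normal, cancer)
        assert split == {"chr1:0-1000000"}
        assert fused == set()

    def test_clean_fusion_detected(self):
        normal = make_map([("chr1", 0, 400_000), ("chr1", 450_000, 1_000_000)])
        cancer = make_map([("chr1", 0, 1_000_000)], condition="cancer")
        cls = compare.classify_tads(normal, cancer)
        split, fused, groups = compare.detect_split_fused(cls, normal, cancer)
        assert fused == {"chr1:0-400000", "chr1:450000-1000000"}
        assert groups == [{"chr1:0-400000", "chr1:450000-1000000"}]
        assert split == set()

    def test_partial_coverage_is_not_split(self):
        # second cancer TAD only half inside the normal TAD
        normal = make_map([("chr1", 0, 1_000_000)])
        cancer = make_map([("chr1", 0, 500_000), ("chr1", 800_000, 1_400_000)],
                          condition="cancer")
        cls = compare.classify_tads(normal, cancer)
        split, fused, _ = compare.detect_split_fused(cls, normal, cancer)
        assert split == set()

    def test_split_and_fused_disjoint_on_simulated_edits(self):
        cfg = SimulationConfig(seed=5)
        base = simulate_base_map(cfg)
        # fusion partners must have comparable sizes, else the covering
        # cancer TAD is > 70% covered by its larger member and the pair is
        # (correctly) ambiguous rather than perturbed
        split_ids = [4, 6, 20]
        fuse_groups = [[1, 2], [13, 14]]
        cancer = derive_cancer_map(base, split_indices=split_ids,
                                   fuse_groups=fuse_groups)
        cls = compare.classify_tads(base, cancer)
        split, fused, groups = compare.detect_split_fused(cls, base, cancer)
        ids = [f"{r.chrom}:{r.start}-{r.end}"
               for r in base.intervals.itertuples(index=False)]
        assert split == {ids[i] for i in split_ids}
        assert fused == {ids[i] for g in fuse_groups for i in g}
        assert split.isdisjoint(fused)
        perturbed = set(cls.loc[cls["label"] == "perturbed", "tad"])
        assert split <= perturbed and fused <= perturbed


class TestScaledProfile:
    def test_uniform_signal_flat_profile(self):
        regions = make_map([("chr1", 2_000_000, 4_000_000)])
        signal = pd.DataFrame([("chr1", 0, 10_000_000)],
                              columns=["chrom", "start", "end"])
        prof = compare.scaled_profile(regions, signal)
        np.testing.assert_allclose(prof.bins["value"], 1.0)

    def test_signal_only_in_body_leaves_flanks_zero(self):
        regions = make_map([("chr1", 2_000_000, 4_000_000)])
        signal = pd.DataFrame([("chr1", 2_000_000, 4_000_000)],
                              columns=["chrom", "start", "end"])
        prof = compare.scaled_profile(regions, signal)
        flank5 = prof.bins[prof.bins["position_class"] == "flank5"]["value"]
        body = prof.bins[prof.bins["position_class"] == "body"]["value"]
        flank3 = prof.bins[prof.bins["position_class"] == "flank3"]["value"]
        assert (flank5 == 0).all() and (flank3 == 0).all()
        np.testing.assert_allclose(body, 1.0)

    def test_central_coverage_after_two_fold_scaling(self):
        # 1 Mb region, one interval covering its central 50%: after scaling
        # the body to 2 Mb, exactly the central half of the body bins is 1
        regions = make_map([("chr1", 2_000_000, 3_000_000)])
        signal = pd.DataFrame([("chr1", 2_250_000, 2_750_000)],
                              columns=["chrom", "start", "end"])
        prof = compare.scaled_profile(regions, signal)
        body = prof.bins[prof.bins["position_class"] == "body"]["value"].to_numpy()
        n = len(body)  # 200 bins
        assert n == 200
        np.testing.assert_allclose(body[: n // 4], 0.0)
        np.testing.assert_allclose(body[n // 4: 3 * n // 4], 1.0)
        np.testing.assert_allclose(body[3 * n // 4:], 0.0)

    def test_short_region_skipped(self, caplog):
        regions = pd.DataFrame([("chr1", 0, 15_000), ("chr1", 100_000, 2_000_000)],
                               columns=["chrom", "start", "end"])
        signal = pd.DataFrame([("chr1", 0, 10_000_000)],
                              columns=["chrom", "start", "end"])
        with caplog.at_level("WARNING"):
            prof = compare.scaled_profile(regions, signal)
        assert prof.n_regions == 1
        assert "skipped" in caplog.text

    def test_median_aggregation_across_regions(self):
        # three regions, one carries signal: median over regions is 0
        regions = make_map([("chr1", 2_000_000, 3_000_000),
                            ("chr1", 5_000_000, 6_000_000),
                            ("chr1", 8_000_000, 9_000_000)])
        signal = pd.DataFrame([("chr1", 2_000_000, 3_000_000)],
                              columns=["chrom", "start", "end"])
        med = compare.scaled_profile(regions, signal, aggregate="median")
        mean = compare.scaled_profile(regions, signal, aggregate="mean")
        body_med = med.bins[med.bins["position_class"] == "body"]["value"]
        body_mean = mean.bins[mean.bins["position_class"] == "body"]["value"]
        np.testing.assert_allclose(body_med, 0.0)
        np.testing.assert_allclose(body_mean, 1 / 3)


class TestReferencePointProfile:
    def test_features_at_centers_make_central_spike(self):
        centers = make_map([("chr1", 990_000, 1_010_000),
                            ("chr1", 4_990_000, 5_010_000)])
        feats = pd.DataFrame([("chr1", 999_000, 1_001_000),
                              ("chr1", 4_999_000, 5_001_000)],
                             columns=["chrom", "start", "end"])
        prof = compare.reference_point_profile(centers, feats)
        vals = prof.bins.set_index("bin")["value"]
        center_bins = vals[(vals.index >= -5_000) & (vals.index <= 5_000)]
        assert center_bins.max() > 0
        assert vals[vals.index < -50_000].max() == 0

    def test_no_features_all_zero(self):
        centers = make_map([("chr1", 500_000, 600_000)])
        feats = pd.DataFrame(columns=["chrom", "start", "end"])
        prof = compare.reference_point_profile(centers, feats)
        np.testing.assert_allclose(prof.bins["value"], 0.0)

    def test_boundary_enriched_features_peak_centrally(self, rng):
        # features drawn densely near TBR midpoints, sparsely elsewhere
        centers = make_map([(f"chr1", s, s + 50_000)
                            for s in range(1_000_000, 20_000_000, 2_000_000)])
        rows = []
        for r in centers.iter_intervals():
            mid = (r.start + r.end) // 2
            for _ in range(30):
                p = int(rng.normal(mid, 15_000))
                rows.append(("chr1", p, p + 500))
        for _ in range(60):
            p = int(rng.integers(0, 20_000_000))
            rows.append(("chr1", p, p + 500))
        feats = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        prof = compare.reference_point_profile(centers, feats)
        vals = prof.bins.set_index("bin")["value"]
        central = vals[(vals.index > -25_000) & (vals.index < 25_000)].mean()
        flanking = vals[abs(vals.index) > 150_000].mean()
        assert central > 3 * flanking

    def test_patient_coverage_merges_per_patient(self):
        segs = [
            CNVSegment("P1", "SIM", GenomicInterval("chr1", 0, 1000), 10, 0.5),
            CNVSegment("P1", "SIM", GenomicInterval("chr1", 500, 2000), 10, 0.5),
            CNVSegment("P2", "SIM", GenomicInterval("chr1", 0, 1000), 10, 0.5),
        ]
        cov = compare.patient_coverage_intervals(segs)
        assert len(cov) == 2  # P1's overlapping segments merged
        p1 = cov[cov["patient_id"] == "P1"].iloc[0]
        assert (p1["start"], p1["end"]) == (0, 2000)
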