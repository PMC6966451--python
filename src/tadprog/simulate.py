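"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the inputs of the analysis end to end:

* a base TAD map (log-normal TAD sizes, median ~1 Mb, short TBR-like
  gaps) plus per-tissue maps derived from it by boundary jitter and
  split/fusion edits, correlated within clades of related tissues;
* clade-structured negative-binomial expression counts, so the tissue
  dendrogram recovers the generating topology;
* per-patient CNV segments (negative-binomial counts, log-uniform
  lengths between 1 kb and 10 Mb, segment means from a two-component
  mixture straddling the +-0.1 filter), with biased placement spiking
  the patient-recurrence of chosen TADs by a known factor while leaving
  the length distribution untouched;
* survival times from an exponential proportional-hazards model over the
  binary feature table (so Cox coefficients equal the generative
  log-hazard-ratios), with independent uniform censoring calibrated to a
  target fraction;
* a "cancer genome" TAD map derived from the base map by known split and
  fusion edits, giving labeled ground truth for the classification step.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CNVSegment, GenomicInterval, SurvivalRecord, TADMap
from .tissue_weights import TreeNode

__all__ = [
    "SimulationConfig",
    "simulate_base_map",
    "simulate_tad_maps",
    "simulate_expression",
    "simulate_cnvs",
    "simulate_survival",
    "derive_cancer_map",
    "default_clade_tree",
]

GRID = 1_000  # all boundaries sit on the 1 kb coordinate grid


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 45_000_000, "chr3": 35_000_000}
    )
    # base map geometry: log-normal TAD sizes with median ~1 Mb, short gaps
    tad_size_log_mean: float = np.log(1_000_000)
    tad_size_log_sd: float = 0.45
    gap_size_log_mean: float = np.log(80_000)
    gap_size_log_sd: float = 0.6
    min_tad: int = 100_000
    # per-tissue perturbations
    n_tissues: int = 8
    boundary_jitter_sd: float = 20_000.0
    split_prob: float = 0.05
    fusion_prob: float = 0.05
    clade_share_prob: float = 0.7  # chance a tissue reuses its clade's edits
    # expression
    n_genes: int = 3_000
    nb_dispersion: float = 0.15
    expression_depth: float = 50.0
    clade_effect_sd: float = 0.6
    # patients / CNVs
    n_patients: int = 100
    cancer_types: tuple[str, ...] = ("SIM",)
    cnv_count_mean: float = 30.0
    cnv_count_dispersion: float = 5.0
    cnv_len_min: int = 1_000
    cnv_len_max: int = 10_000_000
    mean_signal_mu: float = 0.35
    mean_signal_sd: float = 0.1
    mean_noise_sd: float = 0.04
    noise_component_prob: float = 0.15
    enriched_tads: dict[int, float] = field(default_factory=dict)  # tad index -> factor
    # survival
    causal_tads: dict[int, float] = field(default_factory=dict)  # tad index -> log HR
    beta_age: float = 0.3
    beta_sex: float = 0.0
    baseline_hazard: float = 1.0 / 1_000
    censoring_fraction: float = 0.25
    age_mean: float = 65.0
    age_sd: float = 10.0


def _round_grid(x) -> np.ndarray:
    return (np.asarray(x) // GRID * GRID).astype(np.int64)


def simulate_base_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> TADMap:
    """Draw the ground-truth TAD map by walking along each chromosome."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for chrom, size in config.chrom_sizes.items():
        pos = int(_round_grid(rng.lognormal(config.gap_size_log_mean, config.gap_size_log_sd)))
        while True:
            length = int(_round_grid(
                max(config.min_tad,
                    rng.lognormal(config.tad_size_log_mean, config.tad_size_log_sd))
            ))
            if pos + length > size - config.min_tad:
                break
            rows.append((chrom, pos, pos + length))
            gap = int(_round_grid(
                max(GRID, rng.lognormal(config.gap_size_log_mean, config.gap_size_log_sd))
            ))
            pos += length + gap
    return TADMap("base", "normal", pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def default_clade_tree(n_tissues: int) -> TreeNode:
    """A caterpillar of two balanced clades over tissue_00..tissue_{n-1}."""
    labels = [f"tissue_{i:02d}" for i in range(n_tissues)]
    half = max(1, n_tissues // 2)

    def chain(labs: list[str], depth: float) -> TreeNode:
        node = TreeNode(label=labs[0], branch_length=depth)
        for lab in labs[1:]:
            leaf = TreeNode(label=lab, branch_length=depth)
            node = TreeNode(children=[node, leaf], branch_length=depth / 2)
        return node

    left, right = chain(labels[:half], 0.2), chain(labels[half:], 0.2)
    return TreeNode(children=[left, right])


def _clades(n_tissues: int) -> list[list[int]]:
    half = max(1, n_tissues // 2)
    return [list(range(half)), list(range(half, n_tissues))]


def _edit_map(base: pd.DataFrame, rng, jitter_sd, split_prob, fusion_prob,
              chrom_sizes) -> pd.DataFrame:
    rows = []
    for chrom, sub in base.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy().copy()
        ends = sub["end"].to_numpy().copy()
        # fusion of adjacent pairs: fill the gap
        fuse = rng.random(max(len(starts) - 1, 0)) < fusion_prob
        keep_s, keep_e = [], []
        i = 0
        while i < len(starts):
            s, e = starts[i], ends[i]
            while i < len(starts) - 1 and fuse[i]:
                i += 1
                e = ends[i]
            keep_s.append(s)
            keep_e.append(e)
            i += 1
        out = []
        for s, e in zip(keep_s, keep_e):
            if rng.random() < split_prob and e - s >= 4 * GRID:
                cut = int(_round_grid(rng.integers(s + 2 * GRID, e - 2 * GRID)))
                out.extend([(s, cut), (cut + GRID, e)])
            else:
                out.append((s, e))
        # boundary jitter, preserving order and non-overlap
        prev_end = 0
        size = chrom_sizes[chrom]
        for s, e in out:
            for _ in range(20):
                js = int(_round_grid(s + rng.normal(0, jitter_sd)))
                je = int(_round_grid(e + rng.normal(0, jitter_sd)))
                if prev_end <= js < je and je <= size:
                    s, e = js, je
                    break
            s, e = max(s, prev_end), min(e, size)
            if e - s >= GRID:
                rows.append((chrom, s, e))
                prev_end = e
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_tad_maps(config: SimulationConfig) -> tuple[list[TADMap], TADMap]:
    """Per-tissue TAD maps around a shared base map.

    Tissues of the same clade reuse the clade's edit template with
    probability ``clade_share_prob``, which correlates their maps beyond
    the shared base. Returns (maps, base map).
    """
    rng = np.random.default_rng(config.seed)
    base = simulate_base_map(config, rng)
    templates = {}
    for c, members in enumerate(_clades(config.n_tissues)):
        seed = int(rng.integers(0, 2**31 - 1))
        templates[c] = seed
    maps = []
    for c, members in enumerate(_clades(config.n_tissues)):
        for t in members:
            if rng.random() < config.clade_share_prob:
                sub_rng = np.random.default_rng(templates[c])
            else:
                sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
            if config.boundary_jitter_sd == 0 and config.split_prob == 0 and config.fusion_prob == 0:
                df = base.intervals.copy()
            else:
                df = _edit_map(base.intervals, sub_rng, config.boundary_jitter_sd,
                               config.split_prob, config.fusion_prob, config.chrom_sizes)
            maps.append(TADMap(f"tissue_{t:02d}", "normal", df))
    return maps, base


def simulate_expression(tree: TreeNode, n_genes: int = 3_000,
                        config: SimulationConfig | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Clade-correlated negative-binomial counts (genes x tissues).

    Latent per-gene log-means evolve as Brownian motion along the clade
    tree, so tissues separated by short paths have correlated profiles
    and the dendrogram built from the counts recovers the topology.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    effect_sd = config.clade_effect_sd

    leaves = tree.leaf_labels()
    offsets = {}

    def walk(node: TreeNode, acc: np.ndarray):
        acc = acc + rng.normal(0, effect_sd * np.sqrt(max(node.branch_length, 1e-12)), n_genes)
        if node.is_leaf:
            offsets[node.label] = acc
        for child in node.children:
            walk(child, acc)

    walk(tree, np.zeros(n_genes))
    base = rng.normal(np.log(config.expression_depth), 1.0, n_genes)
    disp = config.nb_dispersion
    data = {}
    for tissue in leaves:
        mu = np.exp(base + offsets[tissue])
        # NB via gamma-Poisson mixture
        lam = rng.gamma(shape=1 / disp, scale=mu * disp)
        data[tissue] = rng.poisson(lam)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(data, index=genes)


def _background_hit_prob(tad: tuple[str, int, int], lengths: np.ndarray,
                         chrom_sizes: dict[str, int]) -> float:
    """P(a uniformly placed CNV of random length overlaps the TAD)."""
    chrom, s, e = tad
    sizes = np.array(list(chrom_sizes.values()), dtype=float)
    total = np.maximum(sizes[None, :] - lengths[:, None] + 1, 1).sum(axis=1)
    size_c = chrom_sizes[chrom]
    lo = np.maximum(s - lengths + 1, 0)
    hi = np.minimum(e, size_c - lengths + 1)
    n_hit = np.maximum(hi - lo, 0)
    return float((n_hit / total).mean())


def simulate_cnvs(config: SimulationConfig, tads: TADMap) -> list[CNVSegment]:
    """Patient CNV segments with spiked recurrence in chosen TADs.

    Placement is uniform over valid genome positions except that each CNV
    is redirected to overlap an enriched TAD with a per-TAD probability
    chosen so that the patient-recurrence of that TAD is approximately
    ``factor`` times the background recurrence; lengths and segment means
    are drawn identically for background and redirected CNVs.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    tad_rows = list(tads.intervals.itertuples(index=False))

    # calibration: recurrence is defined on *filtered* CNVs, so estimate the
    # filter pass rate and the length distribution conditional on passing
    cal = np.random.default_rng(config.seed + 7)
    n_ref = 4_000
    ref_lengths = np.exp(cal.uniform(np.log(config.cnv_len_min),
                                     np.log(config.cnv_len_max), n_ref)).astype(np.int64)
    noise = cal.random(n_ref) < config.noise_component_prob
    means = np.where(noise, cal.normal(0.0, config.mean_noise_sd, n_ref),
                     cal.normal(config.mean_signal_mu, config.mean_signal_sd, n_ref))
    probes = np.maximum(1, cal.poisson(ref_lengths / 3_000))
    passes = ((ref_lengths > 1_000) & (ref_lengths <= 10_000_000)
              & (np.abs(means) > 0.1) & (probes >= 10))
    pass_rate = max(passes.mean(), 1e-3)
    m_eff = config.cnv_count_mean * pass_rate
    k = config.cnv_count_dispersion
    kept_lengths = ref_lengths[passes] if passes.any() else ref_lengths
    # for N ~ gamma-Poisson (mean m_eff, shape k) the recurrence at per-CNV
    # hit probability p is r(p) = 1 - (1 + m_eff p / k)^-k, exactly invertible
    redirect: dict[int, float] = {}
    for idx, factor in config.enriched_tads.items():
        row = tad_rows[idx]
        p_bg = _background_hit_prob((row.chrom, row.start, row.end), kept_lengths,
                                    config.chrom_sizes)
        r_bg = 1 - (1 + m_eff * p_bg / k) ** (-k)
        r_target = min(factor * r_bg, 0.95)
        p_hit = (k / m_eff) * ((1 - r_target) ** (-1 / k) - 1)
        redirect[idx] = max(p_hit - p_bg, 0.0)

    segments: list[CNVSegment] = []
    patient_no = 0
    for ctype in config.cancer_types:
        for _ in range(config.n_patients):
            pid = f"P{patient_no:05d}"
            patient_no += 1
            disp = config.cnv_count_dispersion
            lam = rng.gamma(shape=disp, scale=config.cnv_count_mean / disp)
            n_cnv = int(rng.poisson(lam))
            for _ in range(n_cnv):
                length = int(np.exp(rng.uniform(np.log(config.cnv_len_min),
                                                np.log(config.cnv_len_max))))
                placed = False
                u = rng.random()
                acc = 0.0
                for idx, p_extra in redirect.items():
                    acc += p_extra
                    if u < acc:
                        row = tad_rows[idx]
                        size_c = config.chrom_sizes[row.chrom]
                        lo = max(row.start - length + 1, 0)
                        hi = min(row.end, size_c - length + 1)
                        if hi > lo:
                            start = int(rng.integers(lo, hi))
                            chrom = row.chrom
                            placed = True
                        break
                if not placed:
                    placements = np.maximum(sizes - length + 1, 1)
                    ci = rng.choice(len(chroms), p=placements / placements.sum())
                    chrom = chroms[ci]
                    start = int(rng.integers(0, placements[ci]))
                if rng.random() < config.noise_component_prob:
                    mean = rng.normal(0.0, config.mean_noise_sd)
                else:
                    mean = rng.normal(config.mean_signal_mu, config.mean_signal_sd)
                    if rng.random() < 0.5:
                        mean = -mean
                if mean == 0.0:
                    mean = 0.01
                probes = max(1, int(rng.poisson(length / 3_000)))
                segments.append(
                    CNVSegment(
                        patient_id=pid,
                        cancer_type=ctype,
                        interval=GenomicInterval(chrom, start, start + length),
                        num_probes=probes,
                        segment_mean=float(mean),
                    )
                )
    return segments


def simulate_survival(features: pd.DataFrame, config: SimulationConfig,
                      seed: int | None = None) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival over binary features.

    The linear predictor is sum(beta_j x_j) + beta_age * age_high +
    beta_sex * sex over the columns named in ``causal_tads`` (by column
    position) plus the demographic effects; censoring times are uniform
    on (0, c_max) with c_max calibrated so the realized censoring
    fraction matches the target.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = len(features)
    ages = rng.normal(config.age_mean, config.age_sd, n)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    age_high = (ages > np.median(ages)).astype(float)
    sex_ind = (sexes == "female").astype(float)

    lp = np.zeros(n)
    cols = list(features.columns)
    for idx, beta in config.causal_tads.items():
        lp += beta * features[cols[idx]].to_numpy(dtype=float)
    lp += config.beta_age * age_high + config.beta_sex * sex_ind

    t_true = rng.exponential(1.0 / (config.baseline_hazard * np.exp(lp)))
    frac = config.censoring_fraction
    if frac <= 0:
        times, events = t_true, np.ones(n, dtype=int)
    else:
        # P(C < T) with C ~ U(0, c) equals mean(min(t_i/c, 1)); bisect on c
        lo_c, hi_c = 1e-6, float(t_true.max()) * 100
        for _ in range(80):
            mid = np.sqrt(lo_c * hi_c)
            if np.minimum(t_true / mid, 1.0).mean() > frac:
                lo_c = mid
            else:
                hi_c = mid
        c_max = np.sqrt(lo_c * hi_c)
        cens = rng.uniform(0, c_max, n)
        events = (t_true <= cens).astype(int)
        times = np.minimum(t_true, cens)

    records = []
    for i, pid in enumerate(features.index):
        records.append(
            SurvivalRecord(
                patient_id=str(pid),
                cancer_type=config.cancer_types[0],
                time=float(times[i]),
                event=int(events[i]),
                age=float(ages[i]),
                sex=str(sexes[i]),
            )
        )
    return records


def derive_cancer_map(base: TADMap, split_indices: dict[int, int] | list[int] = (),
                      fuse_groups: list[list[int]] = ()) -> TADMap:
    """Apply known split/fusion edits to the base map -> a "cancer" map.

    ``split_indices`` TADs are cut at their midpoint (two halves separated
    by one grid step); each group in ``fuse_groups`` (adjacent TAD
    indices) is merged into a single TAD spanning the group. Gives
    labeled ground truth for the classification operations.
    """
    df = base.intervals
    fuse_lookup = {}
    for g, group in enumerate(fuse_groups):
        for idx in group:
            fuse_lookup[idx] = g
    split_set = set(split_indices)
    rows = []
    done_groups = set()
    for i, row in enumerate(df.itertuples(index=False)):
        if i in fuse_lookup:
            g = fuse_lookup[i]
            if g in done_groups:
                continue
            members = fuse_groups[g]
            chroms = {df.iloc[j]["chrom"] for j in members}
            if len(chroms) != 1:
                raise ValueError("fusion group spans chromosomes")
            rows.append((row.chrom, int(df.iloc[members[0]]["start"]),
                         int(df.iloc[members[-1]]["end"])))
            done_groups.add(g)
        elif i in split_set:
            mid = int(_round_grid((row.start + row.end) // 2))
            rows.append((row.chrom, row.start, mid))
            rows.append((row.chrom, mid + GRID, row.end))
        else:
            rows.append((row.chrom, row.start, row.end))
    return TADMap("cancer_consensus", "cancer",
                  pd.DataFrame(rows, columns=["chrom", "start", "end"]))
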