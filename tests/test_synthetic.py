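"""The synthetic cohort generator: determinism, planted structure, the
alignment fixture and the seq→qPCR coupling."""

import numpy as np
import pandas as pd
import pytest

from tepscore import (
    SyntheticCohortConfig,
    count_isr,
    generate_cohort,
    generate_spliced_alignments,
    simulate_cq,
    simulate_dataset,
    simulate_junction_counts,
    validate_marker,
)
from tepscore.markers import reverse_delta_cq, scale_log2cpm
from tepscore.qpcr import collapse_replicates
from tepscore.simulate import junction_annotation


def test_cohort_mirrors_study_design():
    meta = generate_cohort(SyntheticCohortConfig())
    sizes = meta.groupby(["group", "split"]).size()
    assert len(meta) == 90
    assert sizes[("OC", "train")] == 13 and sizes[("Benign", "train")] == 16
    assert sizes[("OC", "test")] == 4 and sizes[("Benign", "test")] == 21
    assert sizes[("BOT", "test")] == 2
    assert (meta["group"] == "AC").sum() == 34  # full validation control set
    # training sequencing cohort: 13 OC + 16 Benign + 32 AC = 61
    assert (meta["split"] == "train").sum() == 61


def test_dataset_is_deterministic_in_seed():
    a = simulate_dataset(SyntheticCohortConfig(seed=9))
    b = simulate_dataset(SyntheticCohortConfig(seed=9))
    pd.testing.assert_frame_equal(a.meta, b.meta)
    pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
    pd.testing.assert_frame_equal(a.cq, b.cq)
    c = simulate_dataset(SyntheticCohortConfig(seed=10))
    assert not a.counts.counts.equals(c.counts.counts)


def test_boundary_config_fully_penetrant_markers():
    cfg = SyntheticCohortConfig(seed=3, control_leak_rate=0.0,
                               expressing_fraction=1.0)
    meta = generate_cohort(cfg)
    matrix, expressing = simulate_junction_counts(meta, cfg)
    controls = meta.index[meta["group"].isin(["AC", "Benign"])]
    oc = meta.index[meta["group"] == "OC"]
    markers = list(cfg.marker_names)
    assert (matrix.counts.loc[markers, controls] == 0).all().all()
    assert (matrix.counts.loc[markers, oc] > 0).all().all()
    assert expressing[oc].all().all()


def test_library_size_covers_simulated_column_sums():
    ds = simulate_dataset(SyntheticCohortConfig(seed=4))
    assert (ds.counts.library_size >= ds.counts.counts.sum(axis=0)).all()


def test_planted_alignments_recovered_and_decoys_rejected(tmp_path):
    cfg = SyntheticCohortConfig(n_background_junctions=15)
    juncs = junction_annotation(cfg)
    rng = np.random.default_rng(12)
    planted = pd.Series(rng.integers(0, 9, len(juncs)),
                        index=[j.junction_id for j in juncs])
    sam = tmp_path / "reads.sam"
    generate_spliced_alignments(juncs, planted, sam, seed=12, decoys=True)
    counts, _ = count_isr(sam, juncs)
    pd.testing.assert_series_equal(counts, planted, check_names=False,
                                   check_dtype=False)


def test_decoy_only_and_empty_alignment_files(tmp_path):
    cfg = SyntheticCohortConfig(n_background_junctions=5)
    juncs = junction_annotation(cfg)
    zero = pd.Series(0, index=[j.junction_id for j in juncs])
    decoy_sam = tmp_path / "decoys.sam"
    generate_spliced_alignments(juncs, zero, decoy_sam, seed=0, decoys=True)
    counts, stats = count_isr(decoy_sam, juncs)
    assert (counts == 0).all() and stats.primary_reads > 0
    plain_sam = tmp_path / "empty.sam"
    generate_spliced_alignments(juncs, zero, plain_sam, seed=0, decoys=False)
    counts2, _ = count_isr(plain_sam, juncs)
    assert (counts2 == 0).all()


def test_noiseless_cq_gives_perfect_seq_pcr_correlation():
    cfg = SyntheticCohortConfig(seed=6, seq_pcr_noise_sd=0.0,
                               replicate_noise_sd=0.0, actb_cq_sd=0.0,
                               expressing_fraction=1.0, dropout_cq=80.0)
    meta = generate_cohort(cfg)
    matrix, _ = simulate_junction_counts(meta, cfg)
    log2cpm = matrix.log2cpm()
    cq = simulate_cq(meta, log2cpm, cfg)
    collapsed = collapse_replicates(cq)
    actb = collapsed.values["ACTB"]
    oc = meta.index[meta["group"] == "OC"]
    for m in cfg.marker_names[:3]:
        dcq = (collapsed.values[m] - actb).loc[oc]
        scaled = scale_log2cpm(log2cpm.loc[m, oc], log2cpm.loc["ACTB", oc])
        v = validate_marker(m, scaled, reverse_delta_cq(dcq))
        assert v.r_squared == pytest.approx(1.0, abs=1e-9)


def test_default_noise_keeps_seq_pcr_r2_in_band():
    """With default parameters the seq→PCR coupling lands expressed-marker
    R² inside the plausible (0.4, 1.0) band for the vast majority of runs."""
    hits = total = 0
    for seed in range(50):
        cfg = SyntheticCohortConfig(seed=seed)
        meta = generate_cohort(cfg)
        rng = np.random.default_rng(cfg.seed)
        matrix, expressing = simulate_junction_counts(meta, cfg, rng)
        log2cpm = matrix.log2cpm()
        cq = simulate_cq(meta, log2cpm, cfg, rng)
        collapsed = collapse_replicates(cq)
        actb_cq = collapsed.values["ACTB"]
        train = meta.index[meta["split"] == "train"]
        for m in cfg.marker_names[:4]:
            detected = ~collapsed.undetected[m]
            keep = train.intersection(detected[detected].index)
            if len(keep) < 3:
                continue
            dcq = (collapsed.values[m] - actb_cq).loc[keep]
            scaled = scale_log2cpm(log2cpm.loc[m, keep], log2cpm.loc["ACTB", keep])
            v = validate_marker(m, scaled, reverse_delta_cq(dcq))
            total += 1
            hits += 0.4 < v.r_squared < 1.0
    assert total >= 100
    assert hits / total >= 0.9


def test_null_effect_markers_are_silent():
    cfg = SyntheticCohortConfig(seed=2, marker_effect=0.0)
    meta = generate_cohort(cfg)
    matrix, _ = simulate_junction_counts(meta, cfg)
    markers = list(cfg.marker_names)
    leak_free = matrix.counts.loc[markers]
    # at zero effect the expressing level collapses to zero expression
    oc = meta.index[meta["group"] == "OC"]
    assert (leak_free[oc] == 0).all().all()
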