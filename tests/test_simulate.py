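"""Synthetic cohort generator: determinism, calibration, ground truth."""

import numpy as np
import pytest

from spermage import (
    DmrTruth,
    GenomicInterval,
    SimConfig,
    default_dbs_panel,
    fit_linear_trend,
    generate_cohort,
    generate_dbs_measurements,
    generate_embryo_trajectories,
    generate_methylomes,
    make_landscape,
    pool_methylomes,
    select_dbs_cohorts,
    select_pool_donors,
)

SMALL = dict(n_chromosomes=1, cpgs_per_chromosome=3000, n_dmrs_sperm=4, n_dmrs_blood=4)


class TestCohort:
    def test_default_cohort_has_197_donors_in_the_right_bins(self):
        donors = generate_cohort(SimConfig(seed=3))
        assert len(donors) == 197
        sizes = {}
        for d in donors:
            sizes[d.age_group] = sizes.get(d.age_group, 0) + 1
        assert sizes == {1: 34, 2: 36, 3: 28, 4: 39, 5: 36, 6: 24}
        assert all(18 <= d.age <= 84 for d in donors)

    def test_same_seed_gives_identical_cohort(self):
        a = generate_cohort(SimConfig(seed=11))
        b = generate_cohort(SimConfig(seed=11))
        assert [(d.donor_id, d.age, d.dfi_percent, d.rtl_blood) for d in a] == [
            (d.donor_id, d.age, d.dfi_percent, d.rtl_blood) for d in b
        ]
        assert [d.clinical for d in a] == [d.clinical for d in b]

    def test_noiseless_telomere_slopes_recovered_exactly(self):
        cfg = SimConfig(
            seed=5, telomere_noise_sd=0.0, rtl_missing_blood=0, rtl_missing_sperm=0
        )
        donors = generate_cohort(cfg)
        ages = [d.age for d in donors]
        fb = fit_linear_trend(ages, [d.rtl_blood for d in donors])
        fs = fit_linear_trend(ages, [d.rtl_sperm for d in donors])
        assert fb.slope == pytest.approx(-0.0055, abs=1e-12)
        assert fs.slope == pytest.approx(0.0077, abs=1e-12)

    def test_empty_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(group_sizes=())

    def test_group_means_track_the_configured_trend(self):
        """Calibration: per-group clinical means lie on the generating
        trend line. Each (parameter, group) cell is a Gaussian mean, so a
        few of the 96 cells are expected just past 2 pooled SEs; the check
        is that ~95% are within 2 SE and every cell is within 4 SE."""
        cells = within2 = 0
        for seed in (0, 1):
            cfg = SimConfig(seed=seed)
            donors = generate_cohort(cfg)
            for name, (b0, b1, sd) in cfg.clinical_trends.items():
                for g in range(1, 7):
                    vals = [d.clinical[name] for d in donors if d.age_group == g]
                    ages = [d.age for d in donors if d.age_group == g]
                    expect = b0 + b1 * np.mean(ages)
                    se = sd / np.sqrt(len(vals))
                    dev = abs(np.mean(vals) - expect)
                    # clipping at zero can pull means up slightly
                    assert dev < 4 * se + 0.05 * sd, (name, g, seed)
                    cells += 1
                    within2 += dev < 2 * se + 0.05 * sd
        assert within2 / cells >= 0.9

    def test_rtl_missingness_matches_study_ns(self):
        donors = generate_cohort(SimConfig(seed=2))
        assert sum(d.rtl_blood is not None for d in donors) == 194
        assert sum(d.rtl_sperm is not None for d in donors) == 179


class TestMethylomes:
    def test_tracks_deterministic_and_subset_invariant(self):
        cfg = SimConfig(seed=7, **SMALL)
        donors = generate_cohort(cfg)[:3]
        land = make_landscape(cfg)
        t1 = generate_methylomes(donors, cfg, "sperm", land)
        t2 = generate_methylomes(donors[1:2], cfg, "sperm", land)
        a, b = t1[1].chroms["chr1"], t2[0].chroms["chr1"]
        assert np.array_equal(a.meth, b.meth)
        assert np.array_equal(a.total, b.total)

    def test_truth_regions_have_expected_beta(self):
        cfg = SimConfig(seed=7, **SMALL, mean_coverage=2000)
        donors = generate_cohort(cfg)
        land = make_landscape(cfg)
        young, old = select_pool_donors(donors)
        track = generate_methylomes(old[-1:], cfg, "sperm", land)[0]
        d = old[-1]
        for t in land.truths["sperm"]:
            arr = track.chroms[t.interval.chrom]
            lo = np.searchsorted(arr.pos, t.interval.start)
            hi = np.searchsorted(arr.pos, t.interval.end)
            observed = arr.meth[lo:hi].sum() / arr.total[lo:hi].sum()
            assert observed == pytest.approx(float(t.beta_at(d.age)), abs=0.03)

    def test_sperm_and_blood_truths_disjoint(self):
        land = make_landscape(SimConfig(seed=1, **SMALL))
        for ts in land.truths["sperm"]:
            for tb in land.truths["blood"]:
                assert not ts.interval.overlaps(tb.interval)

    def test_overlapping_truth_override_rejected(self):
        truth = {
            "sperm": [
                DmrTruth(GenomicInterval("chr1", 100, 400), 0.008, 0.1),
                DmrTruth(GenomicInterval("chr1", 300, 600), 0.008, 0.1),
            ],
            "blood": [],
        }
        cfg = SimConfig(seed=1, **{**SMALL, "n_dmrs_sperm": 0}, dmr_truth=truth)
        with pytest.raises(ValueError, match="overlapping"):
            make_landscape(cfg)


class TestPooling:
    def test_pooling_one_track_is_identity(self):
        cfg = SimConfig(seed=9, **SMALL)
        donors = generate_cohort(cfg)[:1]
        (track,) = generate_methylomes(donors, cfg, "sperm")
        pooled = pool_methylomes([track])
        assert np.array_equal(
            pooled.chroms["chr1"].meth, track.chroms["chr1"].meth
        )

    def test_two_site_pool_is_count_sum(self):
        from conftest import make_track

        a = make_track([10], [3], [10])
        b = make_track([10], [7], [10])
        pooled = pool_methylomes([a, b])
        arr = pooled.chroms["chr1"]
        assert (int(arr.meth[0]), int(arr.total[0])) == (10, 20)
        assert arr.beta[0] == 0.5

    def test_pooled_counts_conserved_at_every_site(self):
        cfg = SimConfig(seed=9, **SMALL)
        donors = generate_cohort(cfg)[:4]
        tracks = generate_methylomes(donors, cfg, "sperm")
        pooled = pool_methylomes(tracks)
        total_sum = sum(t.chroms["chr1"].total for t in tracks)
        assert np.array_equal(pooled.chroms["chr1"].total, total_sum)

    def test_mismatched_positions_rejected(self):
        from conftest import make_track

        a = make_track([10], [3], [10])
        b = make_track([11], [7], [10])
        with pytest.raises(ValueError, match="positions"):
            pool_methylomes([a, b])


class TestDbs:
    def test_panel_yields_462_measurements_for_42_donors(self):
        cfg = SimConfig(seed=4)
        donors = generate_cohort(cfg)
        train, valid = select_dbs_cohorts(donors, config=cfg)
        assert len(train) == 42 and len(valid) == 33
        assert not {d.donor_id for d in train} & {d.donor_id for d in valid}
        dbs = generate_dbs_measurements(train, default_dbs_panel(cfg), config=cfg)
        assert len(dbs) == 462

    def test_high_depth_concentrates_on_the_age_line(self):
        cfg = SimConfig(seed=4)
        donors = generate_cohort(cfg)[:42]
        panel = default_dbs_panel(cfg)
        dbs = generate_dbs_measurements(
            donors, panel, depth=100_000, beta_noise_sd=0.0, config=cfg
        )
        ages = {d.donor_id: d.age for d in donors}
        devs = [
            abs(m.mean_meth - float(panel[m.region_id].beta_at(ages[m.donor_id])))
            for m in dbs
        ]
        assert max(devs) < 0.01

    def test_zero_beta_gives_exact_zero(self):
        panel = {"flat0": DmrTruth(GenomicInterval("p", 0, 10), 0.0, 0.0)}
        donors = generate_cohort(SimConfig(seed=1))[:5]
        dbs = generate_dbs_measurements(
            donors, panel, depth=50, beta_noise_sd=0.0
        )
        assert all(m.mean_meth == 0.0 for m in dbs)

    def test_unknown_region_id_rejected(self):
        cfg = SimConfig(seed=1)
        donors = generate_cohort(cfg)[:5]
        with pytest.raises(KeyError, match="nope"):
            generate_dbs_measurements(
                donors, default_dbs_panel(cfg), region_ids=["nope"]
            )


class TestEmbryo:
    def test_flags_recovered_by_direct_thresholds(self):
        flags = {f"r{i}": i % 3 == 0 for i in range(60)}
        trajs = generate_embryo_trajectories(list(flags), flags, seed=2)
        for t in trajs:
            m = np.asarray(t.meth)
            is_esc = m.min() >= 0.30 and (m.max() - m.min()) < 0.30
            assert is_esc == flags[t.region_id]

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            generate_embryo_trajectories([], {}, seed=0)

    def test_stage_list_must_end_at_late_pronucleus(self):
        cfg = SimConfig(embryo_stages=("sperm", "zygote_early_PN"))
        with pytest.raises(ValueError, match="zygote_late_PN"):
            generate_embryo_trajectories(["r"], {"r": True}, config=cfg)

    def test_deterministic_under_seed(self):
        flags = {"a": True, "b": False}
        t1 = generate_embryo_trajectories(["a", "b"], flags, seed=5)
        t2 = generate_embryo_trajectories(["a", "b"], flags, seed=5)
        assert [t.meth for t in t1] == [t.meth for t in t2]
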