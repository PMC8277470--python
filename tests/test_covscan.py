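"""Coverage-scan behaviour: windowing, normalization, calling, properties."""

import io

import numpy as np
import pandas as pd
import pytest

from sexscan import covscan as cov
from sexscan import synth
from sexscan.models import FixtureConfig, ValidationError

from .oracles import brute_force_region_scan


def make_track(depths, window=1000, sample_id="s", sex="M", scaffold="sc"):
    df = pd.DataFrame(
        {"scaffold": scaffold, "pos": np.arange(1, len(depths) + 1), "depth": depths}
    )
    return cov.window_depth(df, window, sample_id=sample_id, sex=sex)


class TestWindowDepth:
    def test_constant_depth_partial_trailing_window(self):
        t = make_track([10] * 2500)
        assert list(t.windows["mean_depth"]) == [10.0, 10.0, 10.0]
        assert list(t.windows["end"]) == [1000, 2000, 2500]

    def test_ten_kb_scaffold_gives_ten_windows(self):
        t = make_track([5] * 10_000)
        assert len(t.windows) == 10

    def test_window_means_match_slice_mean_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 60, size=3000)
        t = make_track(d)
        for w in range(3):
            assert t.windows["mean_depth"].iloc[w] == pytest.approx(
                d[1000 * w : 1000 * (w + 1)].mean()
            )

    def test_absent_positions_count_as_zero(self):
        # only every other position reported
        df = pd.DataFrame(
            {"scaffold": "sc", "pos": np.arange(1, 2001, 2), "depth": 10}
        )
        t = cov.window_depth(df, 1000, scaffold_lengths={"sc": 2000})
        assert list(t.windows["mean_depth"]) == [5.0, 5.0]

    def test_nonmonotone_positions_name_line(self):
        tsv = io.StringIO("sc\t1\t5\nsc\t3\t5\nsc\t2\t5\n")
        with pytest.raises(ValidationError, match="line 3"):
            cov.window_depth(tsv, 1000)

    def test_malformed_rows_raise(self):
        tsv = io.StringIO("sc\t1\t5\nsc\tNOPE\t5\n")
        with pytest.raises(ValidationError):
            cov.window_depth(tsv, 1000)

    def test_file_and_inmemory_paths_agree(self, sim_dir, cohort, default_config):
        sample = next(iter(cohort.depth))
        path = sim_dir / "depth" / f"{sample}.depth.tsv"
        from_file = cov.window_depth(
            str(path), default_config.window_size, sample_id=sample, sex="M"
        )
        from_mem = synth.windowed_tracks(cohort)[0]
        pd.testing.assert_frame_equal(from_file.windows, from_mem.windows)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_log2_plus_one(self, raw, expected):
        t = make_track([raw] * 1000)
        assert cov.normalize_depth(t).windows["mean_depth"].iloc[0] == expected


class TestCompareSexes:
    def test_identical_samples_are_symmetric(self):
        d = list(np.random.default_rng(0).integers(0, 50, 3000))
        raw = [make_track(d, sample_id="m", sex="M"), make_track(d, sample_id="f", sex="F")]
        norm = [cov.normalize_depth(t) for t in raw]
        comp = cov.compare_sexes(norm, raw)
        assert np.allclose(comp["mean_norm_F"], comp["mean_norm_M"])

    def test_mean_is_arithmetic_mean(self):
        tracks = []
        for val, sid in zip((1, 3, 7), "abc"):
            tracks.append(make_track([val] * 1000, sample_id=sid, sex="M"))
        tracks.append(make_track([0] * 1000, sample_id="f", sex="F"))
        norm = [cov.normalize_depth(t) for t in tracks]
        comp = cov.compare_sexes(norm, tracks)
        # log2(2), log2(4), log2(8) -> mean 2
        assert comp["mean_norm_M"].iloc[0] == pytest.approx(2.0)

    def test_female_zero_inside_true_region(self, comparisons, cohort):
        scaffold, (s, e) = cohort.truth.true_region
        inside = comparisons[
            (comparisons["scaffold"] == scaffold)
            & (comparisons["start"] >= s)
            & (comparisons["end"] <= e)
        ]
        assert len(inside) == 5
        assert (inside["mean_norm_F"] == 0).all()
        assert (inside["max_raw_F"] == 0).all()

    def test_grid_mismatch_reports_first_discordant_window(self):
        a = make_track([5] * 3000)
        b = make_track([5] * 2000, sample_id="b", sex="F")
        with pytest.raises(ValidationError, match="grid mismatch"):
            cov.compare_sexes([a, b], [a, b])


def random_comparison_grid(seed, n_windows=200, n_planted=3):
    """A single-scaffold comparison table with planted female-zero runs."""
    rng = np.random.default_rng(seed)
    starts = np.arange(n_windows) * 1000
    max_raw_f = rng.uniform(5, 40, n_windows)
    norm_m = rng.uniform(3.5, 5.5, n_windows)
    planted = []
    while len(planted) < n_planted:
        s = int(rng.integers(0, n_windows - 6))
        ln = int(rng.integers(3, 7))
        if all(s + ln < p or s > p + pl for p, pl in planted):
            planted.append((s, ln))
            max_raw_f[s : s + ln] = 0.0
    comp = pd.DataFrame(
        {
            "scaffold": "sc",
            "start": starts,
            "end": starts + 1000,
            "mean_norm_F": np.log2(max_raw_f + 1) / 2,
            "mean_norm_M": norm_m,
            "n_F": 5,
            "n_M": 5,
            "max_raw_F": max_raw_f,
            "max_raw_M": rng.uniform(5, 40, n_windows),
        }
    )
    comp.attrs["median_raw_depth"] = 30.0
    return comp


class TestCallSexSpecific:
    def test_default_fixture_one_region_of_5kb(self, comparisons, cohort):
        regions = cov.call_sex_specific(comparisons)
        assert len(regions) == 1
        r = regions[0]
        assert (r.scaffold, (r.start, r.end)) == cohort.truth.true_region
        assert r.length == 5000
        assert r.specificity == "male_specific"

    def test_identical_sexes_give_empty_list(self):
        d = list(np.random.default_rng(3).integers(10, 50, 3000))
        raw = [make_track(d, sample_id="m", sex="M"), make_track(d, sample_id="f", sex="F")]
        norm = [cov.normalize_depth(t) for t in raw]
        assert cov.call_sex_specific(cov.compare_sexes(norm, raw)) == []

    def test_matches_brute_force_scan_oracle(self):
        """Planted female-zero runs: calls equal an independent full scan."""
        comp = random_comparison_grid(seed=9)
        tau, min_present, max_gap, min_windows = 0.0, 3.0, 1, 3
        regions = cov.call_sex_specific(
            comp, tau_absent=tau, min_present=min_present,
            max_gap=max_gap, min_windows=min_windows,
        )
        seeds = [
            bool(f <= tau and m >= min_present)
            for f, m in zip(comp["max_raw_F"], comp["mean_norm_M"])
        ]
        windows = list(zip(comp["start"], comp["end"]))
        expected = brute_force_region_scan(windows, seeds, max_gap, min_windows)
        assert [(r.start, r.end, r.n_windows) for r in regions] == expected

    def test_sample_and_scaffold_order_invariance(self, cohort):
        raw = synth.windowed_tracks(cohort)
        norm = [cov.normalize_depth(t) for t in raw]
        base = cov.call_sex_specific(cov.compare_sexes(norm, raw))
        rng = np.random.default_rng(0)
        order = rng.permutation(len(raw))
        shuffled = cov.compare_sexes([norm[i] for i in order], [raw[i] for i in order])
        assert cov.call_sex_specific(shuffled) == base

    def test_tau_monotonicity_grows_seed_set(self):
        comp = random_comparison_grid(seed=5)
        kw = dict(min_present=3.0, max_gap=0, min_windows=1)
        low = cov.call_sex_specific(comp, tau_absent=0.0, **kw)
        high = cov.call_sex_specific(comp, tau_absent=10.0, **kw)
        low_w = {(r.start, r.end) for r in low}
        high_cover = set()
        for r in high:
            high_cover.update(range(r.start, r.end, 1000))
        for s, e in low_w:
            assert all(w in high_cover for w in range(s, e, 1000))

    def test_min_windows_monotonicity(self):
        comp = random_comparison_grid(seed=11)
        counts = [
            len(cov.call_sex_specific(comp, min_present=3.0, min_windows=k))
            for k in (1, 2, 3, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_label_swap_symmetry(self, cohort):
        raw = synth.windowed_tracks(cohort)
        swapped_raw = [
            cov.DepthTrack(t.sample_id, "M" if t.sex == "F" else "F", t.windows)
            for t in raw
        ]
        norm = [cov.normalize_depth(t) for t in swapped_raw]
        comp = cov.compare_sexes(norm, swapped_raw)
        assert cov.call_sex_specific(comp, mode="male_specific") == []
        fem = cov.call_sex_specific(comp, mode="female_specific")
        assert len(fem) == 1 and fem[0].length == 5000


def test_depth_panel_plot_renders(comparisons, tmp_path):
    out = tmp_path / "panel.png"
    cov.plot_depth_panel(comparisons, str(out), regions=cov.call_sex_specific(comparisons))
    assert out.exists() and out.stat().st_size > 0


class TestPlantedTruthRecovery:
    def test_region_recovered_across_20_seeds(self, genes):
        """>=19/20 seeds recover the planted region at >=90% reciprocal overlap."""
        hits = 0
        for seed in range(1, 21):
            cfg = FixtureConfig(seed=seed)
            cohort = synth.build_cohort(cfg, genes)
            raw = synth.windowed_tracks(cohort)
            norm = [cov.normalize_depth(t) for t in raw]
            regions = cov.call_sex_specific(cov.compare_sexes(norm, raw))
            truth = (cohort.truth.true_region[0], *cohort.truth.true_region[1])
            if len(regions) == 1 and cov.reciprocal_overlap(
                (regions[0].scaffold, regions[0].start, regions[0].end), truth
            ) >= 0.9:
                hits += 1
        assert hits >= 19
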