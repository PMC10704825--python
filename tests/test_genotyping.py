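import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plantkaryo import (
    CrossSimConfig,
    GenomeLayout,
    GenotypingConfig,
    InformativeSite,
    SampleCall,
    VariantSite,
    classify_origin,
    contribution_summary,
    filter_variants,
    genotype_origin,
    select_informative_sites,
    simulate_cross,
    site_index,
    site_index_table,
    sliding_window_index,
)


def _site(qd=20.0, fs=1.0, p1=(0, 0), p2=(1, 1), off=(0, 1),
          off_ad=(4, 2), off_dp=None, pos=100, chrom="A1"):
    dp = off_dp if off_dp is not None else (sum(off_ad) if off_ad else 0)
    return VariantSite(chrom, pos, "A", "T", qd, fs,
                       ref_parent=SampleCall(p1, None, 10),
                       other_parent=SampleCall(p2, None, 10),
                       offspring=SampleCall(off, off_ad, dp))


class TestFilterVariants:
    @pytest.mark.parametrize("qd,fs,kept", [
        (1.5, 1.0, False),    # low quality-by-depth removed
        (20.0, 61.0, False),  # strand bias removed
        (2.0, 60.0, True),    # boundary values pass (strict inequalities)
        (None, None, True),   # absent annotations pass
        (1.99, None, False),
    ])
    def test_thresholds(self, qd, fs, kept):
        out = filter_variants([_site(qd=qd, fs=fs)])
        assert (len(out) == 1) is kept


class TestSelectInformative:
    def test_canonical_case(self):
        out = select_informative_sites([_site(p1=(0, 0), p2=(1, 1), off_ad=(4, 2))])
        assert len(out) == 1
        s = out[0]
        assert s.ref_parent_allele == "A" and s.other_parent_allele == "T"
        assert (s.ref_parent_count, s.other_parent_count) == (4, 2)

    @pytest.mark.parametrize("p1,p2", [
        ((0, 1), (1, 1)),   # heterozygous parent
        ((0, 0), (0, 0)),   # identical parents
        (None, (1, 1)),     # missing call
    ])
    def test_uninformative_dropped(self, p1, p2):
        assert select_informative_sites([_site(p1=p1, p2=p2)]) == []

    def test_allele_role_swap(self):
        # reference parent carries ALT: AD (ref 4, alt 2) maps to
        # (ref_parent_count 2, other_parent_count 4)
        out = select_informative_sites([_site(p1=(1, 1), p2=(0, 0), off_ad=(4, 2))])
        s = out[0]
        assert (s.ref_parent_count, s.other_parent_count) == (2, 4)
        assert s.ref_parent_allele == "T"


class TestSiteIndex:
    def _inf(self, rc, oc, depth=None, gt=(0, 1), ref_idx=0):
        return InformativeSite("A1", 100, "A", "T", rc, oc,
                               depth if depth is not None else rc + oc, gt, ref_idx)

    def test_allele_fraction_third(self):
        assert site_index(self._inf(4, 2, depth=7)) == pytest.approx(2 / 6)

    def test_low_depth_excluded(self):
        assert site_index(self._inf(4, 2, depth=6)) is None

    def test_zero_denominator_excluded(self):
        assert site_index(self._inf(0, 0, depth=10)) is None

    def test_genotype_match_modes(self):
        cfg = GenotypingConfig(index_mode="genotype_match")
        assert site_index(self._inf(7, 0, gt=(0, 0)), cfg) == 0.0
        assert site_index(self._inf(0, 7, gt=(1, 1)), cfg) == 1.0
        assert site_index(self._inf(4, 3, gt=(0, 1)), cfg) == 1.0

    def test_indexes_bounded(self, rng):
        for _ in range(50):
            rc, oc = rng.integers(0, 30, size=2)
            idx = site_index(self._inf(int(rc), int(oc), depth=int(rc + oc)))
            assert idx is None or 0.0 <= idx <= 1.0


class TestSlidingWindows:
    LAYOUT = GenomeLayout((("A1", 10_000_000),))

    def test_constant_indexes(self):
        table = pd.DataFrame({"chrom": "A1",
                              "pos": np.arange(0, 10_000_000, 5_000),
                              "index": 0.5})
        win = sliding_window_index(table, self.LAYOUT)
        assert win.loc[~win["mean_index"].isna(), "mean_index"].eq(0.5).all()

    def test_matches_brute_force_double_loop(self, rng):
        pos = np.sort(rng.choice(10_000_000, size=1000, replace=False))
        idx = rng.uniform(0, 1, size=1000)
        table = pd.DataFrame({"chrom": "A1", "pos": pos, "index": idx})
        cfg = GenotypingConfig(window_size=2_000_000, step=500_000,
                               min_sites_per_window=1)
        win = sliding_window_index(table, self.LAYOUT, cfg)
        for row in win.itertuples(index=False):
            members = idx[(pos >= row.start) & (pos < row.start + cfg.window_size)]
            if len(members):
                assert row.mean_index == pytest.approx(members.mean())
                assert members.min() - 1e-12 <= row.mean_index <= members.max() + 1e-12
            else:
                assert np.isnan(row.mean_index)

    def test_sparse_windows_missing(self):
        table = pd.DataFrame({"chrom": ["A1"], "pos": [100], "index": [1.0]})
        win = sliding_window_index(table, self.LAYOUT)  # min 10 sites
        assert win["mean_index"].isna().all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_window_count_independent_of_data(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 50))
        table = pd.DataFrame({
            "chrom": "A1",
            "pos": np.sort(r.choice(10_000_000, size=n, replace=False)),
            "index": r.uniform(0, 1, size=n),
        })
        win = sliding_window_index(table, self.LAYOUT)
        assert len(win) == 1000  # ceil(length / step), windows anchored at 0
        assert int(win["n_sites"].sum()) >= n  # overlapping windows recount sites


class TestClassifyOrigin:
    def _windows(self, means, chrom="A1", step=10_000, window=2_000_000):
        starts = np.arange(len(means)) * step
        return pd.DataFrame({"chrom": chrom, "start": starts,
                             "end": starts + window,
                             "mid": starts + window // 2,
                             "mean_index": means, "n_sites": 50})

    @pytest.mark.parametrize("mean,cls", [
        (0.05, "homozygous_ref_parent"),
        (0.2, "homozygous_ref_parent"),    # boundary belongs to homozygous
        (0.5, "heterozygous"),
        (0.8, "homozygous_other_parent"),
        (0.95, "homozygous_other_parent"),
    ])
    def test_window_classes(self, mean, cls):
        segs = classify_origin(self._windows([mean]))
        assert [s.origin for s in segs] == [cls]

    def test_runs_merged_and_missing_bridges(self):
        means = [0.9, 0.9, np.nan, 0.9, 0.1, 0.1]
        segs = classify_origin(self._windows(means))
        assert [s.origin for s in segs] == ["homozygous_other_parent",
                                            "homozygous_ref_parent"]
        assert segs[0].n_windows == 3  # the marker desert did not split the run

    def test_every_window_classified_once(self, rng):
        means = rng.uniform(0, 1, size=200)
        segs = classify_origin(self._windows(means))
        assert sum(s.n_windows for s in segs) == 200


class TestContribution:
    LAYOUT = GenomeLayout((("A1", 10_000_000),))

    def test_all_reference_parent(self):
        table = pd.DataFrame({"chrom": "A1",
                              "pos": np.arange(0, 10_000_000, 10_000),
                              "index": 0.0})
        win = sliding_window_index(table, self.LAYOUT)
        summary = contribution_summary(table, win, self.LAYOUT)
        genome = summary[summary["chrom"] == "genome"].iloc[0]
        assert genome["other_parent_fraction"] == 0.0
        assert genome["ref_parent_fraction"] == 1.0

    def test_fractions_complementary(self, rng):
        table = pd.DataFrame({"chrom": "A1",
                              "pos": np.arange(0, 10_000_000, 10_000),
                              "index": rng.uniform(0, 1, size=1000)})
        win = sliding_window_index(table, self.LAYOUT)
        summary = contribution_summary(table, win, self.LAYOUT)
        total = summary["other_parent_fraction"] + summary["ref_parent_fraction"]
        np.testing.assert_allclose(total, 1.0)


class TestPipelineProperties:
    LAYOUT = GenomeLayout((("A1", 20_000_000),))

    def _cross(self, d, t, seed=11, **kw):
        cfg = CrossSimConfig(self.LAYOUT, [("A1", 0, 20_000_000, d, t)],
                             sites_per_mb=25, mean_depth=10.0, seed=seed, **kw)
        return simulate_cross(cfg)[0]

    def test_parent_swap_symmetry(self):
        sites = self._cross(1, 3)
        swapped = [VariantSite(s.chrom, s.pos, s.ref, s.alt, s.qd, s.fs,
                               ref_parent=s.other_parent,
                               other_parent=s.ref_parent,
                               offspring=s.offspring)
                   for s in sites]
        t1 = site_index_table(select_informative_sites(sites))
        t2 = site_index_table(select_informative_sites(swapped))
        np.testing.assert_allclose(t2["index"], 1.0 - t1["index"], atol=1e-12)

    def test_dosage_monotonicity(self):
        means = []
        for d in range(0, 4):
            table = site_index_table(select_informative_sites(self._cross(d, 3)))
            means.append(table["index"].mean())
            assert means[-1] == pytest.approx(d / 3, abs=0.03)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_origin_breakpoint_recovered_within_one_window(self):
        cfg = CrossSimConfig(
            self.LAYOUT,
            [("A1", 0, 10_000_000, 2, 2), ("A1", 10_000_000, 20_000_000, 0, 2)],
            sites_per_mb=25, mean_depth=10.0, seed=4,
        )
        sites, _ = simulate_cross(cfg)
        res = genotype_origin(sites, self.LAYOUT)
        classes = [s.origin for s in res.segments]
        assert classes[0] == "homozygous_other_parent"
        assert classes[-1] == "homozygous_ref_parent"
        # boundary between the two homozygous blocks within one window (2 Mb)
        boundary = res.segments[0].end
        assert abs(boundary - 10_000_000) <= 2_000_000
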