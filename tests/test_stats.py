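"""Sliding-window statistic against hand enumerations, literal-definition
oracles, and its own distributional guarantees."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from riboslide import (
    SimConfig,
    assign_windows,
    bh_fdr,
    build_windows,
    classify,
    compute_ratio_intensity,
    compute_rpkm,
    compute_te,
    differential_te,
    effective_lengths,
    filter_low_reads,
    select_control_group,
    simulate_experiment,
    z_and_p,
)
from riboslide.stats import StatisticError


def _stats_frame(rng, n):
    return pd.DataFrame(
        {
            "log2_ratio": rng.normal(0, 1, n),
            "log10_intensity": rng.uniform(-1, 4, n),
        },
        index=pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id"),
    )


def _te_frame(te_base, te_alt):
    return pd.DataFrame(
        {
            "te_base": te_base,
            "te_alt": te_alt,
            "rpkm_mrna_base": te_base,
            "rpkm_mrna_alt": te_alt,
        },
        index=pd.Index([f"g{i}" for i in range(len(te_base))], name="gene_id"),
    )


def oracle_pipeline(stats, window=100, step=50):
    """Literal transcription of the method, coded independently.

    Order genes by increasing log10 intensity; summarize mean intensity
    and mean/SD of the log2 ratio in windows of `window` genes advancing
    `step` ranks (final truncated window only when genes would otherwise
    be uncovered); give each gene the window whose mean intensity is
    nearest; z-score the gene's ratio in that window; two-sided normal p.
    """
    ordered = stats.sort_index().sort_values("log10_intensity", kind="stable")
    n = len(ordered)
    windows = []
    if n <= window:
        spans = [(0, n)]
    else:
        spans = []
        s = 0
        while s + window <= n:
            spans.append((s, s + window))
            s += step
        if spans[-1][1] < n:
            spans.append((spans[-1][0] + step, n))
    for lo, hi in spans:
        chunk = ordered.iloc[lo:hi]
        windows.append(
            (
                chunk["log10_intensity"].mean(),
                chunk["log2_ratio"].mean(),
                chunk["log2_ratio"].std(ddof=1),
            )
        )
    out = {}
    for gene, row in stats.iterrows():
        best, best_d = None, None
        for w, (mi, mr, sd) in enumerate(windows):
            d = abs(row["log10_intensity"] - mi)
            if best_d is None or d < best_d:
                best, best_d = w, d
        mi, mr, sd = windows[best]
        z = (row["log2_ratio"] - mr) / sd
        p = 2 * sps.norm.cdf(-abs(z))
        out[gene] = (best, z, max(p, 1e-300))
    return windows, out


def oracle_bh(p):
    """O(m^2) literal step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    sorted_p = np.sort(p, kind="mergesort")
    out = np.empty(m)
    for i in range(m):
        candidates = [
            (sorted_p[j] * m) / (j + 1)
            for j in range(m)
            if sorted_p[j] >= p[i]
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestRatioIntensity:
    def test_closed_forms(self):
        te = _te_frame([1.0, 2.0], [2.0, 2.0])
        ri = compute_ratio_intensity(te, mode="TE")
        assert ri.loc["g0", "log2_ratio"] == pytest.approx(1.0)
        assert ri.loc["g0", "log10_intensity"] == pytest.approx(np.log10(2.0))
        assert ri.loc["g1", "log2_ratio"] == pytest.approx(0.0)
        assert ri.loc["g1", "log10_intensity"] == pytest.approx(2 * np.log10(2.0))

    def test_matches_scalar_formulas(self):
        rng = np.random.default_rng(0)
        base, alt = rng.uniform(0.1, 50, 100), rng.uniform(0.1, 50, 100)
        ri = compute_ratio_intensity(_te_frame(base, alt))
        for i in range(100):
            assert ri.iloc[i]["log2_ratio"] == pytest.approx(
                np.log2(alt[i] / base[i]), rel=1e-12
            )
            assert ri.iloc[i]["log10_intensity"] == pytest.approx(
                np.log10(alt[i] * base[i]), rel=1e-12
            )

    def test_rpkm_mode_uses_mrna_columns(self):
        te = _te_frame([1.0], [1.0])
        te["rpkm_mrna_base"], te["rpkm_mrna_alt"] = 2.0, 8.0
        ri = compute_ratio_intensity(te, mode="RPKM")
        assert ri.loc["g0", "log2_ratio"] == pytest.approx(2.0)

    def test_nonpositive_values_excluded_with_warning(self, caplog):
        te = _te_frame([1.0, 0.0], [1.0, 1.0])
        with caplog.at_level("WARNING"):
            ri = compute_ratio_intensity(te)
        assert list(ri.index) == ["g0"]


class TestWindows:
    def test_exactly_window_size_gives_single_window(self):
        rng = np.random.default_rng(1)
        w = build_windows(_stats_frame(rng, 100))
        assert len(w) == 1
        assert (w.iloc[0]["rank_start"], w.iloc[0]["rank_stop"]) == (0, 100)

    def test_full_windows_every_step(self):
        rng = np.random.default_rng(2)
        w = build_windows(_stats_frame(rng, 250))
        spans = list(zip(w["rank_start"], w["rank_stop"]))
        assert spans == [(0, 100), (50, 150), (100, 200), (150, 250)]

    def test_trailing_genes_form_truncated_window(self):
        rng = np.random.default_rng(3)
        w = build_windows(_stats_frame(rng, 260))
        spans = list(zip(w["rank_start"], w["rank_stop"]))
        assert spans == [(0, 100), (50, 150), (100, 200), (150, 250), (200, 260)]

    def test_constant_ratio_gives_zero_sd(self):
        rng = np.random.default_rng(4)
        stats = _stats_frame(rng, 180)
        stats["log2_ratio"] = 0.7
        w = build_windows(stats)
        assert np.allclose(w["mean_log2_ratio"], 0.7)
        assert np.allclose(w["sd_log2_ratio"], 0.0)

    def test_too_few_genes_is_an_error(self):
        rng = np.random.default_rng(5)
        with pytest.raises(StatisticError):
            build_windows(_stats_frame(rng, 2))


class TestAssignment:
    def test_single_window_takes_everything(self):
        rng = np.random.default_rng(6)
        stats = _stats_frame(rng, 60)
        w = build_windows(stats)
        assert (assign_windows(stats, w) == 0).all()

    def test_midway_tie_goes_to_lower_index(self):
        stats = pd.DataFrame(
            {"log2_ratio": [0.0], "log10_intensity": [1.5]}, index=["g"]
        )
        windows = pd.DataFrame(
            {
                "mean_log10_intensity": [1.0, 2.0],
                "mean_log2_ratio": [0.0, 0.0],
                "sd_log2_ratio": [1.0, 1.0],
            },
            index=pd.Index([0, 1], name="window_index"),
        )
        assert assign_windows(stats, windows).iloc[0] == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        stats = _stats_frame(rng, 400)
        w = build_windows(stats)
        assigned = assign_windows(stats, w)
        means = w["mean_log10_intensity"].to_numpy()
        for gene, row in stats.iterrows():
            dists = np.abs(row["log10_intensity"] - means)
            assert assigned[gene] == int(dists.argmin())


class TestZAndP:
    def test_window_mean_ratio_gives_zero_z_unit_p(self):
        rng = np.random.default_rng(8)
        stats = _stats_frame(rng, 100)
        w = build_windows(stats)
        stats.iloc[0, stats.columns.get_loc("log2_ratio")] = w.iloc[0][
            "mean_log2_ratio"
        ]
        # rebuild so the window mean reflects the edit
        w = build_windows(stats)
        a = assign_windows(stats, w)
        zp = z_and_p(stats, a, w)
        gene = stats.index[0]
        expected_z = (
            stats.loc[gene, "log2_ratio"] - w.iloc[0]["mean_log2_ratio"]
        ) / w.iloc[0]["sd_log2_ratio"]
        assert zp.loc[gene, "z"] == pytest.approx(expected_z, abs=1e-12)

    def test_standard_normal_quantile(self):
        stats = pd.DataFrame(
            {"log2_ratio": [-1.959964], "log10_intensity": [0.0]}, index=["g"]
        )
        windows = pd.DataFrame(
            {
                "mean_log10_intensity": [0.0],
                "mean_log2_ratio": [0.0],
                "sd_log2_ratio": [1.0],
            },
            index=pd.Index([0], name="window_index"),
        )
        zp = z_and_p(stats, pd.Series([0], index=["g"]), windows)
        assert zp.loc["g", "p"] == pytest.approx(0.05, abs=1e-6)

    def test_one_sided_is_lower_tail_quantile(self):
        stats = pd.DataFrame(
            {"log2_ratio": [-1.0, 1.0], "log10_intensity": [0.0, 0.0]},
            index=["a", "b"],
        )
        windows = pd.DataFrame(
            {
                "mean_log10_intensity": [0.0],
                "mean_log2_ratio": [0.0],
                "sd_log2_ratio": [1.0],
            },
            index=pd.Index([0], name="window_index"),
        )
        a = pd.Series([0, 0], index=["a", "b"])
        zp = z_and_p(stats, a, windows, sided="one")
        assert zp.loc["a", "p"] == pytest.approx(sps.norm.cdf(-1.0), rel=1e-12)
        assert zp.loc["b", "p"] == pytest.approx(sps.norm.cdf(1.0), rel=1e-12)

    def test_zero_sd_window_yields_p_one(self, caplog):
        stats = pd.DataFrame(
            {"log2_ratio": [0.3], "log10_intensity": [0.0]}, index=["g"]
        )
        windows = pd.DataFrame(
            {
                "mean_log10_intensity": [0.0],
                "mean_log2_ratio": [0.0],
                "sd_log2_ratio": [0.0],
            },
            index=pd.Index([0], name="window_index"),
        )
        with caplog.at_level("WARNING"):
            zp = z_and_p(stats, pd.Series([0], index=["g"]), windows)
        assert zp.loc["g", "p"] == 1.0

    def test_whole_path_matches_literal_oracle(self):
        rng = np.random.default_rng(9)
        stats = _stats_frame(rng, 500)
        w = build_windows(stats)
        a = assign_windows(stats, w)
        zp = z_and_p(stats, a, w)
        o_windows, o_genes = oracle_pipeline(stats)
        assert len(w) == len(o_windows)
        for i, (mi, mr, sd) in enumerate(o_windows):
            assert w.iloc[i]["mean_log10_intensity"] == pytest.approx(mi, abs=1e-10)
            assert w.iloc[i]["mean_log2_ratio"] == pytest.approx(mr, abs=1e-10)
            assert w.iloc[i]["sd_log2_ratio"] == pytest.approx(sd, abs=1e-10)
        for gene in stats.index:
            ow, oz, op = o_genes[gene]
            assert a[gene] == ow
            assert zp.loc[gene, "z"] == pytest.approx(oz, abs=1e-10)
            assert zp.loc[gene, "p"] == pytest.approx(op, abs=1e-10)


class TestBhFdr:
    def test_all_equal_p_stay_equal(self):
        p = np.full(10, 0.03)
        np.testing.assert_allclose(bh_fdr(p), 0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_quadratic_definition_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 200))
            np.testing.assert_array_equal(bh_fdr(p), oracle_bh(p))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-8, 1.0, 1000)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_monotone_in_p_rank_order(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, 500)
        fdr = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()
        assert ((fdr > 0) & (fdr <= 1)).all()


class TestClassify:
    @pytest.mark.parametrize(
        "log2_ratio,p,expected",
        [
            (np.log2(0.5), 0.01, "down"),
            (np.log2(0.5), 0.2, "unchanged"),
            (np.log2(1.5), 0.049, "up"),       # boundary inclusive
            (np.log2(0.75), 0.049, "down"),    # boundary inclusive
            (np.log2(0.76), 0.001, "unchanged"),
            (np.log2(2.0), 0.05, "unchanged"),  # p boundary exclusive
        ],
    )
    def test_threshold_rules(self, log2_ratio, p, expected):
        stats = pd.DataFrame(
            {"log2_ratio": [log2_ratio], "p": [p]}, index=["g"]
        )
        assert classify(stats).iloc[0] == expected


class TestControlGroup:
    def _stats(self, rng, n=2000):
        df = _stats_frame(rng, n)
        df["p"] = rng.uniform(0, 1, n)
        df["label"] = "unchanged"
        return df

    def test_deterministic_and_all_unchanged(self):
        rng = np.random.default_rng(13)
        stats = self._stats(rng)
        s1 = select_control_group(stats, n=100, seed=5)
        s2 = select_control_group(stats, n=100, seed=5)
        assert list(s1) == list(s2)
        assert len(s1) == 100
        assert (stats.loc[s1, "label"] == "unchanged").all()
        assert (stats.loc[s1, "log2_ratio"].abs() < 0.2).all()
        assert (stats.loc[s1, "p"] > 0.5).all()

    def test_oversized_request_returns_pool_with_warning(self, caplog):
        rng = np.random.default_rng(14)
        stats = self._stats(rng, n=50)
        pool = stats[
            (stats["log2_ratio"].abs() < 0.2) & (stats["p"] > 0.5)
        ].index
        with caplog.at_level("WARNING"):
            got = select_control_group(stats, n=40, seed=1)
        assert set(got) == set(pool)

    def test_stratification_spans_intensity_range(self):
        rng = np.random.default_rng(15)
        stats = self._stats(rng, n=5000)
        got = select_control_group(stats, n=300, seed=2)
        deciles = pd.qcut(stats["log10_intensity"], 10, labels=False)
        covered = deciles.loc[got].nunique()
        assert covered >= 8


class TestEndToEndProperties:
    def _analyze(self, cfg):
        ann, counts, truth = simulate_experiment(cfg)
        rpkm = compute_rpkm(counts, effective_lengths(ann))
        kept, _ = filter_low_reads(counts)
        te = compute_te(rpkm, kept)
        gs, w = differential_te(te)
        return gs, w, truth

    def test_null_p_values_near_uniform(self):
        cfg = SimConfig(n_genes=6000, frac_down=0.0, frac_up=0.0, seed=21)
        gs, _, _ = self._analyze(cfg)
        p = gs["p"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07
        assert sps.kstest(p, "uniform").statistic < 0.05

    def test_shuffling_gene_order_changes_nothing(self):
        cfg = SimConfig(n_genes=800, depth_rpf=800_000, depth_mrna=800_000,
                        seed=22)
        ann, counts, _ = simulate_experiment(cfg)
        rpkm = compute_rpkm(counts, effective_lengths(ann))
        kept, _ = filter_low_reads(counts)
        te = compute_te(rpkm, kept)
        gs1, _ = differential_te(te)
        rng = np.random.default_rng(0)
        shuffled = te.iloc[rng.permutation(len(te))]
        gs2, _ = differential_te(shuffled)
        pd.testing.assert_frame_equal(gs1.sort_index(), gs2.sort_index())

    def test_more_extreme_ratio_never_less_significant(self):
        # push one gene's ratio outward while holding its window fixed
        rng = np.random.default_rng(23)
        stats = _stats_frame(rng, 300)
        w = build_windows(stats)
        a = assign_windows(stats, w)
        gene = stats.index[17]
        base_ratio = stats.loc[gene, "log2_ratio"]
        mean = w.loc[a[gene], "mean_log2_ratio"]
        direction = 1.0 if base_ratio >= mean else -1.0
        last_p = None
        for extra in (0.0, 0.5, 1.0, 2.0):
            mod = stats.copy()
            mod.loc[gene, "log2_ratio"] = base_ratio + direction * extra
            p = z_and_p(mod, a, w).loc[gene, "p"]
            if last_p is not None:
                assert p <= last_p + 1e-15
            last_p = p
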