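import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from cismap.intervals_io import (
    CRM,
    TSS,
    ExpressionMatrix,
    GenomicInterval,
    SignalMatrix,
)
from cismap.map_builder import (
    CandidatePair,
    ConfigError,
    MapBuildConfig,
    UndefinedCorrelation,
    build_map,
    correlation_p_value,
    enumerate_candidates,
    map_summary,
    pearson_r,
    read_links,
    select_nonoverlapping_crms,
    write_links,
)


def _crm(cid, start, end, score=0.0, chrom="chr1"):
    return CRM(cid, GenomicInterval(chrom, start, end), "T1", score)


class TestSelectNonoverlapping:
    def test_higher_score_wins(self):
        a, b = _crm("A", 100, 200, 5), _crm("B", 150, 250, 3)
        assert select_nonoverlapping_crms({a, b}) == {a}

    def test_disjoint_all_kept(self):
        a, c = _crm("A", 100, 200), _crm("C", 300, 400)
        assert select_nonoverlapping_crms({a, c}) == {a, c}

    def test_tie_break_leftmost_then_id(self):
        a, b = _crm("B", 100, 200, 5), _crm("A", 100, 200, 5)
        assert select_nonoverlapping_crms({a, b}) == {b}

    def test_empty(self):
        assert select_nonoverlapping_crms(set()) == set()

    def test_matches_brute_force_greedy(self, rng):
        crms = []
        for i in range(200):
            start = int(rng.integers(0, 20_000))
            crms.append(
                _crm(f"c{i:03d}", start, start + int(rng.integers(50, 500)),
                     float(rng.integers(0, 50)), f"chr{rng.integers(1, 3)}")
            )
        # independent oracle: explicit priority sort + O(n^2) overlap scan
        order = sorted(crms, key=lambda c: (-c.score, c.interval.start, c.crm_id))
        expected = []
        for c in order:
            if not any(c.interval.overlaps(k.interval) for k in expected):
                expected.append(c)
        assert select_nonoverlapping_crms(set(crms)) == set(expected)

    def test_every_discarded_overlaps_a_kept(self, rng):
        crms = {
            _crm(f"c{i}", s := int(rng.integers(0, 5000)), s + 100,
                 float(rng.integers(0, 9)))
            for i in range(60)
        }
        kept = select_nonoverlapping_crms(crms)
        for c in crms - kept:
            assert any(c.interval.overlaps(k.interval) for k in kept)


class TestEnumerateCandidates:
    CFG = MapBuildConfig(theta=0.5, window_bp=1_000_000)

    def test_window_filter(self):
        t = TSS("t", "chr1", 500_000, "+", "g")
        near = _crm("near", 399_000, 401_000)
        far = _crm("far", 1_599_000, 1_601_000)
        pairs = enumerate_candidates({t}, {near, far}, self.CFG)
        assert {p.crm_id for p in pairs} == {"near"}

    def test_cross_chromosome_excluded(self):
        t = TSS("t", "chr1", 500_000, "+", "g")
        c = _crm("c", 499_000, 501_000, chrom="chr2")
        assert enumerate_candidates({t}, {c}, self.CFG) == set()

    def test_matches_all_pairs_oracle(self, rng):
        tss = {
            TSS(f"t{i}", f"chr{rng.integers(1, 3)}",
                int(rng.integers(0, 5_000_000)),
                "+" if rng.random() < 0.5 else "-", f"g{i}")
            for i in range(50)
        }
        crms = {
            _crm(f"c{i}", s := int(rng.integers(0, 5_000_000)), s + 500,
                 chrom=f"chr{rng.integers(1, 3)}")
            for i in range(500)
        }
        cfg = MapBuildConfig(theta=0.5, window_bp=300_000)
        expected = set()
        for t, c in itertools.product(tss, crms):
            if t.chrom != c.chrom:
                continue
            rel = c.midpoint - t.position
            if t.strand == "-":
                rel = -rel
            if abs(rel) <= cfg.window_bp:
                expected.add(CandidatePair(c.crm_id, t.tss_id, rel))
        assert enumerate_candidates(tss, crms, cfg) == expected


class TestPearson:
    def test_exact_linear(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelation):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_matches_direct_formula(self, rng):
        for _ in range(100):
            x = rng.gamma(2.0, 1.0, 15)
            y = rng.gamma(2.0, 1.0, 15)
            xm, ym = x - x.mean(), y - y.mean()
            expected = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
            assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


class TestCorrelationPValue:
    def test_zero_r_gives_one(self):
        for n in (3, 10, 100):
            assert correlation_p_value(0.0, n) == 1.0

    def test_perfect_r_flagged_tiny(self):
        p = correlation_p_value(1.0, 10)
        assert 0 < p < 1e-300

    def test_matches_numerical_t_integration(self):
        # independent oracle: numerically integrate the t density tail
        for r, n in [(0.99, 11), (0.5, 8), (-0.8, 20), (0.3, 50)]:
            df = n - 2
            t = abs(r) * math.sqrt(df / (1 - r * r))
            tail, _ = integrate.quad(
                lambda u: stats.t.pdf(u, df), t, np.inf,
                epsabs=0, epsrel=1e-13, limit=200,
            )
            assert correlation_p_value(r, n) == pytest.approx(
                2 * tail, rel=1e-10
            )

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.95, 10)
        for n in (5, 10, 30):
            ps = [correlation_p_value(r, n) for r in rs]
            assert all(a > b for a, b in zip(ps, ps[1:]))
        for r in (0.3, 0.7):
            ps = [correlation_p_value(r, n) for n in (5, 10, 20, 40, 80)]
            assert all(a > b for a, b in zip(ps, ps[1:]))


def _toy_panel(rng, n_crms=20, n_tss=5, n_tissues=8, planted=None):
    tss = [TSS(f"t{i}", "chr1", 100_000 + 150_000 * i, "+", f"g{i}")
           for i in range(n_tss)]
    crms = [_crm(f"c{i:02d}", 10_000 + 40_000 * i, 10_500 + 40_000 * i)
            for i in range(n_crms)]
    tissues = [f"T{j}" for j in range(n_tissues)]
    h = rng.gamma(2.0, 1.0, (n_crms, n_tissues))
    e = rng.gamma(2.0, 1.0, (n_tss, n_tissues))
    if planted:
        for ci, ti in planted:
            e[ti] = h[ci] + rng.normal(0, 0.01, n_tissues)
            e[ti] = np.clip(e[ti], 0, None)
    histone = SignalMatrix(h, [c.crm_id for c in crms], tissues)
    expr = ExpressionMatrix(e, [t.tss_id for t in tss], tissues)
    return tss, crms, histone, expr


class TestBuildMap:
    def test_identical_vectors_always_linked(self, rng):
        tss, crms, histone, expr = _toy_panel(rng)
        vals = expr.df.copy()
        vals.loc["t0"] = histone.df.loc["c00"]
        expr = ExpressionMatrix(vals.to_numpy(), list(vals.index), list(vals.columns))
        m = build_map(tss, crms, histone, expr, MapBuildConfig(theta=1e-12))
        assert ("c00", "t0") in m.link_pairs

    def test_matches_brute_force_oracle(self, rng):
        tss, crms, histone, expr = _toy_panel(
            rng, planted=[(0, 0), (3, 1), (7, 2)]
        )
        cfg = MapBuildConfig(theta=1e-2, window_bp=400_000)
        m = build_map(tss, crms, histone, expr, cfg)
        expected = set()
        for t, c in itertools.product(tss, crms):
            rel = c.midpoint - t.position
            if abs(rel) > cfg.window_bp:
                continue
            r = pearson_r(histone.row(c.crm_id), expr.row(t.tss_id))
            if correlation_p_value(r, 8) <= cfg.theta:
                expected.add((c.crm_id, t.tss_id))
        assert m.link_pairs == expected

    def test_held_out_tissue_has_no_influence(self, rng):
        tss, crms, histone, expr = _toy_panel(rng, planted=[(0, 0)])
        cfg = MapBuildConfig(theta=1e-2, test_tissue="T3")
        m1 = build_map(tss, crms, histone, expr, cfg)
        h2 = histone.df.copy()
        e2 = expr.df.copy()
        h2["T3"] = rng.gamma(5.0, 3.0, len(h2))
        e2["T3"] = rng.gamma(5.0, 3.0, len(e2))
        m2 = build_map(
            tss,
            crms,
            SignalMatrix(h2.to_numpy(), list(h2.index), list(h2.columns)),
            ExpressionMatrix(e2.to_numpy(), list(e2.index), list(e2.columns)),
            cfg,
        )
        assert m1.link_pairs == m2.link_pairs
        assert [(l.r, l.p_value) for l in sorted(m1.links)] == [
            (l.r, l.p_value) for l in sorted(m2.links)
        ]

    def test_monotone_nesting_in_theta(self, rng):
        tss, crms, histone, expr = _toy_panel(rng, planted=[(0, 0), (5, 3)])
        maps = {
            th: build_map(tss, crms, histone, expr, MapBuildConfig(theta=th))
            for th in (1e-4, 1e-2, 0.2)
        }
        assert maps[1e-4].link_pairs <= maps[1e-2].link_pairs <= maps[0.2].link_pairs

    def test_constant_vector_skipped_and_counted(self, rng):
        tss, crms, histone, expr = _toy_panel(rng)
        h = histone.df.copy()
        h.loc["c02"] = 1.0
        histone = SignalMatrix(h.to_numpy(), list(h.index), list(h.columns))
        m = build_map(tss, crms, histone, expr, MapBuildConfig(theta=0.999))
        assert m.diagnostics["skipped_constant"] > 0
        assert "c02" not in m.linked_crms

    def test_too_few_tissues_rejected(self, rng):
        tss, crms, histone, expr = _toy_panel(rng, n_tissues=5)
        with pytest.raises(ConfigError):
            build_map(tss, crms, histone, expr,
                      MapBuildConfig(theta=0.5, min_tissues=6))

    def test_missing_test_tissue_rejected(self, rng):
        tss, crms, histone, expr = _toy_panel(rng)
        with pytest.raises(ConfigError):
            build_map(tss, crms, histone, expr,
                      MapBuildConfig(theta=0.5, test_tissue="NOPE"))


class TestMapSummary:
    def test_counts(self, rng):
        tss, crms, histone, expr = _toy_panel(rng, planted=[(0, 0)])
        m = build_map(tss, crms, histone, expr, MapBuildConfig(theta=0.9))
        s = map_summary(m, tss)
        deg = m.degree_by_tss()
        assert s["links"] == len(m.links)
        assert s["tsss"] == len(deg)
        assert s["mean_links_per_tss"] == pytest.approx(np.mean(list(deg.values())))
        assert s["median_links_per_tss"] == pytest.approx(np.median(list(deg.values())))

    def test_empty_map(self, rng):
        tss, crms, histone, expr = _toy_panel(rng)
        m = build_map(tss, crms, histone, expr, MapBuildConfig(theta=1e-12))
        s = map_summary(m, tss)
        assert s == {
            "links": 0, "crms": 0, "tsss": 0, "genes": 0,
            "mean_links_per_tss": 0.0, "median_links_per_tss": 0.0,
        }


def test_links_round_trip(tmp_path, small_map):
    prefix = tmp_path / "m"
    write_links(prefix, small_map)
    loaded = read_links(prefix)
    assert loaded.link_pairs == small_map.link_pairs
    assert loaded.tss_universe == small_map.tss_universe
    assert loaded.crm_universe == small_map.crm_universe
    assert loaded.config == small_map.config
    by_pair = {l.pair: l for l in loaded.links}
    for l in small_map.links:
        assert by_pair[l.pair].r == pytest.approx(l.r, rel=1e-9)
        assert by_pair[l.pair].p_value == pytest.approx(l.p_value, rel=1e-9)
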