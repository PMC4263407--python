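import numpy as np
import pandas as pd
import pytest

from methreprog import windows as W
from methreprog.core import make_regions
from methreprog.stats import region_mean_level
from .conftest import make_track


def _uniform_map(n, spacing=50, chrom="chr1"):
    return {chrom: np.arange(n, dtype=np.int64) * spacing + 100}


def _track_from_p(cpg_map, p, depth=30, seed=0, sample_id="t"):
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, pos in cpg_map.items():
        pa = np.broadcast_to(np.asarray(p, float), pos.shape) if np.ndim(p) \
            else np.full(len(pos), p)
        total = np.full(len(pos), depth, np.int64) if np.isscalar(depth) \
            else rng.poisson(depth, len(pos))
        meth = rng.binomial(total, pa)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "context": "CG",
                                    "meth": meth, "total": total}))
    calls = pd.concat(frames, ignore_index=True)
    return make_track(calls.itertuples(index=False), sample_id=sample_id)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def test_window_count_closed_form():
    assert len(W.build_cpg_windows(_uniform_map(20))) == 1
    w = W.build_cpg_windows(_uniform_map(45))
    assert len(w) == 3
    # windows cover CpG index ranges [0,20), [10,30), [20,40)
    assert w["start_idx"].tolist() == [0, 10, 20]
    assert len(W.build_cpg_windows(_uniform_map(19))) == 0


@pytest.mark.parametrize("n", [20, 33, 100, 257, 1001])
def test_window_count_matches_formula(n):
    w = W.build_cpg_windows(_uniform_map(n), size=20, step=10)
    assert len(w) == (n - 20) // 10 + 1


def test_interior_cpgs_covered_by_exactly_two_windows():
    n = 100
    w = W.build_cpg_windows(_uniform_map(n))
    counts = np.zeros(n, int)
    for row in w.itertuples(index=False):
        counts[row.start_idx:row.start_idx + row.n_cpgs] += 1
    last = w["start_idx"].iloc[-1] + 20
    assert (counts[10:last - 10] == 2).all()
    assert (counts[:10] == 1).all()


# ---------------------------------------------------------------------------
# means
# ---------------------------------------------------------------------------

def test_window_means_threshold_and_values():
    cm = _uniform_map(20)
    rows = [("chr1", int(p), "CG", 10, 10) for p in cm["chr1"][:12]]
    t = make_track(rows)
    w = W.build_cpg_windows(cm)
    means = W.window_means(w, t, cm, min_covered=10)
    assert means.iloc[0] == pytest.approx(100.0)
    t9 = make_track(rows[:9])
    assert np.isnan(W.window_means(w, t9, cm, min_covered=10).iloc[0])


def test_window_means_agree_with_region_mean(rng):
    cm = _uniform_map(60)
    t = _track_from_p(cm, 0.4, depth=25, seed=3)
    w = W.build_cpg_windows(cm)
    means = W.window_means(w, t, cm, min_covered=1)
    for _, row in w.iterrows():
        sub = t.calls[(t.calls["pos"] >= row["start"])
                      & (t.calls["pos"] < row["end"])]
        expect = region_mean_level(sub["meth"], sub["total"])
        assert means[row["window_id"]] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

def test_identical_tracks_all_stable():
    cm = _uniform_map(200)
    t = _track_from_p(cm, 0.5, seed=1)
    w = W.build_cpg_windows(cm)
    calls = W.classify_window_changes(w, t, t, cm)
    assert (calls["call"] == "stable").all()
    assert np.allclose(calls["delta"], 0.0)


def test_change_calls_are_antisymmetric():
    cm = _uniform_map(500)
    p = np.full(500, 0.3)
    p[100:160] = 0.9
    p[300:340] = 0.05
    a = _track_from_p(cm, 0.3, seed=2, sample_id="a")
    b = _track_from_p(cm, p, seed=5, sample_id="b")
    w = W.build_cpg_windows(cm)
    ab = W.classify_window_changes(w, a, b, cm)
    ba = W.classify_window_changes(w, b, a, cm)
    vc_ab = ab["call"].value_counts()
    vc_ba = ba["call"].value_counts()
    assert vc_ab.get("increasing", 0) == vc_ba.get("decreasing", 0)
    assert vc_ab.get("decreasing", 0) == vc_ba.get("increasing", 0)
    np.testing.assert_allclose(ab["delta"], -ba["delta"], atol=1e-9)


def test_calls_partition_testable_windows():
    cm = _uniform_map(400)
    a = _track_from_p(cm, 0.6, seed=11)
    b = _track_from_p(cm, 0.25, seed=12)
    w = W.build_cpg_windows(cm)
    calls = W.classify_window_changes(w, a, b, cm)
    assert set(calls["call"]) <= {"increasing", "decreasing", "stable",
                                  "untestable"}
    testable = calls[calls["call"] != "untestable"]
    assert (testable["call"].isin(["increasing", "decreasing", "stable"])).all()
    inc = calls[calls["call"] == "increasing"]
    assert ((inc["delta"] > 20) & (inc["q"] < 0.05)).all()


# ---------------------------------------------------------------------------
# gamete categories and screens
# ---------------------------------------------------------------------------

def test_categorize_gamete_boundaries():
    cats = W.categorize_gamete([90, 79.9, 80.0, 10, 85, 15],
                               [10, 10.0, 20.0, 90, 95, 15])
    assert cats.tolist() == ["oocyte_specific", "other", "oocyte_specific",
                             "sperm_specific", "both_hyper", "both_hypo"]
    assert W.categorize_gamete([np.nan], [10])[0] == "untestable"


def test_screen_strict_threshold():
    means = pd.Series([70.0, 70.1, 30.0, np.nan],
                      index=["w1", "w2", "w3", "w4"])
    sel, frac = W.screen_windows_above(means, 70.0)
    assert sel.index.tolist() == ["w2"]
    assert frac == pytest.approx(1 / 3)
    empty, frac0 = W.screen_windows_above(pd.Series([0.0, 5.0]), 70)
    assert len(empty) == 0 and frac0 == 0.0


def test_window_location_priority_and_oracle(rng):
    promoters = make_regions(pd.DataFrame(
        [{"chrom": "chr1", "start": 100, "end": 300, "kind": "promoter"}]))
    exons = make_regions(pd.DataFrame(
        [{"chrom": "chr1", "start": 250, "end": 500, "kind": "exon"},
         {"chrom": "chr1", "start": 800, "end": 900, "kind": "exon"}]))
    introns = make_regions(pd.DataFrame(
        [{"chrom": "chr1", "start": 500, "end": 800, "kind": "intron"}]))
    w = pd.DataFrame([
        {"window_id": "w1", "chrom": "chr1", "start": 200, "end": 400},
        {"window_id": "w2", "chrom": "chr1", "start": 600, "end": 700},
        {"window_id": "w3", "chrom": "chr1", "start": 5000, "end": 5100},
        {"window_id": "w4", "chrom": "chr1", "start": 450, "end": 600},
    ])
    loc = W.assign_window_locations(w, promoters, exons, introns)
    assert loc.tolist() == ["promoter", "intron", "intergenic", "exon"]
    # randomized fixtures vs brute force
    regs = {"promoter": promoters, "exon": exons, "intron": introns}
    for _ in range(50):
        s = int(rng.integers(0, 1000))
        e = s + int(rng.integers(10, 300))
        wx = pd.DataFrame([{"window_id": "x", "chrom": "chr1",
                            "start": s, "end": e}])
        got = W.assign_window_locations(wx, promoters, exons, introns).iloc[0]
        expect = "intergenic"
        for label in ("intron", "exon", "promoter"):
            if any(s < r.end and e > r.start
                   for r in regs[label].itertuples(index=False)):
                expect = label
        assert got == expect


# ---------------------------------------------------------------------------
# smoothing and density
# ---------------------------------------------------------------------------

def test_bin_smooth_uniform_and_single():
    rows = [("chr1", p, "CG", 3, 5) for p in range(0, 200_000, 1000)]
    t = make_track(rows)
    b = W.bin_smooth(t, 50_000)
    assert np.allclose(b["mean"], 60.0)
    t1 = make_track([("chr1", 10, "CG", 1, 4)])
    b1 = W.bin_smooth(t1, 50_000)
    assert len(b1) == 1 and b1.iloc[0]["mean"] == pytest.approx(25.0)


def test_bin_smooth_chromosome_order_independent():
    rows1 = [("chr1", p, "CG", 2, 4) for p in range(0, 10_000, 500)]
    rows2 = [("chr2", p, "CG", 4, 4) for p in range(0, 10_000, 500)]
    a = W.bin_smooth(make_track(rows1 + rows2))
    b = W.bin_smooth(make_track(rows2 + rows1))
    pd.testing.assert_frame_equal(a, b)


def test_tss_profile_flat_and_strand_symmetry():
    genes_plus = make_regions(pd.DataFrame(
        [{"chrom": "chr1", "start": 50_000, "end": 60_000, "strand": "+",
          "kind": "other", "name": "g1"}]))
    rows = [("chr1", p, "CG", 4, 5) for p in range(44_000, 66_000, 100)]
    t = make_track(rows)
    prof = W.tss_meta_profile(t, genes_plus)
    assert np.nanmean(prof) == pytest.approx(80.0)
    assert np.nanmax(prof) == pytest.approx(80.0)
    # mirror-image gene on the minus strand sees the mirrored profile
    rng = np.random.default_rng(4)
    pos = np.sort(rng.choice(20_000, 300, replace=False))
    lv = rng.integers(0, 6, 300)
    tss = 60_000
    fwd_rows = [("chr1", int(tss + d), "CG", int(m), 5) for d, m in zip(pos - 10_000, lv)]
    rev_rows = [("chr2", int(tss - 1 - d), "CG", int(m), 5)
                for d, m in zip(pos - 10_000, lv)]
    gf = make_regions(pd.DataFrame([{"chrom": "chr1", "start": tss,
                                     "end": tss + 5_000, "strand": "+",
                                     "kind": "other", "name": "gf"}]))
    gr = make_regions(pd.DataFrame([{"chrom": "chr2", "start": tss - 5_000,
                                     "end": tss, "strand": "-",
                                     "kind": "other", "name": "gr"}]))
    pf = W.tss_meta_profile(make_track(fwd_rows), gf)
    pr = W.tss_meta_profile(make_track(rev_rows), gr)
    np.testing.assert_allclose(pf, pr)
    with pytest.raises(ValueError, match="empty"):
        W.tss_meta_profile(t, genes_plus.iloc[0:0])


def test_cpg_density_examples_and_oracle(rng):
    cm = {"chr1": np.array([500, 10_000, 10_010, 10_020, 10_030, 10_040,
                            10_050, 10_060, 10_070, 10_080, 10_090])}
    d = W.cpg_density(cm)["chr1"]
    assert d[0] == pytest.approx(1 / 200)   # isolated CpG
    assert d[1] == pytest.approx(10 / 200)  # 9 neighbours within 100 bp
    pos = np.sort(rng.choice(10_000, 300, replace=False)).astype(np.int64)
    dens = W.cpg_density({"c": pos})["c"]
    brute = np.array([np.sum(np.abs(pos - p) <= 100) for p in pos]) / 200
    np.testing.assert_allclose(dens, brute)
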