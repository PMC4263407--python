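import numpy as np
import pandas as pd
import pytest

from methreprog import repeats as RP
from methreprog.core import make_regions, vntr_table, VNTRRecord
from .conftest import make_track


def _regions(rows):
    return make_regions(pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "kind": "repeat_copy", "name": n}
         for c, s, e, n in rows]))


# ---------------------------------------------------------------------------
# family methylation
# ---------------------------------------------------------------------------

def test_family_methylation_cpg_pooled():
    regs = _regions([("chr1", 0, 100, "F"), ("chr1", 200, 300, "F")])
    # copy 1: three CpGs at 0%, copy 2: one CpG at 100%
    rows = [("chr1", 10, "CG", 0, 4), ("chr1", 20, "CG", 0, 4),
            ("chr1", 30, "CG", 0, 4), ("chr1", 250, "CG", 4, 4)]
    fm = RP.family_methylation(make_track(rows), regs)
    # CpG-pooled: (0+0+0+100)/4 = 25, not the copy-average 50
    assert fm.iloc[0]["mean"] == pytest.approx(25.0)
    all_meth = [("chr1", p, "CG", 4, 4) for p in (10, 20, 30, 250)]
    assert RP.family_methylation(make_track(all_meth), regs).iloc[0]["mean"] \
        == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# protection screen
# ---------------------------------------------------------------------------

def test_protection_screen_counts_and_copy_threshold():
    fam_a = [("chr1", i * 1000, i * 1000 + 500, "A") for i in range(101)]
    fam_b = [("chr2", i * 1000, i * 1000 + 500, "B") for i in range(101)]
    fam_small = [("chr1", 500_000 + i * 1000, 500_000 + i * 1000 + 500, "C")
                 for i in range(99)]
    regs = _regions(fam_a + fam_b + fam_small)
    prot = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50_400}])
    out = RP.protection_screen(regs, prot)
    assert set(out["family"]) == {"A", "B"}  # 99-copy family excluded
    a = out.set_index("family")
    assert a.loc["A", "n_protected"] == 51
    assert a.loc["B", "proportion_protected"] == 0.0
    assert out.iloc[0]["family"] == "A"


def test_protection_monotone_in_threshold(truth, filtered):
    from methreprog import windows as W
    cm = truth.cpg_map
    win = W.build_cpg_windows(cm)
    means = W.window_means(win, filtered["blastocyst"], cm)
    props = []
    for thr in (70.0, 80.0):
        sel, _ = W.screen_windows_above(means, thr)
        pw = win[win["window_id"].isin(sel.index)]
        out = RP.protection_screen(truth.repeats, pw).set_index("family")
        props.append(out["proportion_protected"])
    # raising the threshold never increases any family's proportion
    assert (props[1] <= props[0] + 1e-12).all()


# ---------------------------------------------------------------------------
# naive tandem detector
# ---------------------------------------------------------------------------

def test_detector_perfect_array_scoring():
    out = RP.detect_tandem_repeats_naive("ACGT" * 40)
    assert len(out) == 1
    r = out.iloc[0]
    assert r["period_size"] == 4
    assert r["copy_number"] == 40.0
    assert r["alignment_score"] == 320
    assert (r["start"], r["end"]) == (0, 160)


def test_detector_thresholds_and_errors():
    assert len(RP.detect_tandem_repeats_naive("ACGT" * 10)) == 0  # score 80
    with pytest.raises(ValueError, match="ACGTN"):
        RP.detect_tandem_repeats_naive("ACGU" * 50)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_detector_silent_on_random_sequence(seed):
    rng = np.random.default_rng(seed)
    s = "".join(rng.choice(list("ACGT"), 1000))
    assert len(RP.detect_tandem_repeats_naive(s)) == 0


@pytest.mark.parametrize("period,copies", [(5, 30), (40, 10), (120, 3)])
def test_detector_completeness_on_planted_arrays(period, copies, rng):
    unit = "".join(rng.choice(list("AC"), period))  # binary alphabet avoids
    flank1 = "".join(rng.choice(list("GT"), 300))   # chance periodicity
    flank2 = "".join(rng.choice(list("GT"), 300))
    seq = flank1 + unit * copies + flank2
    out = RP.detect_tandem_repeats_naive(seq)
    hits = out[(out["start"] <= 300) & (out["end"] >= 300 + period * copies)]
    assert len(hits) >= 1
    assert (hits["period_size"] <= period).all()


# ---------------------------------------------------------------------------
# VNTR selection and enrichment
# ---------------------------------------------------------------------------

def _vntrs(rows):
    return vntr_table([VNTRRecord(chrom=c, start=s, end=e, period_size=p,
                                  copy_number=cn, alignment_score=sc)
                       for c, s, e, p, cn, sc in rows])


def test_select_top_vntr_score_then_length_then_position():
    v = _vntrs([("chr1", 100, 200, 10, 10, 150),
                ("chr1", 300, 900, 20, 30, 600),
                ("chr1", 1000, 1700, 20, 35, 600)])
    top = RP.select_top_vntr(("chr1", 0, 2000), v)
    assert top["start"] == 1000  # same score, longer array wins
    assert RP.select_top_vntr(("chr2", 0, 2000), v) is None
    top2 = RP.select_top_vntr(("chr1", 0, 250), v)
    assert top2["alignment_score"] == 150


def test_vntr_enrichment_counts_and_identity():
    group = _regions([("chr1", 0, 100, "g"), ("chr1", 200, 300, "g")])
    v = _vntrs([("chr1", 50, 80, 5, 6, 160)])
    out = RP.vntr_enrichment(group, group, v)
    assert out["group_with"] == 1 and out["background_with"] == 1
    assert out["test"].p_value == pytest.approx(1.0)
    # cells sum to input sizes
    assert out["group_with"] + (out["group_total"] - out["group_with"]) == 2
    with pytest.raises(ValueError, match="empty"):
        RP.vntr_enrichment(group.iloc[0:0], group, v)


def test_vntr_enrichment_planted_rates_significant(rng):
    """25% vs 6% planted VNTR rates at the catalogue sizes of the gDMR/CGI
    comparison are reliably detected; with only 44 group regions the power
    at alpha=1e-4 is ~0.82 (Monte Carlo), near 1 at alpha=0.05."""
    from methreprog.stats import chi_square_2x2
    hits_strict = hits_05 = 0
    n_rep = 200
    for _ in range(n_rep):
        g = rng.binomial(44, 0.25)
        b = rng.binomial(27_718, 0.06)
        if g == 0:
            continue
        p = chi_square_2x2(g, 44 - g, b, 27_718 - b).p_value
        hits_strict += p < 1e-4
        hits_05 += p < 0.05
    assert hits_strict / n_rep >= 0.70
    assert hits_05 / n_rep >= 0.90


def test_cgi_protection_threshold_edge_and_degenerate():
    cgis = make_regions(pd.DataFrame(
        [{"chrom": "chr1", "start": 0, "end": 1000, "kind": "CGI", "name": "a"},
         {"chrom": "chr1", "start": 2000, "end": 3000, "kind": "CGI", "name": "b"}]))
    v = _vntrs([("chr1", 100, 300, 10, 20, 400)])
    out = RP.cgi_protection_by_vntr(cgis, [70.0, 60.0], v)
    # exactly 70.0 is not protected (strict >)
    assert out["vntr_protected"] == 0 and out["vntr_unprotected"] == 1
    assert out["test"] is None and "zero marginal" in out["test_error"]
    out2 = RP.cgi_protection_by_vntr(cgis, [80.0, 60.0], v)
    assert out2["vntr_protected"] == 1 and out2["test"] is not None


def test_compare_vntr_features_identity_and_planted_shift(rng):
    a = _vntrs([("chr1", i * 100, i * 100 + 50, 20, 10.0, 300)
                for i in range(5)])
    same = RP.compare_vntr_features(a, a)
    assert all(v["p"] == pytest.approx(1.0) for v in same.values())
    # planted copy-number shift only
    def draw(nc_mean, n=100):
        return vntr_table([VNTRRecord(
            chrom="chr1", start=i * 1000, end=i * 1000 + 500,
            period_size=int(rng.integers(20, 40)),
            copy_number=float(max(2, rng.normal(nc_mean, 2))),
            alignment_score=300) for i in range(n)])
    res = RP.compare_vntr_features(draw(25), draw(10))
    assert res["copy_number"]["p"] < 0.05
    assert res["period_size"]["p"] > 0.05
    single = RP.compare_vntr_features(a.iloc[:1], a.iloc[1:2])
    assert 0 <= single["copy_number"]["p"] <= 1


def test_planted_protected_family_ranks_first(truth, filtered):
    from methreprog import windows as W
    cm = truth.cpg_map
    win = W.build_cpg_windows(cm)
    means = W.window_means(win, filtered["blastocyst"], cm)
    sel, frac = W.screen_windows_above(means, 70.0)
    pw = win[win["window_id"].isin(sel.index)]
    rank = RP.protection_screen(truth.repeats, pw)
    assert rank.iloc[0]["family"] == "SVA_A"
    assert rank.iloc[0]["proportion_protected"] > 0.9
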