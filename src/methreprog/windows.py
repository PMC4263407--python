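"""Fixed-CpG-count sliding windows and window-level methylation dynamics.

Windows are anchored on a reference CpG map (all genomic dyads), so window
identity is comparable across samples regardless of which CpGs each sample
covers.  The default geometry is 20 CpGs per window with a step of 10
CpGs; a window is testable in a sample when >= 10 of its CpGs pass that
sample's depth filter.  Change calls between two samples require a
>20-percentage-point shift that survives a Student's t-test with
Benjamini–Hochberg correction (q < 0.05), applied across all testable
windows of the one comparison.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import MethylomeTrack
from .stats import bh_adjust, t_test_from_summary

DEFAULT_WINDOW = 20
DEFAULT_STEP = 10
DEFAULT_MIN_COVERED = 10

GAMETE_CATEGORIES = ("oocyte_specific", "sperm_specific", "both_hyper",
                     "both_hypo", "other")


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def build_cpg_windows(cpg_map: Mapping[str, np.ndarray],
                      size: int = DEFAULT_WINDOW,
                      step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Build sliding windows of ``size`` CpGs advancing by ``step`` CpGs.

    For a chromosome with N >= size reference CpGs this yields
    floor((N - size)/step) + 1 windows; trailing CpGs that do not fill a
    window are dropped.  The window span is [first CpG, last CpG + 2) so
    the final dyad is inside the interval.
    """
    if size <= 0 or step <= 0 or step > size:
        raise ValueError("require 0 < step <= size")
    rows = []
    for chrom in sorted(cpg_map):
        pos = np.asarray(cpg_map[chrom])
        n = len(pos)
        if n < size:
            continue
        n_win = (n - size) // step + 1
        starts = np.arange(n_win) * step
        for k, s in enumerate(starts):
            rows.append({"window_id": f"{chrom}:w{k:06d}", "chrom": chrom,
                         "start_idx": int(s), "n_cpgs": size,
                         "start": int(pos[s]), "end": int(pos[s + size - 1]) + 2})
    cols = ["window_id", "chrom", "start_idx", "n_cpgs", "start", "end"]
    return pd.DataFrame(rows, columns=cols)


def _aligned_levels(track: MethylomeTrack, cpg_map: Mapping[str, np.ndarray]
                    ) -> dict[str, np.ndarray]:
    """Per-chromosome level arrays aligned to the reference CpG map
    (NaN where the track has no covered call)."""
    out = {}
    cg = track.cpg_calls()
    for chrom in cpg_map:
        ref = np.asarray(cpg_map[chrom])
        lv = np.full(len(ref), np.nan)
        sub = cg[cg["chrom"] == chrom]
        sub = sub[sub["total"] > 0]
        if len(sub):
            pos = sub["pos"].to_numpy()
            idx = np.searchsorted(ref, pos)
            ok = (idx < len(ref))
            ok[ok] &= ref[idx[ok]] == pos[ok]
            lv[idx[ok]] = (sub["meth"].to_numpy(float)[ok]
                           / sub["total"].to_numpy(float)[ok])
        out[chrom] = lv
    return out


def window_stats(windows: pd.DataFrame, track: MethylomeTrack,
                 cpg_map: Mapping[str, np.ndarray],
                 min_covered: int = DEFAULT_MIN_COVERED) -> pd.DataFrame:
    """Per-window coverage count, mean level (%) and level variance.

    ``mean`` is NaN (untestable) when fewer than ``min_covered`` of the
    window's CpGs are covered in the track.  Variance is the unbiased
    sample variance of the per-CpG levels, used by the summary-statistic
    t-test.
    """
    levels = _aligned_levels(track, cpg_map)
    n_out = np.zeros(len(windows), int)
    mean_out = np.full(len(windows), np.nan)
    var_out = np.full(len(windows), np.nan)
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        lv = levels.get(chrom)
        if lv is None:
            continue
        filled = np.nan_to_num(lv)
        cov = np.isfinite(lv).astype(float)
        c1 = np.concatenate([[0.0], np.cumsum(filled)])
        c2 = np.concatenate([[0.0], np.cumsum(filled ** 2)])
        cn = np.concatenate([[0.0], np.cumsum(cov)])
        sub = windows.loc[widx]
        s = sub["start_idx"].to_numpy()
        w = sub["n_cpgs"].to_numpy()
        n = cn[s + w] - cn[s]
        sm = c1[s + w] - c1[s]
        sq = c2[s + w] - c2[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = sm / n
            var = np.where(n > 1, (sq - n * mu ** 2) / (n - 1), np.nan)
        mu = np.where(n >= min_covered, mu, np.nan)
        var = np.where(n >= min_covered, np.maximum(var, 0.0), np.nan)
        n_out[windows.index.get_indexer(widx)] = n.astype(int)
        mean_out[windows.index.get_indexer(widx)] = mu * 100.0
        var_out[windows.index.get_indexer(widx)] = var * 100.0 ** 2
    return pd.DataFrame({"window_id": windows["window_id"].to_numpy(),
                         "n_covered": n_out, "mean": mean_out, "var": var_out})


def window_means(windows: pd.DataFrame, track: MethylomeTrack,
                 cpg_map: Mapping[str, np.ndarray],
                 min_covered: int = DEFAULT_MIN_COVERED) -> pd.Series:
    """Per-window mean level (%), NaN where untestable."""
    st = window_stats(windows, track, cpg_map, min_covered)
    return pd.Series(st["mean"].to_numpy(), index=st["window_id"], name=track.sample_id)


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

def classify_window_changes(windows: pd.DataFrame,
                            track_a: MethylomeTrack,
                            track_b: MethylomeTrack,
                            cpg_map: Mapping[str, np.ndarray],
                            min_covered: int = DEFAULT_MIN_COVERED,
                            delta_threshold: float = 20.0,
                            q_threshold: float = 0.05) -> pd.DataFrame:
    """Call each window increasing / decreasing / stable from a to b.

    delta = mean_b - mean_a in percentage points.  A window is increasing
    when delta > ``delta_threshold`` and BH-adjusted p < ``q_threshold``
    (decreasing symmetric); all other testable windows are stable, and
    windows untestable in either sample are 'untestable'.  The BH family
    is the set of testable windows of this one comparison.
    """
    sa = window_stats(windows, track_a, cpg_map, min_covered)
    sb = window_stats(windows, track_b, cpg_map, min_covered)
    out = pd.DataFrame({"window_id": windows["window_id"].to_numpy(),
                        "chrom": windows["chrom"].to_numpy(),
                        "start": windows["start"].to_numpy(),
                        "end": windows["end"].to_numpy(),
                        "mean_a": sa["mean"].to_numpy(),
                        "mean_b": sb["mean"].to_numpy()})
    out["delta"] = out["mean_b"] - out["mean_a"]
    testable = np.isfinite(out["mean_a"]) & np.isfinite(out["mean_b"])
    t, p = t_test_from_summary(sb["mean"].to_numpy(), sb["var"].to_numpy(),
                               sb["n_covered"].to_numpy(),
                               sa["mean"].to_numpy(), sa["var"].to_numpy(),
                               sa["n_covered"].to_numpy())
    p = np.where(testable, p, np.nan)
    out["p"] = p
    q = np.full(len(out), np.nan)
    mask = testable.to_numpy() & np.isfinite(p)
    if mask.any():
        q[mask] = bh_adjust(p[mask])
    out["q"] = q
    call = np.where(~testable, "untestable", "stable")
    sig = mask & (q < q_threshold)
    call = np.where(sig & (out["delta"] > delta_threshold), "increasing", call)
    call = np.where(sig & (out["delta"] < -delta_threshold), "decreasing", call)
    out["call"] = call
    return out


def change_call_proportions(calls: pd.DataFrame) -> dict[str, float]:
    """Fractions of testable windows per call (the stacked-bar summary)."""
    testable = calls[calls["call"] != "untestable"]
    n = len(testable)
    if n == 0:
        return {"increasing": float("nan"), "decreasing": float("nan"),
                "stable": float("nan"), "n_testable": 0}
    vc = testable["call"].value_counts()
    return {"increasing": vc.get("increasing", 0) / n,
            "decreasing": vc.get("decreasing", 0) / n,
            "stable": vc.get("stable", 0) / n, "n_testable": n}


# ---------------------------------------------------------------------------
# gamete-specific categories
# ---------------------------------------------------------------------------

def categorize_gamete(oocyte_means, sperm_means,
                      hyper: float = 80.0, hypo: float = 20.0) -> np.ndarray:
    """Assign gamete-specific methylation categories from paired means (%).

    hyper is inclusive (>= 80), hypo is inclusive (<= 20).  A pair with an
    undefined mean is 'untestable'.
    """
    oo = np.asarray(oocyte_means, float)
    sp = np.asarray(sperm_means, float)
    cat = np.full(oo.shape, "other", dtype=object)
    cat[(oo >= hyper) & (sp <= hypo)] = "oocyte_specific"
    cat[(sp >= hyper) & (oo <= hypo)] = "sperm_specific"
    cat[(oo >= hyper) & (sp >= hyper)] = "both_hyper"
    cat[(oo <= hypo) & (sp <= hypo)] = "both_hypo"
    cat[np.isnan(oo) | np.isnan(sp)] = "untestable"
    return cat


def categorize_gamete_windows(windows: pd.DataFrame,
                              oocyte: MethylomeTrack, sperm: MethylomeTrack,
                              cpg_map: Mapping[str, np.ndarray],
                              min_covered: int = DEFAULT_MIN_COVERED,
                              hyper: float = 80.0, hypo: float = 20.0,
                              summarize: MethylomeTrack | None = None) -> pd.DataFrame:
    """Per-window gamete categories, optionally with a third sample's
    per-category median levels (e.g. blastocyst persistence)."""
    mo = window_means(windows, oocyte, cpg_map, min_covered)
    ms = window_means(windows, sperm, cpg_map, min_covered)
    out = pd.DataFrame({"window_id": mo.index,
                        "oocyte_mean": mo.to_numpy(),
                        "sperm_mean": ms.to_numpy()})
    out["category"] = categorize_gamete(out["oocyte_mean"], out["sperm_mean"],
                                        hyper, hypo)
    if summarize is not None:
        m3 = window_means(windows, summarize, cpg_map, min_covered)
        out[f"{summarize.sample_id}_mean"] = m3.to_numpy()
    return out


def category_medians(categorized: pd.DataFrame, value_col: str) -> pd.Series:
    """Median of ``value_col`` per gamete category (NaN-dropped)."""
    return categorized.groupby("category")[value_col].median()


def screen_windows_above(window_means_: pd.Series,
                         threshold: float = 70.0) -> tuple[pd.Series, float]:
    """Windows whose mean strictly exceeds ``threshold`` (%).

    Returns (subset of means, fraction of testable windows selected) —
    the demethylation-protection screen.
    """
    testable = window_means_.dropna()
    sel = testable[testable > threshold]
    frac = len(sel) / len(testable) if len(testable) else float("nan")
    return sel, frac


# ---------------------------------------------------------------------------
# window genomic location
# ---------------------------------------------------------------------------

def assign_window_locations(windows: pd.DataFrame,
                            promoters: pd.DataFrame,
                            exons: pd.DataFrame,
                            introns: pd.DataFrame) -> pd.Series:
    """Single location label per window with priority
    promoter > exon > intron > intergenic, on any-overlap semantics."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for label, regs in (("promoter", promoters), ("exon", exons), ("intron", introns)):
        for row in regs.itertuples(index=False):
            trees.setdefault(row.chrom, {}).setdefault(label, IntervalTree()).addi(
                row.start, row.end)
    labels = []
    for row in windows.itertuples(index=False):
        by_label = trees.get(row.chrom, {})
        for label in ("promoter", "exon", "intron"):
            t = by_label.get(label)
            if t is not None and t.overlap(row.start, row.end):
                labels.append(label)
                break
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=windows["window_id"].to_numpy(), name="location")


# ---------------------------------------------------------------------------
# smoothing / profiles / density
# ---------------------------------------------------------------------------

def bin_smooth(track: MethylomeTrack, bin_size: int = 50_000) -> pd.DataFrame:
    """Mean per-CpG level (%) in fixed-width non-overlapping genomic bins.

    Empty bins are absent from the output (their value is undefined).
    """
    cg = track.cpg_calls()
    cg = cg[cg["total"] > 0]
    if not len(cg):
        return pd.DataFrame(columns=["chrom", "bin_start", "mean", "n_cpgs"])
    lv = cg["meth"].to_numpy(float) / cg["total"].to_numpy(float) * 100.0
    df = pd.DataFrame({"chrom": cg["chrom"].to_numpy(),
                       "bin_start": (cg["pos"].to_numpy() // bin_size) * bin_size,
                       "level": lv})
    out = df.groupby(["chrom", "bin_start"], as_index=False).agg(
        mean=("level", "mean"), n_cpgs=("level", "size"))
    return out.sort_values(["chrom", "bin_start"]).reset_index(drop=True)


def tss_meta_profile(track: MethylomeTrack, genes: pd.DataFrame,
                     flank: int = 5_000, bin_size: int = 5) -> np.ndarray:
    """Strand-aware mean methylation profile (%) around TSSs.

    Returns a vector of ``2*flank/bin_size`` bins covering
    [-flank, +flank) in transcription orientation, pooling the CpGs of all
    genes per bin.  Requires a non-empty gene set.
    """
    if not len(genes):
        raise ValueError("empty gene set")
    n_bins = 2 * flank // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    cg = track.cpg_calls()
    cg = cg[cg["total"] > 0]
    by_chrom = {c: s for c, s in cg.groupby("chrom", sort=False)}
    for g in genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        tss = g.start if g.strand != "-" else g.end - 1
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, tss - flank)
        hi = np.searchsorted(pos, tss + flank)
        if hi <= lo:
            continue
        rel = pos[lo:hi] - tss
        if g.strand == "-":
            rel = -rel
        keep = (rel >= -flank) & (rel < flank)
        rel = rel[keep]
        lv = (sub["meth"].to_numpy(float)[lo:hi][keep]
              / sub["total"].to_numpy(float)[lo:hi][keep]) * 100.0
        b = (rel + flank) // bin_size
        np.add.at(sums, b, lv)
        np.add.at(counts, b, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def cpg_density(cpg_map: Mapping[str, np.ndarray],
                radius: int = 100) -> dict[str, np.ndarray]:
    """Per-CpG density: number of reference CpGs within +-radius bp
    (self included) divided by 2*radius."""
    out = {}
    for chrom, pos in cpg_map.items():
        pos = np.asarray(pos)
        lo = np.searchsorted(pos, pos - radius, side="left")
        hi = np.searchsorted(pos, pos + radius, side="right")
        out[chrom] = (hi - lo) / (2.0 * radius)
    return out


def cpg_density_curve(tracks: Sequence[MethylomeTrack],
                      cpg_map: Mapping[str, np.ndarray],
                      radius: int = 100, min_sites: int = 1000,
                      region_mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean methylation (%) per CpG-density value, per sample.

    Only density values with more than ``min_sites`` CpGs covered in all
    provided tracks enter the curve.  ``region_mask`` (a region table)
    optionally restricts the CpGs to those inside a repeat family or other
    annotation.
    """
    dens = cpg_density(cpg_map, radius)
    levels = [_aligned_levels(t, cpg_map) for t in tracks]
    frames = []
    for chrom, pos in cpg_map.items():
        pos = np.asarray(pos)
        keep = np.ones(len(pos), bool)
        if region_mask is not None:
            keep = np.zeros(len(pos), bool)
            for row in region_mask[region_mask["chrom"] == chrom].itertuples(index=False):
                lo = np.searchsorted(pos, row.start)
                hi = np.searchsorted(pos, row.end)
                keep[lo:hi] = True
        cols = {"density": dens[chrom][keep]}
        for t, lvs in zip(tracks, levels):
            cols[t.sample_id] = lvs[chrom][keep] * 100.0
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    covered_all = df.drop(columns="density").notna().all(axis=1)
    counts = df.loc[covered_all].groupby("density").size()
    good = counts[counts > min_sites].index
    curve = (df[covered_all & df["density"].isin(good)]
             .groupby("density", as_index=False).mean())
    return curve
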