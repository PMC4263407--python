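"""Repeat-family methylation, the demethylation-protection screen and the
VNTR analyses.

Family-level methylation pools CpGs across all copies of a family (not a
mean of per-copy means).  The protection screen asks, per repeat family,
what fraction of its copies overlap windows that stay above 70% methylation
in blastocysts; families with <= 100 genomic copies are excluded from the
ranking.  Tandem arrays come either from parsed Tandem Repeats Finder
output (real genomes) or from a simplified exact-periodicity detector used
by the self-contained synthetic pipeline; both feed the same record type.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import MethylomeTrack, VNTRRecord, vntr_table
from .stats import TestResult, chi_square_2x2, mann_whitney_u

MIN_FAMILY_COPIES = 100
TRF_MATCH_WEIGHT = 2  # per matched base, mirroring TRF's 2,5,7 weights
MAX_PERIOD = 500
MIN_SCORE = 150


# ---------------------------------------------------------------------------
# family methylation + protection screen
# ---------------------------------------------------------------------------

def family_methylation(track: MethylomeTrack, repeat_regions: pd.DataFrame,
                       by: str = "name") -> pd.DataFrame:
    """CpG-pooled mean methylation (%) per repeat family.

    Every CpG falling inside any copy of the family contributes once per
    containing copy; the mean is over CpG levels, not per-copy means, so
    CpG-rich copies weigh more.
    """
    cg = track.cpg_calls()
    cg = cg[cg["total"] > 0]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    copies: dict[str, int] = {}
    by_chrom = {}
    for chrom, sub in cg.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (sub["pos"].to_numpy(),
                           sub["meth"].to_numpy(float) / sub["total"].to_numpy(float))
    for row in repeat_regions.itertuples(index=False):
        fam = getattr(row, by)
        copies[fam] = copies.get(fam, 0) + 1
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos, lv = entry
        lo = np.searchsorted(pos, row.start)
        hi = np.searchsorted(pos, row.end)
        if hi > lo:
            sums[fam] = sums.get(fam, 0.0) + float(lv[lo:hi].sum())
            counts[fam] = counts.get(fam, 0) + (hi - lo)
    rows = []
    for fam, n_cop in sorted(copies.items()):
        n = counts.get(fam, 0)
        rows.append({"family": fam, "n_copies": n_cop, "n_cpgs": n,
                     "mean": 100.0 * sums.get(fam, 0.0) / n if n else float("nan")})
    return pd.DataFrame(rows)


def protection_screen(repeat_regions: pd.DataFrame,
                      protected_windows: pd.DataFrame,
                      by: str = "name",
                      min_copies: int = MIN_FAMILY_COPIES) -> pd.DataFrame:
    """Fraction of each repeat family's copies overlapping protected
    (>70%-methylated) windows, ranked descending.

    ``protected_windows`` needs chrom/start/end columns; overlap is any
    >= 1 bp intersection.  Families with <= ``min_copies`` genomic copies
    are excluded from the ranking.
    """
    trees: dict[str, IntervalTree] = {}
    for w in protected_windows.itertuples(index=False):
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)
    hits: dict[str, int] = {}
    copies: dict[str, int] = {}
    for row in repeat_regions.itertuples(index=False):
        fam = getattr(row, by)
        copies[fam] = copies.get(fam, 0) + 1
        t = trees.get(row.chrom)
        if t is not None and t.overlap(row.start, row.end):
            hits[fam] = hits.get(fam, 0) + 1
    rows = [{"family": fam, "n_copies": n,
             "n_protected": hits.get(fam, 0),
             "proportion_protected": hits.get(fam, 0) / n}
            for fam, n in copies.items() if n > min_copies]
    out = pd.DataFrame(rows, columns=["family", "n_copies", "n_protected",
                                      "proportion_protected"])
    return out.sort_values(["proportion_protected", "family"],
                           ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# tandem array detection (synthetic-pipeline stand-in for TRF)
# ---------------------------------------------------------------------------

def detect_tandem_repeats_naive(sequence: str, chrom: str = "seq",
                                min_period: int = 1,
                                max_period: int = MAX_PERIOD,
                                min_score: int = MIN_SCORE) -> pd.DataFrame:
    """Exact-periodicity scan for tandem arrays in a DNA string.

    A maximal run where ``s[i] == s[i - p]`` spanning at least two full
    copies is reported with score = 2 * array_length (two points per
    matched base), so a perfect array scores 2 * period * copies.  Arrays
    are reported at their smallest period; harmonic re-detections contained
    in an already-reported array are suppressed.  Intended for synthetic
    sequence; real genomes should use parsed Tandem Repeats Finder output.
    """
    if re.search(r"[^ACGTN]", sequence):
        raise ValueError("sequence contains non-ACGTN characters")
    n = len(sequence)
    records: list[VNTRRecord] = []
    claimed: list[tuple[int, int]] = []
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    for p in range(max(1, min_period), min(max_period, n // 2) + 1):
        match = s[p:] == s[:-p]
        if not match.any():
            continue
        # maximal runs of consecutive matches
        m = np.concatenate([[False], match, [False]])
        starts = np.flatnonzero(~m[:-1] & m[1:])
        ends = np.flatnonzero(m[:-1] & ~m[1:])
        for a, b in zip(starts, ends):
            run = b - a           # number of matching positions
            if run < p:           # less than two full copies
                continue
            astart, aend = a, a + run + p  # array interval in sequence coords
            length = aend - astart
            score = TRF_MATCH_WEIGHT * length
            if score < min_score:
                continue
            if any(astart >= cs and aend <= ce for cs, ce in claimed):
                continue  # harmonic of an already-reported array
            consensus = sequence[astart:astart + p]
            records.append(VNTRRecord(chrom=chrom, start=int(astart),
                                      end=int(aend), period_size=p,
                                      copy_number=round(length / p, 1),
                                      alignment_score=int(score),
                                      consensus_pattern=consensus))
            claimed.append((astart, aend))
    return vntr_table(records)


# ---------------------------------------------------------------------------
# VNTR / region integration
# ---------------------------------------------------------------------------

def _vntr_tree(vntrs: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, v in enumerate(vntrs.itertuples(index=False)):
        trees.setdefault(v.chrom, IntervalTree()).addi(v.start, v.end, i)
    return trees


def regions_with_vntr(regions: pd.DataFrame, vntrs: pd.DataFrame) -> np.ndarray:
    """Boolean mask: region overlaps (>= 1 bp) at least one tandem array."""
    trees = _vntr_tree(vntrs)
    out = np.zeros(len(regions), bool)
    for i, row in enumerate(regions.itertuples(index=False)):
        t = trees.get(row.chrom)
        out[i] = bool(t is not None and t.overlap(row.start, row.end))
    return out


def select_top_vntr(region: tuple[str, int, int],
                    vntrs: pd.DataFrame) -> pd.Series | None:
    """The overlapping tandem array with the highest alignment score.

    Ties broken by longer array, then leftmost start.  Returns None when
    no array overlaps the region.
    """
    chrom, start, end = region
    sub = vntrs[(vntrs["chrom"] == chrom) & (vntrs["start"] < end)
                & (vntrs["end"] > start)]
    if not len(sub):
        return None
    sub = sub.assign(_len=sub["end"] - sub["start"])
    sub = sub.sort_values(["alignment_score", "_len", "start"],
                          ascending=[False, False, True])
    return sub.drop(columns="_len").iloc[0]


def vntr_enrichment(group_regions: pd.DataFrame,
                    background_regions: pd.DataFrame,
                    vntrs: pd.DataFrame,
                    correction: str = "none") -> dict:
    """Chi-square enrichment of VNTR-containing regions in a group vs a
    background set (e.g. maternal gDMRs vs all CGIs)."""
    if not len(group_regions):
        raise ValueError("empty group")
    g_with = int(regions_with_vntr(group_regions, vntrs).sum())
    b_with = int(regions_with_vntr(background_regions, vntrs).sum())
    g_n, b_n = len(group_regions), len(background_regions)
    res = chi_square_2x2(g_with, g_n - g_with, b_with, b_n - b_with,
                         correction=correction)
    return {"group_with": g_with, "group_total": g_n,
            "background_with": b_with, "background_total": b_n,
            "test": res}


def cgi_protection_by_vntr(cgis: pd.DataFrame, blastocyst_means,
                           vntrs: pd.DataFrame, threshold: float = 70.0,
                           correction: str = "none") -> dict:
    """Among CGIs hypermethylated in both gametes: does containing a VNTR
    predict staying > ``threshold`` % methylated in blastocysts?

    The caller restricts ``cgis`` to autosomal CGIs with both gamete means
    >= 80; ``blastocyst_means`` aligns with ``cgis`` rows.  The threshold
    is strict (exactly 70.0 counts as not protected).
    """
    means = np.asarray(blastocyst_means, float)
    has_v = regions_with_vntr(cgis, vntrs)
    defined = ~np.isnan(means)
    protected = defined & (means > threshold)
    a = int((has_v & protected).sum())
    b = int((has_v & defined & ~protected).sum())
    c = int((~has_v & protected).sum())
    d = int((~has_v & defined & ~protected).sum())
    out = {"vntr_protected": a, "vntr_unprotected": b,
           "novntr_protected": c, "novntr_unprotected": d}
    try:
        out["test"] = chi_square_2x2(a, b, c, d, correction=correction)
    except ValueError as exc:
        out["test"] = None
        out["test_error"] = str(exc)
    return out


def compare_vntr_features(vntrs_protected: pd.DataFrame,
                          vntrs_unprotected: pd.DataFrame) -> dict[str, dict]:
    """Mann-Whitney comparison of consensus-pattern size, copy number and
    alignment score between protected and unprotected top VNTRs."""
    if not len(vntrs_protected) or not len(vntrs_unprotected):
        raise ValueError("both groups need at least one VNTR")
    out = {}
    for feature in ("period_size", "copy_number", "alignment_score"):
        x = vntrs_protected[feature].to_numpy(float)
        y = vntrs_unprotected[feature].to_numpy(float)
        res: TestResult = mann_whitney_u(x, y)
        out[feature] = {
            "p": res.p_value, "statistic": res.statistic,
            "protected_median": float(np.median(x)),
            "unprotected_median": float(np.median(y)),
            "protected_q1": float(np.percentile(x, 25)),
            "protected_q3": float(np.percentile(x, 75)),
            "unprotected_q1": float(np.percentile(y, 25)),
            "unprotected_q3": float(np.percentile(y, 75)),
        }
    return out
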