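"""Region-level methylation: promoter and gene-body derivation from gene
models, per-region mean levels with kind-specific CpG minimums, and the
cross-sample correlation structure.

Promoters are TSS +- 1 kb (strand-aware, clipped at contig start); gene
bodies are the merged transcribed span of a gene's transcripts minus all of
its promoter intervals, with genes whose merged span is shorter than 300 bp
excluded.  A CpG belongs to a region when its forward-strand C position
lies in [start, end).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MethylomeTrack, make_regions
from .stats import pearson_r
from .windows import categorize_gamete

PROMOTER_FLANK = 1_000
MIN_GENE_SPAN = 300

#: kind-specific minimum number of covered CpGs for a defined mean
MIN_CPGS_BY_KIND = {"CGI": 10, "promoter": 10, "repeat_copy": 5}


def define_promoters(transcripts: pd.DataFrame,
                     flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """One promoter (TSS +- flank) per transcript, strand-aware.

    Overlapping promoters are kept separate; intervals extending past the
    contig start are clipped at 0 rather than dropped.
    """
    rows = []
    for tr in transcripts.itertuples(index=False):
        tss = tr.start if tr.strand != "-" else tr.end
        rows.append({"chrom": tr.chrom, "start": max(0, tss - flank),
                     "end": tss + flank, "strand": tr.strand,
                     "kind": "promoter", "name": tr.name})
    return make_regions(pd.DataFrame(rows))


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out: list[tuple[int, int]] = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(iv: list[tuple[int, int]], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in iv:
        pieces = [(s, e)]
        for cs, ce in cuts:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if cs > ps:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend(pieces)
    return out


def define_gene_bodies(transcripts: pd.DataFrame,
                       gene_col: str = "gene",
                       flank: int = PROMOTER_FLANK,
                       min_span: int = MIN_GENE_SPAN) -> pd.DataFrame:
    """Merged gene bodies: union of a gene's transcribed spans minus all of
    its promoter intervals.

    Genes whose merged transcribed span is shorter than ``min_span`` bp
    (mostly small-RNA hosts) are excluded.  The output may contain several
    rows per gene when promoters punch holes in the span; the summed length
    is recorded in ``gene_length`` on every row.
    """
    if gene_col not in transcripts.columns:
        transcripts = transcripts.assign(**{gene_col: transcripts["name"]})
    promoters = define_promoters(transcripts, flank)
    rows = []
    for gene, sub in transcripts.groupby(gene_col, sort=True):
        merged = _merge_intervals([(int(t.start), int(t.end))
                                   for t in sub.itertuples(index=False)])
        span = sum(e - s for s, e in merged)
        if span < min_span:
            continue
        proms = promoters[promoters["name"].isin(sub["name"])]
        cuts = [(int(p.start), int(p.end)) for p in proms.itertuples(index=False)]
        body = _subtract(merged, cuts)
        body_len = sum(e - s for s, e in body)
        chrom = sub["chrom"].iloc[0]
        strand = sub["strand"].iloc[0]
        for s, e in body:
            if e > s:
                rows.append({"chrom": chrom, "start": s, "end": e,
                             "strand": strand, "kind": "gene_body",
                             "name": gene, "gene_length": body_len})
    if not rows:
        return make_regions(pd.DataFrame(columns=["chrom", "start", "end"]))
    return make_regions(pd.DataFrame(rows))


def derive_exons(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Exon intervals from BED12 block structure (falls back to the full
    span for rows without blocks)."""
    rows = []
    has_blocks = "block_sizes" in transcripts.columns
    for tr in transcripts.itertuples(index=False):
        sizes = getattr(tr, "block_sizes", None) if has_blocks else None
        if sizes in (None, "", 0) or (isinstance(sizes, float) and np.isnan(sizes)):
            rows.append({"chrom": tr.chrom, "start": tr.start, "end": tr.end,
                         "strand": tr.strand, "kind": "exon", "name": tr.name})
            continue
        bsizes = [int(x) for x in str(sizes).split(",") if x]
        bstarts = [int(x) for x in str(tr.block_starts).split(",") if x]
        for bs, bl in zip(bstarts, bsizes):
            rows.append({"chrom": tr.chrom, "start": tr.start + bs,
                         "end": tr.start + bs + bl, "strand": tr.strand,
                         "kind": "exon", "name": tr.name})
    return make_regions(pd.DataFrame(rows)) if rows else make_regions(
        pd.DataFrame(columns=["chrom", "start", "end"]))


def derive_introns(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Intron intervals: transcript span minus its exons."""
    exons = derive_exons(transcripts)
    rows = []
    for tr in transcripts.itertuples(index=False):
        ex = exons[exons["name"] == tr.name]
        cuts = [(int(e.start), int(e.end)) for e in ex.itertuples(index=False)]
        for s, e in _subtract([(int(tr.start), int(tr.end))], cuts):
            if e > s:
                rows.append({"chrom": tr.chrom, "start": s, "end": e,
                             "strand": tr.strand, "kind": "intron",
                             "name": tr.name})
    return make_regions(pd.DataFrame(rows)) if rows else make_regions(
        pd.DataFrame(columns=["chrom", "start", "end"]))


# ---------------------------------------------------------------------------
# region means
# ---------------------------------------------------------------------------

def region_means(regions: pd.DataFrame, track: MethylomeTrack,
                 min_cpgs: int | Mapping[str, int] | None = None) -> pd.DataFrame:
    """Unweighted per-CpG mean methylation (%) per region.

    ``min_cpgs`` is either one integer for all regions or a mapping from
    region kind to minimum covered-CpG count (default: 10 for CGI and
    promoter, 5 for repeat copies, 1 otherwise); regions below their
    minimum get a NaN mean.
    """
    if min_cpgs is None:
        min_map = MIN_CPGS_BY_KIND
    elif isinstance(min_cpgs, int):
        min_map = {}
        default_min = min_cpgs
    else:
        min_map = dict(min_cpgs)
    default_min = min_cpgs if isinstance(min_cpgs, int) else 1

    cg = track.cpg_calls()
    cg = cg[cg["total"] > 0]
    by_chrom = {}
    for chrom, sub in cg.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        lv = sub["meth"].to_numpy(float) / sub["total"].to_numpy(float)
        c1 = np.concatenate([[0.0], np.cumsum(lv)])
        by_chrom[chrom] = (pos, c1)
    n_used = np.zeros(len(regions), int)
    means = np.full(len(regions), np.nan)
    for i, row in enumerate(regions.itertuples(index=False)):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos, c1 = entry
        lo = np.searchsorted(pos, row.start)
        hi = np.searchsorted(pos, row.end)
        n = hi - lo
        n_used[i] = n
        min_n = min_map.get(getattr(row, "kind", "other"), default_min)
        if n >= max(min_n, 1):
            means[i] = (c1[hi] - c1[lo]) / n * 100.0
    out = regions[["chrom", "start", "end", "kind", "name"]].copy()
    out["n_cpgs_used"] = n_used
    out["mean"] = means
    return out


def region_means_matrix(regions: pd.DataFrame,
                        tracks: Sequence[MethylomeTrack],
                        min_cpgs=None) -> pd.DataFrame:
    """Region x sample matrix of mean levels (%)."""
    out = None
    for t in tracks:
        rm = region_means(regions, t, min_cpgs)
        if out is None:
            out = rm[["chrom", "start", "end", "kind", "name"]].copy()
        out[t.sample_id] = rm["mean"].to_numpy()
    return out


def sample_correlation_matrix(feature_means: pd.DataFrame,
                              sample_cols: Sequence[str]) -> pd.DataFrame:
    """Symmetric Pearson matrix across samples over features defined in
    every sample (listwise deletion).  Requires >= 3 complete features."""
    sub = feature_means[list(sample_cols)].dropna()
    if len(sub) < 3:
        raise ValueError("fewer than 3 features defined in all samples")
    n = len(sample_cols)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_r(sub.iloc[:, i], sub.iloc[:, j])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=list(sample_cols), columns=list(sample_cols))


def categorize_gamete_regions(region_means_matrix_: pd.DataFrame,
                              oocyte_col: str, sperm_col: str,
                              hyper: float = 80.0, hypo: float = 20.0) -> pd.DataFrame:
    """Gamete-specific categories for CGIs/promoters — the window rule set
    applied to region means."""
    out = region_means_matrix_.copy()
    out["category"] = categorize_gamete(out[oocyte_col], out[sperm_col],
                                        hyper, hypo)
    return out
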