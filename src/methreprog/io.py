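"""Readers and writers for the bisulfite-methylome file dialects.

Supported inputs: Bismark-style cytosine reports (1-based, per strand),
the Bismark coverage/bedGraph-with-counts dialect, BED3/6/12 annotations,
RepeatMasker ``.out`` tables and Tandem Repeats Finder ``.dat`` output.
All readers are gzip-transparent and convert to 0-based half-open
coordinates at the boundary; duplicate positions are an error, never
silently summed.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (MethylomeTrack, ParseError, VNTRRecord, logger,
                   make_regions, vntr_table)

_CONTEXTS = {"CG", "CHG", "CHH"}


def _open_text(path):
    if str(path).endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# methylome tracks
# ---------------------------------------------------------------------------

def read_cytosine_report(path, sample_id: str | None = None,
                         cell_type: str = "other") -> MethylomeTrack:
    """Read a Bismark-style cytosine report into a :class:`MethylomeTrack`.

    Expected columns (tab-separated): chrom, 1-based position, strand,
    methylated count, unmethylated count, context; a seventh trinucleotide
    column, if present, is ignored.  Positions are converted to 0-based.
    Zero-coverage cytosines are retained (total_reads = 0) so depth
    filtering remains an explicit, separate step.
    """
    chroms, poss, ctxs, meths, totals = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 fields, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            if context not in _CONTEXTS:
                raise ParseError(f"{path}: line {lineno}: unknown context {context!r}")
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                pos = int(pos_s) - 1
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if pos < 0 or meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative value")
            chroms.append(chrom)
            poss.append(pos)
            ctxs.append(context)
            meths.append(meth)
            totals.append(meth + unmeth)
    calls = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, np.int64),
                          "context": ctxs, "meth": np.asarray(meths, np.int64),
                          "total": np.asarray(totals, np.int64)})
    _check_duplicates(calls, path)
    sid = sample_id or os.path.basename(str(path)).split(".")[0]
    return MethylomeTrack(sample_id=sid, cell_type=cell_type, calls=calls)


def write_cytosine_report(track: MethylomeTrack, path) -> None:
    """Write a track in the cytosine-report dialect (1-based, strand '+')."""
    with _open_text_w(path) as fh:
        for row in track.calls.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t+\t{row.meth}\t{row.total - row.meth}\t{row.context}\n")


def _open_text_w(path):
    if str(path).endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "wb"), encoding="utf-8")
    return open(path, "w", encoding="utf-8")


def read_bedgraph_counts(path, sample_id: str | None = None,
                         cell_type: str = "other") -> MethylomeTrack:
    """Read the Bismark coverage dialect: chrom, start, end, level%, meth, unmeth.

    The stored level column is recomputed from the counts; if it disagrees
    with the counts by more than 0.5 percentage points a warning is logged
    and the counts win.
    """
    chroms, poss, meths, totals = [], [], [], []
    n_warn = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields")
            chrom, start_s, _end_s, level_s, meth_s, unmeth_s = parts[:6]
            try:
                start = int(start_s)
                level = float(level_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad field ({exc})") from None
            total = meth + unmeth
            if total > 0 and abs(level - 100.0 * meth / total) > 0.5:
                n_warn += 1
                logger.warning("%s: line %d: level column %.2f inconsistent with counts %d/%d",
                               path, lineno, level, meth, total)
            chroms.append(chrom)
            poss.append(start)
            meths.append(meth)
            totals.append(total)
    calls = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, np.int64),
                          "context": "CG", "meth": np.asarray(meths, np.int64),
                          "total": np.asarray(totals, np.int64)})
    if not len(calls):
        calls = MethylomeTrack(sample_id="_", cell_type="other").calls
    _check_duplicates(calls, path)
    sid = sample_id or os.path.basename(str(path)).split(".")[0]
    return MethylomeTrack(sample_id=sid, cell_type=cell_type, calls=calls)


def write_bedgraph_counts(track: MethylomeTrack, path) -> None:
    with _open_text_w(path) as fh:
        for row in track.calls.itertuples(index=False):
            level = 100.0 * row.meth / row.total if row.total else 0.0
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{level:.6g}\t{row.meth}\t{row.total - row.meth}\n")


def _check_duplicates(calls: pd.DataFrame, path) -> None:
    if len(calls) and calls.duplicated(["chrom", "pos", "context"]).any():
        dup = calls[calls.duplicated(["chrom", "pos", "context"], keep=False)].iloc[0]
        raise ParseError(f"{path}: duplicate position {dup['chrom']}:{dup['pos']}")


# ---------------------------------------------------------------------------
# track transforms
# ---------------------------------------------------------------------------

def merge_cpg_strands(track: MethylomeTrack,
                      cpg_dyads: Mapping[str, np.ndarray],
                      return_report: bool = False):
    """Combine the two strands of each CpG dyad into one call.

    ``cpg_dyads`` maps chromosome -> sorted forward-strand C positions; the
    reverse-strand call of a dyad sits at position + 1.  Reverse calls with
    no matching dyad are kept unchanged (orphans) and counted; non-CpG
    contexts pass through untouched.  Total read counts are conserved
    exactly.
    """
    calls = track.calls
    cg = calls[calls["context"] == "CG"].copy()
    other = calls[calls["context"] != "CG"]
    n_orphans = 0
    out_parts = [other]
    for chrom, sub in cg.groupby("chrom", sort=False):
        dyads = np.asarray(cpg_dyads.get(chrom, np.empty(0, np.int64)))
        pos = sub["pos"].to_numpy()
        is_fwd = np.isin(pos, dyads)
        is_rev = np.isin(pos - 1, dyads) & ~is_fwd
        orphan = ~(is_fwd | is_rev)
        n_orphans += int(orphan.sum())
        anchor = pos.copy()
        anchor[is_rev] = pos[is_rev] - 1
        grp = sub.assign(_anchor=anchor)
        merged = grp.groupby("_anchor", as_index=False).agg(
            chrom=("chrom", "first"), meth=("meth", "sum"), total=("total", "sum"))
        merged["pos"] = merged["_anchor"]
        merged["context"] = "CG"
        out_parts.append(merged[["chrom", "pos", "context", "meth", "total"]])
    out = pd.concat(out_parts, ignore_index=True) if out_parts else calls
    out = out.sort_values(["chrom", "pos", "context"], kind="mergesort").reset_index(drop=True)
    if n_orphans:
        logger.info("merge_cpg_strands: %d reverse-strand call(s) without a matching dyad kept as orphans",
                    n_orphans)
    merged_track = track.with_calls(out)
    if return_report:
        return merged_track, {"n_orphans": n_orphans}
    return merged_track


def filter_depth(track: MethylomeTrack, min_depth: int) -> MethylomeTrack:
    """Keep only calls covered by at least ``min_depth`` reads."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    kept = track.calls[track.calls["total"] >= min_depth]
    return track.with_calls(kept, min_depth_applied=min_depth)


def pool_tracks(tracks: Sequence[MethylomeTrack],
                sample_id: str | None = None) -> MethylomeTrack:
    """Sum per-position counts across biological replicates.

    No depth filter is applied here; callers filter the pooled track, which
    is why pooled coverage can rescue positions below threshold in every
    single replicate.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    cell_types = {t.cell_type for t in tracks}
    if len(cell_types) > 1:
        raise ValueError(f"cannot pool mixed cell types: {sorted(cell_types)}")
    allc = pd.concat([t.calls for t in tracks], ignore_index=True)
    pooled = allc.groupby(["chrom", "pos", "context"], as_index=False)[["meth", "total"]].sum()
    pooled = pooled[["chrom", "pos", "context", "meth", "total"]]
    pooled = pooled.sort_values(["chrom", "pos", "context"], kind="mergesort").reset_index(drop=True)
    sid = sample_id or f"{tracks[0].cell_type}_pooled"
    return MethylomeTrack(sample_id=sid, cell_type=tracks[0].cell_type,
                          calls=pooled, min_depth_applied=None)


def estimate_conversion_rate(spike_track: MethylomeTrack,
                             spike_chrom: str = "lambda") -> float:
    """Bisulfite conversion rate from an unmethylated spike-in contig.

    conversion = 1 - (sum meth) / (sum total) over every cytosine (all
    contexts) of the spike contig.
    """
    spike = spike_track.calls[spike_track.calls["chrom"] == spike_chrom]
    total = int(spike["total"].sum())
    if total == 0:
        raise ValueError("no spike-in coverage")
    return 1.0 - float(spike["meth"].sum()) / total


# ---------------------------------------------------------------------------
# region annotations
# ---------------------------------------------------------------------------

_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand",
               "thick_start", "thick_end", "rgb", "block_count",
               "block_sizes", "block_starts"]


def read_regions(path, dialect: str, kind: str = "other") -> pd.DataFrame:
    """Parse a region annotation file into the canonical region table.

    ``dialect`` must be one of bed3, bed6, bed12, repeatmasker, trf — no
    format sniffing.  BED12 rows additionally carry transcript structure
    columns; TRF rows yield VNTR fields (period size, copy number,
    alignment score, consensus pattern).
    """
    if dialect in {"bed3", "bed6", "bed12"}:
        return _read_bed(path, dialect, kind)
    if dialect == "repeatmasker":
        return _read_repeatmasker(path)
    if dialect == "trf":
        return read_trf_dat(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed(path, dialect, kind):
    nfields = {"bed3": 3, "bed6": 6, "bed12": 12}[dialect]
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < nfields:
                raise ParseError(f"{path}: line {lineno}: expected {nfields} fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: out-of-order or negative coordinates")
            row = {"chrom": parts[0], "start": start, "end": end, "kind": kind}
            if nfields >= 6:
                row["name"] = parts[3]
                row["strand"] = parts[5] if parts[5] in {"+", "-"} else "."
            if nfields == 12:
                row["thick_start"] = int(parts[6])
                row["thick_end"] = int(parts[7])
                row["block_count"] = int(parts[9])
                row["block_sizes"] = parts[10].rstrip(",")
                row["block_starts"] = parts[11].rstrip(",")
            rows.append(row)
    return make_regions(pd.DataFrame(rows)) if rows else make_regions(pd.DataFrame(
        columns=["chrom", "start", "end"]))


def _read_repeatmasker(path):
    """RepeatMasker .out: whitespace table with 3 header lines."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] in {"SW", "score"} or line.startswith("  SW"):
                continue
            if not parts[0].lstrip("-").isdigit():
                continue  # header / continuation lines
            if len(parts) < 11:
                raise ParseError(f"{path}: line {lineno}: truncated RepeatMasker row")
            chrom = parts[4]
            try:
                start = int(parts[5]) - 1  # .out is 1-based inclusive
                end = int(parts[6])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: out-of-order or negative coordinates")
            name = parts[9]
            classfam = parts[10]
            rep_class, _, rep_family = classfam.partition("/")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "strand": "+" if parts[8] == "+" else "-",
                         "kind": "repeat_copy", "name": name,
                         "rep_class": rep_class,
                         "rep_family": rep_family or rep_class})
    return make_regions(pd.DataFrame(rows)) if rows else make_regions(
        pd.DataFrame(columns=["chrom", "start", "end"]))


def read_trf_dat(path) -> pd.DataFrame:
    """Tandem Repeats Finder .dat output -> VNTR table.

    Data lines have 15 whitespace-separated fields; the chromosome comes
    from the preceding ``Sequence:`` header.  TRF coordinates are 1-based
    inclusive and are converted to 0-based half-open.
    """
    records = []
    chrom = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Program", "Version", "Parameters", "Gary")):
                continue
            parts = line.split()
            if len(parts) < 15:
                continue
            try:
                start = int(parts[0]) - 1
                end = int(parts[1])
                period = int(parts[2])
                copies = float(parts[3])
                score = int(parts[7])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad TRF data line") from None
            if chrom is None:
                raise ParseError(f"{path}: line {lineno}: data line before Sequence header")
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: out-of-order or negative coordinates")
            records.append(VNTRRecord(chrom=chrom, start=start, end=end,
                                      period_size=period, copy_number=copies,
                                      alignment_score=score,
                                      consensus_pattern=parts[13]))
    return vntr_table(records)


def reference_cpg_map_from_track(track: MethylomeTrack) -> dict[str, np.ndarray]:
    """Reference CpG dyad positions per chromosome from a track's CG calls."""
    cg = track.cpg_calls()
    return {chrom: np.sort(sub["pos"].unique())
            for chrom, sub in cg.groupby("chrom", sort=True)}


def write_regions_bed6(regions: pd.DataFrame, path) -> None:
    with _open_text_w(path) as fh:
        for row in regions.itertuples(index=False):
            name = getattr(row, "name", "") or "."
            strand = getattr(row, "strand", ".") or "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{strand}\n")
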