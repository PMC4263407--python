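"""Core domain containers shared by every pipeline stage.

A methylome is represented as a table of per-cytosine read counts keyed by
(chromosome, position, context); all coordinates are 0-based half-open, with
a CpG dyad identified by the position of its forward-strand C.  Genomic
annotations (CpG islands, promoters, gene bodies, repeat copies, imprinted
DMRs, windows) share one tabular region representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("methreprog")

#: closed vocabulary of region kinds
REGION_KINDS = frozenset(
    {"CGI", "promoter", "gene_body", "repeat_copy", "DMR", "window", "exon",
     "intron", "VNTR", "other"}
)

CALL_COLUMNS = ["chrom", "pos", "context", "meth", "total"]

REGION_COLUMNS = ["chrom", "start", "end", "strand", "kind", "name",
                  "rep_class", "rep_family"]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "total": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class MethylomeTrack:
    """Per-cytosine methylated/total read counts for one sample.

    ``calls`` has columns chrom, pos (0-based forward-strand C), context
    (CG/CHG/CHH), meth, total.  Keys (chrom, pos, context) are unique.
    """

    sample_id: str
    cell_type: str = "other"
    calls: pd.DataFrame = field(default_factory=_empty_calls)
    min_depth_applied: int | None = None

    def __post_init__(self) -> None:
        c = self.calls
        missing = [col for col in CALL_COLUMNS if col not in c.columns]
        if missing:
            raise ValueError(f"calls table missing columns {missing}")
        if len(c):
            if (c["meth"] > c["total"]).any():
                raise ValueError("meth_reads exceeds total_reads")
            if (c["pos"] < 0).any():
                raise ValueError("negative position")
            bad = set(c["context"].unique()) - {"CG", "CHG", "CHH"}
            if bad:
                raise ValueError(f"unknown context token(s): {sorted(bad)}")

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.calls)

    def cpg_calls(self) -> pd.DataFrame:
        """CpG-context calls only."""
        return self.calls[self.calls["context"] == "CG"]

    def levels(self) -> pd.Series:
        """Per-cytosine methylation fraction (NaN where total == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.calls["meth"].to_numpy(float) / self.calls["total"].to_numpy(float)
        return pd.Series(lv, index=self.calls.index)

    def positions(self, chrom: str, context: str = "CG") -> np.ndarray:
        sub = self.calls[(self.calls["chrom"] == chrom) & (self.calls["context"] == context)]
        return sub["pos"].to_numpy()

    def context_mean_levels(self) -> pd.Series:
        """Global mean methylation (%) per context — the non-CpG summary."""
        c = self.calls[self.calls["total"] > 0]
        lv = c["meth"] / c["total"]
        return lv.groupby(c["context"]).mean() * 100.0

    def with_calls(self, calls: pd.DataFrame, **kw) -> "MethylomeTrack":
        return replace(self, calls=calls.reset_index(drop=True), **kw)

    def sorted(self) -> "MethylomeTrack":
        c = self.calls.sort_values(["chrom", "pos", "context"], kind="mergesort")
        return self.with_calls(c)


def make_regions(rows: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Normalize an iterable of region dicts into the canonical region table."""
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    for col, default in (("strand", "."), ("kind", "other"), ("name", ""),
                         ("rep_class", ""), ("rep_family", "")):
        if col not in df.columns:
            df[col] = default
    if len(df):
        if (df["start"] >= df["end"]).any():
            raise ParseError("region with start >= end")
        if (df["start"] < 0).any():
            raise ParseError("region with negative start")
        unknown = set(df["kind"].unique()) - REGION_KINDS
        if unknown:
            raise ValueError(f"unknown region kind(s): {sorted(unknown)}")
    extra = [c for c in df.columns if c not in REGION_COLUMNS]
    return df[REGION_COLUMNS + extra].reset_index(drop=True)


@dataclass
class VNTRRecord:
    """One tandem-repeat array (a VNTR candidate)."""

    chrom: str
    start: int
    end: int
    period_size: int
    copy_number: float
    alignment_score: int
    consensus_pattern: str = ""

    def __post_init__(self) -> None:
        if self.period_size < 1:
            raise ValueError("period_size must be >= 1")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


def vntr_table(records: Iterable[VNTRRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "period_size": r.period_size, "copy_number": r.copy_number,
            "alignment_score": r.alignment_score,
            "consensus_pattern": r.consensus_pattern,
        }
        for r in records
    ]
    cols = ["chrom", "start", "end", "period_size", "copy_number",
            "alignment_score", "consensus_pattern"]
    return pd.DataFrame(rows, columns=cols)
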