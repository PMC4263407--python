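"""Classification of a known imprinted-DMR catalogue into germline,
placenta-specific and secondary classes, and persistence summaries.

A DMR is a germline DMR (gDMR) when one gamete is hypermethylated
(>= 80%) and the other hypomethylated (<= 20%); maternal vs paternal by
which gamete carries the methylation.  gDMRs that keep an intermediate
blood level (35–65%, closed interval) are classified M-gDMR / P-gDMR;
maternal gDMRs lost in blood but flagged in the catalogue as maintained in
the placenta are placenta-specific M-gDMRs.  Everything else is a
secondary DMR (sDMR).  The placenta flag is catalogue metadata, never
computed here (no placenta methylome is involved).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

DMR_CLASSES = ("M_gDMR", "P_gDMR", "placenta_specific_M_gDMR", "sDMR")


def classify_dmr(oocyte: float, sperm: float, blood: float,
                 placenta_flag: bool = False,
                 hyper: float = 80.0, hypo: float = 20.0,
                 blood_interval: tuple[float, float] = (35.0, 65.0)) -> str:
    """Assign one of the four DMR classes from per-sample means (%).

    Returns 'unclassifiable' when any required mean is undefined.  A gDMR
    whose blood level falls outside the maintenance interval keeps its
    germline class unless the catalogue placenta flag reroutes a maternal
    gDMR to the placenta-specific class.
    """
    if any(np.isnan(v) for v in (oocyte, sperm, blood)):
        return "unclassifiable"
    maternal = oocyte >= hyper and sperm <= hypo
    paternal = sperm >= hyper and oocyte <= hypo
    if not (maternal or paternal):
        return "sDMR"
    lo, hi = blood_interval
    maintained = lo <= blood <= hi
    if maternal and not maintained and placenta_flag:
        return "placenta_specific_M_gDMR"
    return "M_gDMR" if maternal else "P_gDMR"


def classify_dmr_catalogue(catalogue: pd.DataFrame,
                           oocyte_col: str = "oocyte", sperm_col: str = "sperm",
                           blood_col: str = "blood",
                           placenta_col: str = "placenta_maintained",
                           **kwargs) -> pd.DataFrame:
    """Vectorised :func:`classify_dmr` over a catalogue table; adds an
    ``assigned_class`` column."""
    out = catalogue.copy()
    flags = (out[placenta_col].astype(bool) if placenta_col in out.columns
             else pd.Series(False, index=out.index))
    out["assigned_class"] = [
        classify_dmr(o, s, b, f, **kwargs)
        for o, s, b, f in zip(out[oocyte_col], out[sperm_col],
                              out[blood_col], flags)
    ]
    return out


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    vc = classified["assigned_class"].value_counts()
    return {cls: int(vc.get(cls, 0)) for cls in DMR_CLASSES}


def es_stability_summary(gdmr_es_means: pd.DataFrame | pd.Series,
                         threshold: float = 75.0) -> pd.DataFrame:
    """Per ES line: how many gDMRs lost their intermediate level through
    hypermethylation (mean strictly > threshold).

    Input: gDMR x ES-line mean table (placenta-specific gDMRs excluded by
    the caller).
    """
    if isinstance(gdmr_es_means, pd.Series):
        gdmr_es_means = gdmr_es_means.to_frame()
    rows = []
    for col in gdmr_es_means.columns:
        vals = gdmr_es_means[col].dropna()
        n_lost = int((vals > threshold).sum())
        rows.append({"es_line": col, "n_gdmrs": len(vals), "n_lost": n_lost,
                     "fraction_lost": n_lost / len(vals) if len(vals) else float("nan")})
    return pd.DataFrame(rows)


def persistence_comparison(gdmr_blastocyst_means: Sequence[float],
                           cgi_blastocyst_means: Sequence[float],
                           cgi_is_x: Sequence[bool] | None = None) -> dict:
    """Compare blastocyst persistence of gDMRs vs oocyte-specific CGIs.

    Reports group medians/quartiles and a Mann-Whitney p; when
    ``cgi_is_x`` is given the CGIs are additionally split into autosomal
    and X-linked groups (pooled blastocysts show higher X-linked levels
    when maternal methylation persists).
    """
    g = np.asarray(gdmr_blastocyst_means, float)
    c = np.asarray(cgi_blastocyst_means, float)
    g = g[~np.isnan(g)]
    c = c[~np.isnan(c)]
    if len(g) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty with defined means")
    res = mann_whitney_u(g, c)
    out = {
        "gdmr_median": float(np.median(g)),
        "gdmr_q1": float(np.percentile(g, 25)),
        "gdmr_q3": float(np.percentile(g, 75)),
        "cgi_median": float(np.median(c)),
        "cgi_q1": float(np.percentile(c, 25)),
        "cgi_q3": float(np.percentile(c, 75)),
        "mwu_p": res.p_value,
        "n_gdmr": len(g),
        "n_cgi": len(c),
    }
    if cgi_is_x is not None:
        isx = np.asarray(cgi_is_x, bool)
        call = np.asarray(cgi_blastocyst_means, float)
        auto = call[~isx]
        xs = call[isx]
        auto = auto[~np.isnan(auto)]
        xs = xs[~np.isnan(xs)]
        out["cgi_autosomal_median"] = float(np.median(auto)) if len(auto) else float("nan")
        out["cgi_x_median"] = float(np.median(xs)) if len(xs) else float("nan")
    return out
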