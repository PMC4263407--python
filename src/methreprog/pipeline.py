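"""Configuration-driven orchestration of the full analysis.

A run is described by a :class:`RunConfig` (YAML-serializable): sample
table, annotation paths, window geometry, the classification thresholds
and statistics flags.  ``run_full_analysis`` executes the enabled stages
(windows, regions, dmr, repeats, expression) and writes TSV/JSON outputs;
``collate_report`` gathers each stage's machine-readable summary into one
JSON.  Validation is fail-fast: missing files or inconsistent thresholds
abort before any computation starts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import MethylomeTrack, logger
from . import expression as expr_mod
from . import imprinting, io, regions as regions_mod, repeats as repeats_mod
from . import windows as win_mod
from .stats import region_mean_level

ALL_STAGES = ("windows", "regions", "dmr", "repeats", "expression")


@dataclass
class SampleSpec:
    id: str
    cell_type: str
    path: str
    dialect: str = "cytosine_report"  # or bedgraph_counts
    min_depth: int = 5


@dataclass
class RunConfig:
    samples: list[SampleSpec] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    outdir: str = "results"
    seed: int = 0
    window_size: int = 20
    window_step: int = 10
    min_covered: int = 10
    hyper: float = 80.0
    hypo: float = 20.0
    protect_threshold: float = 70.0
    es_loss_threshold: float = 75.0
    blood_interval: list = field(default_factory=lambda: [35.0, 65.0])
    t_test_mode: str = "unpaired"
    chi_square_correction: str = "none"
    min_gene_length: int = 5_000
    expression_boundary: float = -5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        cfg = cls(samples=samples, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def validate(self) -> None:
        for name in ("hyper", "hypo", "protect_threshold", "es_loss_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.hyper <= self.hypo:
            raise ValueError("hyper threshold must exceed hypo threshold")
        if not (0 < self.window_step <= self.window_size):
            raise ValueError("require 0 < step <= window size")
        for s in self.samples:
            if not os.path.exists(s.path):
                raise FileNotFoundError(f"sample {s.id}: missing file {s.path}")
        for key, path in self.annotations.items():
            if path and not os.path.exists(path):
                raise FileNotFoundError(f"annotation {key}: missing file {path}")


# ---------------------------------------------------------------------------

def load_tracks(config: RunConfig) -> dict[str, MethylomeTrack]:
    """Read, depth-filter and index every configured sample."""
    readers = {"cytosine_report": io.read_cytosine_report,
               "bedgraph_counts": io.read_bedgraph_counts}
    tracks = {}
    for s in config.samples:
        t = readers[s.dialect](s.path, sample_id=s.id, cell_type=s.cell_type)
        tracks[s.id] = io.filter_depth(t, s.min_depth)
    return tracks


def _genome_cpg_map(tracks: dict[str, MethylomeTrack],
                    exclude: tuple = ("lambda",)) -> dict[str, np.ndarray]:
    """Reference CpG map as the union of CG positions across samples."""
    pos: dict[str, set] = {}
    for t in tracks.values():
        cg = t.cpg_calls()
        for chrom, sub in cg.groupby("chrom", sort=False):
            if chrom in exclude:
                continue
            pos.setdefault(chrom, set()).update(sub["pos"].tolist())
    return {c: np.array(sorted(p), np.int64) for c, p in sorted(pos.items())}


def _by_cell_type(tracks: dict[str, MethylomeTrack]) -> dict[str, MethylomeTrack]:
    return {t.cell_type: t for t in tracks.values()}


def run_full_analysis(config: RunConfig, stages=None) -> dict:
    """Execute the enabled stages and write their outputs under
    ``config.outdir``; returns the in-memory result bundle."""
    config.validate()
    stages = list(stages or ALL_STAGES)
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    results: dict = {"config": dataclasses.asdict(config),
                     "package_version": __version__}
    try:
        tracks = load_tracks(config)
        by_type = _by_cell_type(tracks)
        cpg_map = _genome_cpg_map(tracks)
        windows = win_mod.build_cpg_windows(cpg_map, config.window_size,
                                            config.window_step)
        if "windows" in stages:
            results["windows"] = _stage_windows(config, windows, by_type, cpg_map)
        if "regions" in stages:
            results["regions"] = _stage_regions(config, tracks, by_type)
        if "dmr" in stages:
            results["dmr"] = _stage_dmr(config, by_type)
        if "repeats" in stages:
            results["repeats"] = _stage_repeats(config, windows, by_type, cpg_map)
        if "expression" in stages:
            results["expression"] = _stage_expression(config, by_type)
        with open(os.path.join(config.outdir, "run_summary.json"), "w") as fh:
            json.dump({k: v for k, v in results.items()
                       if k in {"config", "package_version"}}, fh, indent=2)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, config: RunConfig, name: str) -> None:
    df.to_csv(os.path.join(config.outdir, name), sep="\t", index=False,
              float_format="%.6g")


def _json(obj, config: RunConfig, name: str) -> None:
    with open(os.path.join(config.outdir, name), "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _stage_windows(config, windows, by_type, cpg_map):
    out = {}
    comparisons = [(a, b) for a, b in
                   (("oocyte", "blastocyst"), ("sperm", "blastocyst"),
                    ("blastocyst", "blood"), ("blastocyst", "ES"))
                   if a in by_type and b in by_type]
    proportions = {}
    for a, b in comparisons:
        calls = win_mod.classify_window_changes(
            windows, by_type[a], by_type[b], cpg_map, config.min_covered,
            delta_threshold=20.0, q_threshold=0.05)
        _write(calls, config, f"window_calls_{a}_to_{b}.tsv")
        proportions[f"{a}_to_{b}"] = win_mod.change_call_proportions(calls)
    out["change_proportions"] = proportions
    if "oocyte" in by_type and "sperm" in by_type:
        summarize = by_type.get("blastocyst")
        cats = win_mod.categorize_gamete_windows(
            windows, by_type["oocyte"], by_type["sperm"], cpg_map,
            config.min_covered, config.hyper, config.hypo, summarize=summarize)
        _write(cats, config, "window_gamete_categories.tsv")
        if summarize is not None:
            med = win_mod.category_medians(cats, f"{summarize.sample_id}_mean")
            out["category_blastocyst_medians"] = med.to_dict()
    if "blastocyst" in by_type:
        means = win_mod.window_means(windows, by_type["blastocyst"], cpg_map,
                                     config.min_covered)
        sel, frac = win_mod.screen_windows_above(means, config.protect_threshold)
        prot = windows[windows["window_id"].isin(sel.index)]
        _write(prot[["chrom", "start", "end", "window_id"]], config,
               "protected_windows.bed.tsv")
        out["protected_window_fraction"] = frac
    _json(out, config, "windows_summary.json")
    return out


def _feature_tables(config):
    ann = config.annotations
    cgis = (io.read_regions(ann["cgis"], "bed6", kind="CGI")
            if ann.get("cgis") else None)
    transcripts = (io.read_regions(ann["transcripts"], "bed12")
                   if ann.get("transcripts") else None)
    reps = (io.read_regions(ann["repeats"], "repeatmasker")
            if ann.get("repeats") else None)
    return cgis, transcripts, reps


def _stage_regions(config, tracks, by_type):
    out = {}
    cgis, transcripts, reps = _feature_tables(config)
    sample_ids = list(tracks)
    track_list = list(tracks.values())
    promoters = None
    if transcripts is not None:
        promoters = regions_mod.define_promoters(transcripts)
        bodies = regions_mod.define_gene_bodies(transcripts)
        io.write_regions_bed6(promoters, os.path.join(config.outdir, "promoters.bed"))
        io.write_regions_bed6(bodies, os.path.join(config.outdir, "gene_bodies.bed"))
    for label, regs in (("cgi", cgis), ("promoter", promoters),
                        ("repeat", reps)):
        if regs is None:
            continue
        mat = regions_mod.region_means_matrix(regs, track_list)
        _write(mat, config, f"{label}_means.tsv")
        try:
            corr = regions_mod.sample_correlation_matrix(mat, sample_ids)
            out[f"{label}_correlation"] = corr.round(4).to_dict()
        except ValueError as exc:
            out[f"{label}_correlation_error"] = str(exc)
        if label == "cgi" and "oocyte" in by_type and "sperm" in by_type:
            cats = regions_mod.categorize_gamete_regions(
                mat, by_type["oocyte"].sample_id, by_type["sperm"].sample_id,
                config.hyper, config.hypo)
            _write(cats, config, "cgi_gamete_categories.tsv")
            out["cgi_category_counts"] = (
                cats["category"].value_counts().to_dict())
    _json(out, config, "regions_summary.json")
    return out


def _required(by_type, *names):
    missing = [n for n in names if n not in by_type]
    if missing:
        raise ValueError(f"stage requires sample cell type(s): {missing}")


def _stage_dmr(config, by_type):
    ann = config.annotations
    if not ann.get("dmrs") or not ann.get("dmr_sidecar"):
        return {"skipped": "no DMR catalogue configured"}
    _required(by_type, "oocyte", "sperm", "blood")
    dmr_bed = io.read_regions(ann["dmrs"], "bed6", kind="DMR")
    sidecar = pd.read_csv(ann["dmr_sidecar"], sep="\t")
    cat = dmr_bed.merge(sidecar, on="name", how="left")
    per_sample = {}
    for ct, tr in by_type.items():
        rm = regions_mod.region_means(cat, tr, min_cpgs=1)
        per_sample[ct] = rm["mean"].to_numpy()
    table = cat[["chrom", "start", "end", "name"]].copy()
    for ct, vals in per_sample.items():
        table[ct] = vals
    table["placenta_maintained"] = cat.get(
        "placenta_maintained", pd.Series(False, index=cat.index)).fillna(False)
    classified = imprinting.classify_dmr_catalogue(
        table, oocyte_col="oocyte", sperm_col="sperm", blood_col="blood",
        hyper=config.hyper, hypo=config.hypo,
        blood_interval=tuple(config.blood_interval))
    _write(classified, config, "dmr_classified.tsv")
    out = {"class_counts": imprinting.class_counts(classified)}
    if "ES" in by_type:
        gd = classified[classified["assigned_class"].isin(["M_gDMR", "P_gDMR"])]
        stab = imprinting.es_stability_summary(gd[["ES"]],
                                               config.es_loss_threshold)
        out["es_stability"] = stab.to_dict("records")
    if "blastocyst" in by_type and config.annotations.get("cgis"):
        cgis = io.read_regions(ann["cgis"], "bed6", kind="CGI")
        mo = regions_mod.region_means(cgis, by_type["oocyte"])
        ms = regions_mod.region_means(cgis, by_type["sperm"])
        mb = regions_mod.region_means(cgis, by_type["blastocyst"])
        cats = win_mod.categorize_gamete(mo["mean"], ms["mean"],
                                         config.hyper, config.hypo)
        oo_specific = (cats == "oocyte_specific") & (cgis["chrom"] != "chrX").to_numpy()
        gd = classified[classified["assigned_class"].isin(["M_gDMR", "P_gDMR"])]
        if oo_specific.any() and len(gd):
            out["persistence"] = imprinting.persistence_comparison(
                gd["blastocyst"].to_numpy(),
                mb.loc[oo_specific, "mean"].to_numpy())
    _json(out, config, "dmr_summary.json")
    return out


def _stage_repeats(config, windows, by_type, cpg_map):
    ann = config.annotations
    if not ann.get("repeats"):
        return {"skipped": "no repeat annotation configured"}
    reps = io.read_regions(ann["repeats"], "repeatmasker")
    out = {}
    fam_means = {}
    for ct, tr in by_type.items():
        fm = repeats_mod.family_methylation(tr, reps)
        fam_means[ct] = fm.set_index("family")["mean"]
    fam_table = pd.DataFrame(fam_means).reset_index()
    _write(fam_table, config, "repeat_family_means.tsv")
    out["family_means"] = fam_table.round(3).to_dict("records")
    if "blastocyst" in by_type:
        means = win_mod.window_means(windows, by_type["blastocyst"], cpg_map,
                                     config.min_covered)
        sel, frac = win_mod.screen_windows_above(means, config.protect_threshold)
        prot_windows = windows[windows["window_id"].isin(sel.index)]
        ranking = repeats_mod.protection_screen(reps, prot_windows)
        _write(ranking, config, "repeat_protection_ranking.tsv")
        out["protection_top"] = ranking.head(10).to_dict("records")
        out["protected_window_fraction"] = frac
    if ann.get("vntrs"):
        vntrs = io.read_trf_dat(ann["vntrs"])
        if ann.get("dmrs") and ann.get("cgis") and "dmr" not in out:
            dmr_bed = io.read_regions(ann["dmrs"], "bed6", kind="DMR")
            sidecar = (pd.read_csv(ann["dmr_sidecar"], sep="\t")
                       if ann.get("dmr_sidecar") else None)
            cgis = io.read_regions(ann["cgis"], "bed6", kind="CGI")
            group = dmr_bed
            if sidecar is not None and "true_class" in sidecar.columns:
                merged = dmr_bed.merge(sidecar, on="name", how="left")
                group = merged[merged["true_class"] == "M_gDMR"]
            if len(group):
                enr = repeats_mod.vntr_enrichment(
                    group, cgis, vntrs, correction=config.chi_square_correction)
                out["vntr_enrichment"] = {
                    k: (v if not hasattr(v, "p_value")
                        else {"statistic": v.statistic, "p": v.p_value})
                    for k, v in enr.items()}
            if {"oocyte", "sperm", "blastocyst"} <= set(by_type):
                mo = regions_mod.region_means(cgis, by_type["oocyte"])
                ms = regions_mod.region_means(cgis, by_type["sperm"])
                mb = regions_mod.region_means(cgis, by_type["blastocyst"])
                both_hyper = ((mo["mean"] >= config.hyper)
                              & (ms["mean"] >= config.hyper)
                              & (cgis["chrom"] != "chrX")).to_numpy()
                sub = cgis[both_hyper].reset_index(drop=True)
                sub_means = mb.loc[both_hyper, "mean"].to_numpy()
                if len(sub):
                    prot = repeats_mod.cgi_protection_by_vntr(
                        sub, sub_means, vntrs, config.protect_threshold,
                        correction=config.chi_square_correction)
                    t = prot.pop("test", None)
                    if t is not None:
                        prot["test"] = {"statistic": t.statistic, "p": t.p_value}
                    out["cgi_vntr_protection"] = prot
                    # per-CGI top VNTR feature comparison
                    tops, prot_flags = [], []
                    defined = np.isfinite(sub_means)
                    for i, row in enumerate(sub.itertuples(index=False)):
                        if not defined[i]:
                            continue
                        top = repeats_mod.select_top_vntr(
                            (row.chrom, row.start, row.end), vntrs)
                        if top is not None:
                            tops.append(top)
                            prot_flags.append(sub_means[i] > config.protect_threshold)
                    if tops:
                        tdf = pd.DataFrame(tops).reset_index(drop=True)
                        pf = np.asarray(prot_flags)
                        if pf.any() and (~pf).any():
                            out["vntr_feature_comparison"] = (
                                repeats_mod.compare_vntr_features(tdf[pf], tdf[~pf]))
    _json(out, config, "repeats_summary.json")
    return out


def _stage_expression(config, by_type):
    ann = config.annotations
    needed = ("transcripts", "expression_human")
    if not all(ann.get(k) for k in needed):
        return {"skipped": "expression inputs not configured"}
    _required(by_type, "oocyte")
    transcripts = io.read_regions(ann["transcripts"], "bed12")
    bodies = regions_mod.define_gene_bodies(transcripts)
    rm = regions_mod.region_means(bodies, by_type["oocyte"], min_cpgs=1)
    rm = rm.rename(columns={"name": "gene"})
    agg = rm.groupby("gene").apply(
        lambda g: pd.Series({"mean": np.average(g["mean"], weights=g["n_cpgs_used"])
                             if g["n_cpgs_used"].sum() else float("nan"),
                             "gene_length": (g["end"] - g["start"]).sum()}),
        include_groups=False).reset_index()
    human_expr = expr_mod.load_expression(ann["expression_human"], "human")
    joined = expr_mod.genebody_expression_join(agg, human_expr,
                                               config.min_gene_length)
    joined["state"] = expr_mod.classify_transcriptional_state(
        joined["log2_rpkm"], config.expression_boundary)
    _write(joined, config, "genebody_expression.tsv")
    out = {"n_genes": len(joined),
           "active_mean_meth": float(joined.loc[joined["state"] == "active", "mean"].mean()),
           "inactive_mean_meth": float(joined.loc[joined["state"] == "inactive", "mean"].mean())}
    if ann.get("expression_mouse") and ann.get("homologs"):
        homologs = pd.read_csv(ann["homologs"], sep="\t")
        mouse_expr = expr_mod.load_expression(ann["expression_mouse"], "mouse")
        mouse_table = pd.read_csv(ann["mouse_body_means"], sep="\t") \
            if ann.get("mouse_body_means") else None
        if mouse_table is not None:
            classes = expr_mod.cross_species_genebody_classes(
                joined.rename(columns={"mean": "mean"}), mouse_table, homologs,
                config.hyper, config.hypo)
            _write(classes, config, "cross_species_classes.tsv")
            out["cross_species_counts"] = (
                classes["meth_class"].value_counts().to_dict())
        out["n_mouse_expression"] = len(mouse_expr)
    _json(out, config, "expression_summary.json")
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

REPORT_PARTS = ("windows_summary.json", "regions_summary.json",
                "dmr_summary.json", "repeats_summary.json",
                "expression_summary.json")


def collate_report(outdir: str) -> dict:
    """Gather stage summaries into one report JSON; raises a dependency
    error if no stage has produced output yet."""
    report = {}
    found = 0
    for name in REPORT_PARTS:
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            with open(path) as fh:
                report[name.replace("_summary.json", "")] = json.load(fh)
            found += 1
    if not found:
        raise FileNotFoundError(
            f"no stage summaries found in {outdir}; run the stages first")
    out = os.path.join(outdir, "report.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
    return report
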