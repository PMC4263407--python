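"""Synthetic multi-sample methylome generator with known ground truth.

Builds a miniature genome (a few ~2 Mb chromosomes, one of them an X) whose
CpG landscape contains CpG islands with planted gamete-specific methylation
categories, an imprinted-DMR catalogue with planted classes, repeat
families including a VNTR-bearing SVA-like family protected from
post-fertilization demethylation, gene bodies whose oocyte methylation is
driven by a bimodal expression state, and an unmethylated lambda-like
spike-in contig.  Read sampling is Poisson depth + binomial methylated
counts with a configurable bisulfite conversion rate.

Two contrasting blastocyst models are first-class:

``human_retention``
    the maternal genome is largely retained (one global retention factor,
    no replication-dependent dilution),
``mouse_passive``
    the maternal contribution is halved per replication round, with gDMRs
    exempt.

In both, the paternal genome is globally demethylated except at protected
regions (gDMRs, the SVA-like family, VNTR-bearing CpG islands).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .core import MethylomeTrack, make_regions, vntr_table, VNTRRecord

SAMPLES = ("oocyte", "sperm", "blood", "ES")  # blastocyst is model-derived
DEFAULT_DEPTHS = {"oocyte": 7, "sperm": 24, "blastocyst": 24,
                  "blood": 16, "ES": 16}

#: planted (oocyte, sperm) methylation probabilities per CGI category
CGI_CATEGORY_P = {
    "oocyte_specific": (0.90, 0.05),
    "sperm_specific": (0.05, 0.90),
    "both_hyper": (0.90, 0.90),
    "both_hypo": (0.05, 0.05),
    "intermediate": (0.50, 0.50),
}
CGI_CATEGORY_FRACTIONS = {
    "oocyte_specific": 0.20, "sperm_specific": 0.15, "both_hyper": 0.40,
    "both_hypo": 0.15, "intermediate": 0.10,
}

BASE_P = {"oocyte": 0.55, "sperm": 0.82, "blood": 0.82, "ES": 0.82}


@dataclass
class SyntheticTruth:
    """Ground truth of one generated scenario.

    ``p_true[sample][chrom]`` aligns with ``cpg_map[chrom]``; ``protected``
    marks CpGs whose paternal allele resists post-fertilization
    demethylation and ``gdmr_exempt`` marks CpGs whose maternal allele is
    exempt from passive dilution under the mouse-style model.
    """

    seed: int
    params: dict
    cpg_map: dict = field(default_factory=dict)
    p_true: dict = field(default_factory=dict)
    protected: dict = field(default_factory=dict)
    gdmr_exempt: dict = field(default_factory=dict)
    cgis: pd.DataFrame | None = None
    dmrs: pd.DataFrame | None = None
    repeats: pd.DataFrame | None = None
    transcripts: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    vntrs: pd.DataFrame | None = None
    noncpg: pd.DataFrame | None = None
    spike: pd.DataFrame | None = None


class _ChromBuilder:
    def __init__(self, chrom: str, rng: np.random.Generator):
        self.chrom = chrom
        self.rng = rng
        self.cursor = 1_000
        self.pos: list[np.ndarray] = []
        self.p: dict[str, list[np.ndarray]] = {s: [] for s in SAMPLES}
        self.protected: list[np.ndarray] = []
        self.exempt: list[np.ndarray] = []

    def gap(self, length: int, spacing: int = 200):
        """Background CpGs at roughly one per ``spacing`` bp."""
        n = max(1, length // spacing)
        pos = self.cursor + np.sort(self.rng.choice(length, size=n, replace=False))
        self._emit(pos, {s: np.full(n, BASE_P[s]) for s in SAMPLES})
        self.cursor += length

    def feature(self, length: int, spacing: int, p: dict[str, float],
                protected: bool = False, exempt: bool = False) -> tuple[int, int]:
        start = self.cursor
        pos = np.arange(start, start + length, spacing)
        n = len(pos)
        self._emit(pos, {s: np.full(n, p[s]) for s in SAMPLES},
                   protected=protected, exempt=exempt)
        self.cursor += length + self.rng.integers(300, 900)
        return start, start + length

    def _emit(self, pos, pdict, protected=False, exempt=False):
        n = len(pos)
        self.pos.append(np.asarray(pos, np.int64))
        for s in SAMPLES:
            self.p[s].append(np.asarray(pdict[s], float))
        self.protected.append(np.full(n, protected))
        self.exempt.append(np.full(n, exempt))

    def finish(self):
        pos = np.concatenate(self.pos)
        order = np.argsort(pos, kind="mergesort")
        return (pos[order],
                {s: np.concatenate(self.p[s])[order] for s in SAMPLES},
                np.concatenate(self.protected)[order],
                np.concatenate(self.exempt)[order])


def build_reference(seed: int, n_chroms: int = 3,
                    cgis_per_chrom: int = 60, dmrs_per_chrom: int = 15,
                    genes_per_chrom: int = 25,
                    window_check: int = 20) -> SyntheticTruth:
    """Build the reference scaffold: CpG map, annotations and true
    methylation probabilities for oocyte, sperm, blood and ES.

    The last chromosome is named ``chrX``; the rest ``chr1``…  Raises if
    the resulting CpG map cannot hold a single window per chromosome.
    """
    rng = np.random.default_rng(seed)
    params = {"n_chroms": n_chroms, "cgis_per_chrom": cgis_per_chrom,
              "dmrs_per_chrom": dmrs_per_chrom,
              "genes_per_chrom": genes_per_chrom}
    truth = SyntheticTruth(seed=seed, params=params)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms - 1)] + ["chrX"]

    cgi_rows, dmr_rows, rep_rows, tr_rows, gene_rows = [], [], [], [], []
    vntr_records: list[VNTRRecord] = []
    # per-chrom DMR class layout
    dmr_layout = (["M_gDMR"] * 8 + ["P_gDMR"] + ["placenta_specific_M_gDMR"] * 3
                  + ["sDMR"] * 3)
    cgi_cats = sum(([cat] * int(round(frac * cgis_per_chrom))
                    for cat, frac in CGI_CATEGORY_FRACTIONS.items()), [])
    cgi_cats = (cgi_cats + ["intermediate"] * cgis_per_chrom)[:cgis_per_chrom]

    for chrom in chrom_names:
        b = _ChromBuilder(chrom, rng)
        slots = []
        slots += [("cgi", cat) for cat in cgi_cats]
        slots += [("dmr", cls) for cls in (dmr_layout[:dmrs_per_chrom]
                                           if chrom != "chrX" else ["sDMR"] * 3)]
        slots += [("gene", None)] * genes_per_chrom
        slots += [("sva", None)] * 35
        slots += [("alr", None)] * 35
        slots += [("alu_group", None)] * 12
        slots += [("l1_group", None)] * 8
        rng.shuffle(slots)
        mgdmr_count = 0
        for slot, tag in slots:
            b.gap(rng.integers(2_000, 5_000))
            if slot == "cgi":
                cat = tag
                po, ps = CGI_CATEGORY_P[cat]
                has_vntr = cat == "both_hyper" and rng.random() < 0.3
                if has_vntr:
                    prot = rng.random() < 0.8
                else:
                    prot = cat == "both_hyper" and rng.random() < 0.05
                blood = 0.05 if cat != "both_hyper" else 0.9
                s, e = b.feature(1_000, 8, {"oocyte": po, "sperm": ps,
                                            "blood": blood, "ES": blood},
                                 protected=prot)
                if has_vntr:
                    period = int(rng.integers(20, 51))
                    copies = float(rng.normal(25, 3) if prot else rng.normal(10, 2))
                    copies = max(3.0, round(copies, 1))
                    alen = min(int(period * copies), 800)
                    vstart = s + 100
                    vntr_records.append(VNTRRecord(
                        chrom=chrom, start=vstart, end=vstart + alen,
                        period_size=period, copy_number=copies,
                        alignment_score=2 * alen))
                cgi_rows.append({"chrom": chrom, "start": s, "end": e,
                                 "kind": "CGI",
                                 "name": f"CGI_{chrom}_{len(cgi_rows)}",
                                 "category": cat, "has_vntr": has_vntr,
                                 "protected": prot})
            elif slot == "dmr":
                cls = tag
                if cls == "M_gDMR":
                    es_lost = mgdmr_count % 3 == 0  # ~1/3 hypermethylated in ES
                    mgdmr_count += 1
                    p = {"oocyte": 0.90, "sperm": 0.05, "blood": 0.50,
                         "ES": 0.92 if es_lost else 0.50}
                    prot, exempt, pla = True, True, False
                elif cls == "P_gDMR":
                    p = {"oocyte": 0.05, "sperm": 0.90, "blood": 0.50, "ES": 0.50}
                    prot, exempt, pla = True, True, False
                elif cls == "placenta_specific_M_gDMR":
                    p = {"oocyte": 0.90, "sperm": 0.05, "blood": 0.05, "ES": 0.05}
                    prot, exempt, pla = True, True, True
                else:  # sDMR
                    p = {"oocyte": 0.55, "sperm": 0.50, "blood": 0.50, "ES": 0.50}
                    prot, exempt, pla = False, False, False
                s, e = b.feature(900, 10, p, protected=prot, exempt=exempt)
                has_vntr = cls in {"P_gDMR", "M_gDMR"} and rng.random() < (
                    1.0 if cls == "P_gDMR" else 0.5)
                if has_vntr:
                    period = int(rng.integers(25, 61))
                    copies = round(float(rng.uniform(8, 20)), 1)
                    alen = min(int(period * copies), 700)
                    vntr_records.append(VNTRRecord(
                        chrom=chrom, start=s + 80, end=s + 80 + alen,
                        period_size=period, copy_number=copies,
                        alignment_score=2 * alen))
                dmr_rows.append({"chrom": chrom, "start": s, "end": e,
                                 "kind": "DMR",
                                 "name": f"DMR_{chrom}_{len(dmr_rows)}",
                                 "true_class": cls,
                                 "placenta_maintained": pla,
                                 "has_vntr": has_vntr})
            elif slot == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                active = rng.random() < 0.6
                body_p = 0.85 if active else 0.15
                body_len = int(rng.integers(7_000, 14_000))
                # promoter block then body block in genomic order
                if strand == "+":
                    ps, pe = b.feature(2_000, 20, {s: 0.08 for s in SAMPLES})
                    b.cursor -= 300  # promoter abuts the gene start
                    gs = pe - 1_000
                    s0, e0 = b.feature(body_len, 100,
                                       {"oocyte": body_p, "sperm": 0.85,
                                        "blood": 0.85, "ES": 0.85})
                    start, end = gs, e0
                else:
                    s0, e0 = b.feature(body_len, 100,
                                       {"oocyte": body_p, "sperm": 0.85,
                                        "blood": 0.85, "ES": 0.85})
                    b.cursor -= 300
                    ps, pe = b.feature(2_000, 20, {s: 0.08 for s in SAMPLES})
                    start, end = s0, ps + 1_000
                gene = f"G{chrom}_{len(gene_rows)}"
                rpkm = (float(2 ** rng.normal(4, 2)) if active
                        else float(10 ** rng.uniform(-4, -2.2)))
                mouse_active = active if rng.random() < 0.85 else not active
                gene_rows.append({"gene": gene, "chrom": chrom,
                                  "start": start, "end": end, "strand": strand,
                                  "expression_class": "active" if active else "inactive",
                                  "rpkm": rpkm,
                                  "mouse_rpkm": (float(2 ** rng.normal(5, 2))
                                                 if mouse_active
                                                 else float(10 ** rng.uniform(-3, -1))),
                                  "mouse_body_mean": 85.0 if mouse_active else 10.0,
                                  "homologene_id": 10_000 + len(gene_rows)})
                tr_rows.append({"chrom": chrom, "start": start, "end": end,
                                "name": gene, "strand": strand, "kind": "other",
                                "gene": gene})
            elif slot == "sva":
                s, e = b.feature(1_400, 12, {"oocyte": 0.85, "sperm": 0.90,
                                             "blood": 0.88, "ES": 0.88},
                                 protected=True)
                period = int(rng.integers(35, 50))
                copies = round(float(rng.uniform(15, 25)), 1)
                alen = min(int(period * copies), 900)
                vntr_records.append(VNTRRecord(
                    chrom=chrom, start=s + 200, end=s + 200 + alen,
                    period_size=period, copy_number=copies,
                    alignment_score=2 * alen))
                rep_rows.append({"chrom": chrom, "start": s, "end": e,
                                 "kind": "repeat_copy", "name": "SVA_A",
                                 "rep_class": "SVA", "rep_family": "SVA"})
            elif slot == "alr":
                s, e = b.feature(600, 20, {"oocyte": 0.90, "sperm": 0.60,
                                           "blood": 0.85, "ES": 0.85})
                rep_rows.append({"chrom": chrom, "start": s, "end": e,
                                 "kind": "repeat_copy", "name": "ALR",
                                 "rep_class": "Satellite",
                                 "rep_family": "centr"})
            elif slot == "alu_group":
                for _ in range(10):
                    s, e = b.feature(300, 25, {"oocyte": 0.60, "sperm": 0.85,
                                               "blood": 0.85, "ES": 0.85})
                    rep_rows.append({"chrom": chrom, "start": s, "end": e,
                                     "kind": "repeat_copy", "name": "AluY",
                                     "rep_class": "SINE", "rep_family": "Alu"})
            elif slot == "l1_group":
                for _ in range(5):
                    s, e = b.feature(800, 60, {"oocyte": 0.60, "sperm": 0.85,
                                               "blood": 0.85, "ES": 0.85})
                    rep_rows.append({"chrom": chrom, "start": s, "end": e,
                                     "kind": "repeat_copy", "name": "L1PA3",
                                     "rep_class": "LINE", "rep_family": "L1"})
        b.gap(3_000)
        pos, pdict, prot, exempt = b.finish()
        truth.cpg_map[chrom] = pos
        for s in SAMPLES:
            truth.p_true.setdefault(s, {})[chrom] = pdict[s]
        truth.protected[chrom] = prot
        truth.gdmr_exempt[chrom] = exempt

    for chrom, pos in truth.cpg_map.items():
        if len(pos) < window_check:
            raise ValueError(f"{chrom}: fewer CpGs than one window")

    truth.cgis = make_regions(pd.DataFrame(cgi_rows))
    truth.dmrs = make_regions(pd.DataFrame(dmr_rows))
    truth.repeats = make_regions(pd.DataFrame(rep_rows))
    truth.transcripts = make_regions(pd.DataFrame(tr_rows))
    truth.genes = pd.DataFrame(gene_rows)
    truth.vntrs = vntr_table(vntr_records)

    # non-CpG cytosines: oocyte-specific low CpA-like methylation
    nc_rows = []
    for chrom, pos in truth.cpg_map.items():
        span = int(pos[-1])
        n = 2_000
        npos = np.sort(rng.choice(span, size=n, replace=False))
        ctx = rng.choice(["CHH", "CHG"], size=n, p=[0.7, 0.3])
        nc_rows.append(pd.DataFrame({"chrom": chrom, "pos": npos, "context": ctx}))
    truth.noncpg = pd.concat(nc_rows, ignore_index=True)

    # lambda-like unmethylated spike contig (all contexts)
    n_spike = 3_000
    spos = np.sort(rng.choice(48_000, size=n_spike, replace=False))
    sctx = rng.choice(["CG", "CHG", "CHH"], size=n_spike, p=[0.1, 0.3, 0.6])
    truth.spike = pd.DataFrame({"chrom": "lambda", "pos": spos, "context": sctx})
    return truth


# ---------------------------------------------------------------------------
# blastocyst model + read sampling
# ---------------------------------------------------------------------------

def blastocyst_p(truth: SyntheticTruth, model: str = "human_retention",
                 rounds: int = 1, retention: float = 0.85,
                 pat_demeth: float = 0.10, pat_protected: float = 0.90,
                 x_maternal_weight: float = 0.70) -> dict[str, np.ndarray]:
    """True blastocyst methylation probabilities per chromosome.

    maternal = oocyte x retention (halved ``rounds`` times under
    ``mouse_passive`` except at gDMR-exempt CpGs); paternal = sperm x a
    strong global demethylation factor except at protected CpGs.  On chrX
    the maternal contribution gets extra weight (pooled blastocysts carry
    a maternally derived X in male embryos).
    """
    if model not in {"human_retention", "mouse_passive"}:
        raise ValueError(f"unknown model {model!r}")
    out = {}
    for chrom in truth.cpg_map:
        oo = truth.p_true["oocyte"][chrom]
        sp = truth.p_true["sperm"][chrom]
        prot = truth.protected[chrom]
        exempt = truth.gdmr_exempt[chrom]
        mat_factor = np.full(len(oo), retention)
        if model == "mouse_passive":
            mat_factor = np.where(exempt, retention,
                                  retention * 0.5 ** rounds)
        pat_factor = np.where(prot, pat_protected, pat_demeth)
        mat = oo * mat_factor
        pat = sp * pat_factor
        w = x_maternal_weight if chrom == "chrX" else 0.5
        out[chrom] = w * mat + (1.0 - w) * pat
    return out


def _sample_counts(rng, p, depth, noise_free):
    if noise_free:
        total = np.full(len(p), 1_000, np.int64)
        meth = np.round(p * 1_000).astype(np.int64)
    else:
        total = rng.poisson(depth, size=len(p)).astype(np.int64)
        meth = rng.binomial(total, p)
    return meth, total


def simulate_methylomes(truth: SyntheticTruth,
                        depths: dict[str, float] | None = None,
                        model: str = "human_retention", rounds: int = 1,
                        conversion: float = 0.995,
                        noise_free: bool = False,
                        seed: int | None = None,
                        **model_kw) -> dict[str, MethylomeTrack]:
    """Draw per-CpG read counts for all five samples plus the spike contig.

    Depth is Poisson per CpG per sample; methylated counts are binomial in
    the true probability after applying bisulfite non-conversion
    (observed p = p + (1-p)(1-conversion)).  ``noise_free=True`` replaces
    sampling by counts = round(p x 1000).
    """
    depths = {**DEFAULT_DEPTHS, **(depths or {})}
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    blast = blastocyst_p(truth, model=model, rounds=rounds, **model_kw)
    tracks = {}
    for sample in ("oocyte", "sperm", "blastocyst", "blood", "ES"):
        frames = []
        for chrom, pos in truth.cpg_map.items():
            p = (blast[chrom] if sample == "blastocyst"
                 else truth.p_true[sample][chrom])
            p_obs = p + (1.0 - p) * (1.0 - conversion)
            meth, total = _sample_counts(rng, p_obs, depths[sample], noise_free)
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "context": "CG", "meth": meth,
                                        "total": total}))
        # non-CpG cytosines
        nc = truth.noncpg
        p_nc = np.full(len(nc), 0.05 if sample == "oocyte" else 0.005)
        p_nc_obs = p_nc + (1.0 - p_nc) * (1.0 - conversion)
        meth, total = _sample_counts(rng, p_nc_obs, depths[sample], noise_free)
        frames.append(pd.DataFrame({"chrom": nc["chrom"], "pos": nc["pos"],
                                    "context": nc["context"], "meth": meth,
                                    "total": total}))
        # unmethylated spike
        sp = truth.spike
        p_sp = np.full(len(sp), 1.0 - conversion)
        meth, total = _sample_counts(rng, p_sp, depths[sample], noise_free)
        frames.append(pd.DataFrame({"chrom": sp["chrom"], "pos": sp["pos"],
                                    "context": sp["context"], "meth": meth,
                                    "total": total}))
        calls = pd.concat(frames, ignore_index=True)
        calls = calls.sort_values(["chrom", "pos", "context"],
                                  kind="mergesort").reset_index(drop=True)
        tracks[sample] = MethylomeTrack(sample_id=sample, cell_type=sample,
                                        calls=calls)
    return tracks


# ---------------------------------------------------------------------------
# window-change recovery experiment
# ---------------------------------------------------------------------------

def simulate_change_experiment(seed: int, n_windows: int = 1_000,
                               n_shifted: int = 100, shift: float = 50.0,
                               depth: float = 30.0, baseline: float = 20.0,
                               window: int = 20, step: int = 10):
    """Two-sample experiment with planted window-level methylation shifts.

    One chromosome carries ``n_windows`` sliding windows; ``n_shifted``
    windows, chosen at least three window indices apart, have all their
    CpGs shifted by ``shift`` percentage points in the second sample.
    Because adjacent windows share CpGs, the half-shifted neighbours of a
    planted window are true intermediate changes, not nulls; they are
    listed separately so recovery scoring can exclude them.

    Returns (windows, track_a, track_b, cpg_map, planted_idx, null_idx).
    """
    rng = np.random.default_rng(seed)
    n_cpg = (n_windows - 1) * step + window
    pos = np.arange(n_cpg, dtype=np.int64) * 50 + 100
    cpg_map = {"chrS": pos}
    candidates = np.arange(0, n_windows, 3)
    planted = np.sort(rng.choice(candidates, size=n_shifted, replace=False))
    shifted_cpg = np.zeros(n_cpg, bool)
    for w in planted:
        shifted_cpg[w * step: w * step + window] = True
    p_a = np.full(n_cpg, baseline / 100.0)
    p_b = p_a.copy()
    p_b[shifted_cpg] += shift / 100.0
    tracks = []
    for name, p in (("a", p_a), ("b", p_b)):
        total = rng.poisson(depth, size=n_cpg).astype(np.int64)
        meth = rng.binomial(total, p)
        calls = pd.DataFrame({"chrom": "chrS", "pos": pos, "context": "CG",
                              "meth": meth, "total": total})
        tracks.append(MethylomeTrack(sample_id=name, cell_type="other",
                                     calls=calls))
    from .windows import build_cpg_windows
    windows = build_cpg_windows(cpg_map, size=window, step=step)
    neighbour = np.zeros(n_windows, bool)
    for w in planted:
        for nb in (w - 1, w + 1):
            if 0 <= nb < n_windows:
                neighbour[nb] = True
    is_planted = np.zeros(n_windows, bool)
    is_planted[planted] = True
    null_idx = np.flatnonzero(~is_planted & ~neighbour)
    return windows, tracks[0], tracks[1], cpg_map, planted, null_idx


# ---------------------------------------------------------------------------
# truth emission
# ---------------------------------------------------------------------------

def write_annotations(truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write the scaffold's annotations in the standard dialects the
    parsers read (BED6, BED12, RepeatMasker .out, TRF .dat)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(_p("cgis.bed"), "w") as fh:
        for r in truth.cgis.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\n")
    with open(_p("dmrs.bed"), "w") as fh:
        for r in truth.dmrs.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\n")
    with open(_p("transcripts.bed12"), "w") as fh:
        for r in truth.transcripts.itertuples(index=False):
            ln = r.end - r.start
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}"
                     f"\t{r.start}\t{r.end}\t0\t1\t{ln},\t0,\n")
    with open(_p("repeats.out"), "w") as fh:
        fh.write("   SW  perc perc perc  query     position in query"
                 "     matching repeat\n\n")
        for r in truth.repeats.itertuples(index=False):
            classfam = (f"{r.rep_class}/{r.rep_family}"
                        if r.rep_family and r.rep_family != r.rep_class
                        else r.rep_class)
            fh.write(f"  500  10.0  0.0  0.0  {r.chrom}  {r.start + 1}  {r.end}"
                     f"  (0)  +  {r.name}  {classfam}  1  100  (0)  1\n")
    with open(_p("vntrs.dat"), "w") as fh:
        fh.write("Tandem Repeats Finder Program\n\n")
        for chrom, sub in truth.vntrs.groupby("chrom", sort=True):
            fh.write(f"Sequence: {chrom}\n\n")
            for v in sub.sort_values("start").itertuples(index=False):
                cons = "ACGT" * (v.period_size // 4 + 1)
                cons = cons[:v.period_size]
                fh.write(f"{v.start + 1} {v.end} {v.period_size} {v.copy_number}"
                         f" {v.period_size} 100 0 {v.alignment_score}"
                         f" 25 25 25 25 2.0 {cons} {cons}\n")
    with open(_p("expression_human.tsv"), "w") as fh:
        for g in truth.genes.itertuples(index=False):
            fh.write(f"{g.gene}\t{g.rpkm:.6g}\n")
    with open(_p("expression_mouse.tsv"), "w") as fh:
        for g in truth.genes.itertuples(index=False):
            fh.write(f"m{g.gene}\t{g.mouse_rpkm:.6g}\n")
    with open(_p("mouse_body_means.tsv"), "w") as fh:
        fh.write("gene\tmean\n")
        for g in truth.genes.itertuples(index=False):
            fh.write(f"m{g.gene}\t{g.mouse_body_mean:.6g}\n")
    with open(_p("homologs.tsv"), "w") as fh:
        fh.write("human_gene\tmouse_gene\thomologene_id\n")
        for g in truth.genes.itertuples(index=False):
            fh.write(f"{g.gene}\tm{g.gene}\t{g.homologene_id}\n")
    return paths


def emit_truth_tables(truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write planted-label tables and a manifest for recovery scoring."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    tables = {"cgi_truth.tsv": truth.cgis, "dmr_truth.tsv": truth.dmrs,
              "repeat_truth.tsv": truth.repeats,
              "gene_truth.tsv": truth.genes, "vntr_truth.tsv": truth.vntrs}
    for name, df in tables.items():
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path
    manifest = {"seed": truth.seed, "params": truth.params,
                "package_version": __version__,
                "n_cpgs": {c: int(len(p)) for c, p in truth.cpg_map.items()}}
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_sha1"] = hashlib.sha1(blob).hexdigest()
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest.json"] = mpath
    return paths
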