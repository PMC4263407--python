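"""Gene-body methylation vs transcription: RPKM loading with the 0.01
floor, the >5 kb gene filter, the bimodal active/inactive boundary and the
cross-species gene-body methylation classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ParseError, logger

RPKM_FLOOR = 0.01
MIN_GENE_LENGTH = 5_000
#: expression boundaries separating the two gene-body methylation modes
BOUNDARY_LOG2_RPKM = {"human": -5.0, "mouse": 0.0}


def load_expression(path, species: str = "human",
                    floor: float = RPKM_FLOOR) -> pd.DataFrame:
    """Two-column TSV (gene, RPKM) -> table with floored log2(RPKM).

    RPKM below ``floor`` is set to ``floor`` before the log, bounding
    log2_rpkm below by log2(0.01) ~ -6.644.  Negative RPKM is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "rpkm"], dtype={"gene": str})
    if df["rpkm"].dtype == object:
        # header row present
        df = df.iloc[1:].reset_index(drop=True)
        df["rpkm"] = df["rpkm"].astype(float)
    if (df["rpkm"] < 0).any():
        raise ParseError(f"{path}: negative RPKM")
    df["log2_rpkm"] = np.log2(np.maximum(df["rpkm"], floor))
    df["species"] = species
    return df


def genebody_expression_join(gene_body_means: pd.DataFrame,
                             expression: pd.DataFrame,
                             min_length: int = MIN_GENE_LENGTH) -> pd.DataFrame:
    """Join per-gene body methylation with expression.

    ``gene_body_means`` needs columns gene, gene_length, mean; genes with
    body length <= ``min_length``, undefined mean or no expression record
    are dropped (counts logged).
    """
    gb = gene_body_means.copy()
    n0 = len(gb)
    gb = gb[gb["gene_length"] > min_length]
    n_short = n0 - len(gb)
    gb = gb[np.isfinite(gb["mean"])]
    n_undef = n0 - n_short - len(gb)
    joined = gb.merge(expression, on="gene", how="inner")
    logger.info("gene-body/expression join: %d genes (%d short, %d undefined mean, %d unmatched dropped)",
                len(joined), n_short, n_undef, len(gb) - len(joined))
    if not len(joined):
        raise ValueError("empty join between gene bodies and expression")
    return joined.reset_index(drop=True)


def classify_transcriptional_state(log2_rpkm, boundary: float) -> np.ndarray:
    """'active' iff log2(RPKM) strictly exceeds the boundary."""
    lv = np.asarray(log2_rpkm, float)
    return np.where(lv > boundary, "active", "inactive")


def cross_species_genebody_classes(human_table: pd.DataFrame,
                                   mouse_table: pd.DataFrame,
                                   homolog_pairs: pd.DataFrame,
                                   hyper: float = 80.0,
                                   hypo: float = 20.0) -> pd.DataFrame:
    """Classify homolog pairs by gene-body methylation conservation.

    ``homolog_pairs`` has columns human_gene, mouse_gene (an optional
    homologene_id column is carried through); duplicated genes are dropped
    with a log message.  Classes: both_hyper / both_hypo /
    human_specific_hyper / mouse_specific_hyper / other, using the global
    >= 80 / <= 20 thresholds on each species' body mean.
    """
    pairs = homolog_pairs.copy()
    n0 = len(pairs)
    pairs = pairs.drop_duplicates("human_gene").drop_duplicates("mouse_gene")
    if len(pairs) < n0:
        logger.info("homolog table: dropped %d duplicated pairing(s)", n0 - len(pairs))
    h = human_table[["gene", "mean"]].rename(columns={"gene": "human_gene",
                                                      "mean": "human_mean"})
    m = mouse_table[["gene", "mean"]].rename(columns={"gene": "mouse_gene",
                                                      "mean": "mouse_mean"})
    j = pairs.merge(h, on="human_gene").merge(m, on="mouse_gene")
    j = j[np.isfinite(j["human_mean"]) & np.isfinite(j["mouse_mean"])]
    hm = j["human_mean"].to_numpy()
    mm = j["mouse_mean"].to_numpy()
    cls = np.full(len(j), "other", dtype=object)
    cls[(hm >= hyper) & (mm >= hyper)] = "both_hyper"
    cls[(hm <= hypo) & (mm <= hypo)] = "both_hypo"
    cls[(hm >= hyper) & (mm <= hypo)] = "human_specific_hyper"
    cls[(mm >= hyper) & (hm <= hypo)] = "mouse_specific_hyper"
    j = j.assign(meth_class=cls)
    return j.reset_index(drop=True)
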