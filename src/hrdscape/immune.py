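"""Expression-derived immune and pathway indices.

Three per-sample scores over a gene x sample log2-scale expression matrix
(values are log2(linear + 1)):

* ``cyt_index`` — cytolytic activity: the geometric mean of the
  linear-scale GZMA and PRF1 transcript levels, each offset by 0.01.
* ``ssgsea_score`` — single-sample gene-set enrichment: a rank-based
  running-sum statistic comparing the weighted in-set cumulative
  distribution (weights rank^alpha) to the uniform out-of-set one, used
  here as an immune-infiltration index with a packaged stand-in immune
  gene set.
* ``geneset_mean_z`` — the mean across set genes of per-gene z-scores
  (each gene standardised over samples), a simple per-sample pathway
  activity summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSet, read_gmt

log = logging.getLogger("hrdscape")

CYT_GENES = ("GZMA", "PRF1")
CYT_OFFSET = 0.01
SSGSEA_ALPHA = 0.25


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    score: float
    metric: str


def _linear(values: pd.Series | pd.DataFrame):
    """Invert the log2(x + 1) transform back to the linear scale."""
    return np.power(2.0, values) - 1.0


def cyt_index(expr: pd.DataFrame) -> pd.Series:
    """Cytolytic index per sample: geometric mean of GZMA and PRF1 (+0.01)."""
    missing = [g for g in CYT_GENES if g not in expr.index]
    if missing:
        raise ValueError(f"cyt_index: gene(s) absent from matrix: {missing}")
    linear = _linear(expr.loc[list(CYT_GENES)]) + CYT_OFFSET
    scores = np.sqrt(linear.iloc[0] * linear.iloc[1])
    scores.name = "cyt"
    return scores


def _present_genes(expr: pd.DataFrame, gene_set: GeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in expr.index]
    if not present:
        raise ValueError(f"gene set {gene_set.name!r}: no genes present in matrix")
    if len(present) < 0.5 * len(gene_set.genes):
        raise ValueError(
            f"gene set {gene_set.name!r}: only {len(present)}/{len(gene_set.genes)} "
            "genes present (< 50%)"
        )
    return present


def ssgsea_score(expr: pd.DataFrame, gene_set: GeneSet,
                 alpha: float = SSGSEA_ALPHA) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Genes are ranked by expression within each sample (descending; ties get
    average ranks, with ties broken deterministically by gene name for the
    walk order).  The score is the sum over the ranked list of the
    difference between the weighted in-set ECDF (weights rank^alpha) and
    the uniform out-of-set ECDF.  The degenerate all-genes set scores 0.
    """
    present = set(_present_genes(expr, gene_set))
    n_genes = expr.shape[0]
    n_out = n_genes - len(present)
    genes = expr.index.to_numpy()
    in_set = np.fromiter((g in present for g in genes), dtype=bool, count=n_genes)

    scores = {}
    for sample in expr.columns:
        if n_out == 0:
            scores[sample] = 0.0
            continue
        values = expr[sample].to_numpy(dtype=float)
        ranks = rankdata(values)  # ascending, average ties
        # walk in descending expression order; gene name breaks ties
        order = np.lexsort((genes, -values))
        w = np.abs(ranks[order]) ** alpha
        members = in_set[order]
        w_in = np.where(members, w, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~members) / n_out
        scores[sample] = float((p_in - p_out).sum())
    out = pd.Series(scores, name="immune_ssgsea")
    out.index.name = "sample_id"
    return out


def geneset_mean_z(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample mean of per-gene z-scores over the set genes.

    Genes with constant expression across samples have an undefined z-score
    and are dropped with a warning.
    """
    present = _present_genes(expr, gene_set)
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        log.warning("geneset_mean_z: dropping constant gene(s) %s", constant)
        sub = sub.drop(index=constant)
        if sub.empty:
            raise ValueError(f"gene set {gene_set.name!r}: all genes constant")
        sd = sd.drop(index=constant)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    scores = z.mean(axis=0)
    scores.name = "geneset_mean_z"
    return scores


def load_default_immune_set() -> GeneSet:
    """Packaged stand-in immune gene set (canonical immune-cell markers).

    The immune signature internal to the cited infiltration scoring tool is
    not redistributable; this synthetic stand-in list of well-established
    lymphocyte/cytotoxicity markers is user-replaceable via any GMT file.
    """
    ref = resources.files("hrdscape.data") / "immune_stand_in.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)[0]
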