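"""Single-sample GSEA pathway activity scores.

Each sample is scored independently: genes are ranked by expression
(descending, ties broken lexicographically by gene symbol for determinism),
and each gene set receives the running-sum statistic

    score = sum_i [ P_in(i) - P_out(i) ]

where P_in(i) is the weighted fraction of in-set genes encountered among the
top-i ranks (weights |x|**alpha on in-set genes) and P_out(i) the unweighted
fraction of out-of-set genes. This is the integral (sum over all rank
positions) form of the single-sample enrichment statistic, not the maximal
deviation used by cohort-level GSEA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("pathcalib")

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_GENES = 2


class DegenerateSetError(ValueError):
    """A gene set covers every gene in the matrix (empty complement)."""


@dataclass
class PathwayActivityMatrix:
    """Pathways x samples activity scores with labels carried over.

    ``params`` records the rank-weight exponent alpha and the normalization
    mode so downstream artifacts are self-describing.
    """

    scores: pd.DataFrame
    labels: pd.Series
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("non-finite pathway scores")
        self.labels = self.labels.loc[self.scores.columns]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def restrict(self, sample_ids: list[str]) -> "PathwayActivityMatrix":
        return PathwayActivityMatrix(scores=self.scores[sample_ids],
                                     labels=self.labels.loc[sample_ids],
                                     params=dict(self.params))


def _sample_order(values: pd.Series) -> np.ndarray:
    """Indices ordering genes by expression desc, gene symbol asc on ties."""
    genes = values.index.to_numpy()
    # lexsort: last key is primary; negate for descending expression
    return np.lexsort((genes, -values.to_numpy()))


def ssgsea_scores(expr: ExpressionMatrix,
                  sets: GeneSetCollection,
                  alpha: float = DEFAULT_ALPHA,
                  min_genes: int = DEFAULT_MIN_GENES,
                  normalize: bool = True) -> PathwayActivityMatrix:
    """Score every gene set in every sample.

    Sets overlapping the matrix in fewer than ``min_genes`` genes are dropped
    with a warning; a set covering all genes raises
    :class:`DegenerateSetError`. With ``normalize`` the whole matrix is
    divided by its (max - min) so scores span a range of width one.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = np.asarray(expr.gene_ids)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    memberships: dict[str, np.ndarray] = {}
    for pid in sets.pathway_ids:
        present = [gene_pos[g] for g in sets[pid] if g in gene_pos]
        if len(present) < min_genes:
            logger.warning("dropping %s: only %d/%d genes present",
                           pid, len(present), len(sets[pid]))
            continue
        if len(present) == n:
            raise DegenerateSetError(f"{pid} covers all genes in the matrix")
        ind = np.zeros(n, dtype=bool)
        ind[present] = True
        memberships[pid] = ind
    if not memberships:
        raise ValueError("no gene set overlaps the matrix sufficiently")

    pids = list(memberships)
    member = np.stack([memberships[p] for p in pids])          # (P, n)
    out = np.empty((len(pids), len(expr.sample_ids)))

    for j, sample in enumerate(expr.sample_ids):
        x = expr.values[sample]
        order = _sample_order(x)
        w = np.abs(x.to_numpy()[order]) ** alpha               # rank weights
        m_ord = member[:, order]                               # (P, n)
        win = np.where(m_ord, w, 0.0)
        tot_in = win.sum(axis=1, keepdims=True)
        # all-zero in-set weights (alpha>0, all-zero expression): fall back to
        # unweighted counts so the statistic stays defined
        flat = tot_in[:, 0] == 0
        if flat.any():
            win[flat] = m_ord[flat].astype(float)
            tot_in[flat, 0] = win[flat].sum(axis=1)
        p_in = np.cumsum(win, axis=1) / tot_in
        n_out = (~m_ord).sum(axis=1, keepdims=True)
        p_out = np.cumsum(~m_ord, axis=1) / n_out
        out[:, j] = (p_in - p_out).sum(axis=1)

    scores = pd.DataFrame(out, index=pids, columns=expr.sample_ids)
    mode = "none"
    if normalize:
        width = float(out.max() - out.min())
        if width > 0:
            scores = scores / width
            mode = "range"
        else:
            logger.warning("score matrix has zero range; skipping normalization")
    return PathwayActivityMatrix(
        scores=scores, labels=expr.labels,
        params={"alpha": alpha, "min_genes": min_genes, "normalize": mode})


def read_pas(path: str, labels: pd.Series) -> PathwayActivityMatrix:
    scores = pd.read_csv(path, sep="\t", index_col=0)
    return PathwayActivityMatrix(scores=scores, labels=labels)


def write_pas(pas: PathwayActivityMatrix, path: str) -> None:
    pas.scores.to_csv(path, sep="\t", float_format="%.6g", index_label="pathway")
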