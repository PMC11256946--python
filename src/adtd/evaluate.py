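"""Performance metrics for deconvolution experiments.

Recovery of compositions, hidden proportions and the hidden profile is
scored by Pearson correlation; recovery of spiked cell-type-specific
regulation by a ROC AUC averaged over the up- and down-regulation
directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "recovery_correlations",
    "hidden_recovery",
    "profile_recovery",
    "regulation_auc",
    "rank_regulated_genes",
    "top_gene_overlap",
]

logger = logging.getLogger(__name__)


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return float("nan")
    return float(ac @ bc / (na * nb))


@dataclass
class EvaluationReport:
    """Flat bundle of the metrics of one experiment."""

    per_type_r: dict
    mean_r: float
    hidden_r: float | None = None
    profile_r: float | None = None
    regulation_auc: float | None = None
    run_sd: dict | None = None

    def to_dict(self) -> dict:
        out = {f"r_{k}": v for k, v in self.per_type_r.items()}
        out["mean_r"] = self.mean_r
        if self.hidden_r is not None:
            out["hidden_r"] = self.hidden_r
        if self.profile_r is not None:
            out["profile_r"] = self.profile_r
        if self.regulation_auc is not None:
            out["regulation_auc"] = self.regulation_auc
        if self.run_sd:
            out.update({f"sd_{k}": v for k, v in self.run_sd.items()})
        return out


def recovery_correlations(C_true, C_hat, celltype_ids=None
                          ) -> tuple[dict, float]:
    """Per-cell-type Pearson correlation across samples, and their mean.

    Cell types with constant true proportions have undefined correlation;
    they are reported as NaN, excluded from the mean and logged.
    """
    C_true = np.asarray(C_true, dtype=float)
    C_hat = np.asarray(C_hat, dtype=float)
    if C_true.shape != C_hat.shape:
        raise ValueError("C_true and C_hat must have equal shapes")
    q = C_true.shape[0]
    ids = list(celltype_ids) if celltype_ids is not None else list(range(q))
    per_type = {}
    vals = []
    for k in range(q):
        r = _pearson(C_true[k], C_hat[k])
        per_type[ids[k]] = r
        if np.isnan(r):
            logger.warning("correlation undefined for cell type %s "
                           "(zero variance); excluded from the mean", ids[k])
        else:
            vals.append(r)
    mean_r = float(np.mean(vals)) if vals else float("nan")
    return per_type, mean_r


def hidden_recovery(hidden_true, c_hat) -> float:
    """Pearson correlation of estimated vs. true hidden proportions."""
    return _pearson(hidden_true, c_hat)


def profile_recovery(x_true, x_hat) -> float:
    """Pearson correlation of estimated vs. true hidden profile."""
    return _pearson(x_true, x_hat)


def regulation_auc(Delta_hat, spec, negatives: str = "all_unspiked") -> float:
    """AUC for detecting spiked regulation, averaged over directions.

    Up-regulated (factor > 0) entries are scored by ``Delta_jk - 1`` and
    down-regulated ones by ``1 - Delta_jk``; in both directions the
    negatives are the unspiked (gene, type) pairs.  With
    ``negatives="unspiked_genes"`` pairs belonging to a spiked gene but a
    different type are excluded from the negatives.

    Returns the mean of the two AUCs, or the single available one (with a
    warning) if only one direction was spiked.
    """
    D = np.asarray(Delta_hat, dtype=float)
    p, q = D.shape
    if not spec.entries:
        raise ValueError("empty regulation spec")
    up = np.zeros((p, q), dtype=bool)
    down = np.zeros((p, q), dtype=bool)
    for gj, k, a in spec.entries:
        (up if a > 0 else down)[gj, k] = True
    spiked = up | down
    if negatives == "all_unspiked":
        neg = ~spiked
    elif negatives == "unspiked_genes":
        spiked_genes = spiked.any(axis=1)
        neg = ~spiked & ~spiked_genes[:, None]
    else:
        raise ValueError(f"unknown negatives mode {negatives!r}")
    aucs = []
    for mask, score in ((up, D - 1.0), (down, 1.0 - D)):
        if not mask.any():
            continue
        labels = np.concatenate([np.ones(mask.sum()), np.zeros(neg.sum())])
        scores = np.concatenate([score[mask], score[neg]])
        aucs.append(float(roc_auc_score(labels, scores)))
    if len(aucs) == 1:
        warnings.warn("only one regulation direction present; returning its "
                      "AUC alone", RuntimeWarning, stacklevel=2)
    return float(np.mean(aucs))


def rank_regulated_genes(Delta_hat, gene_ids=None, celltype_ids=None
                         ) -> pd.DataFrame:
    """Rank genes by their strongest rescaling deviation.

    Genes are sorted descending by ``max_k |Delta_jk - 1|`` (ties broken
    by ascending gene index); the arg-max cell type is reported
    alongside.
    """
    D = np.asarray(Delta_hat, dtype=float)
    p, q = D.shape
    gids = list(gene_ids) if gene_ids is not None else list(range(p))
    ctypes = list(celltype_ids) if celltype_ids is not None else list(range(q))
    dev = np.abs(D - 1.0)
    score = dev.max(axis=1)
    argk = dev.argmax(axis=1)
    order = np.lexsort((np.arange(p), -score))
    return pd.DataFrame(
        {
            "gene": [gids[j] for j in order],
            "score": score[order],
            "celltype": [ctypes[argk[j]] for j in order],
            "gene_index": order,
        }
    ).reset_index(drop=True)


def top_gene_overlap(rankings: dict, top_n: int = 10) -> dict:
    """Venn-style overlap of the top-``n`` genes of several rankings.

    ``rankings`` maps group name to a ranked gene list (or the DataFrame
    produced by :func:`rank_regulated_genes`).  Returns a mapping from
    each non-empty group combination (a tuple of names) to the set of
    genes appearing in exactly those groups' top-``n``.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two groups")
    tops = {}
    for name, ranked in rankings.items():
        if isinstance(ranked, pd.DataFrame):
            genes = list(ranked["gene"])
        else:
            genes = list(ranked)
        tops[name] = set(genes[:top_n])
    names = list(tops)
    out = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(tops[c] for c in combo))
            outside = set.union(*(tops[c] for c in names if c not in combo),
                                set())
            cell = inside - outside
            if cell:
                out[combo] = cell
    return out
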