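"""Immune-microenvironment annotation.

Four tools:

* :func:`deconvolve` — reference-based cell-type deconvolution: each bulk
  methylation profile is regressed on the signature columns by non-negative
  least squares and the coefficients are renormalized onto the simplex.
  Validated by mixture recovery (exact at zero noise, RMSE < 0.05 at
  realistic noise), not by bit-compatibility with any particular package.
* :func:`ssgsea` — single-sample gene-set enrichment: per sample, genes are
  mid-ranked by expression and the score integrates the difference between
  the weighted in-set ECDF (weights ``rank^alpha``) and the uniform
  out-of-set ECDF over all positions; scores are then min-max normalized
  across the whole matrix.  The closed form used here equals the classic
  running-sum when there are no ties and averages over tie orderings
  otherwise (so constant expression scores exactly 0 before normalization).
* :func:`ora_hypergeometric` — over-representation analysis with the
  upper-tail hypergeometric test and BH adjustment.
* :func:`gsea_preranked` — weighted Kolmogorov-Smirnov enrichment score on
  a pre-ranked gene list, with a gene-label permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .classifier import bh_adjust
from .io_formats import BetaMatrix, ExprMatrix, GeneSetCollection, SignatureMatrix

log = logging.getLogger(__name__)


@dataclass
class CellProportions:
    """Per-sample cell-type proportions on the simplex, plus fit residuals."""

    proportions: pd.DataFrame  # samples x cell types
    residual: pd.Series        # per-sample residual norm of the NNLS fit

    def __post_init__(self) -> None:
        P = self.proportions.to_numpy(dtype=float)
        if (P < -1e-9).any():
            raise ValueError("negative proportion")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("proportions must sum to 1 per sample")


@dataclass
class EnrichmentResult:
    """One gene set's enrichment call (ES or odds ratio, p, BH q)."""

    name: str
    statistic: float
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

def deconvolve(m: BetaMatrix, sig: SignatureMatrix) -> CellProportions:
    """Estimate cell-type proportions by NNLS on shared marker features.

    Requires at least as many shared markers as cell types and a
    full-column-rank signature on those markers.  Coefficients are
    normalized to sum to one per sample (an all-zero fit is reported as a
    uniform composition with a warning).
    """
    shared = m.values.index.intersection(sig.values.index)
    k = len(sig.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared markers for {k} cell types"
        )
    S = sig.values.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < k:
        raise ValueError("signature matrix is rank deficient on the shared markers")
    X = m.values.loc[shared].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("bulk matrix has missing values at shared markers")
    props = np.empty((X.shape[1], k))
    resid = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        coef, r = nnls(S, X[:, j])
        total = coef.sum()
        if total <= 0:
            log.warning("all-zero NNLS fit for sample %s; reporting uniform",
                        m.values.columns[j])
            props[j] = 1.0 / k
        else:
            props[j] = coef / total
        resid[j] = r
    return CellProportions(
        proportions=pd.DataFrame(props, index=m.values.columns, columns=sig.cell_types),
        residual=pd.Series(resid, index=m.values.columns),
    )


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Closed-form integrated ECDF difference for one sample.

    With descending mid-positions ``mpos`` (1 = highest expression) the
    running-sum score equals
    ``sum_{g in S} w_g (N - mpos_g + 1) - mean_{g not in S}(N - mpos_g + 1)``
    where ``w`` are the normalized ``rank^alpha`` in-set weights; mid-ranks
    make the expression exact in expectation over tie orderings.
    """
    n = len(values)
    asc_rank = sps.rankdata(values)          # 1 = lowest expression
    mpos = n + 1.0 - asc_rank                # descending mid-position
    tail = n - mpos + 1.0                    # how many positions the gene covers
    w = asc_rank[in_set] ** alpha
    total = w.sum()
    if total == 0:
        return 0.0
    hit = float((w / total * tail[in_set]).sum())
    miss = float(tail[~in_set].mean())
    return hit - miss


def ssgsea(
    expr: ExprMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (samples x sets).

    Sets with fewer than two member genes present in the matrix get a
    missing score (warned).  With ``normalize`` the whole score matrix is
    divided by its global max-min range (the standard ssGSEA convention).
    """
    genes = pd.Index(expr.values.index)
    X = expr.values.to_numpy(dtype=float)
    scores = {}
    for name, members in sets.items():
        mask = np.asarray(genes.isin(list(members)))
        if mask.sum() < 2:
            log.warning("gene set %r has <2 genes in the matrix; score missing", name)
            scores[name] = np.full(X.shape[1], np.nan)
            continue
        if mask.all():
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        scores[name] = np.array(
            [_ssgsea_sample(X[:, j], mask, alpha) for j in range(X.shape[1])]
        )
    out = pd.DataFrame(scores, index=expr.values.columns)
    if normalize:
        rng_ = np.nanmax(out.to_numpy()) - np.nanmin(out.to_numpy()) if out.size else 0.0
        if rng_ > 0:
            out = out / rng_
    return out


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def ora_hypergeometric(hits, universe, annotation: GeneSetCollection) -> list:
    """Hypergeometric over-representation of ``hits`` in each annotation set.

    ``p = P(overlap >= observed)`` drawing ``|hits|`` genes from the
    universe with ``|set ∩ universe|`` successes; BH-adjusted q across the
    collection; results sorted by p.  The reported statistic is the
    enrichment odds ratio of the 2x2 overlap table.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits:
        raise ValueError("empty hit list")
    outside = hits - universe
    if outside:
        log.warning("%d hit gene(s) outside the universe dropped", len(outside))
        hits &= universe
        if not hits:
            raise ValueError("no hits remain inside the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in annotation.items():
        K = len(members & universe)
        k = len(hits & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        stat = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else 0.0
        rows.append(EnrichmentResult(name=name, statistic=stat, p=min(p, 1.0)))
    qs = bh_adjust([r.p for r in rows])
    for r, q in zip(rows, qs):
        r.q = float(q)
    rows.sort(key=lambda r: (r.p, r.name))
    return rows


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _es_running_sum(stat_sorted: np.ndarray, in_set_sorted: np.ndarray) -> float:
    """Weighted KS enrichment score on an already-sorted ranking."""
    w = np.abs(stat_sorted) * in_set_sorted
    total_w = w.sum()
    n_miss = (~in_set_sorted.astype(bool)).sum()
    if total_w == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(w) / total_w
    p_miss = np.cumsum(~in_set_sorted.astype(bool)) / n_miss
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_preranked(
    ranking, gene_set, n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Pre-ranked GSEA for one gene set.

    ``ranking`` maps gene -> rank statistic (dict or Series).  The ES is
    the maximum deviation of the weighted KS running sum (weights = |stat|
    for in-set genes); the p-value is the fraction of random same-size gene
    sets with |ES| at least as large (with the +1 small-sample guard).
    """
    ranking = pd.Series(ranking, dtype=float)
    order = np.argsort(-ranking.to_numpy(), kind="mergesort")
    stat = ranking.to_numpy()[order]
    genes = ranking.index.to_numpy()[order]
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k == 0 or k == len(genes):
        raise ValueError("gene set must hit some but not all ranked genes")
    es = _es_running_sum(stat, in_set)
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(genes))
    for _ in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(idx, size=k, replace=False)] = True
        if abs(_es_running_sum(stat, perm)) >= abs(es) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return EnrichmentResult(name="preranked", statistic=es, p=float(p))
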