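"""The diagnostic model and its evaluation statistics.

A three-hidden-layer fully connected network maps region-level methylation
features to a disease score in [0, 1]:

* logistic activations in the hidden layers (default sizes 16, 8, 4),
  sigmoid output, binary cross-entropy loss with an L2 weight penalty,
  trained by full-batch gradient descent — small enough to be exactly
  reproducible under a seed on one CPU;
* features are standardized with training-set means/SDs, which are frozen
  inside the model and reused for every later projection (no leakage from
  validation data);
* the train/validation split is stratified per class at fraction 0.6666
  (round-half-up), matching the study's split of the 21 + 60 augmented
  WGBS sub-samples into 54 training and 27 validation samples.

The module also provides the evaluation statistics used throughout the
analysis, implemented from first principles: rank-based ROC AUC (the
Mann-Whitney U normalization with ties counted 1/2), the two-sided
Mann-Whitney U test (exact enumeration for small samples, normal
approximation with tie and continuity corrections otherwise), Spearman
correlation with a t approximation, Benjamini-Hochberg adjustment, and
Fisher's exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CASE, CONTROL
from .feature_integration import FeatureMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_val(
    features: FeatureMatrix, fraction: float = 0.6666, seed: int = 0, stratified: bool = True
):
    """Stratified train/validation split at the study's 0.6666 fraction.

    Per class, ``round(fraction * class_size)`` samples (round-half-up) go
    to training; the split is disjoint, exhaustive and deterministic under
    ``seed``.  With 21 controls + 60 cases this yields 14+40 = 54 training
    and 7+20 = 27 validation samples.  Raises if any class has fewer than
    two samples or the validation set would be empty.
    """
    if features.groups is None:
        raise ValueError("feature matrix has no group labels")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    strata = (
        [features.groups[features.groups == g].index for g in sorted(features.groups.unique())]
        if stratified
        else [features.values.index]
    )
    for idx in strata:
        n = len(idx)
        if n < 2:
            raise ValueError(f"a class has {n} sample(s); need >= 2")
        n_train = _round_half_up(fraction * n)
        if n_train >= n or n_train < 1:
            raise ValueError(f"fraction {fraction} leaves an empty train or validation set")
        perm = rng.permutation(n)
        train_idx.extend(idx[perm[:n_train]])
        val_idx.extend(idx[perm[n_train:]])

    def subset(ids):
        return FeatureMatrix(
            values=features.values.loc[ids],
            groups=features.groups.loc[ids],
            activity=None if features.activity is None else features.activity.loc[ids],
        )

    return subset(train_idx), subset(val_idx)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class NetSpec:
    """Architecture and optimisation settings for the diagnostic network."""

    hidden_sizes: tuple = (16, 8, 4)
    max_epochs: int = 2000
    learning_rate: float = 0.5
    l2_penalty: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise ValueError("the diagnostic network uses exactly three hidden layers")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class Model:
    """A trained network plus its frozen standardization."""

    weights: list
    biases: list
    feature_ids: list
    mean: np.ndarray
    sd: np.ndarray
    loss_history: list = field(default_factory=list)


@dataclass
class ModelScore:
    sample_id: str
    score: float
    true_group: str = ""
    activity: float = float("nan")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def _forward(model_w, model_b, X):
    a = X
    acts = [a]
    for W, b in zip(model_w, model_b):
        a = _sigmoid(a @ W + b)
        acts.append(a)
    return acts


def train_nn(train: FeatureMatrix, spec: NetSpec = NetSpec()) -> Model:
    """Train the three-hidden-layer network by full-batch gradient descent.

    Features are standardized with training means/SDs (zero-SD features get
    SD 1); labels are 1 for cases.  The loss is mean binary cross-entropy
    plus ``l2_penalty/2 * ||W||^2``.  Raises if the loss turns non-finite
    (reporting the epoch).  Deterministic under ``spec.seed``.
    """
    if train.groups is None:
        raise ValueError("training features need group labels")
    X = train.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training features contain missing values")
    y = (train.groups.to_numpy() == CASE).astype(float)
    if y.min() == y.max():
        raise ValueError("training set has a single class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    rng = np.random.default_rng(spec.seed)
    sizes = [X.shape[1], *spec.hidden_sizes, 1]
    Ws = [rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
          for i in range(len(sizes) - 1)]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    n = len(y)
    history = []
    for epoch in range(spec.max_epochs):
        acts = _forward(Ws, bs, Xs)
        out = acts[-1][:, 0]
        eps = 1e-12
        loss = -np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
        loss += 0.5 * spec.l2_penalty * sum(float((W**2).sum()) for W in Ws)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        history.append(float(loss))
        # backprop: cross-entropy + sigmoid gives (out - y) at the output
        grad = (out - y)[:, None] / n
        for layer in range(len(Ws) - 1, -1, -1):
            a_prev = acts[layer]
            gW = a_prev.T @ grad + spec.l2_penalty * Ws[layer]
            gb = grad.sum(axis=0)
            if layer > 0:
                grad = (grad @ Ws[layer].T) * acts[layer] * (1.0 - acts[layer])
            Ws[layer] = Ws[layer] - spec.learning_rate * gW
            bs[layer] = bs[layer] - spec.learning_rate * gb
    return Model(
        weights=Ws, biases=bs, feature_ids=list(train.values.columns),
        mean=mean, sd=sd, loss_history=history,
    )


def score(model: Model, features: FeatureMatrix) -> list:
    """Score samples with a trained model (columns re-aligned by region id)."""
    missing = [f for f in model.feature_ids if f not in features.values.columns]
    if missing:
        raise ValueError(f"features missing model regions: {missing[:5]}")
    X = features.values[model.feature_ids].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    Xs = (X - model.mean) / model.sd
    out = _forward(model.weights, model.biases, Xs)[-1][:, 0]
    groups = features.groups
    activity = features.activity
    return [
        ModelScore(
            sample_id=s,
            score=float(out[i]),
            true_group="" if groups is None else str(groups.iloc[i]),
            activity=float("nan") if activity is None else float(activity.iloc[i]),
        )
        for i, s in enumerate(features.values.index)
    ]


def scores_frame(scores) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score": [s.score for s in scores],
            "group": [s.true_group for s in scores],
            "activity": [s.activity for s in scores],
        }
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney U normalization; ties count 1/2.

    ``labels`` are truthy for positives.  Raises on single-class input.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([bool(l) for l in labels])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes")
    ranks = sps.rankdata(s)  # mid-ranks
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _u_statistic(ranks_a, n_a):
    return float(np.sum(ranks_a) - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, exact_max_n: int = 12):
    """Two-sided Mann-Whitney U test.

    For combined sample size <= ``exact_max_n`` the p-value is exact:
    every assignment of the pooled mid-ranks to group A is enumerated and
    ``p = P(|U - mu_U| >= |U_obs - mu_U|)`` (so identical samples give
    exactly p = 1).  Larger samples use the normal approximation with tie
    and continuity corrections.  Returns ``(U_a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("empty sample")
    pooled = np.r_[a, b]
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= exact_max_n:
        dev = abs(u_obs - mu)
        hits = total = 0
        for comb in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(comb)], n_a)
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return u_obs, hits / total

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    diff = u_obs - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(sigma2)
    return u_obs, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def spearman(x, y):
    """Spearman rank correlation: Pearson on mid-ranks, t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((rx * ry).sum() / denom)
    n = len(x)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), n - 2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more likely than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    dist = sps.hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, max(p, float(p_obs)))
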