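"""Connectome-based predictive modeling: selection, strengths, LOOCV.

The CPM procedure, per training fold: correlate every edge with the clinical
score, keep edges with two-tailed p < alpha (default 0.001), split them by
correlation sign into a positive and a negative network, sum each subject's
edge weights over each network ("network strength"), fit ordinary
least-squares models relating strength to score (one per network plus a
bivariate combined model), and predict the left-out subject.  Edges selected
in every fold (the consensus) are kept for interpretation.

Leave-one-out statistics are organised so that fold i never numerically
touches subject i's score: per-fold sums are assembled from prefix/suffix
cumulative sums rather than "total minus element", which makes the
no-leakage property hold to bitwise equality, and makes permutation reruns
cheap because the score-independent parts are computed once per cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import stdtr

from .connectome import n_edges_for
from .scores import Cohort

MODEL_NAMES = ("positive", "negative", "combined")

DEFAULT_ALPHA = 0.001

#: Relative tolerance below which a fold variance is treated as zero
#: (constant edge) rather than a real signal.
_VAR_REL_TOL = 1e-12


class CPMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Edge-wise statistics and selection


@dataclass
class EdgeStats:
    """Per-edge Pearson correlation with the score and two-tailed p-value."""

    r: np.ndarray
    p: np.ndarray


@dataclass
class NetworkMask:
    """Boolean per-edge indicator for one network sign."""

    edges: np.ndarray
    sign: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=bool)
        if self.sign not in ("positive", "negative"):
            raise CPMError(f"mask sign must be positive/negative, got {self.sign!r}")

    @property
    def n_selected(self) -> int:
        return int(self.edges.sum())

    def edge_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.edges)]


def correlate_edges(edge_matrix: np.ndarray, scores: np.ndarray) -> EdgeStats:
    """Pearson r (and two-tailed p) of every edge against the score.

    p-values come from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    with n-2 degrees of freedom.  Edges constant across subjects carry
    (r, p) = (0, 1).
    """
    X = np.asarray(edge_matrix, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    n = X.shape[0]
    if n < 4:
        raise CPMError(f"edge-score correlation needs >= 4 subjects, got {n}")
    if y.shape != (n,):
        raise CPMError("scores not aligned with edge matrix rows")
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y == 0.0:
        raise CPMError("score vector is constant; correlations undefined")
    Xc = X - X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    cov = yc @ Xc
    constant = ss_x <= _VAR_REL_TOL * np.max(ss_x, initial=0.0)
    denom = np.sqrt(ss_x * ss_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(constant, 0.0, cov / np.where(denom == 0.0, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        t = np.where(np.isfinite(t), t, np.where(r > 0, np.inf, -np.inf))
    p = 2.0 * stdtr(df, -np.abs(t))
    p = np.where(constant, 1.0, p)
    return EdgeStats(r=r, p=p)


def select_edges(
    edge_stats: EdgeStats, alpha: float = DEFAULT_ALPHA
) -> tuple[NetworkMask, NetworkMask]:
    """Threshold edges at p < alpha (strict) and split by correlation sign.

    At ``alpha = 1.0`` every non-constant edge with nonzero r is selected,
    partitioned by sign.
    """
    if not 0.0 < alpha <= 1.0:
        raise CPMError(f"alpha must be in (0, 1], got {alpha}")
    sig = edge_stats.p < alpha
    pos = NetworkMask(sig & (edge_stats.r > 0.0), "positive")
    neg = NetworkMask(sig & (edge_stats.r < 0.0), "negative")
    return pos, neg


def network_strength(edge_vector: np.ndarray, mask: NetworkMask) -> float:
    """Sum of a subject's edge weights over the mask (empty mask -> 0)."""
    v = np.asarray(edge_vector, dtype=np.float64)
    if v.shape[-1] != mask.edges.size:
        raise CPMError(
            f"edge vector length {v.shape[-1]} != mask length {mask.edges.size}"
        )
    return float(v[..., mask.edges].sum(axis=-1)) if v.ndim == 1 else v[:, mask.edges].sum(axis=1)


def fit_strength_model(strengths: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Least-squares fit of score on network strength(s).

    ``strengths`` is (n,) for a single-network model or (n, k) for the
    combined model.  Returns ``[intercept, slope_1, ..., slope_k]``.  A
    strength column with zero variance gets slope 0 and is absorbed into
    the intercept.
    """
    S = np.asarray(strengths, dtype=np.float64)
    if S.ndim == 1:
        S = S[:, None]
    y = np.asarray(scores, dtype=np.float64)
    n, k = S.shape
    if y.shape != (n,):
        raise CPMError("scores not aligned with strengths")
    if n < k + 1:
        raise CPMError(f"need >= {k + 1} subjects to fit {k} slope(s) + intercept, got {n}")
    return _ols(S, y)


def _ols(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept; zero-variance columns dropped (slope 0)."""
    n, k = S.shape
    keep = [j for j in range(k) if np.ptp(S[:, j]) != 0.0]
    coef = np.zeros(k + 1)
    if not keep:
        coef[0] = y.mean()
        return coef
    design = np.column_stack([np.ones(n)] + [S[:, j] for j in keep])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef[0] = beta[0]
    for pos, j in enumerate(keep):
        coef[1 + j] = beta[1 + pos]
    return coef


# ---------------------------------------------------------------------------
# The frozen, transferable model


@dataclass
class NetworkModel:
    """Frozen CPM artifact: edge masks plus fitted linear coefficients.

    ``coefficients`` maps model name to ``[intercept, slopes...]``: one slope
    for ``positive`` (positive-network strength) and ``negative``; two for
    ``combined`` (positive strength, negative strength).
    """

    pos_mask: NetworkMask
    neg_mask: NetworkMask
    coefficients: dict[str, np.ndarray]
    target: str = ""
    alpha: float = DEFAULT_ALPHA
    n_train: int = 0
    n_nodes: int = 0
    train_subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in MODEL_NAMES:
            if name not in self.coefficients:
                raise CPMError(f"model lacks coefficients for {name!r}")
            self.coefficients[name] = np.asarray(self.coefficients[name], dtype=np.float64)
        if self.coefficients["combined"].size != 3:
            raise CPMError("combined model must have exactly two slopes plus intercept")

    def strengths(self, edge_vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(edge_vectors, dtype=np.float64))
        if X.shape[1] != self.pos_mask.edges.size:
            raise CPMError(
                f"edge vectors have {X.shape[1]} edges; model expects "
                f"{self.pos_mask.edges.size}"
            )
        return (
            X[:, self.pos_mask.edges].sum(axis=1),
            X[:, self.neg_mask.edges].sum(axis=1),
        )

    def to_dict(self) -> dict:
        return {
            "format": "connectome-cpm network model",
            "version": 1,
            "target": self.target,
            "alpha": self.alpha,
            "n_train": self.n_train,
            "n_nodes": self.n_nodes,
            "n_edges": int(self.pos_mask.edges.size),
            "train_subject_ids": list(self.train_subject_ids),
            "pos_edges": self.pos_mask.edge_indices(),
            "neg_edges": self.neg_mask.edge_indices(),
            "coefficients": {k: list(map(float, v)) for k, v in self.coefficients.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        n_edges = d.get("n_edges") or n_edges_for(d["n_nodes"])
        pos = np.zeros(n_edges, dtype=bool)
        pos[np.asarray(d["pos_edges"], dtype=int)] = True
        neg = np.zeros(n_edges, dtype=bool)
        neg[np.asarray(d["neg_edges"], dtype=int)] = True
        return cls(
            pos_mask=NetworkMask(pos, "positive"),
            neg_mask=NetworkMask(neg, "negative"),
            coefficients={k: np.asarray(v) for k, v in d["coefficients"].items()},
            target=d.get("target", ""),
            alpha=d.get("alpha", DEFAULT_ALPHA),
            n_train=d.get("n_train", 0),
            n_nodes=d["n_nodes"],
            train_subject_ids=tuple(d.get("train_subject_ids", ())),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_score(model: NetworkModel, edge_vectors: np.ndarray, which: str) -> np.ndarray:
    """Predict scores from edge vectors with a frozen model.

    ``which`` selects the positive, negative, or combined model.  Returns a
    scalar for a single edge vector, else an array.
    """
    if which not in MODEL_NAMES:
        raise CPMError(f"unknown model {which!r}; choose from {MODEL_NAMES}")
    single = np.asarray(edge_vectors).ndim == 1
    sp, sn = model.strengths(edge_vectors)
    c = model.coefficients[which]
    if which == "positive":
        out = c[0] + c[1] * sp
    elif which == "negative":
        out = c[0] + c[1] * sn
    else:
        out = c[0] + c[1] * sp + c[2] * sn
    return float(out[0]) if single else out


def train_full_model(
    cohort: Cohort, target: str, alpha: float = DEFAULT_ALPHA
) -> NetworkModel:
    """Select edges and fit all three strength models on the full sample.

    This is the frozen artifact transferred to independent samples: no
    cross-validation is involved; selection and fitting use every subject.
    """
    y = _target_scores(cohort, target)
    pos, neg = select_edges(correlate_edges(cohort.edge_matrix, y), alpha)
    sp = cohort.edge_matrix[:, pos.edges].sum(axis=1)
    sn = cohort.edge_matrix[:, neg.edges].sum(axis=1)
    coefficients = {
        "positive": fit_strength_model(sp, y),
        "negative": fit_strength_model(sn, y),
        "combined": fit_strength_model(np.column_stack([sp, sn]), y),
    }
    try:
        n_nodes = cohort.n_nodes
    except Exception:
        n_nodes = 0  # edge count is not triangular; model keeps n_edges instead
    return NetworkModel(
        pos_mask=pos,
        neg_mask=neg,
        coefficients=coefficients,
        target=target,
        alpha=alpha,
        n_train=cohort.n_subjects,
        n_nodes=n_nodes,
        train_subject_ids=tuple(cohort.subject_ids),
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


@dataclass
class CPMResult:
    """LOOCV output: per-subject predictions, fit metrics, consensus masks."""

    observed: np.ndarray
    predictions: dict[str, np.ndarray]
    r: dict[str, float]
    rmse: dict[str, float]
    fold_masks: list[tuple[NetworkMask, NetworkMask]] = field(default_factory=list)
    consensus_pos: NetworkMask | None = None
    consensus_neg: NetworkMask | None = None
    target: str = ""
    alpha: float = DEFAULT_ALPHA
    p_perm: dict[str, float] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.observed.size


def consensus_masks(
    fold_masks: list[tuple[NetworkMask, NetworkMask]],
) -> tuple[NetworkMask, NetworkMask]:
    """Intersect per-fold masks: consensus edges appear in every fold."""
    if not fold_masks:
        raise CPMError("need at least one fold")
    pos = np.logical_and.reduce([p.edges for p, _ in fold_masks])
    neg = np.logical_and.reduce([n.edges for _, n in fold_masks])
    return NetworkMask(pos, "positive"), NetworkMask(neg, "negative")


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0.0 when either vector is constant (no signal)."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0.0:
        return 0.0
    return float((ac @ bc) / denom)


def _prefix_suffix_sums(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pre[i] = sum of rows < i; suf[i] = sum of rows > i (row i excluded)."""
    n = A.shape[0]
    pre = np.zeros((n + 1,) + A.shape[1:])
    np.cumsum(A, axis=0, out=pre[1:])
    suf = np.zeros_like(pre)
    suf[:n] = np.cumsum(A[::-1], axis=0)[::-1]
    return pre[:n], suf[1:]


class _FoldCache:
    """Score-independent leave-one-out statistics, computed once per cohort."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        self.X = X
        n = X.shape[0]
        self.n = n
        m = n - 1
        pre, suf = _prefix_suffix_sums(X)
        self.sx = pre + suf  # (n_folds, n_edges): per-fold edge sums
        pre2, suf2 = _prefix_suffix_sums(X * X)
        sxx = pre2 + suf2
        self.varx = sxx - self.sx * self.sx / m  # m * fold variance
        self.var_floor = _VAR_REL_TOL * np.max(sxx / m, initial=0.0)


def _r_crit_sq(alpha: float, df: int) -> float:
    """Squared correlation whose two-tailed p equals alpha at df dof."""
    if df < 1:
        return np.inf  # selection impossible; folds fall back to mean prediction
    t = stats.t.isf(alpha / 2.0, df)
    return t * t / (t * t + df)


def _loocv_engine(
    y: np.ndarray,
    cache: _FoldCache,
    alpha: float,
    keep_masks: bool = False,
) -> tuple[dict[str, np.ndarray], list[tuple[NetworkMask, NetworkMask]]]:
    """Run the full LOOCV (per-fold selection + fit + prediction).

    Returns per-subject predictions for the positive/negative/combined
    models and, optionally, the per-fold masks.
    """
    X = cache.X
    n, m = cache.n, cache.n - 1
    rcrit2 = _r_crit_sq(alpha, m - 2)

    # Per-fold score statistics, bitwise independent of the held-out score.
    pre_y, suf_y = _prefix_suffix_sums(y)
    sy = pre_y + suf_y
    pre_y2, suf_y2 = _prefix_suffix_sums(y * y)
    vary = (pre_y2 + suf_y2) - sy * sy / m  # (n,)

    pre_p, suf_p = _prefix_suffix_sums(X * y[:, None])
    sxy = pre_p + suf_p
    cov = sxy - cache.sx * sy[:, None] / m  # (n_folds, n_edges)

    denom = cache.varx * vary[:, None]
    usable = (cache.varx > cache.var_floor) & (denom > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(usable, cov * cov / np.where(denom > 0.0, denom, 1.0), 0.0)
    selected = usable & (r2 > rcrit2) if np.isfinite(rcrit2) else np.zeros_like(usable)
    pos_masks = selected & (cov > 0.0)
    neg_masks = selected & (cov < 0.0)

    # Strengths of every subject on every fold's masks: (n_subjects, n_folds).
    s_pos = X @ pos_masks.T.astype(np.float64)
    s_neg = X @ neg_masks.T.astype(np.float64)

    preds = {name: np.empty(n) for name in MODEL_NAMES}
    train = np.ones(n, dtype=bool)
    for i in range(n):
        train[i] = False
        y_tr = y[train]
        sp_tr, sn_tr = s_pos[train, i], s_neg[train, i]
        for name in MODEL_NAMES:
            if name == "positive":
                cols, test = sp_tr[:, None], (s_pos[i, i],)
            elif name == "negative":
                cols, test = sn_tr[:, None], (s_neg[i, i],)
            else:
                cols, test = np.column_stack([sp_tr, sn_tr]), (s_pos[i, i], s_neg[i, i])
            coef = _ols(cols, y_tr)
            preds[name][i] = coef[0] + sum(c * s for c, s in zip(coef[1:], test))
        train[i] = True

    fold_masks: list[tuple[NetworkMask, NetworkMask]] = []
    if keep_masks:
        fold_masks = [
            (NetworkMask(pos_masks[i], "positive"), NetworkMask(neg_masks[i], "negative"))
            for i in range(n)
        ]
    return preds, fold_masks


def run_loocv(
    cohort: Cohort,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    keep_masks: bool = True,
) -> CPMResult:
    """Leave-one-out CPM: one prediction per subject, consensus masks.

    For each subject, edge selection and model fitting use only the other
    n-1 subjects; folds whose mask is empty predict the training-mean score
    for that model.  Fold order is subject order; nothing is random.
    """
    y = _target_scores(cohort, target)
    n = cohort.n_subjects
    if n < 3:
        raise CPMError(f"LOOCV needs >= 3 subjects, got {n}")
    if n < 10:
        warnings.warn(f"LOOCV with only {n} subjects is fragile", stacklevel=2)
    cache = _FoldCache(cohort.edge_matrix)
    preds, fold_masks = _loocv_engine(y, cache, alpha, keep_masks=keep_masks)
    result = CPMResult(
        observed=y.copy(),
        predictions=preds,
        r={name: _safe_pearson(preds[name], y) for name in MODEL_NAMES},
        rmse={name: float(np.sqrt(np.mean((preds[name] - y) ** 2))) for name in MODEL_NAMES},
        fold_masks=fold_masks,
        target=target,
        alpha=alpha,
    )
    if keep_masks:
        result.consensus_pos, result.consensus_neg = consensus_masks(fold_masks)
    return result


def _target_scores(cohort: Cohort, target: str) -> np.ndarray:
    y = cohort.score(target)
    if np.any(np.isnan(y)):
        missing = [cohort.subject_ids[i] for i in np.flatnonzero(np.isnan(y))]
        raise CPMError(
            f"target {target!r} missing for subject(s) {missing}; "
            "pre-filter with assemble_cohort"
        )
    return np.asarray(y, dtype=np.float64)
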