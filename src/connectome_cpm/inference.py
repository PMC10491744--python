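"""Whole-model inference: permutation p-values, partial correlation, RMSE.

Leave-one-out folds are not independent, so parametric p-values on the
predicted-observed concordance overstate the degrees of freedom.  Model
significance is instead assessed by permutation: the score vector is
shuffled over subjects (covariates stay attached to their subjects), the
full LOOCV pipeline — per-fold edge selection included — is rerun on each
shuffle, and the observed concordance is ranked in the null distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np
from scipy.special import stdtr

from .cpm import (
    MODEL_NAMES,
    DEFAULT_ALPHA,
    _FoldCache,
    _loocv_engine,
    _safe_pearson,
    _target_scores,
)
from .scores import Cohort

DEFAULT_N_PERM = 5000

#: n! becomes unmanageable quickly; exhaustive mode is for tiny samples.
_MAX_EXHAUSTIVE_N = 8


class InferenceError(ValueError):
    pass


@dataclass
class PermutationResult:
    """Observed concordance, null distribution, and p_perm per model.

    ``p_perm`` uses the add-one Monte-Carlo convention (1 + c) / (B + 1)
    where c counts null draws with r >= observed (ties count); the raw
    proportion c / B is kept in ``raw_proportion``.  In exhaustive mode the
    null enumerates all n! orderings (identity included) and
    ``p_perm = c / n!``.
    """

    observed_r: dict[str, float]
    null_r: dict[str, np.ndarray]
    p_perm: dict[str, float]
    raw_proportion: dict[str, float]
    n_perm: int
    seed: int | None = None
    exhaustive: bool = False
    target: str = ""
    alpha: float = DEFAULT_ALPHA

    def summary(self) -> dict:
        out = {
            "target": self.target,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "models": {},
        }
        for name in MODEL_NAMES:
            null = self.null_r[name]
            out["models"][name] = {
                "observed_r": self.observed_r[name],
                "p_perm": self.p_perm[name],
                "raw_proportion": self.raw_proportion[name],
                "null_quantiles": {
                    q: float(np.quantile(null, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
                },
            }
        return out


def permutation_test(
    cohort: Cohort,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation significance of the LOOCV concordance, per model.

    Each permutation reassigns the score vector over subjects and reruns
    the complete LOOCV (selection + fitting in every fold) through the
    identical code path used for the observed data, so the identity
    permutation reproduces the observed concordance exactly.
    """
    y = _target_scores(cohort, target)
    n = cohort.n_subjects
    cache = _FoldCache(cohort.edge_matrix)

    def concordance(y_perm: np.ndarray) -> dict[str, float]:
        preds, _ = _loocv_engine(y_perm, cache, alpha, keep_masks=False)
        return {name: _safe_pearson(preds[name], y_perm) for name in MODEL_NAMES}

    observed = concordance(y)

    if exhaustive:
        if n > _MAX_EXHAUSTIVE_N:
            raise InferenceError(
                f"exhaustive enumeration of {n}! orderings is infeasible (n <= "
                f"{_MAX_EXHAUSTIVE_N})"
            )
        orderings = [np.asarray(p, dtype=int) for p in _all_permutations(range(n))]
        n_perm = len(orderings)  # n!
        null = {name: np.empty(n_perm) for name in MODEL_NAMES}
        for b, perm in enumerate(orderings):
            rb = concordance(y[perm])
            for name in MODEL_NAMES:
                null[name][b] = rb[name]
        p_perm = {
            name: float(np.sum(null[name] >= observed[name])) / n_perm
            for name in MODEL_NAMES
        }
        raw = dict(p_perm)
    else:
        if n_perm < 1:
            raise InferenceError(f"n_perm must be >= 1, got {n_perm}")
        rng = np.random.default_rng(seed)
        null = {name: np.empty(n_perm) for name in MODEL_NAMES}
        for b in range(n_perm):
            rb = concordance(rng.permutation(y))
            for name in MODEL_NAMES:
                null[name][b] = rb[name]
        counts = {
            name: int(np.sum(null[name] >= observed[name])) for name in MODEL_NAMES
        }
        p_perm = {name: (1.0 + counts[name]) / (n_perm + 1.0) for name in MODEL_NAMES}
        raw = {name: counts[name] / n_perm for name in MODEL_NAMES}

    return PermutationResult(
        observed_r=observed,
        null_r=null,
        p_perm=p_perm,
        raw_proportion=raw,
        n_perm=n_perm,
        seed=seed,
        exhaustive=exhaustive,
        target=target,
        alpha=alpha,
    )


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates.

    Both vectors are residualized on the covariates (plus intercept) by
    least squares; the correlation of the residuals is returned with a
    two-tailed p at ``n - 2 - n_covariates`` degrees of freedom.  With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if y.size != n:
        raise InferenceError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        k = 0
        rx, ry = x, y
    else:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise InferenceError("covariates not aligned with x/y")
        k = C.shape[1]
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < k + 1:
            raise InferenceError("rank-deficient covariate matrix")
        bx, *_ = np.linalg.lstsq(design, x, rcond=None)
        by, *_ = np.linalg.lstsq(design, y, rcond=None)
        rx = x - design @ bx
        ry = y - design @ by
    df = n - 2 - k
    if df < 1:
        raise InferenceError(f"need n > n_covariates + 2, got n={n}, k={k}")
    r = _safe_pearson(rx, ry)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stdtr(df, -abs(t)))
    return r, p


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root-mean-square prediction error."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.size == 0:
        raise InferenceError("rmse of empty vectors is undefined")
    if predicted.shape != observed.shape:
        raise InferenceError("predicted and observed must have equal length")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def confound_check(cohort: Cohort, targets: tuple[str, ...] = ("hdrs5", "ymrs")) -> dict:
    """Correlate mean framewise displacement with each target, and the
    targets with each other; a motion confound would show up here.

    Returns a report dict; missing ``mean_fd`` downgrades the motion part
    to a warning and the check is skipped.
    """
    report: dict = {"fd_vs_target": {}, "between_targets": {}}
    targets = tuple(t for t in targets if t in cohort.scores)
    fd = None
    if "mean_fd" in getattr(cohort.covariates, "columns", ()):
        fd = cohort.covariates["mean_fd"].to_numpy(dtype=np.float64)
    if fd is None or np.all(np.isnan(fd)):
        warnings.warn("mean_fd not available; motion confound check skipped", stacklevel=2)
    else:
        for t in targets:
            y = cohort.score(t)
            ok = ~np.isnan(y) & ~np.isnan(fd)
            r, p = partial_pearson(fd[ok], y[ok])
            report["fd_vs_target"][t] = {"r": r, "p": p, "n": int(ok.sum())}
    for i, a in enumerate(targets):
        for b in targets[i + 1:]:
            ya, yb = cohort.score(a), cohort.score(b)
            ok = ~np.isnan(ya) & ~np.isnan(yb)
            r, p = partial_pearson(ya[ok], yb[ok])
            report["between_targets"][f"{a}~{b}"] = {"r": r, "p": p, "n": int(ok.sum())}
    return report
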