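"""Out-of-sample validation of a frozen network model.

The trained model's edge masks and linear coefficients are applied, without
any re-selection or re-fitting, to an independent cohort: strengths come
from the frozen masks, predictions from the frozen coefficients, and the
predicted-observed concordance is reported both plain and adjusted for age
and gender.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cpm import MODEL_NAMES, NetworkModel, predict_score
from .inference import partial_pearson, rmse
from .scores import Cohort


class ValidationError(ValueError):
    pass


@dataclass
class ValidationReport:
    """Transfer evaluation: n used, concordance (plain & adjusted), RMSE."""

    target: str
    n_subjects: int
    n_excluded_missing: int
    predictions: dict[str, np.ndarray]
    observed: np.ndarray
    r: dict[str, float]
    p: dict[str, float]
    r_adjusted: dict[str, float] = field(default_factory=dict)
    p_adjusted: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    model_provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "n_subjects": self.n_subjects,
            "n_excluded_missing": self.n_excluded_missing,
            "r": self.r,
            "p": self.p,
            "r_adjusted": self.r_adjusted,
            "p_adjusted": self.p_adjusted,
            "rmse": self.rmse,
            "model_provenance": self.model_provenance,
        }


def apply_trained_model(
    model: NetworkModel, cohort: Cohort, enforce_disjoint: bool = True
) -> dict[str, np.ndarray]:
    """Predict scores for a cohort from a frozen model.

    No re-selection and no re-fitting happen here; the masks and
    coefficients are used exactly as serialized.  By default the cohort
    must share no subject id with the training sample; pass
    ``enforce_disjoint=False`` for deliberate in-sample (closure) checks.
    """
    if cohort.edge_matrix.shape[1] != model.pos_mask.edges.size:
        raise ValidationError(
            f"cohort has {cohort.edge_matrix.shape[1]} edges; model expects "
            f"{model.pos_mask.edges.size}"
        )
    overlap = set(cohort.subject_ids) & set(model.train_subject_ids)
    if overlap and enforce_disjoint:
        raise ValidationError(
            f"validation cohort shares {len(overlap)} subject id(s) with the "
            f"training sample: {sorted(overlap)[:5]}"
        )
    return {
        name: np.asarray(predict_score(model, cohort.edge_matrix, name))
        for name in MODEL_NAMES
    }


def evaluate_transfer(
    predictions: dict[str, np.ndarray],
    observed: np.ndarray,
    covariates: np.ndarray | None = None,
    target: str = "",
    model: NetworkModel | None = None,
) -> ValidationReport:
    """Concordance of frozen-model predictions with observed scores.

    Subjects with a missing (NaN) observed score are excluded and counted.
    Reports plain Pearson r/p and, when covariates (age, gender) are given,
    the partial correlation controlling for them, plus RMSE per model.
    """
    observed = np.asarray(observed, dtype=np.float64)
    ok = ~np.isnan(observed)
    n_excluded = int((~ok).sum())
    y = observed[ok]
    if y.size < 4:
        raise ValidationError(f"too few subjects with observed scores ({y.size})")
    if np.ptp(y) == 0.0:
        raise ValidationError("observed scores are constant; concordance undefined")
    C = None
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        C = C[ok]
    r, p, r_adj, p_adj, err = {}, {}, {}, {}, {}
    preds_used = {}
    for name in MODEL_NAMES:
        pred = np.asarray(predictions[name], dtype=np.float64)[ok]
        preds_used[name] = pred
        if np.ptp(pred) == 0.0:
            r[name], p[name] = 0.0, 1.0
        else:
            r[name], p[name] = partial_pearson(pred, y)
        if C is not None and np.ptp(pred) != 0.0:
            r_adj[name], p_adj[name] = partial_pearson(pred, y, C)
        err[name] = rmse(pred, y)
    provenance = {}
    if model is not None:
        provenance = {
            "target": model.target,
            "alpha": model.alpha,
            "n_train": model.n_train,
            "n_nodes": model.n_nodes,
            "pos_edges": model.pos_mask.n_selected,
            "neg_edges": model.neg_mask.n_selected,
        }
    return ValidationReport(
        target=target,
        n_subjects=int(ok.sum()),
        n_excluded_missing=n_excluded,
        predictions=preds_used,
        observed=y,
        r=r,
        p=p,
        r_adjusted=r_adj,
        p_adjusted=p_adj,
        rmse=err,
        model_provenance=provenance,
    )


def validate_model(
    model: NetworkModel,
    cohort: Cohort,
    target: str,
    covariate_names: tuple[str, ...] = ("age", "gender"),
) -> ValidationReport:
    """Full transfer pipeline: apply frozen model, then evaluate."""
    predictions = apply_trained_model(model, cohort)
    observed = cohort.score(target)
    cols = [c for c in covariate_names if c in getattr(cohort.covariates, "columns", ())]
    C = cohort.covariates[cols].to_numpy(dtype=np.float64) if cols else None
    return evaluate_transfer(predictions, observed, C, target=target, model=model)
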