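"""Clinical predictor variables and cohort assembly.

Two mood-severity targets drive the predictive models: a five-item depressed
mood score (HDRS-5, the sum of the five Hamilton Depression Rating Scale
items loading highest on depression) and the Young Mania Rating Scale total
(sum of its eleven items).  The full 29-item HDRS total is retained for
exploratory use.  Scores, covariates (age, gender, mean framewise
displacement) and edge vectors are aligned into a :class:`Cohort`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, n_nodes_for, vectorize

logger = logging.getLogger(__name__)

#: The five HDRS items whose sum is the depressed-mood (HDRS-5) score.
HDRS5_ITEMS = (
    "depressed_mood",
    "work_and_interests",
    "guilt",
    "psychomotor_retardation",
    "suicide",
)

N_YMRS_ITEMS = 11

#: Canonical target names accepted by the pipeline.
TARGETS = ("hdrs5", "hdrs29", "ymrs")


class ScoreError(ValueError):
    pass


def hdrs5_score(items) -> int:
    """Sum the five named HDRS items into the depressed-mood score.

    ``items`` maps item names to non-negative integer ratings and must
    contain every name in :data:`HDRS5_ITEMS` (extra items are ignored).
    """
    total = 0
    for name in HDRS5_ITEMS:
        if name not in items:
            raise ScoreError(f"HDRS-5 item missing: {name!r}")
        v = items[name]
        if int(v) != v or v < 0:
            raise ScoreError(f"HDRS item {name!r} must be a non-negative integer, got {v!r}")
        total += int(v)
    return total


def ymrs_total(items) -> int:
    """Sum the eleven YMRS items into the elevated-mood total score."""
    items = list(items)
    if len(items) != N_YMRS_ITEMS:
        raise ScoreError(f"YMRS has {N_YMRS_ITEMS} items, got {len(items)}")
    for v in items:
        if int(v) != v or v < 0:
            raise ScoreError(f"YMRS items must be non-negative integers, got {v!r}")
    return int(sum(int(v) for v in items))


@dataclass
class Cohort:
    """Aligned subject ids, edge vectors, clinical scores and covariates.

    ``scores`` maps a target name to a float vector (NaN marks a missing
    score); ``covariates`` holds ``age``, ``gender`` (female=1 indicator)
    and optionally ``mean_fd``, row-aligned with ``subject_ids``.
    """

    subject_ids: list[str]
    edge_matrix: np.ndarray
    scores: dict[str, np.ndarray]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ScoreError("duplicate subject ids in cohort")
        self.edge_matrix = np.asarray(self.edge_matrix, dtype=np.float64)
        if self.edge_matrix.shape[0] != n:
            raise ScoreError("edge matrix row count does not match subject ids")
        for name, v in self.scores.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (n,):
                raise ScoreError(f"score {name!r} not aligned with subjects")
            self.scores[name] = v
        if len(self.covariates) not in (0, n):
            raise ScoreError("covariates not aligned with subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return n_nodes_for(self.edge_matrix.shape[1])

    def score(self, target: str) -> np.ndarray:
        if target not in self.scores:
            raise ScoreError(f"unknown target {target!r}; have {sorted(self.scores)}")
        return self.scores[target]


_GENDER_CODES = {"female": 1, "f": 1, "male": 0, "m": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype table.

    Expected columns: ``subject_id age gender mean_fd hdrs5 hdrs29_total
    ymrs_total`` (any score column optional), plus optional item columns
    ``hdrs_<name>`` and ``ymrs_<k>`` from which missing totals are derived.
    Gender is re-coded to a female=1 indicator.
    """
    t = pd.read_csv(path, sep="\t")
    if "subject_id" not in t.columns:
        raise ScoreError("phenotype table needs a subject_id column")
    t["subject_id"] = t["subject_id"].astype(str)
    if "gender" in t.columns:
        t["gender"] = [
            _GENDER_CODES[g.lower() if isinstance(g, str) else g] for g in t["gender"]
        ]
    item_cols = [f"hdrs_{n}" for n in HDRS5_ITEMS]
    if "hdrs5" not in t.columns and all(c in t.columns for c in item_cols):
        t["hdrs5"] = [
            hdrs5_score({n: row[f"hdrs_{n}"] for n in HDRS5_ITEMS})
            for _, row in t.iterrows()
        ]
    ymrs_cols = [f"ymrs_{k}" for k in range(1, N_YMRS_ITEMS + 1)]
    if "ymrs_total" not in t.columns and all(c in t.columns for c in ymrs_cols):
        t["ymrs_total"] = [ymrs_total(row[ymrs_cols]) for _, row in t.iterrows()]
    return t


_SCORE_COLUMNS = {"hdrs5": "hdrs5", "hdrs29": "hdrs29_total", "ymrs": "ymrs_total"}
_COVARIATE_COLUMNS = ("age", "gender", "mean_fd")


def assemble_cohort(matrices, phenotypes: pd.DataFrame, target: str) -> Cohort:
    """Align matrices with phenotypes and drop subjects missing ``target``.

    ``matrices`` is either a mapping subject_id -> edge vector, or a list of
    :class:`~connectome_cpm.connectome.ConnectivityMatrix`.  Subjects with a
    matrix but no phenotype row are dropped with a warning; subjects missing
    the requested target score are excluded from that target's analysis and
    the exclusion is logged.  Output subject order is sorted.
    """
    if target not in _SCORE_COLUMNS:
        raise ScoreError(f"unknown target {target!r}; choose from {TARGETS}")
    if isinstance(matrices, dict):
        vectors = {str(k): np.asarray(v, dtype=np.float64) for k, v in matrices.items()}
    else:
        vectors = {m.subject_id: vectorize(m) for m in matrices}
    pheno = phenotypes.set_index(phenotypes["subject_id"].astype(str))
    extra = set(pheno.index) - set(vectors)
    if extra:
        raise ScoreError(f"phenotype rows without matrices: {sorted(extra)}")
    orphans = sorted(set(vectors) - set(pheno.index))
    if orphans:
        warnings.warn(
            f"dropping {len(orphans)} subject(s) without phenotype rows: {orphans}",
            stacklevel=2,
        )
    col = _SCORE_COLUMNS[target]
    if col not in pheno.columns:
        raise ScoreError(f"phenotype table lacks the {col!r} column for target {target!r}")
    kept, excluded = [], []
    for sid in sorted(set(vectors) & set(pheno.index)):
        if pd.isna(pheno.at[sid, col]):
            excluded.append(sid)
        else:
            kept.append(sid)
    if excluded:
        logger.info(
            "target %s: excluding %d subject(s) with missing scores: %s",
            target, len(excluded), excluded,
        )
    if not kept:
        raise ScoreError(f"no subjects remain with a {target!r} score")
    edge_matrix = np.vstack([vectors[s] for s in kept])
    scores = {}
    for name, c in _SCORE_COLUMNS.items():
        if c in pheno.columns:
            scores[name] = pheno.loc[kept, c].to_numpy(dtype=np.float64)
    cov_cols = [c for c in _COVARIATE_COLUMNS if c in pheno.columns]
    covariates = pheno.loc[kept, cov_cols].reset_index(drop=True)
    if "gender" in covariates.columns and covariates["gender"].dtype == object:
        covariates["gender"] = [
            _GENDER_CODES[g.lower() if isinstance(g, str) else g]
            for g in covariates["gender"]
        ]
    covariates = covariates.astype(np.float64)
    logger.info("assembled cohort for %s: %d subjects, order %s", target, len(kept), kept)
    return Cohort(kept, edge_matrix, scores, covariates)
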