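"""Cohort-directory I/O shared by the CLI and the acceptance tooling.

A cohort directory holds two tab-separated files: ``edges.tsv`` (one row
per subject, columns ``subject_id`` then the canonical ``i_j`` edge names,
1-based) and ``phenotypes.tsv`` (the phenotype table read by
:func:`connectome_cpm.scores.read_phenotypes`).
"""

from __future__ import annotations

import os

import pandas as pd

from .connectome import read_edge_table, write_edge_table
from .scores import Cohort, assemble_cohort, read_phenotypes

EDGES_FILE = "edges.tsv"
PHENOTYPES_FILE = "phenotypes.tsv"


def write_cohort_dir(cohort: Cohort, out_dir) -> None:
    """Write a cohort as ``edges.tsv`` + ``phenotypes.tsv``."""
    os.makedirs(out_dir, exist_ok=True)
    write_edge_table(
        cohort.subject_ids, cohort.edge_matrix, os.path.join(out_dir, EDGES_FILE)
    )
    pheno = pd.DataFrame({"subject_id": cohort.subject_ids})
    for col in getattr(cohort.covariates, "columns", ()):
        pheno[col] = cohort.covariates[col].to_numpy()
    rename = {"hdrs5": "hdrs5", "hdrs29": "hdrs29_total", "ymrs": "ymrs_total"}
    for name, values in cohort.scores.items():
        pheno[rename.get(name, name)] = values
    pheno.to_csv(os.path.join(out_dir, PHENOTYPES_FILE), sep="\t", index=False)


def read_cohort_dir(cohort_dir, target: str) -> Cohort:
    """Read a cohort directory and assemble it for ``target``."""
    ids, X, _ = read_edge_table(os.path.join(cohort_dir, EDGES_FILE))
    pheno = read_phenotypes(os.path.join(cohort_dir, PHENOTYPES_FILE))
    vectors = {sid: X[k] for k, sid in enumerate(ids)}
    return assemble_cohort(vectors, pheno, target)
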