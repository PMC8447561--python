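"""End-to-end stages: derivation, replication, prediction.

Each stage is a plain function taking a :class:`~lipophen.cohort.CohortTable`
and returning a result object whose pieces the CLI (and tests) serialize.
The derivation protocol is: median imputation → z-normalization (no capping
by default; the ±3 SD clamp belongs to the replication projection) →
Spearman/Ward clustering → k=2 cut → HDL-C-anchored labelling → per-feature
t-test signature with embedded transfer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .cluster import (
    HYPO, ClusterQuality, LinkageTree, SpearmanWardClusterer,
)
from .preprocess import MedianImputer, apply_scaler, fit_scaler
from .schema import (
    ANCHOR_FEATURE, CLUSTERING_FEATURES, LASSO_CANDIDATES, SIGNATURE_FEATURES,
)
from .signature import (
    ClusterSignature, ConcordanceReport, ProjectionResult, SignatureProjector,
    concordance, derive_signature,
)
from .stats import (
    LassoFit, OutcomeTable, RocResult, cluster_outcome_table,
    compare_signature_auc, lasso_select,
)

__all__ = ["DerivationResult", "ReplicationResult", "PredictionResult",
           "run_derivation", "run_replication", "run_prediction",
           "ordered_matrix"]


@dataclass
class DerivationResult:
    cohort_id: str
    z_matrix: pd.DataFrame
    linkage: LinkageTree
    phenotype: pd.Series                 # semantic label per patient
    quality: ClusterQuality
    signature: ClusterSignature
    outcome_table: OutcomeTable
    imputed_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReplicationResult:
    cohort_id: str
    projection: ProjectionResult
    phenotype: pd.Series
    concordance: ConcordanceReport
    outcome_table: OutcomeTable


@dataclass
class PredictionResult:
    lasso: LassoFit
    rocs: list[RocResult]


def run_derivation(cohort: CohortTable,
                   clustering_features: Sequence[str] = CLUSTERING_FEATURES,
                   signature_features: Sequence[str] = SIGNATURE_FEATURES,
                   anchor_feature: str = ANCHOR_FEATURE,
                   test_variant: str = "welch",
                   cap_derivation: bool = False,
                   cap: float = 3.0) -> DerivationResult:
    """Cluster the derivation cohort and extract its signature."""
    cohort.adjudicate()
    table = cohort.to_frame()
    feats = list(clustering_features)
    imp = MedianImputer(features=feats).fit(table)
    filled = imp.transform(table)
    scaler = fit_scaler(filled, feats, cap=cap, cohort_id=cohort.cohort_id)
    z = apply_scaler(filled, scaler, do_cap=cap_derivation)
    clusterer = SpearmanWardClusterer(
        n_clusters=2, anchor_feature=anchor_feature).fit(z)
    phenotype = clusterer.assignment_.semantic().reindex(table.index.astype(str))
    signature = derive_signature(
        filled, clusterer.assignment_, signature_features,
        test_variant=test_variant, cohort_id=cohort.cohort_id, cap=cap,
        anchor_feature=anchor_feature)
    outcomes = cohort.outcome_frame()
    outcome_table = cluster_outcome_table(
        phenotype, outcomes["outcome"], outcomes["mortality_28d"])
    return DerivationResult(
        cohort_id=cohort.cohort_id, z_matrix=z, linkage=clusterer.linkage_,
        phenotype=phenotype, quality=clusterer.quality_, signature=signature,
        outcome_table=outcome_table,
        imputed_counts=imp.report_.per_feature,
    )


def run_replication(cohort: CohortTable, signature: ClusterSignature,
                    impute_source: str = "derivation",
                    do_cap: bool = True) -> ReplicationResult:
    """Project an independent cohort through a derivation signature."""
    cohort.adjudicate()
    table = cohort.to_frame()
    projector = SignatureProjector(
        signature, impute_source=impute_source, do_cap=do_cap)
    projection = projector.project(table)
    phenotype = projection.assignment.semantic()
    report = concordance(signature, table, projection)
    outcomes = cohort.outcome_frame()
    outcome_table = cluster_outcome_table(
        phenotype, outcomes["outcome"].reindex(phenotype.index),
        outcomes["mortality_28d"].reindex(phenotype.index))
    return ReplicationResult(
        cohort_id=cohort.cohort_id, projection=projection, phenotype=phenotype,
        concordance=report, outcome_table=outcome_table)


def run_prediction(cohort: CohortTable,
                   phenotype: Optional[pd.Series] = None,
                   candidates: Sequence[str] = LASSO_CANDIDATES,
                   cv_folds: int = 10, seed: int = 0) -> PredictionResult:
    """LASSO-selected logistic model of CCI-or-early-death plus the ROC
    comparison of cluster membership vs SOFA vs APACHE II."""
    cohort.adjudicate()
    table = cohort.to_frame()
    outcomes = cohort.outcome_frame()
    y = (outcomes["outcome"] != "rapid_recovery").astype(int)
    fit = lasso_select(table, candidates, y, cv_folds=cv_folds, seed=seed)
    if phenotype is None:
        result = run_derivation(cohort)
        phenotype = result.phenotype
    membership = (phenotype == HYPO).astype(int)
    rocs = compare_signature_auc(
        membership, table["sofa_total"], table["apache2"],
        y.reindex(membership.index))
    return PredictionResult(lasso=fit, rocs=rocs)


def ordered_matrix(z_matrix: pd.DataFrame, linkage: LinkageTree,
                   schema) -> pd.DataFrame:
    """Features (rows, sorted by category then name) × patients (columns, in
    dendrogram leaf order) — the heatmap-ready export."""
    order = [linkage.ids[i] for i in linkage.leaf_order()]
    cats = {s.name: s.category for s in schema}
    feats = sorted(z_matrix.columns, key=lambda f: (cats.get(f, "zz"), f))
    return z_matrix.loc[order, feats].T
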