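"""Cluster signature derivation and cross-cohort replication.

The signature is the portable artifact of a derivation run: for each feature,
the per-cluster means and a two-sided t-test of their difference (Welch by
default), tiered at p < 0.05 (*) and p < 0.0001 (**), together with the
scaler parameters (means, scaling factors, medians, cap) needed to project a
new cohort into the derivation z-space.  Replication re-uses the fixed
feature list: eligibility filter (> 20% of signature features missing
excludes a patient) → median imputation → z-normalization with the stored
derivation parameters, outliers capped at ±3 SD → Spearman/Ward clustering →
k=2 cut → anchored Hypo/Normo labelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import (
    HYPO, NORMO, ClusterAssignment, SpearmanWardClusterer, calinski_harabasz,
)
from .preprocess import (
    MedianImputer, ScalerParams, apply_scaler, eligibility_filter, fit_scaler,
)

__all__ = [
    "FeatureTest", "ClusterSignature", "ProjectionResult", "ConcordanceReport",
    "derive_signature", "rank_features", "project_replication", "concordance",
    "SignatureProjector",
]

TIER_NONE = "not_significant"
TIER_05 = "p<0.05"
TIER_0001 = "p<0.0001"


class SignatureError(ValueError):
    pass


@dataclass
class FeatureTest:
    """One feature's between-cluster test: means, t, p, tier, direction.

    ``direction`` is the sign of (normo mean − hypo mean): +1 when the
    feature is higher in the Normolipoprotein cluster.
    """

    feature: str
    mean_hypo: float
    mean_normo: float
    t_statistic: float
    p_value: float
    tier: str
    direction: int

    @staticmethod
    def tier_for(p: float) -> str:
        if p < 1e-4:
            return TIER_0001
        if p < 0.05:
            return TIER_05
        return TIER_NONE


@dataclass
class ClusterSignature:
    """Per-feature test results plus the transfer (scaler) parameters."""

    features: list[str]
    tests: dict[str, FeatureTest]
    scaler: ScalerParams
    cohort_id: str = ""
    anchor_feature: str = "hdl_c"
    test_variant: str = "welch"

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise SignatureError("signature needs >= 2 features")

    def selected(self) -> list[str]:
        """Features significant at the p < 0.05 tier or better."""
        return [f for f in self.features if self.tests[f].tier != TIER_NONE]

    def directions(self) -> dict[str, int]:
        return {f: self.tests[f].direction for f in self.features}

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "version": 1,
            "features": self.features,
            "tests": {f: asdict(t) for f, t in self.tests.items()},
            "scaler": asdict(self.scaler),
            "cohort_id": self.cohort_id,
            "anchor_feature": self.anchor_feature,
            "test_variant": self.test_variant,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "ClusterSignature":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        return cls(
            features=obj["features"],
            tests={f: FeatureTest(**t) for f, t in obj["tests"].items()},
            scaler=ScalerParams(**obj["scaler"]),
            cohort_id=obj.get("cohort_id", ""),
            anchor_feature=obj.get("anchor_feature", "hdl_c"),
            test_variant=obj.get("test_variant", "welch"),
        )


@dataclass
class ProjectionResult:
    """Outcome of projecting a cohort through a signature."""

    assignment: ClusterAssignment
    excluded: dict[str, str]                # patient id -> reason
    imputed_counts: dict[str, int]
    ch_score: float
    z_matrix: pd.DataFrame


@dataclass
class ConcordanceReport:
    """Cross-cohort agreement of per-feature directions and significance."""

    rows: pd.DataFrame                      # one row per feature
    bonferroni_threshold: float
    fraction_concordant: float

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------

def _two_cluster_groups(table: pd.DataFrame, assignment: ClusterAssignment):
    sem = assignment.semantic()
    hypo_ids = sem.index[sem == HYPO]
    normo_ids = sem.index[sem == NORMO]
    if len(hypo_ids) < 2 or len(normo_ids) < 2:
        raise SignatureError("each cluster needs >= 2 patients for t-tests")
    return table.loc[table.index.intersection(hypo_ids)], \
        table.loc[table.index.intersection(normo_ids)]


def derive_signature(table: pd.DataFrame, assignment: ClusterAssignment,
                     feature_list: Sequence[str], test_variant: str = "welch",
                     cohort_id: str = "", cap: float = 3.0,
                     anchor_feature: str = "hdl_c") -> ClusterSignature:
    """Per-feature two-sided t-tests between the k=2 clusters.

    All tested features are retained with tiers (the replication protocol
    re-uses the fixed list); the *selected* subset is tier >= p<0.05.  The
    scaler parameters fitted on the derivation table are embedded for
    transfer.
    """
    if test_variant not in ("welch", "student"):
        raise SignatureError(f"unknown test variant {test_variant!r}")
    feature_list = list(feature_list)
    sub = table[feature_list]
    if sub.isna().any().any():
        raise SignatureError("impute features before deriving the signature")
    hypo, normo = _two_cluster_groups(sub, assignment)
    tests = {}
    for f in feature_list:
        a, b = hypo[f].to_numpy(), normo[f].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=(test_variant == "student"))
            t, p = float(t), float(p)
        delta = float(b.mean() - a.mean())
        tests[f] = FeatureTest(
            feature=f, mean_hypo=float(a.mean()), mean_normo=float(b.mean()),
            t_statistic=t, p_value=p, tier=FeatureTest.tier_for(p),
            direction=int(np.sign(delta)),
        )
    scaler = fit_scaler(table, feature_list, cap=cap, cohort_id=cohort_id)
    return ClusterSignature(
        features=feature_list, tests=tests, scaler=scaler,
        cohort_id=cohort_id, anchor_feature=anchor_feature,
        test_variant=test_variant,
    )


def rank_features(signature: ClusterSignature) -> list[str]:
    """Features ordered by |t| descending (ties alphabetically)."""
    return sorted(signature.features,
                  key=lambda f: (-abs(signature.tests[f].t_statistic), f))


class SignatureProjector:
    """Applies a derivation signature's replication protocol to a cohort.

    Transfer-mode knobs: ``impute_source`` chooses whether missing cells are
    filled with the stored derivation medians (pure transfer, the default) or
    the projected cohort's own medians; ``do_cap`` applies the ±cap clamp.
    """

    def __init__(self, signature: ClusterSignature,
                 impute_source: str = "derivation", do_cap: bool = True,
                 max_missing_fraction: float = 0.20):
        if impute_source not in ("derivation", "replication"):
            raise SignatureError(f"unknown impute_source {impute_source!r}")
        self.signature = signature
        self.impute_source = impute_source
        self.do_cap = do_cap
        self.max_missing_fraction = max_missing_fraction

    def project(self, table: pd.DataFrame) -> ProjectionResult:
        sig = self.signature
        absent = [f for f in sig.features if f not in table.columns]
        if absent:
            raise SignatureError(f"signature features absent from cohort: {absent}")
        kept, dropped = eligibility_filter(
            table, sig.features, self.max_missing_fraction)
        allowed = int(np.floor(self.max_missing_fraction * len(sig.features)))
        excluded = {
            str(pid): f"missing>{int(self.max_missing_fraction * 100)}%"
            for pid in dropped.index
        }
        if len(kept) < 4:
            raise SignatureError(
                f"only {len(kept)} eligible patients (> {allowed} of "
                f"{len(sig.features)} features missing excludes a patient)"
            )
        medians = sig.scaler.median if self.impute_source == "derivation" else None
        imp = MedianImputer(features=sig.features, medians=medians).fit(kept)
        filled = imp.transform(kept)
        z = apply_scaler(filled, sig.scaler, do_cap=self.do_cap)
        clusterer = SpearmanWardClusterer(
            n_clusters=2, anchor_feature=sig.anchor_feature).fit(z)
        assignment = clusterer.assignment_
        ch = calinski_harabasz(
            z.iloc[np.argsort(z.index.astype(str), kind="stable")], assignment)
        return ProjectionResult(
            assignment=assignment,
            excluded=excluded,
            imputed_counts=imp.report_.per_feature,
            ch_score=float(ch),
            z_matrix=z,
        )


def project_replication(replication_table: pd.DataFrame,
                        signature: ClusterSignature,
                        impute_source: str = "derivation",
                        do_cap: bool = True) -> ProjectionResult:
    """Functional wrapper over :class:`SignatureProjector`."""
    return SignatureProjector(signature, impute_source=impute_source,
                              do_cap=do_cap).project(replication_table)


def concordance(signature: ClusterSignature, replication_table: pd.DataFrame,
                projection: ProjectionResult,
                test_variant: Optional[str] = None) -> ConcordanceReport:
    """Re-test each signature feature between the replication clusters and
    compare directions with derivation; significance at 0.05/|F| (Bonferroni).
    """
    variant = test_variant or signature.test_variant
    feats = signature.features
    medians = signature.scaler.median
    sem = projection.assignment.semantic()
    sub = replication_table.loc[sem.index, feats]
    filled = MedianImputer(features=feats, medians=medians).fit(sub).transform(sub)
    hypo = filled.loc[sem[sem == HYPO].index]
    normo = filled.loc[sem[sem == NORMO].index]
    if len(hypo) < 2 or len(normo) < 2:
        raise SignatureError("replication cluster of size < 2")
    m = len(feats)
    threshold = 0.05 / m
    rows = []
    agree = 0
    for f in feats:
        a, b = hypo[f].to_numpy(), normo[f].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
            t, p = float(t), float(p)
        rep_dir = int(np.sign(b.mean() - a.mean()))
        der_dir = signature.tests[f].direction
        flag = rep_dir == der_dir and rep_dir != 0
        agree += flag
        rows.append({
            "feature": f, "derivation_direction": der_dir,
            "replication_direction": rep_dir, "agreement": bool(flag),
            "replication_t": t, "replication_p": p,
            "bonferroni_threshold": threshold,
            "significant": bool(p < threshold),
        })
    return ConcordanceReport(
        rows=pd.DataFrame(rows),
        bonferroni_threshold=threshold,
        fraction_concordant=agree / m,
    )
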