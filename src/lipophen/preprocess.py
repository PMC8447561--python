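"""Imputation, z-normalization and outlier capping with transferable parameters.

The derivation protocol fits medians/means/SDs on the derivation cohort; the
replication protocol re-applies those *stored* parameters to a new cohort
(median imputation, z-normalization with the derivation means and scaling
factors, capping at ±3 SD).  Both stages are exposed as sklearn-style
transformers plus thin functional wrappers, and the fitted parameters
round-trip through JSON so a derivation run can be shipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScalerParams", "ImputationReport", "MedianImputer", "CappedStandardScaler",
    "impute_median", "eligibility_filter", "fit_scaler", "apply_scaler",
]


class PreprocessError(ValueError):
    pass


@dataclass
class ScalerParams:
    """Per-feature mean/SD/median fitted on one cohort, plus the cap (in SD
    units) used when projecting another cohort through them."""

    features: list[str]
    mean: dict[str, float]
    sd: dict[str, float]
    median: dict[str, float]
    cap: float = 3.0
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise PreprocessError("feature list is empty")
        if len(set(self.features)) != len(self.features):
            raise PreprocessError("duplicate features in ScalerParams")
        if self.cap <= 0:
            raise PreprocessError("cap must be > 0")
        for f in self.features:
            if self.sd[f] < 0:
                raise PreprocessError(f"negative SD for {f!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps({"version": 1, **asdict(self)}, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "ScalerParams":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        obj.pop("version", None)
        return cls(**obj)


@dataclass
class ImputationReport:
    """Bookkeeping of which cells were filled in."""

    per_feature: dict[str, int] = field(default_factory=dict)
    per_patient: dict[str, int] = field(default_factory=dict)
    mask: Optional[pd.DataFrame] = None     # True where a cell was imputed

    @property
    def total(self) -> int:
        return int(sum(self.per_feature.values()))


class MedianImputer(TransformerMixin, BaseEstimator):
    """Fill missing cells with per-feature medians.

    In fit mode the medians come from the fitted table; supplying ``medians``
    switches to transfer mode (e.g. derivation medians applied to a
    replication cohort).
    """

    def __init__(self, features: Optional[Sequence[str]] = None,
                 medians: Optional[dict[str, float]] = None):
        self.features = features
        self.medians = medians

    def fit(self, X: pd.DataFrame, y=None) -> "MedianImputer":
        feats = list(self.features) if self.features is not None else list(X.columns)
        missing_cols = [f for f in feats if f not in X.columns]
        if missing_cols:
            raise PreprocessError(f"features absent from table: {missing_cols}")
        if self.medians is not None:
            uncovered = [f for f in feats if f not in self.medians]
            if uncovered:
                raise PreprocessError(f"supplied medians do not cover: {uncovered}")
            self.medians_ = {f: float(self.medians[f]) for f in feats}
        else:
            med = X[feats].median()
            dead = [f for f in feats if not np.isfinite(med[f])]
            if dead:
                raise PreprocessError(
                    f"all values missing and no supplied median for: {dead}"
                )
            self.medians_ = {f: float(med[f]) for f in feats}
        self.feature_names_in_ = np.asarray(feats, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = list(self.feature_names_in_)
        out = X.copy()
        mask = out[feats].isna()
        for f in feats:
            out[f] = out[f].fillna(self.medians_[f])
        self.report_ = ImputationReport(
            per_feature={f: int(mask[f].sum()) for f in feats},
            per_patient={str(i): int(r) for i, r in mask.sum(axis=1).items()},
            mask=mask,
        )
        return out


class CappedStandardScaler(TransformerMixin, BaseEstimator):
    """z-normalization with stored means/scaling factors and optional ±cap.

    SD uses the n−1 denominator.  A constant feature (SD 0) maps to z = 0
    with a warning rather than NaN, making it cluster-neutral.
    """

    def __init__(self, features: Optional[Sequence[str]] = None,
                 cap: float = 3.0, do_cap: bool = True):
        self.features = features
        self.cap = cap
        self.do_cap = do_cap

    def fit(self, X: pd.DataFrame, y=None) -> "CappedStandardScaler":
        feats = list(self.features) if self.features is not None else list(X.columns)
        sub = X[feats]
        if len(sub) < 2:
            raise PreprocessError("need at least 2 rows to fit a scaler")
        if sub.isna().any().any():
            raise PreprocessError("impute before fitting the scaler")
        self.params_ = ScalerParams(
            features=feats,
            mean={f: float(sub[f].mean()) for f in feats},
            sd={f: float(sub[f].std(ddof=1)) for f in feats},
            median={f: float(sub[f].median()) for f in feats},
            cap=float(self.cap),
        )
        constant = [f for f in feats if self.params_.sd[f] == 0.0]
        if constant:
            warnings.warn(f"constant features (SD=0), z set to 0: {constant}")
        self.feature_names_in_ = np.asarray(feats, dtype=object)
        return self

    def set_params_object(self, params: ScalerParams) -> "CappedStandardScaler":
        """Install externally fitted parameters (transfer mode)."""
        self.params_ = params
        self.feature_names_in_ = np.asarray(params.features, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        p = self.params_
        absent = [f for f in p.features if f not in X.columns]
        if absent:
            raise PreprocessError(f"features absent from table: {absent}")
        sub = X[p.features]
        if sub.isna().any().any():
            raise PreprocessError("impute before scaling")
        z = sub.copy().astype(float)
        for f in p.features:
            sd = p.sd[f]
            if sd == 0.0:
                z[f] = 0.0
            else:
                z[f] = (z[f] - p.mean[f]) / sd
        if self.do_cap:
            z = z.clip(-p.cap, p.cap)
        return z


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def impute_median(table: pd.DataFrame, feature_list: Sequence[str],
                  medians: Optional[dict[str, float]] = None):
    """Median-impute ``feature_list`` columns; returns ``(table', report)``."""
    imp = MedianImputer(features=feature_list, medians=medians).fit(table)
    out = imp.transform(table)
    return out, imp.report_


def eligibility_filter(table: pd.DataFrame, feature_list: Sequence[str],
                       max_missing_fraction: float = 0.20):
    """Split patients by the missing-feature eligibility rule.

    A patient is excluded when strictly more than
    ``floor(max_missing_fraction * len(feature_list))`` of the listed
    features are missing — with 15 features and 0.20, more than 3 missing.
    Returns ``(kept, excluded)`` as DataFrames (same columns).
    """
    allowed = int(np.floor(max_missing_fraction * len(feature_list)))
    n_missing = table[list(feature_list)].isna().sum(axis=1)
    keep = n_missing <= allowed
    return table.loc[keep], table.loc[~keep]


def fit_scaler(table: pd.DataFrame, feature_list: Sequence[str],
               cap: float = 3.0, cohort_id: str = "") -> ScalerParams:
    """Sample mean/SD (n−1)/median per feature, packaged for transfer."""
    sc = CappedStandardScaler(features=feature_list, cap=cap).fit(table)
    sc.params_.fitted_on = cohort_id
    return sc.params_


def apply_scaler(table: pd.DataFrame, params: ScalerParams,
                 do_cap: bool = True) -> pd.DataFrame:
    """z = (x − μ)/σ per feature with optional clamping to ±params.cap."""
    sc = CappedStandardScaler(cap=params.cap, do_cap=do_cap)
    sc.set_params_object(params)
    return sc.transform(table)
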