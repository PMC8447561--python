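"""Synthetic sepsis cohorts with planted two-phenotype lipoprotein structure.

The generator emulates the joint structure the pipeline is built to detect:

* two latent phenotypes — ``hypo`` (hypolipoprotein: low HDL-C/ApoA-I/
  cholesterol, high endothelial and inflammatory markers, worse organ
  failure) and ``normo`` — with configurable prevalence;
* right-skewed biomarkers drawn log-normally, correlated through a single
  latent severity factor with the field-reported sign pattern (lipids load
  negatively, endothelial/inflammatory markers and triglycerides positively);
* ordinal 0–4 SOFA components obtained by thresholding the same latent
  severity, so organ failure co-moves with the biomarker block;
* phenotype-conditional outcome draws (rapid recovery / chronic critical
  illness / early death) and 28-day mortality;
* missing-completely-at-random cells in the laboratory biomarkers.

Everything is driven by :class:`SimulationConfig`; the two packaged defaults
(:func:`default_derivation_config`, :func:`default_replication_config`)
anchor per-phenotype medians to the reported derivation/replication cluster
summaries, the replication cohort being smaller and sicker overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .cohort import CohortTable, PatientRecord
from .schema import (
    DEFAULT_SCHEMA, LIPID_FEATURES, ENDOTHELIAL_FEATURES,
    INFLAMMATORY_FEATURES, SOFA_COMPONENTS,
)

__all__ = [
    "SimulationConfig", "generate_cohort",
    "default_derivation_config", "default_replication_config",
    "generate_planted_effect_cohort",
]

PHENOTYPES = ("hypo", "normo")


class ConfigError(ValueError):
    """An inconsistent or invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Full generative specification of one synthetic cohort.

    ``feature_means`` holds per-phenotype locations on the *latent* scale:
    natural log of the target median for log-transformed features, the plain
    mean for linear features.  ``feature_sds`` are latent-scale standard
    deviations shared by the phenotypes.  ``severity_loadings`` couple each
    continuous feature to the latent severity factor (signed, in (−1, 1));
    the implied feature correlation matrix is ``L L' + diag(1 − L²)``.  An
    explicit ``correlation`` matrix may be supplied instead, in which case
    severity is drawn independently of the biomarkers.
    """

    cohort_id: str
    n: int
    prevalence_hypo: float
    feature_means: dict[str, dict[str, float]]
    feature_sds: dict[str, float]
    severity_loadings: dict[str, float] = field(default_factory=dict)
    correlation: Optional[list[list[float]]] = None
    sofa_thresholds: list[float] = field(default_factory=lambda: [0.3, 0.9, 1.5, 2.1])
    sofa_severity_loading: float = 0.6
    sofa_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    binary_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    mortality28_probs: dict[str, float] = field(default_factory=dict)
    mortality_1y_extra: float = 0.15
    missing_rate: float = 0.05
    maskable_features: list[str] = field(default_factory=list)
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        if not 0.0 < self.prevalence_hypo < 1.0:
            raise ConfigError("prevalence_hypo must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for ph in PHENOTYPES:
            if ph not in self.feature_means:
                raise ConfigError(f"feature_means missing phenotype {ph!r}")
            probs = self.outcome_probs.get(ph)
            if probs is None:
                raise ConfigError(f"outcome_probs missing phenotype {ph!r}")
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigError(f"outcome_probs[{ph!r}] must be 3 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"outcome_probs[{ph!r}] sums to {sum(probs)!r}, not 1"
                )
            p28 = self.mortality28_probs.get(ph)
            if p28 is None or not 0.0 <= p28 <= 1.0:
                raise ConfigError(f"mortality28_probs[{ph!r}] must be in [0, 1]")
            if p28 < probs[2] - 1e-12:
                raise ConfigError(
                    f"mortality28_probs[{ph!r}] below the early-death probability"
                )
        feats = self.continuous_features()
        if set(self.feature_means["hypo"]) != set(self.feature_means["normo"]):
            raise ConfigError("phenotype feature_means cover different features")
        missing_sd = [f for f in feats if f not in self.feature_sds]
        if missing_sd:
            raise ConfigError(f"feature_sds missing for {missing_sd}")
        for f, l in self.severity_loadings.items():
            if not -1.0 < l < 1.0:
                raise ConfigError(f"severity loading for {f!r} outside (-1, 1)")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(feats), len(feats)):
                raise ConfigError("correlation matrix shape mismatch")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ConfigError("correlation matrix not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ConfigError("correlation matrix diagonal not unit")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ConfigError("correlation matrix not positive semidefinite")
        if self.sofa_thresholds != sorted(self.sofa_thresholds):
            raise ConfigError("sofa_thresholds must be non-decreasing")
        unknown = set(self.maskable_features) - set(feats)
        if unknown:
            raise ConfigError(f"maskable features not generated: {sorted(unknown)}")

    def continuous_features(self) -> list[str]:
        return list(self.feature_means["hypo"].keys())

    def correlation_matrix(self) -> np.ndarray:
        """Feature correlation on the latent Gaussian scale."""
        if self.correlation is not None:
            return np.asarray(self.correlation, dtype=float)
        feats = self.continuous_features()
        l = np.array([self.severity_loadings.get(f, 0.0) for f in feats])
        return np.outer(l, l) + np.diag(1.0 - l * l)

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["outcome_probs"] = {
            k: tuple(v) for k, v in raw.get("outcome_probs", {}).items()
        }
        return cls(**raw)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_LOG_SCALE = set(LIPID_FEATURES + ENDOTHELIAL_FEATURES + INFLAMMATORY_FEATURES
                 + ["lactate"])
_ROUNDED = {"apache2"}          # integer-valued severity scores
_NONNEGATIVE = {"ivf_24h", "apache2", "systolic_bp", "age"}

_RECOVERY_DISPOSITIONS = ("home", "rehab", "skilled_nursing")
_CCI_SHORT_DISPOSITIONS = ("ltac", "other_hospital", "hospice")


def generate_cohort(config: SimulationConfig):
    """Draw one cohort; returns ``(CohortTable, labels)``.

    ``labels`` is the per-patient ground-truth phenotype list (``"hypo"`` /
    ``"normo"``), the oracle for cluster-recovery tests.  Fully reproducible
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    feats = config.continuous_features()
    p = len(feats)

    phenotype = np.where(rng.random(n) < config.prevalence_hypo, "hypo", "normo")

    # latent severity + feature noise
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    if config.correlation is None:
        l = np.array([config.severity_loadings.get(f, 0.0) for f in feats])
        z = g[:, None] * l[None, :] + eps * np.sqrt(1.0 - l * l)[None, :]
    else:
        L = np.linalg.cholesky(
            config.correlation_matrix() + 1e-10 * np.eye(p)
        )
        z = eps @ L.T

    means = {ph: np.array([config.feature_means[ph][f] for f in feats])
             for ph in PHENOTYPES}
    sds = np.array([config.feature_sds[f] for f in feats])
    mu = np.where((phenotype == "hypo")[:, None], means["hypo"], means["normo"])
    latent = mu + z * sds[None, :]

    values = np.empty_like(latent)
    for j, f in enumerate(feats):
        col = latent[:, j]
        if f in _LOG_SCALE:
            col = np.exp(col)
        if f in _NONNEGATIVE:
            col = np.clip(col, 0.0, None)
        if f in _ROUNDED:
            col = np.round(col)
        values[:, j] = col

    # SOFA components share the severity latent g
    w = config.sofa_severity_loading
    thresholds = np.asarray(config.sofa_thresholds)
    sofa = {}
    for comp in SOFA_COMPONENTS:
        eta = rng.standard_normal(n)
        shift = np.array([
            config.sofa_shifts.get(ph, {}).get(comp, 0.0) for ph in phenotype
        ])
        s = w * g + math.sqrt(max(0.0, 1.0 - w * w)) * eta + shift
        sofa[comp] = (s[:, None] > thresholds[None, :]).sum(axis=1).astype(float)
    sofa_total = np.sum([sofa[c] for c in SOFA_COMPONENTS], axis=0) if n else np.zeros(0)

    # binary clinical covariates
    binaries = {}
    for name in ("mech_vent", "vasopressor_use", "statin_use",
                 "gender_male", "race_white"):
        probs = np.array([
            config.binary_probs.get(ph, {}).get(name, 0.5) for ph in phenotype
        ])
        binaries[name] = (rng.random(n) < probs).astype(float)
    vaso_days = binaries["vasopressor_use"] * np.round(
        np.exp(rng.normal(math.log(3.0), 0.5, size=n))
    )
    charlson = np.clip(np.round(rng.normal(3.5, 2.5, size=n)), 0, 14)

    # outcomes conditional on phenotype
    outcome_idx = np.zeros(n, dtype=int)
    for ph in PHENOTYPES:
        mask = phenotype == ph
        probs = np.asarray(config.outcome_probs[ph], dtype=float)
        probs = probs / probs.sum()
        outcome_idx[mask] = rng.choice(3, size=int(mask.sum()), p=probs)
    outcome = np.array(["rapid_recovery", "cci", "early_death"])[outcome_idx] \
        if n else np.array([], dtype=str)

    # 28-day mortality: certain under early death, top-up Bernoulli otherwise,
    # so the per-phenotype marginal equals the configured probability
    u28 = rng.random(n)
    mort28 = np.zeros(n, dtype=bool)
    for ph in PHENOTYPES:
        mask = phenotype == ph
        p28 = config.mortality28_probs[ph]
        p_ed = config.outcome_probs[ph][2]
        extra = 0.0 if p_ed >= 1.0 else max(0.0, (p28 - p_ed) / (1.0 - p_ed))
        mort28[mask] = (outcome[mask] == "early_death") | (u28[mask] < extra)
    mort1y = mort28 | (rng.random(n) < config.mortality_1y_extra)

    # outcome-consistent admission/discharge fields
    death_day = rng.integers(1, 15, size=n)
    icu_rr = rng.integers(0, 15, size=n)
    icu_cci_long = rng.integers(15, 31, size=n)
    cci_short = rng.random(n) < 0.2
    dispo_rr = rng.choice(_RECOVERY_DISPOSITIONS, size=n, p=[0.7, 0.15, 0.15])
    dispo_cci_long = rng.choice(("rehab", "skilled_nursing", "ltac"), size=n)
    dispo_cci_short = rng.choice(_CCI_SHORT_DISPOSITIONS, size=n)
    miss_mask = rng.random((n, p)) < config.missing_rate
    maskable = np.array([f in set(config.maskable_features) for f in feats])
    miss_mask &= maskable[None, :]

    width = max(3, len(str(max(n, 1))))
    patients = []
    labels = []
    for i in range(n):
        feats_i = {
            f: float(values[i, j])
            for j, f in enumerate(feats) if not miss_mask[i, j]
        }
        for comp in SOFA_COMPONENTS:
            feats_i[comp] = float(sofa[comp][i])
        feats_i["sofa_total"] = float(sofa_total[i])
        for name, arr in binaries.items():
            feats_i[name] = float(arr[i])
        feats_i["vasopressor_days"] = float(vaso_days[i])
        feats_i["charlson"] = float(charlson[i])

        out = outcome[i]
        if out == "early_death":
            dd = int(death_day[i])
            rec = dict(icu_days=min(dd, int(icu_rr[i]) + 1), death_day=dd,
                       disposition="died", organ_dysfunction_at_day14=None)
        elif out == "cci":
            if cci_short[i]:
                rec = dict(icu_days=int(icu_rr[i]),
                           disposition=str(dispo_cci_short[i]),
                           death_day=None, organ_dysfunction_at_day14=False)
            else:
                rec = dict(icu_days=int(icu_cci_long[i]),
                           disposition=str(dispo_cci_long[i]),
                           death_day=None, organ_dysfunction_at_day14=True)
        else:
            rec = dict(icu_days=int(icu_rr[i]), disposition=str(dispo_rr[i]),
                       death_day=None, organ_dysfunction_at_day14=False)

        patients.append(PatientRecord(
            patient_id=f"{config.cohort_id}-{i:0{width}d}",
            features=feats_i,
            mortality_28d=bool(mort28[i]),
            mortality_1y=bool(mort1y[i]),
            outcome=str(out),
            **rec,
        ))
        labels.append(str(phenotype[i]))

    return CohortTable(config.cohort_id, DEFAULT_SCHEMA, patients), labels


# ---------------------------------------------------------------------------
# packaged default configurations
# ---------------------------------------------------------------------------

def _ln(x: float) -> float:
    return math.log(x)


# reported overall medians for markers without per-cluster summaries
_OVERALL_MEDIANS = {
    "triglycerides": 121.0, "hdl_inflammatory_index": 1.9,
    "mpo": 203.0, "gro": 1081.0, "g_csf": 334.0, "gm_csf": 12.0,
    "ifn_gamma": 28.0, "il10": 74.0, "il8": 67.0, "il6": 176.0,
    "il12p70": 12.0, "ip10": 1066.0, "mcp1": 739.0, "mip1a": 8.0,
    "tnf_alpha": 70.0, "e_selectin": 68.0,
}

# log-scale SDs: the signature lipids are tight enough that the planted
# between-phenotype separation at the reported cluster medians is >= 2 SD —
# the clearly-separated two-phenotype regime the pipeline is designed for
_FEATURE_SDS = {
    "total_cholesterol": 0.20, "hdl_c": 0.53, "ldl_c": 0.23,
    "pon1_activity": 0.25, "apoa1": 0.25, "icam1": 0.30,
    "triglycerides": 0.50, "hdl_inflammatory_index": 0.50,
    "e_selectin": 0.60,
    "mpo": 0.80, "gro": 0.80, "g_csf": 0.80, "gm_csf": 0.80,
    "ifn_gamma": 0.80, "il10": 0.80, "il8": 0.80, "il6": 0.80,
    "il12p70": 0.80, "ip10": 0.80, "mcp1": 0.80, "mip1a": 0.80,
    "tnf_alpha": 0.80,
    "systolic_bp": 15.0, "temperature_f": 1.3, "lactate": 0.45,
    "age": 13.0, "apache2": 6.0, "ivf_24h": 1.2,
}

# Within-phenotype severity-factor loadings: lipids negative, endothelial/
# inflammatory and triglycerides positive, per the reported correlation sign
# structure.  Magnitudes are moderate because the reported whole-cohort
# (marginal) correlations of ~|0.4| arise mostly from the phenotype mixture
# itself; strong conditional coupling would both overshoot the marginal
# target and smear patients along the very axis separating the phenotypes.
_SEVERITY_LOADINGS = {
    **{f: -0.18 for f in ("total_cholesterol", "hdl_c", "ldl_c",
                          "pon1_activity", "apoa1")},
    "triglycerides": 0.45, "hdl_inflammatory_index": 0.45,
    "icam1": 0.18, "e_selectin": 0.18,
    **{f: 0.15 for f in INFLAMMATORY_FEATURES},
    "systolic_bp": -0.15, "temperature_f": 0.05, "lactate": 0.15,
    "age": 0.03, "apache2": 0.18, "ivf_24h": 0.09,
}

_BINARY_PROBS = {
    "hypo": {"mech_vent": 0.55, "vasopressor_use": 0.55, "statin_use": 0.33,
             "gender_male": 0.58, "race_white": 0.72},
    "normo": {"mech_vent": 0.25, "vasopressor_use": 0.20, "statin_use": 0.38,
              "gender_male": 0.58, "race_white": 0.72},
}

_MASKABLE = LIPID_FEATURES + ENDOTHELIAL_FEATURES + INFLAMMATORY_FEATURES


def _base_means(cluster_medians: dict[str, tuple[float, float]],
                cytokine_factor: tuple[float, float],
                vitals: dict[str, tuple[float, float]]) -> dict:
    means = {"hypo": {}, "normo": {}}
    for f, (mh, mn) in cluster_medians.items():
        means["hypo"][f] = _ln(mh)
        means["normo"][f] = _ln(mn)
    fh, fn = cytokine_factor
    for f in INFLAMMATORY_FEATURES + ["hdl_inflammatory_index", "e_selectin"]:
        m = _OVERALL_MEDIANS[f]
        means["hypo"][f] = _ln(m * fh)
        means["normo"][f] = _ln(m * fn)
    # triglycerides: near-equal medians (no reported cluster difference) with
    # a slight elevation under hypo, consistent with their positive coupling
    # to severity and endothelial dysfunction
    means["hypo"]["triglycerides"] = _ln(1.074 * _OVERALL_MEDIANS["triglycerides"])
    means["normo"]["triglycerides"] = _ln(0.950 * _OVERALL_MEDIANS["triglycerides"])
    for f, (vh, vn) in vitals.items():
        means["hypo"][f] = vh
        means["normo"][f] = vn
    return means


def default_derivation_config(n: int = 172, seed: int = 0) -> SimulationConfig:
    """Default derivation-cohort generator (medians anchored to the reported
    Hypolipoprotein/Normolipoprotein cluster summaries)."""
    means = _base_means(
        cluster_medians={
            "total_cholesterol": (67.0, 108.0), "hdl_c": (7.0, 26.0),
            "ldl_c": (30.0, 52.0), "pon1_activity": (35.81, 65.99),
            "apoa1": (754_631.0, 1_400_000.0), "icam1": (589.75, 346.502),
        },
        cytokine_factor=(1.8, 0.65),
        vitals={"systolic_bp": (97.0, 113.0), "temperature_f": (98.6, 99.6),
                "lactate": (_ln(2.8), _ln(1.8)), "age": (61.0, 61.0),
                "apache2": (19.0, 12.0), "ivf_24h": (2.8, 2.2)},
    )
    cfg = SimulationConfig(
        cohort_id="synthetic-derivation",
        n=n,
        prevalence_hypo=58.0 / 168.0,
        feature_means=means,
        feature_sds=dict(_FEATURE_SDS),
        severity_loadings=dict(_SEVERITY_LOADINGS),
        sofa_shifts={
            "hypo": {"sofa_cardiovascular": 0.75, "sofa_neurologic": 1.2,
                     "sofa_coagulation": 0.0, "sofa_hepatic": -0.3,
                     "sofa_renal": 1.2, "sofa_respiratory": 1.2},
            "normo": {"sofa_cardiovascular": 0.35, "sofa_neurologic": -0.2,
                      "sofa_coagulation": -0.2, "sofa_hepatic": -0.5,
                      "sofa_renal": 0.5, "sofa_respiratory": -0.1},
        },
        binary_probs={ph: dict(v) for ph, v in _BINARY_PROBS.items()},
        outcome_probs={
            "hypo": (0.448, 0.397, 0.155),    # 26/58, 23/58, 9/58
            "normo": (0.791, 0.145, 0.064),   # 87/110, 16/110, 7/110
        },
        mortality28_probs={"hypo": 0.241, "normo": 0.173},  # 14/58, 19/110
        missing_rate=0.05,
        maskable_features=list(_MASKABLE),
        seed=seed,
    )
    cfg.validate()
    return cfg


def default_replication_config(n: int = 86, seed: int = 1) -> SimulationConfig:
    """Default replication-cohort generator: same generative family with the
    reported replication cluster medians and a higher overall severity."""
    means = _base_means(
        cluster_medians={
            "total_cholesterol": (87.0, 101.0), "hdl_c": (10.0, 34.0),
            "ldl_c": (41.0, 46.0), "pon1_activity": (46.77, 89.42),
            "apoa1": (475_785.0, 793_130.0), "icam1": (649.15, 351.92),
        },
        cytokine_factor=(1.9, 0.9),
        vitals={"systolic_bp": (101.0, 108.0), "temperature_f": (99.0, 99.4),
                "lactate": (_ln(3.2), _ln(2.4)), "age": (60.0, 60.0),
                "apache2": (21.0, 17.0), "ivf_24h": (3.0, 2.6)},
    )
    cfg = SimulationConfig(
        cohort_id="synthetic-replication",
        n=n,
        prevalence_hypo=26.0 / 86.0,
        feature_means=means,
        feature_sds=dict(_FEATURE_SDS),
        severity_loadings=dict(_SEVERITY_LOADINGS),
        # higher overall severity than derivation, organ failure worse under
        # hypo on every component (shared planted direction structure)
        sofa_shifts={
            "hypo": {"sofa_cardiovascular": 1.2, "sofa_neurologic": 0.9,
                     "sofa_coagulation": 0.6, "sofa_hepatic": 1.2,
                     "sofa_renal": 0.9, "sofa_respiratory": 0.9},
            "normo": {"sofa_cardiovascular": 0.6, "sofa_neurologic": 0.3,
                      "sofa_coagulation": -0.3, "sofa_hepatic": -0.3,
                      "sofa_renal": 0.5, "sofa_respiratory": 0.3},
        },
        binary_probs={
            "hypo": {**_BINARY_PROBS["hypo"], "mech_vent": 0.65,
                     "vasopressor_use": 0.65},
            "normo": {**_BINARY_PROBS["normo"], "mech_vent": 0.40,
                      "vasopressor_use": 0.35},
        },
        outcome_probs={
            "hypo": (0.461, 0.231, 0.308),    # 12/26, 6/26, 8/26
            "normo": (0.550, 0.317, 0.133),   # 33/60, 19/60, 8/60
        },
        mortality28_probs={"hypo": 0.423, "normo": 0.283},  # 11/26, 17/60
        missing_rate=0.05,
        maskable_features=list(_MASKABLE),
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# planted-effect design for variable-selection recovery studies
# ---------------------------------------------------------------------------

def generate_planted_effect_cohort(
    n: int = 400,
    effect_feature: str = "apoa1",
    or_per_sd: float = 0.2,
    base_rate: float = 0.35,
    seed: int = 0,
):
    """Cohort where exactly one candidate predictor carries an outcome effect.

    All 29 candidate predictors are drawn from their default (normo-phenotype)
    marginals, mutually independent; the binary outcome (CCI-or-early-death)
    follows a logistic model whose only non-zero coefficient is
    ``ln(or_per_sd)`` per standard deviation of the effect feature on its
    model scale (log scale for log-transformed biomarkers).  Returns
    ``(X, y)``: a DataFrame of candidates on the measurement scale and an
    outcome vector.
    """
    from .schema import LASSO_CANDIDATES

    cfg = default_derivation_config()
    rng = np.random.default_rng(seed)
    cols = {}
    z_effect = None
    for f in LASSO_CANDIDATES:
        if f in ("mech_vent", "vasopressor_use", "statin_use",
                 "gender_male", "race_white"):
            cols[f] = (rng.random(n) < _BINARY_PROBS["normo"][f]).astype(float)
        elif f == "vasopressor_days":
            cols[f] = np.round(np.exp(rng.normal(math.log(3.0), 0.5, n))) * \
                cols["vasopressor_use"]
        elif f == "charlson":
            cols[f] = np.clip(np.round(rng.normal(3.5, 2.5, n)), 0, 14)
        elif f == "sofa_total":
            cols[f] = np.clip(np.round(rng.normal(6.0, 3.0, n)), 0, 24)
        else:
            z = rng.standard_normal(n)
            mu = cfg.feature_means["normo"][f]
            sd = cfg.feature_sds[f]
            x = mu + sd * z
            cols[f] = np.exp(x) if f in _LOG_SCALE else x
            if f == effect_feature:
                z_effect = z
    if z_effect is None:
        raise ConfigError(f"effect feature {effect_feature!r} is not continuous")
    import pandas as pd

    X = pd.DataFrame(cols, index=[f"pe-{i:04d}" for i in range(n)])
    intercept = math.log(base_rate / (1.0 - base_rate))
    eta = intercept + math.log(or_per_sd) * z_effect
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, pd.Series(y, index=X.index, name="cci_or_early_death")
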