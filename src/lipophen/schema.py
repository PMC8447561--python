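"""Default feature schema: the measured variables of the sepsis lipid panel.

Groups mirror the measurement blocks used throughout the pipeline:

* lipids — cholesterol fractions, triglycerides, HDL function markers
* endothelial — soluble adhesion molecules (endothelial dysfunction)
* inflammatory — cytokine/chemokine panel plus myeloperoxidase
* sofa components — six organ-system subscores (0–4 each)
* vitals — enrollment systolic blood pressure and temperature
* clinical/severity — covariates and composite severity scores
"""

from __future__ import annotations

from .cohort import FeatureSpec

__all__ = [
    "LIPID_FEATURES", "ENDOTHELIAL_FEATURES", "INFLAMMATORY_FEATURES",
    "SOFA_COMPONENTS", "VITAL_FEATURES", "CLINICAL_FEATURES",
    "SEVERITY_FEATURES", "DEFAULT_SCHEMA", "CLUSTERING_FEATURES",
    "SIGNATURE_FEATURES", "LASSO_CANDIDATES", "ANCHOR_FEATURE",
]

LIPID_FEATURES = [
    "total_cholesterol", "hdl_c", "ldl_c", "triglycerides",
    "hdl_inflammatory_index", "pon1_activity", "apoa1",
]
ENDOTHELIAL_FEATURES = ["icam1", "e_selectin"]
INFLAMMATORY_FEATURES = [
    "mpo", "gro", "g_csf", "gm_csf", "ifn_gamma", "il10", "il8", "il6",
    "il12p70", "ip10", "mcp1", "mip1a", "tnf_alpha",
]
SOFA_COMPONENTS = [
    "sofa_cardiovascular", "sofa_neurologic", "sofa_coagulation",
    "sofa_hepatic", "sofa_renal", "sofa_respiratory",
]
VITAL_FEATURES = ["systolic_bp", "temperature_f"]
CLINICAL_FEATURES = [
    "age", "gender_male", "race_white", "lactate", "charlson",
    "mech_vent", "statin_use", "vasopressor_use", "vasopressor_days",
    "ivf_24h",
]
SEVERITY_FEATURES = ["sofa_total", "apache2"]

_UNITS = {
    "total_cholesterol": "mg/dL", "hdl_c": "mg/dL", "ldl_c": "mg/dL",
    "triglycerides": "mg/dL", "hdl_inflammatory_index": "index",
    "pon1_activity": "nmol/min/ml", "apoa1": "ng/mL",
    "icam1": "ng/mL", "e_selectin": "ng/mL",
    "mpo": "ug/L", "gro": "pg/mL", "g_csf": "pg/mL", "gm_csf": "pg/mL",
    "ifn_gamma": "pg/mL", "il10": "pg/mL", "il8": "pg/mL", "il6": "pg/mL",
    "il12p70": "pg/mL", "ip10": "pg/mL", "mcp1": "pg/mL", "mip1a": "pg/mL",
    "tnf_alpha": "pg/mL",
    "systolic_bp": "mm Hg", "temperature_f": "°F",
    "age": "years", "lactate": "mmol/dL", "charlson": "score points",
    "vasopressor_days": "days", "ivf_24h": "L",
    "sofa_total": "score points", "apache2": "score points",
}

# right-skewed biomarkers modelled on the log scale
_LOG_FEATURES = set(
    LIPID_FEATURES + ENDOTHELIAL_FEATURES + INFLAMMATORY_FEATURES + ["lactate"]
)


def _spec(name: str, category: str) -> FeatureSpec:
    return FeatureSpec(
        name=name,
        category=category,
        units=_UNITS.get(name, ""),
        transform="log" if name in _LOG_FEATURES else "none",
    )


DEFAULT_SCHEMA = (
    [_spec(n, "lipid") for n in LIPID_FEATURES]
    + [_spec(n, "endothelial") for n in ENDOTHELIAL_FEATURES]
    + [_spec(n, "inflammatory") for n in INFLAMMATORY_FEATURES]
    + [_spec(n, "sofa_component") for n in SOFA_COMPONENTS]
    + [_spec(n, "vital_sign") for n in VITAL_FEATURES]
    + [_spec(n, "clinical") for n in CLINICAL_FEATURES]
    + [_spec(n, "severity_score") for n in SEVERITY_FEATURES]
)

#: features entering derivation clustering: all biomarkers + SOFA + vitals.
#: Procalcitonin-style partially-assayed markers are excluded by construction.
CLUSTERING_FEATURES = (
    LIPID_FEATURES + ENDOTHELIAL_FEATURES + INFLAMMATORY_FEATURES
    + SOFA_COMPONENTS + ["sofa_total"] + VITAL_FEATURES
)

#: the 15-feature cluster signature used for cross-cohort replication
SIGNATURE_FEATURES = [
    "total_cholesterol", "hdl_c", "ldl_c", "pon1_activity", "apoa1", "icam1",
    *SOFA_COMPONENTS, "systolic_bp", "temperature_f", "sofa_total",
]

#: the 29 candidate predictors entering LASSO selection
LASSO_CANDIDATES = [
    "age", "gender_male", "race_white", "pon1_activity", "apoa1", "hdl_c",
    "ldl_c", "total_cholesterol", "triglycerides", "g_csf", "gm_csf",
    "ifn_gamma", "il10", "il12p70", "il6", "il8", "ip10", "mcp1", "mip1a",
    "tnf_alpha", "sofa_total", "lactate", "mech_vent", "statin_use",
    "vasopressor_use", "vasopressor_days", "ivf_24h", "apache2", "charlson",
]

#: semantic cluster labelling anchors on HDL-C (top discriminating feature)
ANCHOR_FEATURE = "hdl_c"

assert len(SIGNATURE_FEATURES) == 15
assert len(LASSO_CANDIDATES) == 29
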