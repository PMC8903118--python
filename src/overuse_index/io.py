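"""Delimited-text schemas and readers/writers for every pipeline table.

All inter-stage files are plain CSV with header rows (auditable; no binary
formats).  The schemas are the documented contract for feeding real extracts
into the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SimulationTruth, SyntheticBundle

__all__ = [
    "SCHEMAS",
    "read_claims",
    "read_beneficiaries",
    "read_linkage",
    "read_characteristics",
    "read_cells",
    "read_index_table",
    "write_table",
    "write_truth",
    "read_truth",
    "write_bundle",
]

#: documented column contracts for the delimited-text interfaces
SCHEMAS = {
    "claims": [
        "beneficiary_id",
        "service_date",
        "ccn",
        "diagnosis_codes",  # ';'-separated
        "procedure_codes",  # ';'-separated
        "setting",  # inpatient | outpatient
    ],
    "beneficiaries": ["beneficiary_id", "birth_date", "sex", "chronic_condition_count"],
    "linkage": ["ccn", "hospital_name", "system_id", "vintage"],
    "cells": [
        "ccn",
        "system_id",
        "quarter_index",
        "indicator_id",
        "eligible_count",
        "event_count",
        "mean_age",
        "proportion_women",
        "median_chronic_conditions",
    ],
    "index": ["system_id", "raw_phi", "oi", "category"],
    "coefficients": ["parameter", "estimate", "se"],
}

_BOOL_CHAR_COLS = [
    "investor_owned",
    "very_major_teaching_hospital",
    "major_teaching_hospital",
    "high_disadvantaged_share",
    "high_uncompensated_burden",
    "upper_quartile_uncompensated",
    "any_insurance_product",
    "medicare_advantage",
    "medicaid_managed_care",
    "aco_contract",
    "bundled_payment",
    "alternative_payment_model",
]


def _require(df: pd.DataFrame, schema: str, path) -> None:
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required {schema} columns {missing}")


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ccn": str, "beneficiary_id": str}, keep_default_na=False)
    _require(df, "claims", path)
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def read_beneficiaries(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"beneficiary_id": str})
    _require(df, "beneficiaries", path)
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def read_linkage(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ccn": str})
    _require(df, "linkage", path)
    if df.duplicated(["ccn", "vintage"]).any():
        raise ValueError(f"{path}: (ccn, vintage) pairs must be unique")
    return df


def read_characteristics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "system_id" not in df.columns:
        raise ValueError(f"{path}: missing system_id column")
    for c in _BOOL_CHAR_COLS:
        if c in df.columns and df[c].dtype != bool:
            df[c] = df[c].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ccn": str})
    _require(df, "cells", path)
    return df


def read_index_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, "index", path)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == "datetime64[ns]":
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def write_truth(truth: SimulationTruth, path) -> Path:
    """Simulation ground truth as a structured plain-text (YAML) file."""
    doc = {
        "base_log_rate": truth.base_log_rate,
        "dispersion": truth.dispersion,
        "hospital_variance": truth.hospital_variance,
        "quarter_effects": [float(x) for x in truth.quarter_effects],
        "indicator_effects": [float(x) for x in truth.indicator_effects],
        "covariate_betas": [float(x) for x in truth.covariate_betas],
        "system_tendencies": {k: float(v) for k, v in truth.system_tendencies.items()},
        "hospital_intercepts": {k: float(v) for k, v in truth.hospital_intercepts.items()},
        "characteristic_effects": {k: float(v) for k, v in truth.characteristic_effects.items()},
        "state_effects": {k: float(v) for k, v in truth.state_effects.items()},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def read_truth(path) -> SimulationTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return SimulationTruth(
        system_tendencies=doc["system_tendencies"],
        hospital_intercepts=doc["hospital_intercepts"],
        quarter_effects=np.asarray(doc["quarter_effects"]),
        indicator_effects=np.asarray(doc["indicator_effects"]),
        covariate_betas=np.asarray(doc["covariate_betas"]),
        dispersion=doc["dispersion"],
        hospital_variance=doc["hospital_variance"],
        characteristic_effects=doc["characteristic_effects"],
        base_log_rate=doc["base_log_rate"],
        state_effects=doc.get("state_effects", {}),
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write all bundle tables; returns a name -> path manifest."""
    outdir = Path(outdir)
    paths = {
        "claims": write_table(bundle.claims, outdir / "claims.csv"),
        "beneficiaries": write_table(bundle.beneficiaries, outdir / "beneficiaries.csv"),
        "linkage": write_table(bundle.linkage, outdir / "linkage.csv"),
        "characteristics": write_table(bundle.characteristics, outdir / "characteristics.csv"),
        "cells_truth": write_table(bundle.cells, outdir / "cells_truth.csv"),
        "truth": write_truth(bundle.truth, outdir / "truth.yaml"),
    }
    return {k: str(v) for k, v in paths.items()}
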