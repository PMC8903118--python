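"""End-to-end orchestration: claims -> cells -> model -> index -> associations."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as oio
from .associations import fit_ols_state_fe, fit_mixed_state_re, make_tertiles
from .config import PipelineConfig, default_indicator_definitions, load_indicator_config
from .calendars import StudyCalendar
from .glmm import DesignSpec, fit_nb_glmm
from .index import build_index_table
from .indicators import EngineLog, count_cells

__all__ = ["run_pipeline", "prepare_association_features"]


def prepare_association_features(characteristics: pd.DataFrame) -> pd.DataFrame:
    """Derive modeling features from raw characteristics.

    Adds tertile labels for the right-skewed counts and a major-teaching flag;
    leaves the raw columns in place.
    """
    chars = characteristics.copy()
    for col, name in [
        ("primary_care_physicians", "pcp_tertile"),
        ("hospitals", "hospitals_tertile"),
        ("beds", "beds_tertile"),
        ("medical_groups", "medical_groups_tertile"),
    ]:
        if col in chars.columns:
            try:
                labels, _ = make_tertiles(chars[col])
            except ValueError:
                continue  # constant or near-empty column: no tertile feature
            chars[name] = pd.array(labels, dtype="Int64")
            chars.loc[chars[name] == 0, name] = pd.NA
    if "teaching_intensity" in chars.columns:
        chars["major_teaching"] = chars["teaching_intensity"] == "major"
    return chars


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs; returns the manifest.

    Stages: indicator counting (claims -> cells), the NB2 mixed-model fit,
    index standardization and categorization, and the association models.
    The manifest records the seed, per-stage row counts and output paths;
    rerunning with an identical config reproduces identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = EngineLog()
    manifest: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # stage: count
    claims = _stage("load")(lambda: oio.read_claims(config.claims_path))
    bene = oio.read_beneficiaries(config.beneficiaries_path)
    linkage = oio.read_linkage(config.linkage_path)
    defs = (
        load_indicator_config(config.indicator_config)
        if config.indicator_config
        else default_indicator_definitions()
    )
    calendar = StudyCalendar()
    cells = _stage("count")(
        lambda: count_cells(
            claims,
            bene,
            linkage,
            defs,
            calendar=calendar,
            min_eligible=config.min_eligible,
            min_eligible_per_quarter=config.min_eligible_per_quarter,
            log=log,
        )
    )
    cells_path = oio.write_table(cells, outdir / "cells.csv")
    manifest["stages"]["count"] = {"path": str(cells_path), "rows": len(cells)}

    # stage: fit
    fit = _stage("fit")(
        lambda: fit_nb_glmm(
            cells,
            DesignSpec(
                reference_quarter=config.reference_quarter,
                reference_indicator=config.reference_indicator,
                reference_system=config.reference_system,
                standardize_covariates=config.standardize_covariates,
            ),
            max_iter=config.max_iter,
            tol=config.tol,
            gtol=config.gtol,
        )
    )
    coef_path = oio.write_table(fit.summary_frame(), outdir / "coefficients.csv")
    manifest["stages"]["fit"] = {
        "path": str(coef_path),
        "converged": fit.converged_,
        "loglik": fit.loglik_,
        "n_cells": fit.n_cells_,
        "dispersion": fit.dispersion_,
        "hospital_variance": fit.hospital_variance_,
    }

    # stage: index
    index_table = _stage("index")(lambda: build_index_table(fit.system_effects_))
    index_path = oio.write_table(index_table, outdir / "index.csv")
    manifest["stages"]["index"] = {"path": str(index_path), "rows": len(index_table)}

    # stage: associations
    if config.characteristics_path:
        chars = prepare_association_features(oio.read_characteristics(config.characteristics_path))
        covs = [c for c in config.association_covariates if c in chars.columns]
        if config.association_state_mode == "random":
            assoc = _stage("associate")(
                lambda: fit_mixed_state_re(index_table, chars, covs)
            )
        else:
            state_col = "state" if config.association_state_mode == "fixed" else None
            assoc = _stage("associate")(
                lambda: fit_ols_state_fe(index_table, chars, covs, state_col=state_col)
            )
        assoc_path = oio.write_table(assoc.table, outdir / "associations.csv")
        manifest["stages"]["associate"] = {
            "path": str(assoc_path),
            "n_systems": assoc.n_systems,
            "model_label": assoc.model_label,
        }

    log_path = oio.write_table(log.to_frame(), outdir / "log.csv")
    manifest["stages"]["log"] = {"path": str(log_path)}
    config.to_yaml(outdir / "config_snapshot.yaml")
    manifest["config_snapshot"] = str(outdir / "config_snapshot.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
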