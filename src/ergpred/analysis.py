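"""End-to-end cohort analysis: marker tables, feature matrices and the
R² comparison grid.

The canonical cohort table is long format, one row per eye and
stimulus condition::

    individual_id, eye, condition, a_uV, b_uV, i_uV, phnr1_uV, phnr2_uV, ergc

The headline analysis is a 2x2x2 grid — {PhNR-only, all markers} x
{linear, MARS} x {chromatic, achromatic} — of model R² values for
predicting the eRGC count, with individual-level cluster-bootstrap
p-values for the three pairwise questions: do the extra markers help,
does MARS beat linear, and does the achromatic stimulus beat the
chromatic one.
"""
from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .compare import FEATURE_SETS, ComparisonResult, ModelSpec, cluster_bootstrap_compare, fit_spec
from .exceptions import ErgPredError
from .simulate import CohortConfig, SyntheticEye
from .waveform import MARKER_NAMES, process_sweeps

logger = logging.getLogger(__name__)

#: marker name (waveform module) -> feature column (cohort table)
MARKER_COLUMNS = {
    "a_wave": "a_uV",
    "b_wave": "b_uV",
    "i_wave": "i_uV",
    "phnr1": "phnr1_uV",
    "phnr2": "phnr2_uV",
}

FAMILIES = ("linear", "mars")
CONDITIONS = ("chromatic", "achromatic")
FEATURE_SET_NAMES = ("phnr_only", "all_markers")


def feature_table_from_truth(cohort: Sequence[SyntheticEye]) -> pd.DataFrame:
    """Cohort table built from the generator's true component amplitudes
    (bypasses trace synthesis and marker extraction)."""
    rows = []
    for eye in cohort:
        for cond, amps in eye.true_amplitudes.items():
            row = {
                "individual_id": eye.individual_id,
                "eye": eye.side,
                "condition": cond,
                "ergc": eye.ergc,
            }
            for marker, col in MARKER_COLUMNS.items():
                row[col] = amps[marker]
            rows.append(row)
    return pd.DataFrame(rows)


def extract_feature_table(
    cohort: Sequence[SyntheticEye],
    config: CohortConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table built by the full measurement pipeline: synthesize
    raw sweeps per eye and condition, then filter, reject artifacts,
    average and locate markers. Eyes whose extraction fails (e.g. an
    unmarkable waveform) are logged and skipped."""
    rng = np.random.default_rng(seed)
    rows = []
    for eye in cohort:
        for cond in config.conditions:
            sweeps = eye.sweeps(cond, config, rng=rng)
            try:
                markers = process_sweeps(sweeps)
            except ErgPredError as exc:
                logger.warning(
                    "marker extraction failed for individual %d %s (%s): %s",
                    eye.individual_id, eye.side, cond, exc,
                )
                continue
            row = {
                "individual_id": eye.individual_id,
                "eye": eye.side,
                "condition": cond,
                "ergc": eye.ergc,
            }
            for marker, col in MARKER_COLUMNS.items():
                row[col] = markers[marker].amplitude_uV
            rows.append(row)
    return pd.DataFrame(rows)


def pivot_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-eye table with condition-suffixed feature columns
    (``a_uV_chromatic``, ... ``phnr2_uV_achromatic``), keeping only eyes
    measured under every condition present."""
    value_cols = list(MARKER_COLUMNS.values())
    wide = table.pivot_table(
        index=["individual_id", "eye", "ergc"],
        columns="condition",
        values=value_cols,
    )
    wide.columns = [f"{col}_{cond}" for col, cond in wide.columns]
    return wide.dropna().reset_index()


def _spec(features: str, condition: str, family: str, cv: str, k: int, max_terms: int) -> ModelSpec:
    cols = tuple(f"{c}_{condition}" for c in FEATURE_SETS[features])
    return ModelSpec(
        family=family, features=cols, k_folds=k, max_terms=max_terms,
        grouped_cv=(cv == "grouped"),
    )


def table2_grid(
    table: pd.DataFrame,
    seed: int = 0,
    n_resamples: int = 1000,
    cv: Literal["grouped", "plain"] = "grouped",
    k_folds: int = 10,
    max_terms: int = 40,
    score: Literal["apparent", "cv"] = "apparent",
) -> dict:
    """Compute the 8-cell R² grid plus pairwise bootstrap p-values.

    ``table`` is a long-format cohort table covering both stimulus
    conditions. Returns a JSON-serializable report: apparent and
    cross-validated R² per cell, and one-sided cluster-bootstrap
    p-values for markers-vs-PhNR, MARS-vs-linear and
    achromatic-vs-chromatic comparisons.
    """
    wide = pivot_conditions(table)
    if wide.empty:
        raise ValueError("no eye has complete measurements across conditions")
    y = wide["ergc"].to_numpy(dtype=float)

    r2: dict[str, dict[str, dict[str, float]]] = {}
    cv_r2: dict[str, dict[str, dict[str, float]]] = {}
    specs: dict[tuple[str, str, str], ModelSpec] = {}
    models: dict[tuple[str, str, str], object] = {}
    for cond in CONDITIONS:
        r2[cond], cv_r2[cond] = {}, {}
        for feats in FEATURE_SET_NAMES:
            r2[cond][feats], cv_r2[cond][feats] = {}, {}
            for family in FAMILIES:
                key = (cond, feats, family)
                spec = _spec(feats, cond, family, cv, k_folds, max_terms)
                specs[key] = spec
                model = fit_spec(spec, wide, outcome="ergc", seed=seed)
                models[key] = model
                r2[cond][feats][family] = float(
                    model.score(wide[list(spec.feature_columns())], y)
                )
                cv_r2[cond][feats][family] = (
                    float(model.cv_r2) if model.cv_r2 is not None else None
                )

    def compare(key_a, key_b) -> float:
        res = cluster_bootstrap_compare(
            specs[key_a], specs[key_b], wide,
            n_resamples=n_resamples, seed=seed, outcome="ergc", score=score,
            fitted=(models[key_a], models[key_b]),
        )
        return res.p_value

    p_values = {"phnr_vs_markers": {}, "linear_vs_mars": {}, "chromatic_vs_achromatic": {}}
    for cond in CONDITIONS:
        for family in FAMILIES:
            p_values["phnr_vs_markers"][f"{cond}_{family}"] = compare(
                (cond, "phnr_only", family), (cond, "all_markers", family)
            )
        for feats in FEATURE_SET_NAMES:
            p_values["linear_vs_mars"][f"{cond}_{feats}"] = compare(
                (cond, feats, "linear"), (cond, feats, "mars")
            )
    for feats in FEATURE_SET_NAMES:
        for family in FAMILIES:
            p_values["chromatic_vs_achromatic"][f"{feats}_{family}"] = compare(
                ("chromatic", feats, family), ("achromatic", feats, family)
            )

    return {
        "n_eyes": int(len(wide)),
        "n_individuals": int(wide["individual_id"].nunique()),
        "seed": seed,
        "n_resamples": n_resamples,
        "cv": cv,
        "score": score,
        "r2": r2,
        "cv_r2": cv_r2,
        "p_values": p_values,
    }


def grid_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a table2 report's R² grid to a tidy frame."""
    rows = []
    for cond, by_feat in report["r2"].items():
        for feats, by_fam in by_feat.items():
            for family, val in by_fam.items():
                rows.append(
                    {
                        "condition": cond,
                        "features": feats,
                        "family": family,
                        "r2": val,
                        "cv_r2": report["cv_r2"][cond][feats][family],
                    }
                )
    return pd.DataFrame(rows)
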