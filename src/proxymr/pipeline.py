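"""End-to-end orchestration of the three stratified MR analyses.

Each invocation runs exactly one analysis on a cohort table (read from
disk or simulated on the fly) and writes a deterministic artifact set to
the output directory: ``results.csv`` (one row per stratum estimate,
contrast or heterogeneity test), ``summary.json`` (config hash, seed,
software version, counts) and ``run.log``.

Analyses
--------
g1_birthweight
    Proof-of-principle design: G1 birthweight per G1 allele within G0
    pregnancy-smoking strata, crude and adjusted (sex + 10 PCs), with
    Cochran's Q between strata.
g1_adult_outcomes
    Each configured adult outcome per allele within the 2x2 of G0
    pregnancy smoking x G1 ever smoking, adjusted for age, sex and 10
    PCs (sex omitted for women-only outcomes); sensitivity
    re-stratification by smoking before adult height (age 17 men / 15
    women) or before menarche.
g2_birthweight
    G2 birthweight per G1 allele within the 2x2 of G0 x G1 pregnancy
    smoking (G1 status derived by the whole-year rules; indeterminate
    women excluded and counted), adjusted for 10 PCs, with per-G1-stratum
    G0 differences and their difference-of-differences.
confounder_scan
    Instrument-dosage associations with smoking indicators and candidate
    confounders.
power
    Proxy-versus-direct power grid (delegates to :mod:`proxymr.power`).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PC_COLUMNS, check_columns, read_cohort, write_cohort
from .config import SimulationConfig
from .estimate import (
    DifferenceEstimate,
    HeterogeneityResult,
    StratumEstimate,
    cochran_q,
    confounder_scan,
    difference_of_differences,
    fit_association,
    stratify_and_fit,
    stratum_difference,
)
from .phenotypes import classify_cohort_pregnancy_smoking
from .power import run_power_study
from .simulate import generate_cohort

logger = logging.getLogger(__name__)

ANALYSES = (
    "g1_birthweight",
    "g1_adult_outcomes",
    "g2_birthweight",
    "confounder_scan",
    "power",
)

RESULT_COLUMNS = (
    "analysis",
    "model",
    "kind",
    "label",
    "n",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "z",
    "p",
    "family",
    "q_stat",
    "df",
    "odds_ratio",
    "converged",
    "note",
)

DEFAULT_SCAN_VARIABLES = (
    "g0_preg_smoker",
    "g1_ever",
    "confounder",
    "g1_age",
    "g1_sex",
    "pc1",
    "pc2",
)


@dataclass(frozen=True)
class AnalysisSpec:
    """One pipeline invocation: which analysis, on what data, written where."""

    analysis: str
    out_dir: str | Path
    config: SimulationConfig = field(default_factory=SimulationConfig)
    input_path: str | Path | None = None  # None -> simulate on the fly
    seed: int | None = None  # overrides config.seed
    # power-study grids
    n_grid: Sequence[int] = (10_000, 50_000, 200_000)
    effect_grid: Sequence[float] = (0.0, -0.01, -0.02, -0.04)
    reps: int = 500
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(
                f"unknown analysis {self.analysis!r}; choose from {ANALYSES}"
            )


def validate_config(path: str | Path) -> tuple[SimulationConfig | None, list[str]]:
    """Load a YAML config, returning every violation rather than the first."""
    try:
        config = SimulationConfig.from_yaml(str(path))
    except (OSError, ValueError) as exc:
        return None, [str(exc)]
    return config, config.validate()


# ----------------------------------------------------------------------
# result-row assembly


def _est_row(analysis: str, model: str, est: StratumEstimate) -> dict:
    return {
        "analysis": analysis,
        "model": model,
        "kind": "stratum",
        "label": est.stratum_label,
        "n": est.n,
        "estimate": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "z": est.beta / est.se if est.se else np.nan,
        "p": est.p,
        "family": est.family,
        "odds_ratio": est.odds_ratio,
        "converged": est.converged,
        "note": est.note,
    }


def _diff_row(analysis: str, model: str, kind: str, d: DifferenceEstimate) -> dict:
    return {
        "analysis": analysis,
        "model": model,
        "kind": kind,
        "label": d.label,
        "estimate": d.delta,
        "se": d.se,
        "ci_low": d.ci_low,
        "ci_high": d.ci_high,
        "z": d.z,
        "p": d.p,
    }


def _q_row(analysis: str, model: str, label: str, q: HeterogeneityResult) -> dict:
    return {
        "analysis": analysis,
        "model": model,
        "kind": "heterogeneity",
        "label": label,
        "q_stat": q.q_stat,
        "df": q.df,
        "p": q.p,
    }


# ----------------------------------------------------------------------
# individual analyses


def _analyze_g1_birthweight(cohort: pd.DataFrame, config: SimulationConfig) -> list[dict]:
    check_columns(cohort, ("g1_birthweight_kg", "g1_dosage", "g0_preg_smoker"))
    rows = []
    models = {"crude": (), "adjusted": ("g1_sex", *PC_COLUMNS)}
    for model, covs in models.items():
        if model == "adjusted":
            check_columns(cohort, covs)
        estimates = stratify_and_fit(
            cohort, "g1_birthweight_kg", ["g0_preg_smoker"], "linear", covs
        )
        rows += [_est_row("g1_birthweight", model, e) for e in estimates]
        if len(estimates) == 2:
            rows.append(
                _q_row(
                    "g1_birthweight",
                    model,
                    "g0_smoker_vs_nonsmoker",
                    cochran_q(estimates),
                )
            )
    return rows


def _sensitivity_class(cohort: pd.DataFrame, outcome_name: str) -> pd.Series | None:
    """Ever-smoked-before-outcome reclassification for height/menarche.

    Adult height is assumed fixed by 17 (men) / 15 (women); menarche uses
    each woman's own reported age. Returns 'ever_before' / 'never_before'
    with NA for indeterminate rows, or None when not applicable.
    """
    if "height" in outcome_name:
        threshold = np.where(cohort["g1_sex"] == 1, 15.0, 17.0)
    elif "menarche" in outcome_name:
        threshold = np.round(cohort[outcome_name].to_numpy(dtype=float))
    else:
        return None
    status = cohort["g1_smoking_status"].to_numpy(dtype=object)
    started = cohort["g1_age_started"].to_numpy(dtype=float, na_value=np.nan)
    out = np.full(len(cohort), pd.NA, dtype=object)
    never = status == "never"
    out[never] = "never_before"
    with np.errstate(invalid="ignore"):
        known = ~never & np.isfinite(started) & np.isfinite(threshold)
        out[known & (started < threshold)] = "ever_before"
        out[known & (started >= threshold)] = "never_before"
    return pd.Series(out, index=cohort.index, dtype="object")


def _analyze_adult_outcomes(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[list[dict], dict]:
    check_columns(
        cohort, ("g1_dosage", "g0_preg_smoker", "g1_ever", "g1_age", "g1_sex", *PC_COLUMNS)
    )
    rows: list[dict] = []
    counts: dict[str, int] = {}
    for spec in config.adult_outcome_specs:
        if spec.name not in cohort.columns:
            logger.warning("outcome %s not present in cohort; skipped", spec.name)
            continue
        sub = cohort[cohort["g1_sex"] == 1] if spec.women_only else cohort
        covs = ["g1_age", *PC_COLUMNS] if spec.women_only else [
            "g1_age", "g1_sex", *PC_COLUMNS
        ]
        family = {"linear": "linear", "binary": "logistic", "ordinal": "ordinal"}[
            spec.family
        ]
        estimates = stratify_and_fit(
            sub, spec.name, ["g0_preg_smoker", "g1_ever"], family, covs
        )
        rows += [_est_row("g1_adult_outcomes", spec.name, e) for e in estimates]
        for g1_val, tag in ((0, "g1_never"), (1, "g1_ever")):
            pair = [
                e
                for e in estimates
                if f"g1_ever={g1_val}" in e.stratum_label and e.converged
            ]
            if len(pair) == 2:
                rows.append(
                    _q_row(
                        "g1_adult_outcomes",
                        spec.name,
                        f"g0_interaction_{tag}",
                        cochran_q(pair),
                    )
                )
        sens = _sensitivity_class(sub, spec.name)
        if sens is not None:
            counts[f"{spec.name}_sensitivity_indeterminate"] = int(sens.isna().sum())
            sub2 = sub.assign(smoked_before_outcome=sens).dropna(
                subset=["smoked_before_outcome"]
            )
            estimates = stratify_and_fit(
                sub2, spec.name, ["g0_preg_smoker", "smoked_before_outcome"], family, covs
            )
            rows += [
                _est_row("g1_adult_outcomes", f"{spec.name}_sensitivity", e)
                for e in estimates
            ]
    return rows, counts


def _analyze_g2_birthweight(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[list[dict], dict]:
    check_columns(
        cohort,
        (
            "g2_birthweight_kg",
            "g1_dosage",
            "g0_preg_smoker",
            "g1_smoking_status",
            "g1_age_started",
            "g1_age_stopped",
            "g1_age_first_birth",
            *PC_COLUMNS,
        ),
    )
    women = cohort[cohort["g2_birthweight_kg"].notna()].copy()
    women["g1_preg_class"] = classify_cohort_pregnancy_smoking(women)
    n_indeterminate = int((women["g1_preg_class"] == "indeterminate").sum())
    logger.info(
        "G1 pregnancy-smoking derivation: %d indeterminate of %d women excluded "
        "from pregnancy-smoking strata",
        n_indeterminate,
        len(women),
    )
    covs = list(PC_COLUMNS)
    rows: list[dict] = []
    differences: dict[str, DifferenceEstimate] = {}
    # "all women" pair plus the two determinate G1 strata
    groups = {"g1_all": women}
    for cls in ("non_smoker", "smoker"):
        groups[f"g1_{cls}"] = women[women["g1_preg_class"] == cls]
    for tag, sub in groups.items():
        estimates = stratify_and_fit(
            sub, "g2_birthweight_kg", ["g0_preg_smoker"], "linear", covs
        )
        for e in estimates:
            rows.append(
                _est_row("g2_birthweight", tag, e)
            )
        if len(estimates) == 2:
            # estimates sorted by label: g0_preg_smoker=0 first
            diff = stratum_difference(
                estimates[1], estimates[0], label=f"{tag}:g0_smoker_minus_nonsmoker"
            )
            differences[tag] = diff
            rows.append(_diff_row("g2_birthweight", tag, "difference", diff))
            rows.append(
                _q_row("g2_birthweight", tag, "g0_smoker_vs_nonsmoker", cochran_q(estimates))
            )
    if "g1_smoker" in differences and "g1_non_smoker" in differences:
        dod = difference_of_differences(
            differences["g1_smoker"],
            differences["g1_non_smoker"],
            label="g1_smoker_minus_g1_non_smoker",
        )
        rows.append(
            _diff_row("g2_birthweight", "interaction", "difference_of_differences", dod)
        )
    counts = {
        "g2_women_with_birthweight": len(women),
        "g1_preg_indeterminate": n_indeterminate,
    }
    return rows, counts


def _analyze_confounders(cohort: pd.DataFrame) -> list[dict]:
    variables = [v for v in DEFAULT_SCAN_VARIABLES if v in cohort.columns]
    estimates = confounder_scan(cohort, "g1_dosage", variables)
    return [_est_row("confounder_scan", "overall", e) for e in estimates]


# ----------------------------------------------------------------------


def run_pipeline(spec: AnalysisSpec) -> dict[str, Path]:
    """Run one analysis end to end; returns paths of the written artifacts."""
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("proxymr")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        config = spec.config.require_valid()
        seed = spec.seed if spec.seed is not None else config.seed
        config = config.replace(seed=seed)
        counts: dict[str, int] = {}
        artifacts: dict[str, Path] = {"log": log_path}

        if spec.analysis == "power":
            results = run_power_study(
                config,
                n_grid=spec.n_grid,
                effect_grid=spec.effect_grid,
                reps=spec.reps,
                alpha=spec.alpha,
                seed=seed if seed is not None else 0,
            )
            frame = pd.DataFrame([r.__dict__ for r in results])
            n_tests = len(frame)
        else:
            if spec.input_path is not None:
                cohort = read_cohort(spec.input_path)
                logger.info("read cohort of %d families from %s", len(cohort), spec.input_path)
            else:
                cohort = generate_cohort(config)
                logger.info("simulated cohort of %d families", len(cohort))
            if spec.analysis == "g1_birthweight":
                rows = _analyze_g1_birthweight(cohort, config)
            elif spec.analysis == "g1_adult_outcomes":
                rows, counts = _analyze_adult_outcomes(cohort, config)
            elif spec.analysis == "g2_birthweight":
                rows, counts = _analyze_g2_birthweight(cohort, config)
            else:
                rows = _analyze_confounders(cohort)
            frame = pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)
            n_tests = int(frame["p"].notna().sum())

        results_path = out_dir / "results.csv"
        frame.to_csv(results_path, index=False, float_format="%.10g")
        artifacts["results"] = results_path

        summary = {
            "analysis": spec.analysis,
            "seed": seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "n_rows": len(frame),
            "n_tests": n_tests,
            "counts": counts,
        }
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        artifacts["summary"] = summary_path
        logger.info("wrote %s and %s", results_path, summary_path)
        return artifacts
    finally:
        root_logger.removeHandler(handler)
        handler.close()
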