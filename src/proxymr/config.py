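"""Simulation configuration for the three-generation smoking cohort.

All generative knobs of the simulator live in :class:`SimulationConfig`.
Defaults describe a UK-population-like cohort: a smoking-heaviness
instrument with effect-allele frequency 0.33, maternal pregnancy-smoking
prevalence 0.4, one cigarette/day per smoking-increasing allele among
smokers, and a -0.02 kg birthweight change per maternal cigarette/day.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

FAMILIES = ("linear", "binary", "ordinal")


@dataclass(frozen=True)
class AdultOutcomeSpec:
    """Generative recipe for one adult (G1) outcome.

    Parameters
    ----------
    name : outcome column name.
    family : "linear", "binary" or "ordinal".
    beta_own_cigs : effect of G1's own cigarettes/day (outcome units, or
        log-odds for binary/ordinal).
    beta_maternal_cigs : effect of G0 pregnancy cigarettes/day.
    noise_sd : residual SD (linear family only).
    n_categories : number of ordered levels (ordinal family only).
    baseline : intercept — outcome units for linear, log-odds of the
        prevalence for binary; ignored for ordinal (levels are cut at
        equal baseline probabilities).
    women_only : generate for women only (e.g. age at menarche).
    """

    name: str
    family: str
    beta_own_cigs: float = 0.0
    beta_maternal_cigs: float = 0.0
    noise_sd: float = 1.0
    n_categories: int = 0
    baseline: float = 0.0
    women_only: bool = False

    def validate(self) -> list[str]:
        problems = []
        if not self.name:
            problems.append("adult outcome with empty name")
        if self.family not in FAMILIES:
            problems.append(
                f"outcome {self.name!r}: family {self.family!r} not in {FAMILIES}"
            )
        if self.family == "linear" and self.noise_sd < 0:
            problems.append(f"outcome {self.name!r}: noise_sd must be >= 0")
        if self.family == "ordinal" and self.n_categories < 3:
            problems.append(
                f"outcome {self.name!r}: ordinal family needs n_categories >= 3"
            )
        return problems


@dataclass(frozen=True)
class SelectionModel:
    """Logistic participation model.

    P(retained) = expit(intercept + sum_j coefficients[col_j] * col_j).
    Columns are looked up in the cohort table at application time.
    """

    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        for key, val in dict(self.coefficients).items():
            if not isinstance(key, str):
                problems.append(f"selection coefficient key {key!r} is not a column name")
            try:
                float(val)
            except (TypeError, ValueError):
                problems.append(f"selection coefficient for {key!r} is not numeric")
        return problems


def default_adult_outcomes() -> tuple[AdultOutcomeSpec, ...]:
    """Representative adult-outcome set spanning the three model families.

    Own-smoking effects follow established findings (heavier smoking lowers
    BMI and lung function); maternal effects default to zero, the null the
    interaction tests are calibrated against.
    """
    return (
        AdultOutcomeSpec("height_cm", "linear", 0.0, 0.0, 6.5, baseline=168.0),
        AdultOutcomeSpec("bmi", "linear", -0.10, 0.0, 4.0, baseline=27.0),
        AdultOutcomeSpec("fev1_l", "linear", -0.02, 0.0, 0.7, baseline=2.8),
        AdultOutcomeSpec("asthma", "binary", 0.0, 0.0, baseline=-2.0),
        AdultOutcomeSpec("depression_anxiety", "binary", 0.01, 0.0, baseline=-0.85),
        AdultOutcomeSpec("happiness", "ordinal", 0.01, 0.0, n_categories=6),
        AdultOutcomeSpec(
            "menarche_age", "linear", 0.0, 0.0, 1.5, baseline=13.0, women_only=True
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the three-generation model.

    Generations: G0 = participants' mothers, G1 = participants,
    G2 = first child of G1 women. The instrument is an additively coded
    0/1/2 dosage of the smoking-increasing allele; it shifts cigarettes/day
    among smokers only.
    """

    n_families: int = 10_000
    allele_freq: float = 0.33
    p_g0_smoker: float = 0.4
    p_g1_ever: float = 0.45
    p_g1_preg_smoker: float = 0.35  # P(smoked in first pregnancy | ever smoker)
    p_current_given_ever: float = 0.4
    p_first_birth: float = 0.85
    intergen_smoking_or: float = 1.5
    or_gene_smoker: float = 1.0  # odds ratio per allele on smoking-status odds
    beta_gene_cigs: float = 1.0  # cigarettes/day per allele, among smokers
    cigs_base_mean: float = 15.0
    cigs_base_sd: float = 8.0
    beta_cigs_bw_g1: float = -0.02  # kg per maternal (G0) cigarette/day
    beta_cigs_bw_g2: float = -0.02  # kg per maternal (G1) cigarette/day
    beta_g0cigs_g2: float = 0.0  # grandmaternal pathway, kg per G0 cigarette/day
    bw_mean: float = 3.4
    bw_sd: float = 0.5
    sex_effect_bw: float = -0.12  # kg, female vs male birthweight
    confounder_smoking: float = 0.3  # log-odds of smoking per SD of confounder
    confounder_outcome: float = 0.1  # outcome units per SD of confounder
    adult_outcome_specs: tuple[AdultOutcomeSpec, ...] = field(
        default_factory=default_adult_outcomes
    )
    misclass_g0: float = 0.0
    misclass_g1: float = 0.0
    selection_model: SelectionModel | None = None
    include_g2: bool = True
    clone_transmission: bool = False  # test-only: child copies maternal genotype
    seed: int | None = None

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of every invariant violation (empty when valid)."""
        problems = []
        if not (isinstance(self.n_families, int) and self.n_families >= 1):
            problems.append(f"n_families must be a positive integer, got {self.n_families!r}")
        if not 0.0 < self.allele_freq < 1.0:
            problems.append(f"allele_freq must be in (0, 1), got {self.allele_freq!r}")
        for name in (
            "p_g0_smoker",
            "p_g1_ever",
            "p_g1_preg_smoker",
            "p_current_given_ever",
            "p_first_birth",
            "misclass_g0",
            "misclass_g1",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                problems.append(f"{name} must be a probability in [0, 1], got {val!r}")
        if self.intergen_smoking_or <= 0:
            problems.append(f"intergen_smoking_or must be > 0, got {self.intergen_smoking_or!r}")
        if self.or_gene_smoker <= 0:
            problems.append(f"or_gene_smoker must be > 0, got {self.or_gene_smoker!r}")
        if self.cigs_base_mean < 0:
            problems.append(f"cigs_base_mean must be >= 0, got {self.cigs_base_mean!r}")
        if self.cigs_base_sd <= 0:
            problems.append(f"cigs_base_sd must be > 0, got {self.cigs_base_sd!r}")
        if self.bw_sd <= 0:
            problems.append(f"bw_sd must be > 0, got {self.bw_sd!r}")
        for spec in self.adult_outcome_specs:
            problems.extend(spec.validate())
        names = [s.name for s in self.adult_outcome_specs]
        if len(set(names)) != len(names):
            problems.append("duplicate adult outcome names")
        if self.selection_model is not None:
            problems.extend(self.selection_model.validate())
        if self.seed is not None and not isinstance(self.seed, int):
            problems.append(f"seed must be an integer or None, got {self.seed!r}")
        return problems

    def require_valid(self) -> "SimulationConfig":
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimulationConfig:\n- " + "\n- ".join(problems))
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["adult_outcome_specs"] = [dataclasses.asdict(s) for s in self.adult_outcome_specs]
        if self.selection_model is not None:
            d["selection_model"] = {
                "intercept": self.selection_model.intercept,
                "coefficients": dict(self.selection_model.coefficients),
            }
        return d

    def config_hash(self) -> str:
        """Stable hash identifying the generative setup (seed excluded)."""
        d = self.to_dict()
        d.pop("seed", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {', '.join(unknown)}; "
                f"known keys: {', '.join(sorted(known))}"
            )
        kwargs = dict(data)
        if "adult_outcome_specs" in kwargs and kwargs["adult_outcome_specs"] is not None:
            specs = []
            for item in kwargs["adult_outcome_specs"]:
                if isinstance(item, AdultOutcomeSpec):
                    specs.append(item)
                else:
                    specs.append(AdultOutcomeSpec(**item))
            kwargs["adult_outcome_specs"] = tuple(specs)
        sel = kwargs.get("selection_model")
        if sel is not None and not isinstance(sel, SelectionModel):
            kwargs["selection_model"] = SelectionModel(
                intercept=float(sel.get("intercept", 0.0)),
                coefficients=dict(sel.get("coefficients", {})),
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        """Load a config from YAML, rejecting unknown keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
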