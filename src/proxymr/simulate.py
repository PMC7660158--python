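"""Three-generation synthetic cohort generator.

The causal structure mirrors the proxy gene-by-environment MR design:

* G0 (mother) genotype drawn at Hardy–Weinberg proportions; G1 receives
  one maternal allele by Mendelian transmission plus one paternal allele
  drawn from the population frequency (random mating, paternal genotype
  marginalised).
* The instrument shifts cigarettes/day among smokers only; never smokers
  have exactly zero cigarette-mediated effect on every outcome.
* G1 birthweight responds linearly to G0 pregnancy cigarettes/day;
  G2 birthweight to G1 pregnancy cigarettes/day, with an optional
  grandmaternal (G0) term.
* A standard-normal family confounder loads on smoking propensity and on
  outcomes; reporting misclassification and selection are explicit
  operators so bias studies can switch them on independently.

Smoking start/stop ages of G1 women with a birth are generated
consistently with their true pregnancy-smoking status, so the rule-based
derivation in :mod:`proxymr.phenotypes` recovers the truth on every
determinate row.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import logistic as _logistic_dist

from .cohort import PC_COLUMNS
from .config import SelectionModel, SimulationConfig

__all__ = [
    "sample_parent_genotypes",
    "sample_child_dosage",
    "assign_smoking",
    "generate_cohort",
    "apply_reporting_error",
    "apply_selection",
]


def sample_parent_genotypes(
    allele_freq: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. Binomial(2, allele_freq) dosages (Hardy–Weinberg).

    Degenerate frequencies 0 and 1 are permitted (useful in tests).
    """
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele_freq must be in [0, 1], got {allele_freq!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    return rng.binomial(2, allele_freq, size=n).astype(np.int8)


def sample_child_dosage(
    maternal_dosage: np.ndarray | int,
    allele_freq: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mendelian transmission: one maternal allele, one paternal from the population.

    Returns ``(child_dosage, maternal_allele)`` where ``maternal_allele`` is
    the transmitted 0/1 indicator, kept so transmission is traceable.
    """
    m = np.atleast_1d(np.asarray(maternal_dosage))
    if not np.isin(m, (0, 1, 2)).all():
        raise ValueError("maternal dosage values must be in {0, 1, 2}")
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele_freq must be in [0, 1], got {allele_freq!r}")
    maternal_allele = rng.binomial(1, m / 2.0)
    paternal_allele = rng.binomial(1, allele_freq, size=m.shape)
    child = (maternal_allele + paternal_allele).astype(np.int8)
    return child, maternal_allele.astype(np.int8)


def _truncated_cigs(
    dosage: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    mean = config.cigs_base_mean + config.beta_gene_cigs * dosage
    return np.maximum(0.0, rng.normal(mean, config.cigs_base_sd))


def assign_smoking(
    dosage: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    role: str = "G0",
    confounder: np.ndarray | None = None,
    g0_smoked: np.ndarray | None = None,
    p_smoker: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw smoking status and cigarettes/day for one generation.

    Status comes from a logistic model on the confounder and — for G1 —
    the intergenerational odds ratio given G0 pregnancy smoking. Among
    smokers, cigarettes/day = max(0, Normal(base_mean + beta_gene * dosage,
    base_sd)); never smokers get exactly 0.

    Returns ``(smoker, cigs)`` with ``smoker`` a boolean array.
    """
    dosage = np.asarray(dosage)
    n = dosage.shape[0]
    if p_smoker is None:
        p_smoker = config.p_g0_smoker if role == "G0" else config.p_g1_ever
    if p_smoker in (0.0, 1.0):
        eta = np.full(n, -np.inf if p_smoker == 0.0 else np.inf)
    else:
        eta = np.full(n, logit(p_smoker))
        if confounder is not None:
            eta = eta + config.confounder_smoking * np.asarray(confounder)
        if role == "G1" and g0_smoked is not None:
            eta = eta + np.log(config.intergen_smoking_or) * np.asarray(g0_smoked)
        if config.or_gene_smoker != 1.0:
            # departure from a clean G-by-E instrument, for bias studies
            eta = eta + np.log(config.or_gene_smoker) * dosage
    smoker = rng.random(n) < expit(eta)
    cigs = np.where(smoker, _truncated_cigs(dosage, config, rng), 0.0)
    return smoker, cigs


def _bounded_uniform_int(
    u: np.ndarray, low: np.ndarray, high: np.ndarray
) -> np.ndarray:
    """Map uniforms in [0,1) to integers in [low, high] (element-wise)."""
    span = np.maximum(high - low + 1, 1)
    return (low + np.floor(u * span)).astype(float)


def _smoking_ages(
    n: int,
    ever: np.ndarray,
    current: np.ndarray,
    has_birth: np.ndarray,
    preg: np.ndarray,
    b: np.ndarray,
    age: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer start/stop smoking ages consistent with pregnancy status.

    For mothers, ages are placed so the rule-based pregnancy-smoking
    derivation is determinate and recovers the true flag; for everyone
    else ages are merely plausible (start 14–25, stop before baseline).
    """
    u1 = rng.random(n)
    u2 = rng.random(n)
    u3 = rng.random(n)

    started = np.full(n, np.nan)
    stopped = np.full(n, np.nan)
    former = ever & ~current
    other = ever & ~has_birth  # men and women without a first birth

    started[other] = _bounded_uniform_int(
        u1[other], np.full(other.sum(), 14), np.full(other.sum(), 25)
    )
    m = other & former
    stopped[m] = _bounded_uniform_int(u2[m], started[m] + 1, age[m])

    mothers = ever & has_birth
    # pregnancy smokers: started <= b-1; former ones stopped >= b+1
    m = mothers & preg
    started[m] = _bounded_uniform_int(u1[m], np.maximum(12, b[m] - 12), b[m] - 1)
    m = mothers & preg & former
    stopped[m] = _bounded_uniform_int(u2[m], b[m] + 1, np.minimum(age[m], b[m] + 12))
    # non-pregnancy smokers, current: started >= b+1
    m = mothers & ~preg & current
    started[m] = _bounded_uniform_int(u1[m], b[m] + 1, np.minimum(age[m], b[m] + 8))
    # non-pregnancy smokers, former: late start or early quit
    late = mothers & ~preg & former & (u3 < 0.5)
    started[late] = _bounded_uniform_int(
        u1[late], b[late] + 1, np.minimum(age[late] - 1, b[late] + 6)
    )
    stopped[late] = _bounded_uniform_int(u2[late], started[late] + 1, age[late])
    early = mothers & ~preg & former & (u3 >= 0.5)
    started[early] = _bounded_uniform_int(
        u1[early], np.maximum(12, b[early] - 14), b[early] - 3
    )
    stopped[early] = _bounded_uniform_int(u2[early], started[early], b[early] - 2)
    return started, stopped


def generate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a full three-generation cohort table.

    Bit-reproducible given ``config.seed`` (or an explicitly passed ``rng``).
    Misclassification and selection operators are applied last when their
    config parameters are active, so the returned table is analysis-ready.
    """
    config.require_valid()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_families

    g0_dosage = sample_parent_genotypes(config.allele_freq, n, rng)
    if config.clone_transmission:
        g1_dosage = g0_dosage.copy()
        maternal_allele = np.minimum(g0_dosage, 1)
    else:
        g1_dosage, maternal_allele = sample_child_dosage(
            g0_dosage, config.allele_freq, rng
        )
    confounder = rng.standard_normal(n)

    g0_smoker, g0_cigs = assign_smoking(
        g0_dosage, config, rng, role="G0", confounder=confounder
    )

    g1_sex = rng.binomial(1, 0.5, size=n)  # 1 = female
    g1_birthweight = (
        config.bw_mean
        + config.beta_cigs_bw_g1 * g0_cigs
        + config.sex_effect_bw * g1_sex
        + config.confounder_outcome * confounder
        + rng.normal(0.0, config.bw_sd, size=n)
    )

    g1_ever, g1_cigs = assign_smoking(
        g1_dosage,
        config,
        rng,
        role="G1",
        confounder=confounder,
        g0_smoked=g0_smoker,
    )
    g1_current = g1_ever & (rng.random(n) < config.p_current_given_ever)
    status = np.where(g1_current, "current", np.where(g1_ever, "former", "never"))

    g1_age = rng.integers(40, 70, size=n)
    women = g1_sex == 1
    has_birth = women & (rng.random(n) < config.p_first_birth)
    # clipped so consistent smoking ages always exist given baseline age >= 40
    b_all = np.clip(np.round(rng.normal(26.0, 4.0, size=n)), 16, 38)
    g1_preg = has_birth & g1_ever & (rng.random(n) < config.p_g1_preg_smoker)

    started, stopped = _smoking_ages(
        n, g1_ever, g1_current, has_birth, g1_preg, b_all, g1_age, rng
    )
    g1_preg_cigs = np.where(g1_preg, g1_cigs, 0.0)

    df = pd.DataFrame(
        {
            "family_id": np.arange(n),
            "g0_dosage": g0_dosage,
            "g1_dosage": g1_dosage,
            "g1_maternal_allele": maternal_allele,
            "confounder": confounder,
            "g0_preg_smoker_true": g0_smoker.astype(int),
            "g0_preg_smoker": g0_smoker.astype(int),
            "g0_cigs": g0_cigs,
            "g1_sex": g1_sex,
            "g1_birthweight_kg": g1_birthweight,
            "g1_smoking_status": status,
            "g1_age_started": pd.array(started, dtype="Int64"),
            "g1_age_stopped": pd.array(stopped, dtype="Int64"),
            "g1_ever_true": g1_ever.astype(int),
            "g1_ever": g1_ever.astype(int),
            "g1_cigs": g1_cigs,
            "g1_age": g1_age,
            "g1_age_first_birth": pd.array(
                np.where(has_birth, b_all, np.nan), dtype="Int64"
            ),
            "g1_preg_smoker_true": np.where(
                has_birth, g1_preg.astype(float), np.nan
            ),
        }
    )

    if config.include_g2:
        g2_bw = (
            config.bw_mean
            + config.beta_cigs_bw_g2 * g1_preg_cigs
            + config.beta_g0cigs_g2 * g0_cigs
            + config.confounder_outcome * confounder
            + rng.normal(0.0, config.bw_sd, size=n)
        )
        df["g2_birthweight_kg"] = np.where(has_birth, g2_bw, np.nan)

    for i, col in enumerate(PC_COLUMNS):
        df[col] = rng.standard_normal(n)

    for spec in config.adult_outcome_specs:
        linpred = (
            spec.beta_own_cigs * g1_cigs
            + spec.beta_maternal_cigs * g0_cigs
            + config.confounder_outcome * confounder
        )
        if spec.family == "linear":
            vals = spec.baseline + linpred + rng.normal(0.0, spec.noise_sd, size=n)
        elif spec.family == "binary":
            vals = (rng.random(n) < expit(spec.baseline + linpred)).astype(float)
        else:  # ordinal: latent logistic cut at equal baseline probabilities
            latent = linpred + _logistic_dist.rvs(size=n, random_state=rng)
            cuts = _logistic_dist.ppf(np.arange(1, spec.n_categories) / spec.n_categories)
            vals = 1.0 + (latent[:, None] > cuts[None, :]).sum(axis=1)
        if spec.women_only:
            vals = np.where(women, vals, np.nan)
        df[spec.name] = vals

    if config.misclass_g0 > 0 or config.misclass_g1 > 0:
        df = apply_reporting_error(df, config.misclass_g0, config.misclass_g1, rng)
    if config.selection_model is not None:
        df = apply_selection(df, config.selection_model, rng)
    return df


def apply_reporting_error(
    cohort: pd.DataFrame,
    flip_prob_g0: float,
    flip_prob_g1: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flip the reported smoking indicators; truth columns are untouched.

    ``g0_preg_smoker`` and ``g1_ever`` flip independently with the given
    probabilities, starting from the ``*_true`` columns.
    """
    for p in (flip_prob_g0, flip_prob_g1):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"flip probability must be in [0, 1], got {p!r}")
    out = cohort.copy()
    n = len(out)
    flip0 = rng.random(n) < flip_prob_g0
    flip1 = rng.random(n) < flip_prob_g1
    out["g0_preg_smoker"] = np.where(
        flip0, 1 - out["g0_preg_smoker_true"], out["g0_preg_smoker_true"]
    )
    out["g1_ever"] = np.where(flip1, 1 - out["g1_ever_true"], out["g1_ever_true"])
    return out


def apply_selection(
    cohort: pd.DataFrame, selection_model: SelectionModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Retain rows independently with logistic participation probability.

    The pre-selection row count is recorded in ``DataFrame.attrs``
    under ``n_before_selection``.
    """
    eta = np.full(len(cohort), float(selection_model.intercept))
    for col, coef in dict(selection_model.coefficients).items():
        if col not in cohort.columns:
            raise KeyError(f"selection model refers to missing column {col!r}")
        eta = eta + float(coef) * cohort[col].to_numpy(dtype=float)
    prob = expit(eta)
    if np.any(prob < 0) or np.any(prob > 1) or np.any(~np.isfinite(prob)):
        raise ValueError("selection model produced probabilities outside [0, 1]")
    keep = rng.random(len(cohort)) < prob
    out = cohort.loc[keep].reset_index(drop=True)
    out.attrs["n_before_selection"] = len(cohort)
    return out
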