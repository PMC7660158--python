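"""Power and calibration studies for proxy versus direct G×E MR.

The direct design stratifies offspring birthweight on maternal (G0)
pregnancy smoking and uses the *maternal* genotype as instrument; the
proxy design uses the *offspring* genotype instead. Because the
offspring dosage carries one paternal allele drawn from the population,
its regression on any maternal-genotype-mediated outcome is attenuated
by exactly 1/2 under random mating, which lowers the noncentrality of
the interaction (Cochran's Q) test — these studies quantify that cost.

Replicate seeds are spawned deterministically from the master seed via
``numpy.random.SeedSequence`` so every cell is independently
reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .config import SimulationConfig
from .estimate import cochran_q, fit_association
from .simulate import generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PowerResult",
    "Type1ErrorResult",
    "AttenuationResult",
    "run_power_study",
    "type1_error_study",
    "attenuation_estimate",
]

DESIGN_EXPOSURE = {"proxy": "g1_dosage", "direct": "g0_dosage"}


@dataclass(frozen=True)
class PowerResult:
    """Interaction-test rejection rate for one (design, n, effect) cell."""

    design: str
    n_families: int
    effect_size: float  # kg per cigarette/day
    per_allele_effect: float  # effect_size * beta_gene_cigs
    reps: int
    n_valid: int
    alpha: float
    power: float
    mc_se: float
    valid: bool = True


@dataclass(frozen=True)
class Type1ErrorResult:
    rate: float
    ci_low: float
    ci_high: float
    reps: int
    alpha: float


@dataclass(frozen=True)
class AttenuationResult:
    """Proxy/direct slope ratio in the exposed stratum over replicates."""

    mean_ratio: float
    ci_low: float  # percentile interval of replicate ratios
    ci_high: float
    mc_se: float  # Monte-Carlo SE of the mean ratio
    ratios: tuple[float, ...]
    n_excluded: int
    reps: int


def _lean(config: SimulationConfig, n: int, effect: float) -> SimulationConfig:
    """Strip generation the birthweight interaction test never touches."""
    return config.replace(
        n_families=int(n),
        beta_cigs_bw_g1=float(effect),
        adult_outcome_specs=(),
        include_g2=False,
        seed=None,
    )


def _interaction_p(cohort, exposure_col: str) -> float | None:
    """Two-stratum Cochran's Q p for G1 birthweight by G0 smoking (crude)."""
    estimates = []
    for value in (0, 1):
        sub = cohort[cohort["g0_preg_smoker"] == value]
        if len(sub) < 50:
            return None
        try:
            estimates.append(
                fit_association(
                    sub["g1_birthweight_kg"], sub[exposure_col], None, "linear"
                )
            )
        except ValueError:
            return None
    return cochran_q(estimates).p


def run_power_study(
    base_config: SimulationConfig,
    n_grid: Sequence[int] = (10_000, 50_000, 200_000),
    effect_grid: Sequence[float] = (0.0, -0.01, -0.02, -0.04),
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    designs: Sequence[str] = ("direct", "proxy"),
) -> list[PowerResult]:
    """Simulated power of the interaction test over a (n, effect) grid.

    Each replicate cohort is analysed under every requested design
    (shared cohorts make the proxy/direct comparison paired). Power is
    the fraction of valid replicates with interaction p < alpha, with
    binomial Monte-Carlo SE.
    """
    if reps < 1 or not n_grid or not effect_grid:
        raise ValueError("reps must be >= 1 and both grids nonempty")
    for d in designs:
        if d not in DESIGN_EXPOSURE:
            raise ValueError(f"unknown design {d!r}; choose from {set(DESIGN_EXPOSURE)}")
    root = np.random.SeedSequence(seed)
    results: list[PowerResult] = []
    for cell_ss, (n, effect) in zip(
        root.spawn(len(n_grid) * len(effect_grid)),
        [(n, e) for n in n_grid for e in effect_grid],
    ):
        config = _lean(base_config, n, effect)
        rejections = {d: 0 for d in designs}
        n_valid = {d: 0 for d in designs}
        for rep_ss in cell_ss.spawn(reps):
            cohort = generate_cohort(config, rng=np.random.default_rng(rep_ss))
            for d in designs:
                p = _interaction_p(cohort, DESIGN_EXPOSURE[d])
                if p is None:
                    continue
                n_valid[d] += 1
                rejections[d] += p < alpha
        for d in designs:
            valid = n_valid[d] > 0
            if not valid:
                logger.warning(
                    "power cell n=%d effect=%g design=%s invalid: no usable replicates",
                    n, effect, d,
                )
            power = rejections[d] / n_valid[d] if valid else np.nan
            mc_se = (
                float(np.sqrt(power * (1 - power) / n_valid[d])) if valid else np.nan
            )
            results.append(
                PowerResult(
                    design=d,
                    n_families=int(n),
                    effect_size=float(effect),
                    per_allele_effect=float(effect * base_config.beta_gene_cigs),
                    reps=reps,
                    n_valid=n_valid[d],
                    alpha=alpha,
                    power=power,
                    mc_se=mc_se,
                    valid=valid,
                )
            )
    return results


def type1_error_study(
    null_config: SimulationConfig,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    design: str = "proxy",
) -> Type1ErrorResult:
    """Rejection rate of the interaction test under the maternal-effect null.

    Requires every maternal-effect parameter of the config to be zero;
    returns the rate with an exact (Clopper–Pearson) binomial CI.
    """
    maternal = {
        "beta_cigs_bw_g1": null_config.beta_cigs_bw_g1,
        "beta_cigs_bw_g2": null_config.beta_cigs_bw_g2,
        "beta_g0cigs_g2": null_config.beta_g0cigs_g2,
        **{
            f"{s.name}.beta_maternal_cigs": s.beta_maternal_cigs
            for s in null_config.adult_outcome_specs
        },
    }
    nonzero = [k for k, v in maternal.items() if v != 0]
    if nonzero:
        raise ValueError(
            "null_config has nonzero maternal-effect parameters: " + ", ".join(nonzero)
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha!r}")
    config = _lean(null_config, null_config.n_families, 0.0)
    root = np.random.SeedSequence(seed)
    k = 0
    n_valid = 0
    for rep_ss in root.spawn(reps):
        cohort = generate_cohort(config, rng=np.random.default_rng(rep_ss))
        p = _interaction_p(cohort, DESIGN_EXPOSURE[design])
        if p is None:
            continue
        n_valid += 1
        k += p < alpha
    ci = binomtest(k, n_valid).proportion_ci(confidence_level=0.95, method="exact")
    return Type1ErrorResult(
        rate=k / n_valid, ci_low=ci.low, ci_high=ci.high, reps=n_valid, alpha=alpha
    )


def attenuation_estimate(
    config: SimulationConfig,
    n: int = 200_000,
    reps: int = 50,
    seed: int = 0,
) -> AttenuationResult:
    """Ratio of proxy to direct per-allele slope in the exposed stratum.

    Under random mating the offspring dosage regression recovers exactly
    half the maternal-dosage slope, so the ratio converges to 0.5 (and to
    1.0 in the test-only clone-transmission mode). Replicates where the
    direct slope is indistinguishable from zero (|z| < 2) are excluded
    and counted.
    """
    if config.beta_cigs_bw_g1 == 0:
        raise ValueError("attenuation requires a nonzero maternal effect")
    lean = _lean(config, n, config.beta_cigs_bw_g1)
    root = np.random.SeedSequence(seed)
    ratios = []
    n_excluded = 0
    for rep_ss in root.spawn(reps):
        cohort = generate_cohort(lean, rng=np.random.default_rng(rep_ss))
        exposed = cohort[cohort["g0_preg_smoker"] == 1]
        direct = fit_association(
            exposed["g1_birthweight_kg"], exposed["g0_dosage"], None, "linear"
        )
        if abs(direct.beta / direct.se) < 2:
            n_excluded += 1
            continue
        proxy = fit_association(
            exposed["g1_birthweight_kg"], exposed["g1_dosage"], None, "linear"
        )
        ratios.append(proxy.beta / direct.beta)
    if not ratios:
        raise RuntimeError("no replicate had a detectable direct slope")
    arr = np.asarray(ratios)
    return AttenuationResult(
        mean_ratio=float(arr.mean()),
        ci_low=float(np.percentile(arr, 2.5)),
        ci_high=float(np.percentile(arr, 97.5)),
        mc_se=float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan,
        ratios=tuple(float(r) for r in arr),
        n_excluded=n_excluded,
        reps=reps,
    )
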