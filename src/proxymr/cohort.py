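"""Cohort table schema and delimited-text I/O.

A cohort is a :class:`pandas.DataFrame`, one row per family (G0 mother,
G1 participant, and — for G1 women with a first birth — G2 child).

Core columns
------------
family_id              int, unique
g0_dosage, g1_dosage   instrument dosage, 0/1/2 smoking-increasing alleles
g1_maternal_allele     0/1, the allele G1 received from G0
confounder             standard-normal family confounder (simulation truth)
g0_preg_smoker_true    1 if G0 smoked in the pregnancy of G1 (truth)
g0_preg_smoker         reported indicator (equals truth unless misclassified)
g0_cigs                G0 cigarettes/day in pregnancy (0 for non-smokers)
g1_sex                 0 = male, 1 = female
g1_birthweight_kg      G1 birthweight
g1_smoking_status      'never' | 'former' | 'current'
g1_age_started         integer age started smoking (missing for never)
g1_age_stopped         integer age stopped (former only)
g1_ever_true, g1_ever  ever-smoker indicator, truth and reported
g1_cigs                G1 cigarettes/day (0 for never smokers)
g1_age                 age at baseline, whole years
g1_age_first_birth     age at first birth (women with a birth)
g1_preg_smoker_true    1 if G1 smoked in her first pregnancy (truth)
g2_birthweight_kg      first child's birthweight (women with a birth)
pc1..pc10              nuisance covariates emulating genetic PCs
plus one column per configured adult outcome.

Missing values are written as empty fields; CSV or TSV is chosen from the
file extension.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))

REQUIRED_COLUMNS = (
    "family_id",
    "g0_dosage",
    "g1_dosage",
    "g0_preg_smoker",
    "g1_sex",
)

_INT_NULLABLE = ("g1_age_started", "g1_age_stopped", "g1_age_first_birth")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV/TSV with empty-string missing values."""
    cohort.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in _INT_NULLABLE:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def check_columns(cohort: pd.DataFrame, needed: tuple[str, ...]) -> None:
    """Raise with the full missing list if required columns are absent."""
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise KeyError(
            f"cohort is missing required column(s): {', '.join(missing)}; "
            f"available: {', '.join(cohort.columns)}"
        )


def read_dosage_vcf(path: str | Path, effect_allele: str) -> np.ndarray:
    """Read 0/1/2 effect-allele dosages from a single-variant VCF.

    Uses the DS FORMAT field when present, otherwise counts effect alleles
    in GT. The variant's REF or ALT must match ``effect_allele``; dosages
    are flipped when the effect allele is REF.
    """
    from cyvcf2 import VCF  # optional dependency

    variants = list(VCF(str(path)))
    if len(variants) != 1:
        raise ValueError(f"expected a single-variant VCF, found {len(variants)} records")
    v = variants[0]
    alts = list(v.ALT)
    if effect_allele == v.REF:
        flip = True
    elif effect_allele in alts:
        flip = False
    else:
        raise ValueError(
            f"effect allele {effect_allele!r} matches neither REF {v.REF!r} nor ALT {alts}"
        )
    try:
        ds = v.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        dosage = np.asarray(ds, dtype=float).reshape(-1)
    else:
        gts = np.asarray(v.genotypes, dtype=object)
        dosage = np.array([int(g[0] > 0) + int(g[1] > 0) for g in gts], dtype=float)
    if flip:
        dosage = 2.0 - dosage
    if np.nanmin(dosage) < 0 or np.nanmax(dosage) > 2:
        raise ValueError("dosages outside [0, 2] after allele alignment")
    return dosage
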