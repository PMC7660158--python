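# proxymr

Proxy gene-by-environment Mendelian randomization (G×E MR) for
transgenerational questions: does maternal smoking heaviness in pregnancy
causally affect offspring birthweight, offspring adult health, or
grandchild birthweight — when the maternal genotype was never measured?

## The design

A smoking-heaviness instrument (an rs16969968/*CHRNA5*-like SNP, coded
0/1/2 smoking-increasing alleles) shifts cigarettes/day among smokers
only. In a G×E MR design one therefore expects a per-allele association
with the outcome *only* in the smoking-exposed stratum; heterogeneity of
the stratum associations (Cochran's Q) is evidence of a causal effect via
smoking heaviness.

When the mother's (G0) genotype is unavailable, her offspring's (G1)
genotype can proxy for it: under random mating

    E[G1 dosage | G0 dosage] = G0 dosage / 2 + p,

so a regression on the offspring dosage recovers exactly **half** the
maternal per-allele slope — the other half of the offspring instrument is
of paternal origin. The package implements this proxy design end to end:

- **`proxymr.simulate`** — a three-generation cohort simulator
  (Hardy–Weinberg G0 genotypes, Mendelian transmission, genotype-dependent
  smoking heaviness among smokers, per-cigarette birthweight effects,
  confounding, misclassification and selection operators);
- **`proxymr.phenotypes`** — the whole-year rule-based derivation of
  "smoked in first pregnancy" from smoking history and age at first
  birth, with explicit indeterminate cases;
- **`proxymr.estimate`** — stratified per-allele fits (linear / logistic /
  proportional-odds ordinal), Cochran's Q heterogeneity, stratum
  differences and the difference-of-differences interaction, and an
  instrument–confounder scan;
- **`proxymr.power`** — power, type-I error and attenuation studies
  comparing the proxy (offspring-genotype) and direct (maternal-genotype)
  designs;
- **`proxymr.cli` / `proxymr.pipeline`** — a `proxymr` command with
  `simulate`, `derive`, `analyze`, `power` and `validate` subcommands.

## Worked example

```python
from proxymr import SimulationConfig, generate_cohort, stratify_and_fit, cochran_q

config = SimulationConfig(n_families=200_000, seed=1)  # defaults: 1 cig/day
cohort = generate_cohort(config)                       # per allele, -0.02 kg/cig

estimates = stratify_and_fit(
    cohort, "g1_birthweight_kg", ["g0_preg_smoker"], "linear",
    covariate_names=["g1_sex", *[f"pc{i}" for i in range(1, 11)]],
)
for e in estimates:
    print(f"{e.stratum_label}: {e.beta:+.4f} kg/allele "
          f"(95% CI {e.ci_low:+.4f}, {e.ci_high:+.4f}), n={e.n}")
print(f"interaction p = {cochran_q(estimates).p:.4g}")
```

prints

```
g0_preg_smoker=0: -0.0013 kg/allele (95% CI -0.0056, +0.0031), n=119934
g0_preg_smoker=1: -0.0109 kg/allele (95% CI -0.0165, -0.0054), n=80066
interaction p = 0.007422
```

The per-allele deficit appears only among offspring of pregnancy smokers
— the G×E signature — and its size is about half of the implanted
maternal-genotype effect (1 cig/day/allele × −0.02 kg/cig = −0.02 kg;
the proxy recovers ≈ −0.01 kg/allele) because half of the offspring
instrument is paternal.

The same analyses are available from the shell:

```sh
proxymr simulate --seed 1 --n-families 200000 --out cohort.csv
proxymr analyze --analysis g1_birthweight --in cohort.csv --out results/
proxymr power --out power/ --reps 200 --n-grid 10000,50000 --effect-grid 0,-0.02
```

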