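# tadrive

Genotype-to-phenotype modeling, rate inference and forward simulation for
CRISPR **toxin-antidote gene drives** (TADE modification, TADE suppression,
TARE) in a split-drive *Drosophila* setting.

The package models three unlinked autosomal loci — the drive allele
(gRNAs + recoded rescue + DsRed), a supporting Cas9 allele (EGFP), and the
essential target gene — with a dosage viability rule: haplolethal targets
need two functional doses (TADE), haplosufficient targets one (TARE).
Wild-type target alleles can be disrupted in the germline of drive+Cas9
parents, disrupted in the embryo by maternally deposited Cas9/gRNA, or
converted to functional recoded alleles by homology-directed repair off a
minimally recoded rescue element.

## Modules

| module | what it does |
| --- | --- |
| `tadrive.genetics` | allele/genotype/architecture types, dosage viability, female fertility, fluorescence markers |
| `tadrive.cross` | deterministic gamete and offspring enumeration for one cross: expected egg-to-adult viability and drive (DsRed) inheritance; zero-survivor confidence bounds |
| `tadrive.inference` | closed-form cut-rate/resistance-rate estimators from pooled viabilities; binomial / beta-binomial maximum likelihood on vial counts with profile-likelihood CIs; exact binomial and Fisher tests |
| `tadrive.popsim` | discrete-generation deterministic/stochastic population recursion, genetic load, introduction-threshold bisection |
| `tadrive.synth` | synthetic vial-count datasets with known ground truth (binomial survival, logit-normal batch effects) |
| `tadrive.io` / `tadrive.cli` | TOML config, vial-count CSV, TSV/JSON reports, `tadrive` command line |

## Command line

All subcommands read a single TOML config with `[architecture]`,
`[params]` and `[task]` sections:

```toml
[architecture]
system = "tade_suppression"       # tade_modification | tade_suppression | tare
rescue_functional = false

[params]
c_germline = 0.10                  # germline cut rate per transmitted allele
c_embryo = 0.02                    # embryo cut rate per wild-type allele
baseline_viability = 0.83          # control egg-to-adult survival

[[task.crosses]]
id = "male_drive"
mother = { drive = 0, cas9 = 0 }
father = { drive = 1, cas9 = 1 }
```

```bash
tadrive simulate-cross --config config.toml --out out/          # cross predictions (TSV + JSON)
tadrive generate-data --config config.toml --seed 1 --out data/ # synthetic vials.csv + ground truth
tadrive estimate --config config.toml --data data/vials.csv --out est/  # ML rates + profile CIs
tadrive simulate-population --config pop.toml --out pop/        # trajectory TSV, optional threshold
tadrive report --data data/vials.csv                            # pooled human-readable summary
```

## Notes

- Cutting requires the parent (germline) or mother (embryo deposition) to
  carry at least one drive **and** one Cas9 allele; embryo cutting exposes
  both still-wild-type alleles of the zygote.
- The vial-level mixed-effects analysis is approximated with a
  beta-binomial dispersion parameter (`fit_ml(..., overdispersion=True)`)
  rather than a binomial GLMM.
- Population simulation is panmictic with nonoverlapping generations and
  no density dependence; suppression is reported as genetic load.
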