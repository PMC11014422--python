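# divsel

Forward-in-time simulation of two populations under divergent selection,
with approximate Bayesian computation (ABC) for jointly estimating the loci
under selection and their selection coefficients.

Two haploid binary SNP populations (`Ne x L` matrices of 0/1) evolve in
migration-selection cycles: `t_star - 1` generations of isolated,
fitness-weighted asexual reproduction, then one generation of symmetric
migration followed by fitness-free sexual or asexual reproduction; the run
ends at `t_final = n_cycles * t_star - 1`.  Datasets are summarized by
per-locus differentiation statistics (FST, signed FST, pX - pY) and
haplotype homozygosity statistics (EHH profiles, XP-EHH), optionally
shortlisted by a 95%-quantile FST outlier scan, and fed to ABC-rejection
with a kernel-weighted local-linear regression correction.  A deterministic
single-locus expectation model serves as an oracle for drift assessment.

## Layout

| module                | contents                                                            |
| --------------------- | ------------------------------------------------------------------- |
| `divsel.simulator`    | founding, recombination, selection, migration, full runs            |
| `divsel.sumstats`     | FST / signFST / pdiff, EHH, XP-EHH, FST outlier scan                 |
| `divsel.abc`          | MAD standardization, rejection, kernel weights, regression adjust   |
| `divsel.oracle`       | deterministic single-locus recursion on the simulator's schedule    |
| `divsel.experiments`  | priors, the four scenarios, both inference methods, MSE evaluation  |
| `divsel.io`           | TSV matrix dialect, YAML configs/sidecars, haploid VCF export       |
| `divsel.cli`          | `divsel` command-line interface                                     |

## CLI

```bash
# simulate one dataset (config mirrors the fixed parameters + prior)
divsel simulate --config config.yaml --seed 1 --out-prefix run1

# summary statistics and outlier scan
divsel sumstats --in-x run1_X.tsv --in-y run1_Y.tsv --stats signFST,FST --out stats.tsv
divsel outlier-scan --in stats.tsv --quantile 0.95 --out outliers.tsv

# ABC on a pre-computed reference table (param:* / stat:* columns)
divsel abc --table table.tsv --obs obs.tsv --tolerance 0.001 \
           --kernel gaussian --method regression --out accepted.tsv

# deterministic single-locus trajectory
divsel oracle --p0 0.5 --s 0.2 --m 0 --t-star 5 --n-cycles 4 --out traj.tsv

# one evaluation scenario end to end (desk scale by default; --full-scale
# restores Ne=10,000 / n_sim=100,000)
divsel scenario --name 1 --method fixed --seed 1 --out-dir out/
```

Example `config.yaml`:

```yaml
r: 3.0e-4
t_star: 5
n_cycles: 4
Ne: 1000
L: 100
snp_spacing: 165
seed: 1
prior:
  s_bound: 0.25
```

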