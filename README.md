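# eparscan

Tools for detecting and characterizing the **extended pseudoautosomal
region (ePAR)** — a ~115-kb proximal extension of PAR1 carried by some
human Y chromosomes — and its reciprocal X-chromosome deletion, both
products of a single non-allelic homologous recombination (NAHR)
crossover between two ~550-bp LTR6B elements flanking the
pseudoautosomal boundary.

The package is aimed at population/statistical geneticists working with
SNP-array biobank data, Y-STR forensic panels and breakpoint (junction)
sequences. It provides:

- **Dosage screen** (`eparscan.dosage`): a scikit-learn style
  `DosageScreen` estimator. Sample intensities over the 60 informative
  X SNPs of the 113-kb interval (chrX:2,776,959–2,890,559, GRCh38) are
  normalized as the median of deviation from the per-marker female
  median, so a normal female sits at 0 and each missing copy shifts a
  sample down by one copy-signal unit. Central-95% reference bands for
  the haploid and diploid classes then call males as REF / EPAR /
  DEL_HEMI and females as REF / HET_DEL / HOM_DEL, after a sex-balance
  filter (median log2 ratios over non-PAR X and Y flank markers)
  excludes aneuploidies.
- **Y-lineage tools** (`eparscan.ylineage`): haplogroup assignment by a
  tree walk over branch-defining SNPs, founder-anchored **ASD dating**
  (T = mean over loci of ASD_l/μ_l, with E[ASD] = μT under the
  single-step mutation model), a Poisson SNP-accumulation clock with
  exact confidence bounds, and stepwise distance matrices.
- **Junction analysis** (`eparscan.junctions`): maps recombinant LTR6B
  sequences onto a variant catalog in the 559-bp alignment frame, types
  them by exact sequence identity (Junc1, Junc2, ...), bounds the NAHR
  crossover between the flanking informative sites (fixed differences
  only, or parental major-allele differences), counts distinct
  rearranged chromosomes using flanking-SNP haplotypes, and tests
  allele-sharing asymmetry between the parental elements with a
  one-tailed Fisher exact test.
- **History** (`eparscan.history`): minimum independent NAHR origins by
  irreversible (gain-only) parsimony on a haplogroup tree, the
  per-generation NAHR formation rate from phylogeny branch-generation
  totals, founder-expansion folds, and a joint male/female X-linked
  Hardy–Weinberg test.
- **PheWAS lite** (`eparscan.phewas`): `FirthLogisticRegression`
  (Jeffreys-penalized likelihood, finite under complete separation,
  penalized-LRT p-values) for binary traits, OLS for quantitative
  traits, Benjamini–Hochberg FDR across the scan.
- **Synthetic data** (`eparscan.simdata`): generators with known truth
  for every stage — intensity cohorts, star-genealogy Y-STR evolution,
  recombinant junction sets planted on a tree, phenotype tables.

## Worked example

```python
from eparscan import (CohortSpec, DosageScreen, simulate_cohort,
                      incidence_summary, hwe_x_test)
from eparscan.history import RateInputs, branch_generations_and_rate

cohort = simulate_cohort(CohortSpec(n_males=5000, n_females=5000,
                                    freq_epar=0.0077,
                                    freq_xdel_allele=0.005,
                                    noise_sd=0.08, seed=42))
screen = DosageScreen()
calls = screen.fit_predict(cohort.intensities, cohort.sex, cohort.markers)
summary = incidence_summary(calls)
print(summary[summary["count"] > 0])
```

```
sex         call  count  denominator  percent
  F          REF   4697         5000    93.94
  F      HET_DEL     53         5000     1.06
  F UNCLASSIFIED    250         5000     5.00
  M          REF   4696         5000    93.92
  M         EPAR     40         5000     0.80
  M     DEL_HEMI     17         5000     0.34
  M UNCLASSIFIED    247         5000     4.94
```

41 of the 5,000 simulated males truly carry the ePAR (planted frequency
0.77%); the screen calls 40 of them EPAR — males whose normalized
intensity falls in the female (diploid) band. The ~5% UNCLASSIFIED rate
is the expected spill of each class outside its central-95% band.

The historical quantities are plain arithmetic on published phylogeny
summaries:

```python
g, r = branch_generations_and_rate(
    RateInputs(s_total=60_555, s_tip_mean=1_300,
               tmrca_years=190_000, gen_years=31, n_events=18))
print(f"generations {g:.0f}  rate {r:.2e}")
h = hwe_x_test(44, 218_282, 137, 0, 264_300)
print(f"HWE chi2 {h.chi_square:.2f}  p {h.p_value:.2f}")
```

```
generations 285495  rate 6.30e-05
HWE chi2 2.14  p 0.34
```

i.e. ~285k generations of branch length in the reference MSY phylogeny,
an NAHR formation rate of ~6×10⁻⁵ per generation for 18 independent
origins, and no departure of the X-deletion allele from Hardy–Weinberg
equilibrium (p = 0.34).

## Command line

`eparscan` exposes subcommands `simulate`, `screen`, `haplogroup`,
`tmrca` (`--method asd|snp`, `--panel all|slow|fast`), `junctions`
(`--mode fixed|major`), `origins`, `rate`, `hwe`, `phewas` and `run`
(full synthetic pipeline from a YAML config). All tables are TSV;
junction sets are FASTA; trees are Newick.

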