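# invbehave

Behavioral phenotyping and genotype-by-environment mixed-model inference
for *Drosophila* tube assays.

The chromosomal inversion In(2L)t segregates at intermediate frequency in
*D. melanogaster* populations worldwide and, by suppressing recombination,
ties together alleles that influence behavior.  `invbehave` implements the
desk-scale workflow for asking how In(2L)t karyotype (inverted homozygote
`INV`, heterozygote `HET`, standard `STD`) shapes sleep, startle response
and foraging position across sexes and temperatures:

1. **Phenotyping** — from a single fly's 1-D tube trajectory, six traits:
   sleep (minutes per hour in bouts of ≥ 5 consecutive inactive minutes),
   baseline speed (mm/s in the pre-stimulus hour), startle duration (time
   for the 10-s smoothed speed to return to baseline after a mechanical
   stimulus), startle magnitude (post-stimulus-minute speed excess), and
   occupancy of the food-adjacent and food-distal eighths of the tube.
2. **Inference** — for each trait, a ladder of four nested linear mixed
   models fitted by maximum likelihood with a random intercept per
   experiment block,

       null:         trait ~ 1                     + (1 | block)
       inversion:    trait ~ genotype              + (1 | block)
       covariate:    trait ~ genotype + cov        + (1 | block)
       interaction:  trait ~ genotype * cov        + (1 | block)

   compared by likelihood-ratio χ² tests (structural npar 3/5/6/8, LRT df
   2/1/2; covariate = sex as a factor, or temperature in °C as numeric;
   proportion traits arcsin-√ transformed).  A significant genotype or
   interaction LRT (α = 0.05) gates Welch pairwise t-tests between
   genotypes within each stratum.
3. **Synthetic cohorts** — a trajectory generator with known ground truth
   (alternating-renewal sleep/wake, mean-reverting bounded walk toward a
   genotype-dependent preferred position, exponential-decay startle
   kinetics, block random intercepts), so the whole chain is testable
   without any raw tracking data.

## Worked example

`examples/03_model_ladder.py` simulates a phenotype table with a planted
genotype sleep effect (HET −3, INV −6 min/h vs STD) and runs the between-sex
analysis:

```
Trait             Model  npar      AIC    logLik  Chisq    Df     p
Sleep        Null Model     3 5665.059 -2829.530    NaN   NaN   NaN
Sleep   Inversion Model     5 5645.592 -2817.796 23.467 2.000 0.000
Sleep         Sex Model     6 5631.798 -2809.899 15.794 1.000 0.000
Sleep Interaction Model     8 5634.932 -2809.466  0.866 2.000 0.649

gate (genotype or interaction p < 0.05): True
trait stratum genotype_1 genotype_2       t       df      p  mean_diff  n_1  n_2
Sleep       F        INV        STD -2.9664 236.1272 0.0033    -4.3127  120  120
Sleep       M        INV        STD -3.9990 237.7321 0.0001    -6.3439  120  120
...
```

Reading it: adding genotype to the null model raises the log-likelihood by
11.7 units (χ² = 23.5 on 2 df, p ≈ 8e-6) — the planted genotype effect is
detected; sex also matters, the genotype×sex interaction does not.  The
gate being open, post-hoc Welch tests localize the effect: inverted
homozygotes sleep ~4–6 min/h less than standard flies in both sexes, close
to the planted −6 min/h.

The other examples cover cohort simulation (`01`), single-fly phenotyping
(`02`) and the one-command pipeline with manifest and plots (`04`).  A thin
CLI wraps the same functions:

```bash
invbehave simulate --config sim.yaml --out-dir data/
invbehave phenotype data/trajectories.csv data/metadata.csv --out phenotypes.csv
invbehave analyze phenotypes.csv data/metadata.csv --mode sex --out-dir results/
invbehave run --config full.yaml --out-dir results/   # all of the above
```

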