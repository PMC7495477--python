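# memstab

**Rank, build and validate stabilising point variants of α-helical membrane
proteins.**

Membrane proteins are routinely too unstable in detergent for structural
and biophysical work, and classical alanine-scanning (mutating every
position and measuring each variant) is prohibitively expensive for most
laboratories. `memstab` implements a rational selection pipeline: three
independent evidence streams each rank every position of a target protein
by its likelihood of yielding a stabilising substitution, a selector merges
the ranked lists under exclusion lists and overlap policies, and supporting
modules design the mutagenic primers and analyse the downstream
thermal-stability assays.

## The three evidence streams

**Deep-sequence.** Substitutions toward residues favoured in a large,
redundant multiple-sequence alignment ("odd-one-out" replacement). The
built-in independent-sites consensus scorer computes, per position and
candidate residue *x*,

    effect(i, x) = ln[(n_x(i) + c) / (n_wt(i) + c)]

from alignment column counts (pseudocount *c* = 1); genuine covariance-model
output tables can be ingested unchanged. Only favourable substitutions with
a normalised score above 70 % of the best site are kept, best substitution
per site.

**Model-based.** Per-model ΔΔG-of-unfolding tables from in-silico saturation
mutagenesis (negative ΔΔG = stabilising throughout). Alanine-scan ΔΔG values
are averaged across models; positions are ranked first by the number of
models in which the change is stabilising, then by mean ΔΔG; positions above
the 70 % normalised cut-off go to a full position scan on the single best
model (lowest unfolding free energy), where the most negative substitution
per site wins.

**Data-driven.** A scoring matrix derived from an alanine-scan style
compendium of variant stability records (relative stability as percent of
wild-type; > 140 % = stabilising, < 80 % = destabilising). For each of six
bioinformatic factors — wild-type amino acid, topology class, conservation
decade, lipid-contact bin, helix-contact bin, disorder bin — every level's
*abundance-weighted* association with each class is

    stab_weight(ℓ)   = # stabilising records at ℓ / # records at ℓ

and analogously for destabilisation. Levels are ranked on both weights; a
level at stabilising rank *r* among *L* levels scores *L* + 1 − *r*, and the
level *least* associated with destabilisation scores *L* on the second
ordering. With 20 amino acids, a residue type 4th by stabilising and 20th by
destabilising association scores 17 + 20 = **37**. A query position's final
score is the product of its factors' combined scores, reported as percent of
the target's best position.

## Supporting machinery

* **Primer design** — non-overlapping inverse-PCR primer pairs; the forward
  primer carries the mutant codon with ≥ 10 matched bases either side of the
  mismatch and is grown at its 3′ end until its nearest-neighbour melting
  temperature

      Tm = (ΔH°ᵢ + ΣΔH°) · 1000 / (ΔS°ᵢ + ΣΔS° + R·ln Cₚ) − 273.15

  enters 65–70 °C; the reverse primer abuts it on the opposite strand and is
  matched in Tm; a joint refinement pushes the shared annealing
  recommendation toward 62 °C. Blunt ligation of the in-silico amplicon is
  checked to reconstruct exactly the intended mutant plasmid.
* **Melt analysis** — gel-quantified GFP signal, normalised to the on-ice
  aliquot, fitted with a four-parameter logistic (variable slope); Tm is the
  inflection point; per-construct SEM over repeats; ΔTm vs wild-type with
  quadrature error propagation (SEM_Δ = √(SEM_wt² + SEM_var²)); the
  stabilising/destabilising cut-off is the campaign mean of SEM_Δ. A
  single-temperature screen calls hits above the lower bound of the t-based
  95 % confidence interval of all pooled survival measurements.
* **Evaluation** — cumulative-hit enrichment curves versus rank,
  random-sampling baselines, and campaign success rates.
* **Synthetic fixtures** — seeded generators for every input class
  (stability compendium with planted factor effects, redundant MSAs,
  multi-model ΔΔG tables, noisy melt curves, circular plasmids), so the
  whole pipeline is testable without any external data.

## Worked example

Everything below is generated — no downloads:

```sh
memstab simulate --what stability --seed 1 -o sim
memstab matrix --stability sim/stability.tsv \
    --features SYN1=sim/SYN1.features.tsv \
    --features SYN2=sim/SYN2.features.tsv \
    --features SYN3=sim/SYN3.features.tsv -o matrix.tsv
memstab score --mode data-driven --fasta sim/SYN1.fa \
    --features sim/SYN1.features.tsv --matrix matrix.tsv -o ranked.tsv
head -4 ranked.tsv
```

```text
module       position  wt_aa  mut_aa  ...  raw_score   normalised_score  rank
data_driven  115       A      L       ...  3.1185e+06  100               1
data_driven  168       G      A       ...  2.646e+06   84.8485           2
data_driven  127       K      A       ...  2.592e+06   83.1169           3
```

The top candidate substitutes alanine 115 with leucine (native alanines are
changed to leucine, everything else to alanine): its six factor scores
multiply to 3,118,500, the best product in this target, hence the
normalised score of 100. Primers for a chosen variant:

```sh
memstab simulate --what plasmid --seed 1 -o sim
memstab primers --plasmid sim/plasmid.fa --cds-start 254 \
    --variants variants.tsv -o primers.tsv
```

```text
variant  forward                      reverse                          tm_forward  tm_reverse  annealing
D10A     GGCAAGGAGGCCGGCTACTGTGTGAGT  AATTACCATCCACTGGCCCCGAGACAAATAA  65.1        64.9        61.9
```

Both primers sit in the 65–70 °C window, matched within 0.2 °C, with the
shared annealing recommendation just under the 62 °C target. Finally, melt
curves:

```sh
memstab simulate --what melt --seed 1 -o sim
memstab melt --curves sim/curves.tsv --wildtype WT --cutoff 1.3 -o melt.tsv
```

reports a wild-type apparent Tm of 49.3 ± 0.1 °C over three simulated
repeats (the generator's true Tm is 49.3 °C).

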