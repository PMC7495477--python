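# Methods

This note documents the models, parameter choices and numerical decisions
behind `memstab`, and what the synthetic test data do and do not establish.

## Data-driven scoring matrix

**Classification.** Records are classed from relative stability (percent of
wild-type) with strict inequalities: > 140 % stabilising, < 80 %
destabilising, everything else (including the boundaries) neutral. Negative
stabilities are rejected at load.

**Abundance weighting.** For each factor level, the stabilising and
destabilising weights are the class frequencies among that level's records.
Neutral records enter the denominator but neither numerator. This removes
the skew toward abundant levels (alanine is common; tryptophan is rare) that
raw counts would carry. Multi-state records of the same variant (apo /
agonist / antagonist) are treated as independent observations, as the
conformations differ.

**Binning.** Conservation is binned into ten 10-percent decades (trends in
this kind of data are reported per decade, e.g. moderate conservation of
50–60 % associating with stabilisation); lipid-contact, helix-contact and
disorder scores into five equal bins over [0, 1]. Edges are configurable;
values exactly at the top fold into the top bin.

**Rank scores.** Within a factor with *L* observed levels, levels are sorted
by stabilising weight descending (rank *r* scores *L* + 1 − *r*) and by
destabilising weight descending (rank *r* scores *r*, so the least
destabilising level scores *L*). Ties break by observation count (more
observations first), then level name — fully deterministic. Combined score =
sum; with 20 amino-acid levels the range is [2, 40].

**Position score.** Product of the wild-type amino-acid, topology,
conservation-bin, lipid-bin and helix-bin combined scores, with a sixth
disorder-bin factor included by default (`include_disorder=False` restores
the five-factor mode used before disorder prediction was added). The factor
scores are multiplied as raw combined integers — the worked 17 + 20 = 37
example presents the combined integer as the quantity used — not rescaled
per factor; rescaling before multiplication would change only the relative
weighting of factors with different level counts and is intentionally not
done. No smoothing is applied to sparse levels. Scores are reported as
percent of the target's best position. A query level unseen in training
receives the factor's median combined score with a warning (small training
compendia will miss rare residues); failing the whole query for one rare
residue would be worse.

## Evidence streams

**Deep-sequence.** The full pairwise-covariance treatment of evolutionary
couplings is out of scope; the built-in scorer is an independent-sites
consensus model over alignment columns, `ln[(n_x + c)/(n_wt + c)]` with
pseudocount c = 1 (guards the degenerate all-identical column). It
preserves the operational core — propose "odd-one-out" replacements toward
frequently used residues — and real covariance-model output can be ingested
as a table instead. Selection keeps strictly positive effects, takes the
argmax substitution per site, normalises to percent of the best site and
retains entries above the 70 % cut-off.

**Model-based.** ΔΔG convention: negative = stabilising, everywhere. The
alanine-scan aggregation sorts positions first by the number of models in
which the alanine change is stabilising (damps single-model bias from
poorly modelled sites), then by mean ΔΔG ascending. The normalised score is
100 · mean/most-negative-mean, restricted to stabilising means (avoids
negative percentages); positions above 70 % pass to the position scan of the
best model (argmin unfolding free energy). Ties anywhere break by position
ascending so output files are reproducible.

## Selection

Normalised percent scores are compared directly across modules for overlap
resolution — a known approximation, adopted because the merge step needs a
shared scale and each stream's scores are percent-of-best by construction.
"Top X % of ranked sites" is interpreted per module. Overlap rules:
`highest_score_wins` (one candidate per position; ties break by module
priority data-driven > model-based > deep-sequence, then substitution
alphabetically), `drop_identical_substitution_only` (identical
position+substitution pairs collapse to the higher-scoring entry; different
substitutions at a site coexist), `allow_all`. Quotas are filled per module
by rank. Every drop is recorded with a reason
(`excluded_position | overlap | below_fraction | over_quota`), so
kept ∪ dropped always partitions the input.

## Primer design

**Thermodynamics.** Unified oligonucleotide nearest-neighbour parameters
(ΔH° in kcal/mol, ΔS° in cal K⁻¹ mol⁻¹, per-terminal initiation terms),
R = 1.987 cal K⁻¹ mol⁻¹, primer concentration used directly (default
0.5 µM, the PCR recipe concentration; no Cₚ/4 correction). The packaged
parameterisation applies the standard entropic monovalent-salt correction
ΔS += 0.368 · (N−1) · ln[Na⁺] at a default 50 mM: the stack table's
reference state is 1 M NaCl, at which a minimum-length primer (10-nt flanks
around the codon) already melts above 70 °C on a GC-balanced template —
the grow-into-window iteration could never operate. Both the salt level and
the whole table are configurable in `ThermoParams`. Mismatched bases
contribute no stack terms (both flanking stacks are skipped); the salt term
follows primer length.

**Codon choice.** Among the target residue's codons, minimal edit distance
from the wild-type codon wins; ties break by host usage frequency (an
E. coli K-12 table ships; any table can be passed), then alphabetically.
Stop codons are unsupported.

**Design loop.** Forward: seed with 10 matched bases either side of the
mismatch, then grow/shrink at the 3′ end only until Tm ∈ [65, 70] °C
(closest achievable if the window is skipped between single-base steps, or
unreachable at the flank floor). Reverse: binds the opposite strand ending
immediately 5′ of the forward footprint; grown at its 3′ end to minimise
|Tm_rev − Tm_fwd|. Joint refinement scans feasible forward lengths and
keeps the pair whose annealing recommendation — min(Tm_fwd, Tm_rev) − 3 °C,
capped at 62 °C (the annealing formula itself is this package's choice; the
62 °C goal is the method's) — lands closest to 62 °C. Primers below 18 nt
are rejected outright. Every designed pair is verified by in-silico blunt
ligation: the reassembled circle must equal the template with exactly the
intended codon replaced, and the two footprints must not overlap.

## Melt analysis

The 4PL is parameterised `y(T) = bottom + (top − bottom)/(1 + exp(h (T −
Tm)))` ("dose-response, variable slope" names the family but not a formula;
this logistic-in-temperature form makes Tm the inflection directly). Fits
are multi-start nonlinear least squares: Tm₀ at the half-maximal
temperature, h₀ ∈ {0.2, 0.5, 1.0}, top/bottom from data extremes, best
residual wins. Signals are normalised to the on-ice aliquot first; multiple
intensity columns per lane (double-banded constructs, e.g. glycosylated
forms) are summed before normalisation. A fit is flagged unreliable when
the fitted Tm falls outside the sampled grid, the curve rises with
temperature, or the transition amplitude is < 0.2 of the normalised range
(a flat trace makes the 4PL unidentifiable and is reported as
no-transition rather than fitted).

Per construct: mean Tm over repeats, SEM = sample SD/√n for n > 1 (absent
for n = 1). ΔTm = variant mean − wild-type mean; SEM_Δ by quadrature; if
either SEM is absent so is SEM_Δ. The classification cut-off defaults to
the campaign mean of available SEM_Δ values (|ΔTm| ≥ cut-off decides), and
can be overridden with an explicit value. The stated rule is applied
uniformly, including to single-repeat constructs whose own SEM is
unavailable.

**Single-temperature screen.** The hit cut-off is the lower bound of the
two-sided t-based 95 % confidence interval of the pooled measurement mean.
Whether published cut-offs of this kind came from the pooled mean, pooled
median or the wild-type distribution is not derivable from their
description; the pooled-mean reading is implemented and `--cutoff` allows
an externally chosen survival threshold to be imposed instead. Hits
require median survival strictly above the cut-off.

## Evaluation

Cumulative-% -of-stabilisers and running true-positive rate at every rank;
unknown-truth positions are skipped and logged. The random baseline draws
subsets without replacement (default 10 samplings of 100 positions) and
reports mean ± SD stabiliser/destabiliser counts. Success rates are rounded
to the nearest integer percent, half away from zero.

## Synthetic data: what it emulates and what it does not

The stability generator emulates a compendium of three receptor-sized
targets measured in 3, 2 and 1 conformational states (≈ 2,000 records at
the default), with base rates of 7.6 % stabilising and 48.5 % destabilising
records and planted multiplicative enrichments: amino acids G, T, A, Q, E,
H (descending) among stabilisers and I, Y, W, D, C, V among destabilisers;
transmembrane-helix positions stabiliser-enriched and cytosolic-helix
positions destabiliser-enriched; conservation 50–60 % stabiliser- and
80–90 % destabiliser-enriched. Class probabilities are renormalised
products of base rate × multipliers, so marginal rates stay near the base
rates. Topology is laid down as alternating helix/loop architecture;
conservation and contact scores are uniform. The MSA generator plants
"odd-one-out" query positions in consensus-dominated columns (depth 500 by
default — scaled down from the > 8,000-sequence alignments the real stream
uses, which is ample for an independent-sites scorer). The ΔΔG generator
plants ~12 stabilising sites at mean −2 kcal/mol against a +1 kcal/mol
background with per-model noise. Melt curves are 4PL plus Gaussian noise on
the published ten-temperature grid.

None of this mimics real sequence families, real force-field energetics or
real gel noise; passing tests demonstrate that the machinery recovers
planted structure of realistic shape and magnitude, not that the method's
published success rates transfer to any particular protein. Problem sizes
in the test suite (120–333-residue targets, 20–50 seeds per Monte-Carlo
property, 100 melt fits, 100 designed primer pairs) were chosen so the full
suite completes in a few minutes while keeping every stochastic acceptance
bound calibrated by repeated simulation rather than a single run.

## Known limitations

* The deep-sequence scorer ignores residue covariation and sequence
  reweighting; it is an independent-sites simplification.
* Cross-module score comparability in the selector is heuristic.
* No primer secondary-structure/hairpin/dimer screening; no degenerate
  codon libraries.
* The packaged default scoring matrix is derived from the synthetic fixture
  (seed 0) and is labelled accordingly; it is for smoke tests and examples,
  not production ranking.
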