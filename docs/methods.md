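# Methods

This note documents the models behind `ilkit`, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genome and map model

A genome is a list of chromosomes with a physical length (bp) and a
genetic length (cM). The default configuration is melon-like: 12
chromosomes, 450 Mb and 1100 cM in total, split equally. The equal split
is a modeling default — per-chromosome empirical lengths can be supplied
by constructing `Genome` directly. The 1100 cM total is itself a
modeling choice: it makes each chromosome ~0.92 Morgans, consistent with
roughly one crossover per chromosome per meiosis and with the BC1
segment-count arithmetic below.

Physical↔genetic conversion goes through a `GeneticMap`, an ordered
marker table with both coordinates. Conversion is piecewise linear
between flanking markers; a query at a marker returns that marker's cM.
Beyond the terminal markers the map **clamps** (constant extrapolation).
Rationale: linear extrapolation at telomeres can produce negative or
runaway genetic lengths; clamping keeps `segment_genetic_length`
non-negative and bounded, at the cost of assigning 0 cM to terminal
physical stretches beyond the outermost markers. All intervals are
0-based, half-open bp internally; human-facing tables print Mb with two
decimals.

## Meiosis

Crossovers follow the Haldane model: per chromosome the crossover count
is Poisson with mean equal to the genetic length in Morgans, positions
are uniform on the cM scale, there is no interference and no obligate
chiasma. Positions are mapped from cM to bp through the map's inverse,
so recombination hot/cold regions implied by a non-linear map are
respected. A gamete starts from a uniformly chosen parental haplotype
and switches at each crossover. Two closed-form consequences anchor the
tests: the recombinant fraction at map distance d Morgans is
r = (1 − e^(−2d))/2, and a BC1 individual carries an expected
(L + 1)/2 donor segments on a chromosome of L Morgans — summed over the
default genome, (11 + 12)/2 = 11.5.

Randomness: a single `numpy` Generator seeded from the master seed is
threaded through the scheme in a fixed order, so whole-program runs are
bitwise reproducible.

## Genotyping model

Marker calls are A (homozygous recurrent), H (heterozygous), B
(homozygous donor), derived by looking up both haplotypes' founder
labels at the marker position. The error model is missingness only
(independent masking at a configurable rate); miscalls are not simulated
by default because no error rates are available to calibrate them — the
`missing_rate` knob is the only data-quality control.

## Introgression calling

Graphical genotypes are reconstructed with two conventions: the boundary
between two adjacent **informative** markers with different calls is the
midpoint of their bp positions (the "virtual recombination breakpoint"),
and runs touching the first or last genotyped marker of a chromosome
extend to the chromosome ends (the non-genotyped extremes are assumed to
share the terminal marker's haplotype). Missing calls are skipped, never
imputed: a run is broken only by a conflicting informative call.
Heterozygous and homozygous-donor runs are reported as separate
segments. Singleton conflicting calls are *not* smoothed — no
double-recombinant filter is applied — because the calling conventions
above are defined purely on observed calls; a smoothing pass would be a
separate, optional model.

Population statistics follow directly: introgression count = number of
called segments of any zygosity; genome composition percentages come
from called segment lengths over the genome total; per-marker observed
heterozygosity H₀ is the fraction of non-missing calls that are H, and
the population H₀ is the mean over markers. Segregation distortion is a
χ² against 1:1 A:H (backcross) or 1:2:1 (selfed), df = classes − 1;
significance is flagged at α = 0.05 on the raw p — the convention in
backcross screening reports — with Bonferroni-adjusted p reported
alongside rather than substituted.

## Hierarchical selection

Selection implements the breeder's hierarchy: (1) the donor genome must
be contained at least twice among the selected plants, (2) lines should
carry as few introgressions as possible, (3) lines should carry as much
recurrent genome as possible. "Contained at least twice" is read as
per-position multiplicity ≥ 2 over the selected lines' donor segments
(per physical interval, not per genotyped marker) — the redundancy
guards against losing a region to a single failed plant.

The implementation is a greedy set-multicover with criterion (1) as the
constraint and (2)/(3) as the preference order: candidates are ranked by
(fewest introgressions, fewest donor bp, id) and the best-ranked
candidate that still adds coverage below multiplicity 2 is admitted;
the loop stops when no candidate adds coverage, i.e. multiplicity-2
coverage is maximal over the pool; a final pruning pass drops any line
whose removal leaves the capped coverage unchanged, worst-ranked lines
first. The procedure is deterministic for a given input. A
gain-maximizing greedy was rejected because it prefers few
many-introgression plants, inverting criteria (2)/(3): a breeder keeps
many low-introgression plants, accepting a larger selected set. No
optimality is claimed — exhaustive subset search is used as a test
oracle on ≤ 4-candidate instances only.

Heterozygous segments count toward coverage in intermediate generations
(selfing fixes targets later); finished ILs require a homozygous-donor
target.

Bins are computed by an endpoint sweep: every maximal interval with a
constant, non-empty carrier set is a bin, so bin boundaries coincide
with segment endpoints and bin lengths sum exactly to the covered bp.

## Breeding-scheme simulation

`run_breeding_scheme` executes: F1 → BC1 (default 320 plants, screened
with a 48-SNP panel homogeneously spaced in bp) → hierarchical selection
→ BC2 → BC3 (full 96-SNP panel, reselection each round) → finishing
rounds in which each line is self-pollinated once it carries at most
three introgressions and backcrossed otherwise. A line whose segments
are all already homozygous but number more than one is backcrossed —
selfing can never remove a fixed donor segment. Progeny with exactly one
homozygous-donor segment and no other donor calls at panel markers are
"finished"; rounds continue until every retrievable donor region is
represented, progress stalls for three rounds, or the generation budget
(default 10 finishing rounds) is exhausted. A final greedy cover at
multiplicity 1 picks the IL collection, renamed `IL<chromosome>.<rank>`
by target position. If a generation yields no viable candidate the run
aborts with an error naming the generation.

Default sizes (320 BC1, 16 progeny per selected line, 48/96-SNP panels)
mirror the scale of a real melon program; on one CPU a full run takes
roughly 20 s. The scaled-down configuration used by the test suite
(60 BC1, 10 progeny, 24/48 SNPs) exercises every branch in a few
seconds.

## Phenotype simulation

For a quantitative trait, a replicate value is

```
value = control_mean × (1 + Σ expressed percent effects / 100)
        + year_effect + N(0, sd)
```

QTL effects are specified as percent of the control mean, the convention
used when reporting IL effects. The default dominance mode is
"recessive": an effect is expressed only by homozygous-donor segments,
because finished ILs are homozygous and that is the only observable
regime; "dominant" and "additive" modes are available for intermediate
generations. Qualitative traits are single-locus presence/absence with a
penetrance in [0, 1]; flesh colour is the two-locus epistatic lookup
(any *Gf* allele → orange; else any *Wf* allele → white; else green;
missing calls → "undetermined").

The default trait architecture uses control means, residual SDs and
effect magnitudes typical of a climacteric × non-climacteric melon
cross: sugar content around 8.78 °Brix with donor alleles of −34.3% and
+20.6%, fruit-weight reductions of 39–45%, ripening-earliness shifts of
±9–18% on the days-after-pollination scale, firmness shifts of −50% to
+65%, and year effects confined to the size-related traits (FW, FA, FP,
FL, FWI). What the generator does **not** emulate: genotype × year
interaction, non-Gaussian or heteroscedastic residuals, shared
greenhouse-block effects, plant loss, and measurement-protocol artefacts
— so passing tests demonstrate correctness of the pipeline under its
stated model, not robustness to every failure mode of field data.

## QTL mapping

Year gating: for each trait, a one-way ANOVA F-test on the control line
across years at α = 0.05 decides merge versus split-by-year; splits are
applied to the size traits, mirroring the observation that only
size-related traits respond to the year. The ANOVA F was chosen because
it matches the ANOVA framework of the main test.

The main scan is Dunnett's many-to-one comparison: two-sided t
statistics with the pooled ANOVA error term and family-wise adjusted
p-values. Two backends are provided and recorded in the result
metadata: `mvt` (multivariate-t quadrature via `scipy.stats.dunnett`,
with a fixed quasi-Monte-Carlo state so reruns are identical to ~1e-4)
and `montecarlo` (≥ 10⁵ vectorized draws of the null max-|t|
distribution; absolute error < 10⁻³ at the default draw count). The
degenerate cases are defined explicitly: zero pooled variance with equal
group means returns p = 1 for every line (nothing can be flagged); zero
pooled variance with unequal means is an error, since no finite t exists.
A Mann–Whitney two-sided rank test per IL (unadjusted) is always
computed alongside, and the Dunnett/Mann–Whitney concordance fraction is
reported. Three significance levels (0.05, 0.01, 0.001) map to */**/***.

Effects are 100 × (x̄_IL − x̄_ctrl)/x̄_ctrl, signed. QTL intervals follow
the overlap rule: significant ILs on a chromosome are grouped into
overlap components; within a component the interval is the intersection
of the significant ILs' segments minus every region shared with a
non-significant IL — possibly a union of disjoint candidate intervals
(a significant IL with a nested non-significant one). Qualitative traits
are mapped by co-segregation instead: (∩ showing ILs) − (∪ non-showing
ILs) per chromosome, with an explicit "inconsistent segregation" error
when the showing ILs share nothing. All interval endpoints inherit the
marker-midpoint convention from segment calling; the delimitation
operations never invent new endpoints. QTLs are named
`<TRAIT>QP<chromosome>.<ordinal>`.

The flesh-colour index FC is the signed sum of the per-channel (a, b, L)
IL-minus-control mean differences — the literal definition — with an
absolute-sum variant behind a flag because the signed sum can cancel
across channels.

## Numerical and design choices

* Greedy selection tie-breaks and the pruning order are fully
  deterministic (documented above) so reruns are reproducible.
* The `mvt` Dunnett backend fixes its QMC state; the `montecarlo`
  backend takes an explicit generator.
* `simulate_gamete` deduplicates crossover positions that collapse to
  the same bp after inverse interpolation (an even number of crossovers
  between two markers is invisible at bp resolution anyway).
* Zero-genetic-length chromosomes transmit one parental haplotype
  unchanged, chosen with probability 1/2.
* Chromosomes whose calls are all missing are omitted from segment
  calling with a warning rather than an error, so one failed assay does
  not abort a whole-population analysis.

## Problem sizes used in the tests

The acceptance-style checks simulate 320 BC1 individuals at one marker
per 0.25 Mb; the Dunnett family-wise calibration uses 30 lines × 6
replicates against a 6-replicate control over 2000 null families; the
pipeline-recovery check uses 25 runs of a 6-line collection with effect
sizes of |20–45|% and 5–7 replicates. These sizes were chosen to keep
each Monte-Carlo standard error well below the tolerance it is compared
against.

## Known limitations

* No interference model (χ² or gamma) — Haldane only.
* No organellar inheritance; the cross direction has no computational
  consequence.
* No imputation and no phasing beyond founder-origin inference; missing
  calls are simply non-informative.
* The selection heuristic is not an exact set-multicover solver.
* No composite-interval mapping, mixed models, multi-QTL joint fits or
  QTL × QTL interaction tests — mapping is strictly IL-versus-control.
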