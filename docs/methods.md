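# Methods

This note records the model assumptions, the parameter defaults and their
rationale, the design of the synthetic-data generator, and the numerical
choices made in the implementation.

## Junction calling (sonication mode)

Paired-end reads are reduced to the first 20 bp of each mate (end tags);
reads shorter than 20 bp are skipped and counted. A read pair is a junction
read when one tag maps uniquely inside the bait and the other maps uniquely
more than 300 bp away; pairs at ≤ 300 bp are excluded as uninformative
self-ligation/incomplete-digestion products. Distances are measured from
the nearest contained base of the bait interval (a position `p ≥ end` is at
distance `p − (end − 1)`), so a tag exactly 300 bp past the last bait base
is excluded and 301 bp is kept; a tag-to-tag distance mode is also
available. Junctions are classified proximal (≤ 10 kb), distal cis
(> 10 kb, bait chromosome) or trans. Pairs with both tags in the bait
(`bait_only`), both outside (`distal_only`), any non-unique tag, or a
malformed mate structure are tallied separately — the tally always
partitions the input read pairs.

Distal junctions are merged into unique interacting sites by single-linkage
clustering with a 100 bp gap rule (PCR duplicates of one ligation event
land within sonication-shear distance of each other); the site position is
the central base of the merged span and `support` counts the merged read
pairs. Sites with `support == 1` are removed — a genuine interaction
sequenced at reasonable depth is expected to yield multiple read pairs, and
singletons are dominated by artifacts. Proximal junctions are never merged
into sites; they are summarized by a distance-decay profile instead.

## Window statistics and permutation FDR

Under the null, the `n` interacting sites of a chromosome of length `L` are
uniform, so the count `C` in a window of length `l` is binomial with mean
`μ = n·l/L` and success probability `p = μ/l`, giving
`z = (C − μ)/sqrt(μ(1 − p))`. Windows are centered on each site (the focal
site is included in `C`) and truncated at chromosome ends with `l` set to
the actual length — re-anchoring to a full-width window would bias edge
scores. Window half-widths: 1 Mb (inter-chromosomal), 200 kb
(intra-chromosomal).

The empirical FDR redraws all site positions uniformly per chromosome 100
times, recomputes z on each permutation, and sets
`rawFDR(z_i) = mean_perm(count null z ≥ z_i) / count(observed z ≥ z_i)`,
capped at 1. Because rawFDR need not be monotone in z, q-values are
monotonized by a reverse cumulative minimum over descending z (step-up),
so a more extreme score never receives a larger q. Thresholds: q ≤ 0.05
(inter), q ≤ 0.20 (intra) — the intra analysis has far fewer sites and a
correspondingly weaker null, so a looser threshold is used. Each positive
site defines a candidate domain spanning all sites within the window radius;
overlapping domains are merged, and each reported domain carries its member
count, positive count and minimum q.

Enzyme mode uses the same binomial machinery on the reduced restriction-site
genome: consecutive segments of 500 (or 250/125) sites for the
inter-chromosomal analysis, and sliding 100-site windows against a
3000-site centered local background for the intra analysis; both truncate
at chromosome ends and scale `μ` by the actual segment/background size.
Permutations redraw which site ordinals are ligated, without replacement.

## Reproducibility and depth titration

Replicate concordance is the Pearson correlation of per-bin site counts
(2 Mb default; 1 Mb and 500 kb variants probe resolution), with the bait
chromosome excluded for the trans analysis; a constant track yields NaN
rather than a fabricated value. Coverage is the fraction of one replicate's
sites with a site of the other replicate within 10 kb (asymmetric). The
depth titration subsamples read *pairs* at fractions
{0.10, 0.25, 0.50, 0.75, 0.90, 1.00} without replacement and reruns
junction calling, duplicate merging and the singleton filter at each depth,
so the reported curves respond to depth exactly the way a resequenced
library would (shallower data lose duplicate support and drop below the
singleton filter first).

## Epigenome enrichment

The histone-mark enrichment factor is `observed / expected`, where
`observed` counts interacting sites within ±5 kb of a peak (peaks padded by
5 kb and merged, so containment in the padded set equals
distance-to-nearest-peak ≤ 5 kb) and `expected` is the Monte-Carlo mean of
the same count over ≥ 100 sets of uniform positions on the analysis
chromosome. TF tag density counts ChIP tag 5′ positions within ±1 kb of
each site, normalized to a 10-million-tag library, minus the identically
processed input/background library. Site densities are compared with
densities at equally many uniform random positions by a one-sided unpaired
Wilcoxon–Mann–Whitney test: exact null distribution when the pooled sample
is tie-free with both groups ≤ 25, otherwise the normal approximation with
continuity and tie correction; fully degenerate input returns p = 1.

## Synthetic-data generator

The generator replaces deposited sequencing data with datasets whose every
read pair traces to a known event. Default study conditions: a five-
chromosome genome (4 × 100 Mb + 95 Mb), bait on chr17 at 30 Mb, 4 500
proximal self-ligation events with a truncated-exponential distance decay
(scale 500 bp on 300 bp–2 kb), 400 uniform background distal events, three
planted 1 Mb trans domains of 35 events each (≈ 40× background density),
geometric PCR duplication (mean 3) with ±50 bp positional jitter, and noise
read pairs (30 % bait-only, 5 % genomic contamination). Two
pseudo-replicates share the planted domains but redraw all events
independently.

Guard margins make round trips exact by construction rather than
probabilistically: proximal distances are floored at 351 bp
(300 + jitter + 1) so no jittered duplicate can cross the 300 bp exclusion,
distal events keep > 10 050 bp from the bait so none can cross the 10 kb
proximal cutoff, and events on one chromosome are at least 301 bp apart so
the 100 bp merge rule can never fuse two events (duplicates of one event
span ≤ 101 bp). Consequently the simulator's category tally equals the
junction caller's tally field for field, and every ≥ 2-duplicate distal
event yields exactly one filtered site within 100 bp of truth.

The enzyme-mode generator plants `AAGCTT` at randomized 250–600 bp spacings
on a two-chromosome toy genome (1 200 + 800 sites), emits primer-prefixed
reads whose tails start at ligated sites, and only chooses sites whose
30 bp tail is globally unique, so exact-match placement recovers the truth
set exactly. The ChIP fixture generator produces peaks centered on given
sites and tag sets whose density inside ±1 kb of sites is a chosen multiple
of the uniform rate, with exactly `n_tags` tags in both treatment and
background (the uniform/extra split is solved in closed form).

What the generator does **not** emulate: real read sequences and alignment
(sonication mode emits alignments directly), mappability variation,
GC/fragment-length bias, chromatin-state-dependent ligation efficiency,
inter-replicate batch effects, and genome-wide distance-decay beyond the
proximal decay. Conclusions about those factors cannot be drawn from this
data.

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng` with composite
  seeds (e.g. `[seed, 1]` / `[seed, 2]` for the two replicates), so every
  pipeline is bit-reproducible and replicate streams are independent.
* Window counts use sorted arrays and `searchsorted`; the test suite checks
  them against brute-force recounting to < 1e-9.
* Coordinates are 0-based with half-open intervals throughout; BED I/O
  matches this convention.
* z is NaN when μ = 0 (no sites on the chromosome beyond the focal
  window's contribution being undefined) and the FDR step treats NaN as
  non-significant.
* Problem sizes (chromosome counts, event numbers, site counts) were chosen
  so the full test suite runs in well under a minute of statistics per
  stage on one CPU while keeping Monte-Carlo standard errors far from the
  asserted thresholds.

## Limitations

* The permutation null (uniform positions per chromosome) is conservative
  when strong true signal inflates the per-chromosome site count; q-values
  near strong domains are anti-conservative in the opposite direction only
  through the shared μ.
* The singleton filter assumes duplicate-level depth; very shallow
  libraries lose true sites before false ones, which is precisely what the
  titration quantifies.
* The enrichment factor's uniform random expectation ignores mappability
  and chromatin accessibility; with real data a matched background model
  would be preferable.
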