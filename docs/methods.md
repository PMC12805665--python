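# Methods

## The model-selection view of window size

A non-overlapping window (NOW) analysis of a chromosome alignment of length
$L$ at window size $w$ fits one unrooted tree per window under the
Jukes–Cantor (JC) model.  Each window of $t$ data-bearing taxa contributes
$2t-3$ free parameters (branch lengths; JC has no free rates or
frequencies).  Summing log-likelihoods and parameter counts across windows
gives a single composite model per window size, scored as

    AIC = -2 ln L + 2 K
    BIC = -2 ln L + K ln n

with `K` the summed parameter count and `n` the total number of sites
analyzed.  Comparing AIC across sizes is valid only if every size analyzes
the same sites; this drives two design rules below (the dropped trailing
remainder, and the stepwise joint filter).  The size with the lowest AIC is
selected; exact ties go to the larger (more parsimonious) size.

The branch-length floor `blmin = 1/w` makes every branch represent at least
one substitution in a window of `w` sites.  Without it, near-empty windows
support arbitrary resolved topologies at negligible likelihood cost; with
it, resolution must be paid for, which penalizes gene-tree estimation error
in uninformative windows.  `blmax = 10` substitutions/site bounds the
optimizer; it is never reached on realistic data.

## Likelihood engine

Felsenstein pruning over compressed site patterns with JC transition
probabilities `P(same) = 1/4 + 3/4 e^{-4t/3}`, `P(diff) = 1/4 - 1/4
e^{-4t/3}`.  Gap, `?`, `.` and all non-ACGT ambiguity codes are missing data
(partial-likelihood vectors of ones); an all-missing column therefore
contributes exactly zero to the log-likelihood, and likelihood values are
invariant to the internal rooting used by the implementation (asserted in
tests against brute-force state enumeration).

Branch lengths are optimized by iterative smoothing: a down-pass computes
subtree partials, then a pre-order pass re-optimizes each branch given the
current values of the others.  On a single branch the site likelihood is
affine in `e = exp(-4t/3)`, so the profile log-likelihood is concave in `e`
and each 1-D optimization is a safeguarded Newton iteration on its monotone
derivative, clamped to `[blmin, blmax]`.  Sweeps repeat until the exact
log-likelihood improves by less than `tolerance` (default 1e-3; with at most
20 sweeps).  The returned lnL is always computed exactly from a final
down-pass.

Topology search is exhaustive for up to 5 taxa (3 or 15 candidates, each
fully optimized; likelihood ties broken toward the lexicographically
smallest canonical topology, so degenerate windows are deterministic).  For
6+ taxa the search starts from neighbor joining on JC-corrected,
pattern-weighted distances and hill-climbs with NNI: candidate
rearrangements around each internal edge are scored by re-optimizing only
the central branch against cached directed partials (the four surrounding
subtrees held fixed), and the best improving move is applied followed by a
full smoothing pass, until no move improves the likelihood.  On 5-taxon
windows with strong signal this search agrees with the exhaustive optimum in
≥95% of simulated trials (tested); like any hill-climber it can in principle
stop in a local optimum on conflicted data.

Topology identity uses a canonical string: root the unrooted tree at the
neighbor of the lexicographically smallest taxon and sort children
recursively by their canonical substrings, ignoring branch lengths.  Equal
strings are equivalent to unrooted Robinson–Foulds distance zero
(cross-checked against dendropy).

Branch support, when requested, is a standard nonparametric bootstrap:
resample pattern weights multinomially, re-run the search, and report each
internal branch's bipartition frequency (mean over branches, in percent).
Windows with fewer than four unique sequences get no support value rather
than a misleading one, and are excluded whenever a support threshold is
applied.  This is deliberately *not* the ultrafast bootstrap approximation;
the ≥95 mean-support filtering semantics are preserved, but absolute support
values may differ from UFBoot's.

## Synthetic chromosomes

The generator emulates a chromosome alignment of six *Heliconius*
erato-sara-clade species plus an outgroup.  Gene trees come from a
multispecies coalescent with recombination on a dated species tree;
sequences are then evolved locus by locus under JC and concatenated, with
the per-site truth retained.

Time conventions: species-tree node ages are in Myr and converted to
ms-style coalescent units (4Ne generations) at 0.75 Myr per unit.  `rho` is
the population-scaled recombination parameter 4Nr over the whole simulated
segment.  `ils_scale` multiplies all node ages in coalescent units (low/
medium/high = 1.5/1.0/0.6): shorter internal branches mean more incomplete
lineage sorting.  Introgression events are instantaneous admixture pulses
with probability γ; bidirectional events are two pulses, the reverse
direction offset by half a generation (2.5e-5 units) because the ARG
recorder rejects a lineage migrating twice at the same instant.

Default demography (all exposed as configuration): node ages 1.7
(erato/himera), 3.0 (demeter/sara), 3.5 (+telesiphe), 3.9 (+hecalesia), 4.5
(crown), 12.5 Myr (outgroup); pulses himera↔erato (0.4 Myr, γ=0.10),
telesiphe→hecalesia (2.0 Myr, γ=0.05), telesiphe↔demeter+sara ancestor
(3.35 Myr, γ=0.10); `mutation_scale` 0.0075 substitutions/site per
coalescent unit.  These values were fixed once by calibrating against the
published characteristics of such data: at ρ=2000 on 10 Mb the generator
yields ~117k loci of ~86 bp mean length, a dominant-topology site share of
~50%, and ~14 parsimony-informative sites per 250 bp window.

**Locus semantics.**  A "locus" is a segment between recombination
breakpoints falling in material ancestral to the sample — the segments an
`ms -T` run prints one tree for.  Many such breakpoints do not change the
marginal genealogy (the recombining lineage coalesces straight back), so
adjacent loci can carry identical trees; `TruthMap.merge_same_topology()`
gives the merged, topology-only view (about an order of magnitude fewer
blocks).  Implementation-wise the simulator records the full ARG for the
breakpoints but converts only the distinct genealogies of the simplified
tree sequence.  Because the full ARG is memory-hungry at high ρ, chromosomes
longer than `block_length` (default 1 Mb) are simulated as independent
consecutive blocks with ρ apportioned by length; this leaves all local
statistics unchanged and only removes (already negligible at these ρ)
long-range linkage across blocks.  `rho=0` is never blocked, so it yields
exactly one chromosome-spanning locus.  With a discrete genome all interval
bounds are integers and tile exactly.

**What the generator does not emulate:** indels and alignment error,
rate heterogeneity among sites or branches, non-JC substitution biases,
gene/exon structure, diploid phasing, and recombination-rate variation along
the chromosome.  Passing tests therefore show that the criterion behaves as
claimed for clean, homogeneously recombining JC data — not that real
alignments are free of the additional error sources above.

## Accuracy measures

Site accuracy: the percent of sites whose covering window was assigned the
same unrooted topology the site was simulated from; computed by an interval
sweep (verified exactly against a per-site loop).  For plain NOW runs the
denominator is the full chromosome, so sites in a dropped trailing remainder
count as incorrect; for stepwise runs a "covered" denominator restricted to
the analyzed windows is available, since jointly filtered regions are
excluded by design.  RMSE compares predicted (truth) and observed (window)
topology-weight distributions over the union of topologies seen in either,
`sqrt(sum_i (P_i - O_i)^2 / n)` with `n` the union size; observed weights
are site-weighted by default (window-counted available), matching the
site-weighted truth.

## Stepwise procedure

`joint_filter` keeps a large window iff it and both halves pass the
analyzability rule, so the retained site sets at the two compared sizes are
identical (asserted, not assumed).  The chain starts at 64 kb by default,
compares `(w, w/2)` with `blmin` recomputed per size, and by default stops
at the first comparison the larger size wins — since each step's AICs are
computed on a different retained region, AIC values are not comparable
*across* steps, and the pairwise-winner chain is the only coherent
descent rule.  A `full_chain` mode records every comparison for reporting.
Reaching the floor (125 bp default) with the smaller size still winning sets
a "still declining" flag: the best size is at most the floor.  Analyzability
defaults to strict (every taxon must have data in the window, required for a
fixed-taxon-set likelihood comparison); the lenient ≥3-taxa rule is
available, in which case windows contribute `k = 2t-3` with their own `t`.
Bootstrap support is computed only at the selected size.

## Numerical and degenerate-input choices

- Pattern compression before any likelihood work; per-node rescaling guards
  underflow on longer windows.
- JC distances use pairwise complete sites; saturated (p ≥ 0.75) or
  data-free pairs get `blmax`.  NJ ties break on the smallest index pair;
  negative NJ branch estimates are clamped to zero before optimization.
- All-identical windows: every topology ties; the lexicographically first
  canonical topology is returned (deterministic).
- Window grids: the remainder `L mod w` is excluded from analysis so the
  partition is exactly equal-sized; `n_sites` counts analyzed sites only.
- Determinism: every stochastic component (simulation, bootstrap) is driven
  by an explicit seed; identical inputs and seeds give identical outputs.

## Scaled-down validation study

The validation suite runs the simulation study at desk scale: the gene-tree
scale check at the full 10 Mb (trees only, no sequences), and the criterion
behavior on 1 Mb chromosomes with ten replicates per setting, using the same
*per-base* recombination density as the corresponding 10 Mb setting (a 1 Mb
chromosome at the "ρ=2000" density uses segment-total ρ=200) and the size
grid {1, 2, 5, 10, 20, 50 kb, full length}.  One-megabase replicates show
substantially more between-replicate variance in topology-weight summaries
than 10 Mb chromosomes, especially at low recombination densities where few
independent topology blocks exist; quantities tied to those weights
(concatenation accuracy, accuracy ceilings) are therefore assessed on
replicate means and, where a stable value is needed, at the 10 Mb scale.

## Known limitations

- JC only, by design: the point is the window-size criterion, not the
  substitution model.
- The NNI hill-climb is a local search; IQ-TREE-style stochastic restarts
  are out of scope.
- Support values are plain bootstrap, not UFBoot; thresholds transfer in
  spirit, not numerically.
- The AIC selects a single window size per chromosome; recombination-rate
  variation within a chromosome (and hence variable window sizes) is not
  modeled.
- The maximum achievable site accuracy at the highest recombination density
  comes out a few percentage points below the published ~75% under this
  generator's calibration (see the validation suite); the fitted trees are
  at their ML statistical limit, so this reflects residual differences
  between the emulated and original (unpublished) demographic calibrations.
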