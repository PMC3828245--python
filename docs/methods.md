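# Methods

## Coordinate frame and variant nomenclature

All variants are expressed in the 16,569-bp rCRS coordinate frame.
Sequences are treated as linear strings already in rCRS register (position
1 first), as deposited mitogenome records are; circular rotation is not
detected — a rotated or non-mitochondrial input fails the alignment
identity floor (default 0.90) instead.

Alignment is global with affine gaps, match/mismatch/open/extend =
+1/−1/−8/−1 (configurable). Because inputs are near-identical to the
reference, the dynamic program is restricted to a diagonal band (default
half-width 32, doubled and re-run whenever the optimal path touches a band
edge), which makes a full-genome alignment take milliseconds rather than
seconds. Gap runs are then shifted leftmost wherever the move is
score-neutral, the usual normalization convention, so indel placement is
deterministic. One visible consequence: an insertion inside a homopolymer
is reported at the 5′ end of the run (a C inserted into the 311–315 tract
surfaces as `310.1C`); since poly-C length variation is masked for
classification, network building and dating, the choice has no downstream
effect there.

Variant labels follow field convention: transitions by bare position,
transversions with the derived base appended, deletions per reference
position with a collapsed `start-enddel` form for runs, insertions as
`pos.kN`. IUPAC ambiguity codes yield no variant; the position is removed
from the sample's compared set and treated as missing in every distance and
diversity computation — heteroplasmies never force an allele choice.

The packaged reference (`data/synthetic_rcrs.fasta`) is a synthetic
stand-in: deterministic pseudo-random sequence of the correct length
carrying the coordinate anchors the conventions depend on (poly-C tracts at
303–315 and 16184–16194 with T at 310/16189, T at 16519, A at
16182/16183, the CCCCCTCTA tract at 8281–8289, and classical anchor states
at positions such as 73, 263, 750, 2706, 7028). The gene-annotation table
uses the real human mtDNA gene coordinates; intergenic gaps are filled as
noncoding spacers at load time so the table tiles the genome. Functional
annotation (synonymous / nonsynonymous / rna / noncoding) translates
codons against the packaged reference under the vertebrate mitochondrial
code; positions in an incomplete trailing codon (mitochondrial stop codons
completed by polyadenylation) are classed noncoding, indels in coding genes
nonsynonymous by convention, and a substitution covered by overlapping
coding genes is nonsynonymous if it changes the protein of any of them.
Every internal computation is consistent with whatever reference is loaded,
so analyses of real data should load the genuine rCRS.

## Masking

The default mask removes all variants at 16182, 16183 and 16519 and all
length variants (insertions/deletions) inside 303–315 and 16184–16194;
substitutions inside the poly-C tracts other than the listed positions are
kept. Masking applies to classification, network construction and dating.
Diversity and structure statistics use unmasked profiles by default — the
exclusion list exists to stabilize mutation counts on genealogy branches,
not to redefine the site pool — with a config flag (`mask_diversity`) to
mask them too.

## Haplogroup classification

The haplogroup hierarchy is a rooted tree whose edges carry defining
mutations in the same label nomenclature; `label!` marks a back mutation.
For each node the cumulative expected state is accumulated along the root
path (a back mutation deletes its slot; a later motif at an occupied slot
replaces it). A profile is scored per node as matched − missing; the
maximal score wins, ties broken by larger matched count, then depth, then
lexicographic name, with co-optima recorded. The scoring rule is
deliberately simple so that an exhaustive per-node oracle can verify it;
adding a private variant shifts all scores equally and can never change an
assignment. A ~40-node toy hierarchy ships for tests and examples; a full
Phylotree import is an ordinary input file, not a dependency.

## Networks and genealogies

Samples with identical masked label sets collapse into haplotype classes;
classes become binary presence/absence vectors over the observed variant
labels (unit weights by default; a per-label weight hook exists). The
median-joining construction at ε = 0 links classes by the
minimum-spanning network (all MST-tied edges), adds majority-consensus
medians of mutually adjacent triplets, iterates to a fixed point, and
finally discards unsampled medians of degree ≤ 2 (such nodes sit on
geodesics and never change tree length). Construction is invariant to input
order.

For dating, the network is resolved into a rooted tree. On small instances
(≤ 10 terminals, ≤ 16 segregating labels) the minimum Steiner tree
connecting the observed classes is computed exactly by the Dreyfus–Wagner
dynamic program, drawing candidate junctions from the median closure of the
node set — for binary characters the median closure contains the junctions
of every most-parsimonious tree, so the extracted genealogy attains the MP
length (verified against exhaustive topology enumeration with Fitch
counting). Larger instances fall back to a deterministic
minimum-spanning-tree resolution preferring fewer mutations, then higher
observed multiplicity, then label order. Exact-mode ties are broken by
canonical vertex order. Edges carry their separating labels, so clocks can
restrict which mutations they count.

## ρ dating

ρ is the multiplicity-weighted mean mutation count from sampled haplotypes
to the root; σ² = Σ(n_e/n)²·m_e over edges. A linear clock converts ρ to
years: the complete-genome clock defaults to 1.665×10⁻⁸
substitutions/site/year over 16,569 sites; a synonymous clock counts only
edge labels annotated synonymous, with its rate and site count as config
parameters. A ρ→ρ′ correction hook (identity by default) is exposed for
saturation/selection rate curves; the linear clocks are the tested surface.
Intervals are ρ ± σ by default (± 2σ by flag), floored at zero.

The ±2σ interval should be read as heuristic, not nominal-95%: σ̂ is
unbiased for Var(ρ | genealogy) but at small expected counts (a few
mutations per lineage) it is noisy and positively correlated with ρ, which
makes the interval anticonservative. The acceptance script quantifies this
by simulation (`tmrca_coverage_2sigma_pct`, 200 constant-size clades of 30
samples with true age ≈ 15 ky scored on their true genealogies): measured
coverage sits just below 0.9 rather than at 0.95. This is a property of
the estimator at that mutation depth, not of tree reconstruction — the
experiment uses the true genealogy, an upper bound for any reconstruction.

## Diversity statistics

Computed from variant profiles under a deletion policy: complete deletion
(default — a position ambiguous in any sample is dropped for all) or
pairwise deletion; sites are substitutions only by default, with indel
slots includable by flag. Hd uses the unbiased estimator n/(n−1)(1−Σp²)
with its standard sampling variance; k accumulates per-segregating-site
mismatch counts (equivalent to the O(n²) pair loop, which the tests run as
an oracle); π = k / compared sites with the total-variance estimator
(n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1)). Tajima's D uses the full
constant cascade a₁…e₂; it raises on S = 0 or n < 4 rather than returning
NaN. Significance is a two-tailed empirical p from neutral constant-size
coalescent replicates conditioned on S (mutations scattered on branches in
proportion to length), binned at 0.05/0.01/0.001; the replicate count and
seed are explicit (10,000 is a sensible production setting; tests and the
bundled pipeline default to smaller counts, which is a precision choice —
p-value granularity — not a validity one). Haplotype counts include indels
by default (profiles are complete genomes); a toggle restricts them to
substitutions.

## AMOVA, Φ statistics, MDS

Pairwise difference counts are used directly as squared distances, the
convention for haplotype data. Sums of squared deviations give
method-of-moments variance components for the 2-level (populations in
total) and 3-level (populations in groups) designs; Φ_ST, Φ_SC, Φ_CT are
component ratios. Negative components are reported as computed;
percentages are renormalized for display only. Permutation tests (default
10,000, p = (b+1)/(m+1)) shuffle sample indices among populations for
Φ_ST, within groups for Φ_SC, and whole populations among groups for
Φ_CT; samples are canonically ordered by (population, id) first, so
p-values are invariant to input row order under a fixed seed. A pairwise
Φ_ST matrix runs each pair as a 2-level AMOVA, which is exactly consistent
with the global 2-population case.

MDS is Kruskal's nonmetric scaling (stress-1): iterative majorization
(Guttman transform) alternating with monotone regression by
pool-adjacent-violators, started from the classical (Torgerson) solution
plus seeded random restarts (default 8); best stress wins, metric scaling
available by flag. Slightly negative Φ_ST inputs are clamped to zero with
a warning. On exactly embeddable inputs the classical start already gives
stress ≈ 0.

## The simulator: what it emulates, what it does not

The generator produces data with the statistical structure the analysis
assumes: Kingman genealogies under constant size, exponential growth or a
two-epoch size change (waiting times by analytic inversion of the
cumulative coalescence rate); Poisson mutations at a per-site per-year rate
(default 1.665×10⁻⁸, generation time 25 y, 95% transitions) with
multiplicative hotspot factors (default 50× at 16182/16183/16519, 20×
across the poly-C tracts) so that masking demonstrably matters; and a
finite symmetric island model (defaults: 50 demes of haploid size 500, 8
demes sampled × 8 samples) whose equilibrium differentiation for haploid
demes is F_ST = 1/(1 + 2Nm(d/(d−1))²) — with 50 demes within 0.01 of the
idealized 1/(1+2Nm) recorded in the truth table. Deme count and sampling
fractions were fixed from that analytic correction, not fitted.

Recurrent hits are possible but rare at default rates and are flagged in
the truth table so round-trip tests can condition on unique-site
instances. The simulator does not emulate: length-variant mutational
processes (poly-C indels arise in real data but only substitutions are
simulated — masking of simulated hotspots stands in for them), rate
heterogeneity beyond hotspots, selection, recombination, sequencing error,
or heteroplasmy. Passing recovery tests therefore validates the estimators
under the neutral clock model, not robustness to those real-data
complications.

## Numerical and degenerate-input choices

Banded alignment re-runs with a doubled band if the optimal path touches a
band edge, so results never silently depend on the band. Tajima's D and
haplotype diversity raise explicit errors on undefined inputs (S = 0,
n < 2, n < 4). AMOVA refuses singleton populations. A single haplotype
class yields a one-node network, not an error. All permutation and
simulation seeds are explicit arguments recorded in outputs; pipeline
outputs embed a config hash and are byte-identical across reruns.

## Known limitations

- The classifier is a transparent scoring rule, not a re-implementation of
  any published classifier; on real data with heavy homoplasy its
  tie-breaks may differ from expert curation.
- ε > 0 median-joining is implemented as connection-level slack but only
  ε = 0 is exercised by the validation suite.
- The Steiner-exact path is exponential in terminal count and is capped;
  large clades use the MST heuristic, which can exceed MP length on
  pathological character conflicts.
- ±2σ ρ intervals are anticonservative at shallow mutation depths (see ρ
  dating above).
- The synthetic reference makes absolute functional-annotation calls
  (which exact codon changes) meaningful only relative to itself.
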