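# Methods

## Problem setting

Gut bacterial lineages can diversify in parallel with their hosts
(co-diversification), so that the symbiont phylogeny within a clade mirrors
the host phylogeny. `codiverge` implements the statistical pipeline for
detecting such clades across a genome-resolved symbiont phylogeny (tips are
metagenome-assembled genomes, MAGs, each linked to the host species it was
recovered from), for asking which detected clades are ancestral and whether
they survived domestication of the host, for contrasting selection and
genetic drift between laboratory- and wild-mouse symbiont strains, and for
re-analysing germ-free co-housing competition experiments. All stages run
on synthetic inputs produced by `codiverge.simulate`, which encodes the
statistical structure the analyses assume, together with ground-truth
labels for recovery tests.

## Cophylogenetic tests

Three complementary permutation tests, all operating on a set of links
(symbiont tip, host species) and two patristic distance matrices:

* **Hommola-style Mantel test.** For every unordered pair of links, the
  host distance of the two linked hosts is paired with the symbiont
  distance of the two linked symbionts; the statistic is the Pearson
  correlation r over these pairs. The null permutes the host-assignment
  and symbiont-assignment indexings independently.
* **PACo (Procrustes) test.** Both distance matrices are embedded by
  principal coordinates (Cailliez-corrected, see below); the symbiont
  configuration, one row per link, is superimposed on the host
  configuration by least-squares Procrustes after centering and unit-trace
  scaling. The statistic is the residual sum of squares m² ∈ [0, 1]
  (small = congruent); the null permutes the rows of the binary
  association matrix.
* **ParaFit global test.** With host and symbiont principal-coordinate
  matrices B and C and association matrix A, the statistic is
  trace(D′D) with D = C′AB; the null permutes host assignments within A.
  The implementation reproduces `ape::parafit` exactly on shared fixtures.

Permutation p-values use the add-one convention p = (1 + c)/(1 + B) with
ties counted as extreme, so p ≥ 1/(B + 1) and never 0. With 999
permutations the attainable floor is 0.001, consistent with reporting
"p < 0.01" at that permutation count.

Principal coordinates are computed by Gower-centering −d²/2 and
eigendecomposition; axes with eigenvalues ≤ 1e−9 × the leading eigenvalue
are dropped and coordinates are eigenvectors scaled by √eigenvalue. Tree
distances are generally non-Euclidean, so PACo/ParaFit use the Cailliez
correction: the closed-form smallest constant c (largest eigenvalue of the
2n × 2n Cailliez block matrix) added to off-diagonal distances to make the
matrix Euclidean.

## The genome-wide scan

`scan.scan_tree` tests every internal node of the symbiont tree passing
three filters (defaults are the study settings):

| filter | default | rationale |
| --- | --- | --- |
| min hosts | 3 | fewer host species leave the correlation undefined or trivial |
| min symbionts | 7 | smaller clades have negligible power at 999 permutations |
| span fraction | 0.25 | restricts tests to the distal part of the phylogeny, where clades postdate the host radiation |

The "distal quarter" is operationalised as clade span (largest tip-to-tip
patristic distance within the clade) < 0.25 × whole-tree span; span is
monotone from tips to root, so the filter selects a distal frontier. Node
height or rank are alternative readings; span matches the phrasing
"spanned less than a quarter of the total phylogeny" most directly and is
invariant to rootward rearrangements.

A clade is called co-diversifying when r > 0.75 and p < 0.01 (999
permutations). Per-node seeds are derived from the master seed plus the
node index, so scans are reproducible and order-independent. Nodes with
undefined statistics (zero distance variance) are recorded with NaN and
excluded from counts.

Nested significant clades share tips, so per-node p-values are not
independent and no FDR correction is applied across nodes. Two devices
replace it:

* **Host-label permutation null** (`null_label_scan`): species names are
  shuffled uniformly across host-tree tips and the entire scan re-run; the
  distribution of significant-clade counts under label permutation gives a
  non-parametric p for the observed count. Uniform shuffling (rather than
  topology-constrained swaps) is the simplest exchangeable null.
* **Dereplicated scan** (`dereplicated_scan`): each testable clade is
  collapsed to one genome per maximal monophyletic group of tips sharing a
  host species (representative chosen uniformly under the seed), removing
  pseudoreplication from repeated sampling of one host species; all three
  tests are then run, and clades with ≥ 2 tests at p < 0.01 are flagged as
  multi-support.

`resolve_nested` reduces significant clades to the maximal (most
inclusive) non-nested set — the ancestral clade subsumes its descendants —
and `sensitivity_scan` re-runs the scan leaving each host species out in
turn, reporting how many originally significant clades survive.

## Retention, contingency, and clocks

A non-nested significant clade is *ancestral to murids* when it contains
at least one genome from the focal host (Mus musculus domesticus), one
from another murid, and one from an outgroup to murids. Over ancestral
clades, presence/absence in wild versus laboratory house mice forms a 2×2
table tested by Pearson's chi-squared without continuity correction
(df = 1). The no-correction choice is deliberate: on the published table
[[7,33],[16,24]] it gives p = 0.0262 (χ² = 4.943), whereas the
Yates-corrected p is ≈ 0.049; the package asserts the uncorrected value as
a regression test.

Molecular-clock regressions relate pairwise symbiont divergence (patristic
distance on the clade tree) to host divergence time over all
cross-host-species pairs of linked tips, by ordinary least squares with a
95% t-interval on the slope. Pairs are used without
phylogenetic-independence correction, and the interval is on the slope
(not a prediction band) — the simplest reading of a base-R regression
workflow. The caveat is that shared paths make pairs positively
correlated, so the nominal interval is anticonservative; the coverage test
uses independent-noise synthetic pairs where the nominal level holds.

## dN/dS estimation

Maximum-likelihood branch models (CODEML-style) are replaced by a
counting estimator — the one deliberate methodological substitution in the
package. It is desk-scale, dependency-free, and the downstream statistics
(group means, quadrant counts, paired log-ratio tests) consume per-branch
dN/dS values regardless of how they were estimated.

* **Sites (NG86).** Each codon position contributes syn/3 synonymous and
  (non-stop nonsynonymous)/3 nonsynonymous sites over its three possible
  changes; mutations to stop codons are excluded, so a codon with stop
  neighbors totals slightly under 3 sites.
* **Differences.** Codon pairs are resolved by averaging the synonymous /
  nonsynonymous step counts over all stop-free minimal mutational
  pathways (all pathways, with stop steps counted as nonsynonymous, in the
  rare case every pathway is blocked). Codons with gaps or ambiguity in
  either sequence are skipped.
* **Correction.** Proportions are corrected with the Jukes–Cantor formula
  d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 (saturation) leaves the branch
  undefined. dN/dS is defined only when both dN and dS are positive and
  finite; undefined branches drop out of group means, and genes with no
  defined branch in a group are excluded — matching the convention of
  analysing only genes with nonzero dN and dS.

Ancestral sequences are reconstructed per nucleotide column by Fitch
parsimony (gaps treated as fully ambiguous). Ties are broken
deterministically: a node takes its parent's state when compatible,
otherwise a state from its first child's downpass set (falling back to the
alphabetically first base). This places equally parsimonious changes on
terminal branches, which is where the branch estimates are read: each tip
is compared to its parent's reconstructed sequence. Trees with two tips
fall back to the direct pairwise comparison.

Known bias: the counting estimator ignores the transition/transversion
ratio, which at κ = 2 depresses dN/dS by ≈ 11% (first order); with the
short branches typical of recently diverged strains the measured recovery
is 0.90–0.95 of the simulated ω. The bias cancels exactly in the paired
lab−wild log contrast, which is the quantity of scientific interest.

## Group contrasts and drift

Per gene, unweighted means of terminal-branch dN/dS are taken over
laboratory-derived and wild-derived gene copies (branch-length weighting
is a defensible alternative; unweighted is the simplest reading and is
what the recovery tests calibrate). Genes are classified by quadrant
(lab mean vs 1, wild mean vs 1), the asymmetry between
lab-positive/wild-purifying and wild-positive/lab-purifying counts is
tested by an exact two-sided binomial test against 1/2, and genome-wide
drift is tested by a paired t-test on per-gene
log(lab mean) − log(wild mean), optionally restricted to genes under
purifying selection in both environments (both means < 1). Per-clade tests
are Benjamini–Hochberg corrected across clades. Genome-wide elevation of
dN/dS across many genes is the signature of reduced effective population
size (drift), as opposed to gene-specific positive selection.

The phylogenetic ANOVA uses the ordinary one-way F statistic with a null
distribution from Brownian-motion simulations on the tree: the trait's
rate is the GLS (phylogenetically weighted) residual variance, traits are
simulated with covariance σ²·C (C = shared root-distance matrix), and
p = (1 + #{F_sim ≥ F_obs})/(1 + n_sim). On a star tree this reproduces the
classical F-test; with groups confounded with deep clades it is properly
more conservative.

## Competition reanalysis

Samples are rarefied to a common depth (40,000 reads by default) by
hypergeometric subsampling; samples below depth are dropped with a log
message. Diagnostic ASVs are those in co-diversified taxa detected
(count > 0, assessed after rarefaction) at day 0 in exactly one source
group, labeled wildling- or lab-derived. Dice dissimilarity
1 − 2|A∩B|/(|A|+|B|) on diagnostic presence profiles measures strain
sharing (two empty profiles are defined as 0, logged); ordination uses
Cailliez-corrected principal coordinates.

The headline contrast — are germ-free (GF) recipients closer to the
wildling or the laboratory source community? — averages each GF mouse's
longitudinal dissimilarities within each contrast first (the mouse is the
experimental unit; samples within a mouse are dependent), then runs a
two-sided permutation t-test over the per-mouse-averaged values,
permuting group labels across units. Because each GF mouse contributes a
unit to both contrast groups, the raw pipeline's null is conservative;
calibration is therefore assessed under the exchangeable label-copy null
(labels reassigned at random across units), where the type-I error is
nominal (0.045–0.05 at α = 0.05 in the acceptance run). The trajectory
test computes, per GF sample in days 7–17, the relative-abundance
difference between wildling- and lab-derived ASVs of a genus, and applies
a one-sample two-sided t-test to the differences.

## Synthetic data

`simulate` generates every input: hosts under a unit-rate Yule (pure
birth) process (ultrametric; a fixed ladder topology is available for
deterministic fixtures); co-diversifying clades that copy a host subtree,
jitter branch lengths by exp(N(0, σ²)) with σ = 0.1, re-associate each
lineage to a random other host with probability s (host switch modeled as
tip re-association, the simplest mechanism that degrades congruence
continuously), and sprout 2 genomes per host on short within-host
branches; random clades as independent Yule trees with uniformly assigned
hosts; and a deep star backbone joining clades so that only within-clade
nodes fall in the distal quarter. Scan-stage defaults (5 planted + 20
random clades, 10 hosts) mirror the planted-recovery design of the
acceptance checks.

Codon alignments evolve by an attempt/rejection mechanism deliberately
disjoint from the counting estimator (no shared code path): attempts
arrive as a Poisson process with the branch length as expected attempts
per nucleotide site, target bases are drawn with transition:transversion
odds κ:1 (κ = 2 by default), changes creating stops are rejected, and
nonsynonymous changes are accepted with relative probability ω of the
branch class (lab 0.6 / wild 0.3 by default, reflecting relaxed purifying
selection in the laboratory; ω > 1 instead thins synonymous changes by
1/ω). Gene trees default to lab/wild sister groups of two tips each with
0.05-substitution branches — closely related strains diverged recently,
so divergence is low and the Jukes–Cantor correction stays nearly linear.
Default gene lengths are 2,000 codons for recovery checks and 200 codons
(a typical bacterial gene) for the replicated drift simulations.

The competition generator mirrors the scale of the rarefied co-housing
dataset: 2,640 ASVs of which ~105 are diagnostic (52 wildling-specific +
52 lab-specific in four co-diversified genera, the rest shared
background), lognormal(0, 1.5) abundance weights shared between the two
source profiles (disjoint ASVs, identical weights — so with advantage 0
the design is exactly symmetric and colonization dynamics are the only
signal), 4 + 4 source mice at day 0 and 6 GF mice sampled daily on days
1–17, each sample a multinomial draw of 40,000 reads from a mixture whose
wildling weight follows a logistic in time with slope `advantage`
(default 0.5) centered at day 4. At this scale rare ASVs sit near the
detection limit, giving the presence/absence profiles the sampling noise
the Dice analyses assume.

What the generators do **not** emulate: real sequencing error and chimera
formation, within-host strain population dynamics, horizontal transfer of
genes (as opposed to whole-lineage host switches), selection heterogeneity
along sequences (sitewise ω classes), compositional correlations between
taxa, and cage effects in the co-housing design. Passing tests therefore
demonstrate that the statistics recover the signals they target under
their own assumptions at realistic scale — not that those assumptions hold
in any particular real dataset.

## Numerical conventions and degenerate inputs

* Permutation ties count toward the extreme tail (conservative); all
  permutation p-values use the add-one convention.
* Seeds are explicit everywhere; batch operations derive per-item seeds
  from the master seed so results are independent of evaluation order.
* Zero-length branches are allowed and never block monophyly or
  distances; multifurcations are preserved, not resolved.
* Zero-variance distance vectors, degenerate groupings, empty taxa sets,
  and all-below-depth tables raise typed errors; a scan logs and records
  such nodes rather than aborting.
* Paired tests return (0, 1) when all differences are exactly zero and
  raise on nonzero constant differences (undefined t).

## Problem sizes

The default test suite and the acceptance script use the problem sizes
chosen for the package's own verification: 1,000 null clades at 199
permutations for calibration; a 5-planted/20-random clade tree (~220
genomes) at 999 permutations and 19 label permutations for scan recovery;
16 genes × 2,000 codons per ω for recovery; 50 × 100-gene and 200 ×
30-gene replicates for drift power and calibration; 20 and 200 replicates
for competition power and calibration. The suite completes in well under
two minutes on one CPU.

## Known limitations

* The NG86/Fitch estimator is a first-order stand-in for ML branch
  models; absolute ω values carry the κ bias discussed above.
* The clock CI ignores pair non-independence.
* The label-permutation null permutes all host labels uniformly; if host
  sampling effort is strongly structured, a constrained permutation
  scheme could be preferable.
* `select_diagnostic`'s day-0 detection filter runs after rarefaction;
  ASVs lost to subsampling at day 0 cannot become diagnostic.
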