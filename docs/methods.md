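# Methods

## The question and the approach

An allopolyploid genome carries the traces of its own history in the
divergence of its duplicated genes.  For a hexaploid weed genome formed from
three subgenomes, every retained ancestral gene contributes paralog pairs
(split by the polyploidization/hybridization event) and ortholog pairs to
related diploid genomes (split at older speciations).  The transversion rate
at four-fold degenerate third codon positions (4dTv) of a gene pair is a
nearly neutral divergence proxy: third positions of four-fold codon families
are free of protein-level constraint, and restricting to transversions
(purine <-> pyrimidine changes) slows saturation, which for this statistic
occurs at 0.5.  The distribution of 4dTv over syntenic gene pairs therefore
shows one mode per divergence event, and a molecular clock converts mode
positions to ages.

The package implements that chain of reasoning as five stages — simulate,
per-pair 4dTv, synteny chaining, peak dating, family statistics — each
usable alone, plus an orchestrated pipeline.  Because the original genome
data are not needed to validate the *method*, a simulator generates genome
sets with known divergence structure and per-pair ground truth.

## Simulator

Sequence evolution is a site-independent two-parameter (Kimura-type)
nucleotide process: transitions at rate kappa*beta, each of the two
transversion types at rate beta.  Divergence is parameterized directly in
beta*t units ("tau", the total pairwise path length), never in years; the
clock enters only in the dating stage.  Under this model the expected
transversion-difference fraction between two sequences separated by tau is

    Q(tau) = (1 - exp(-4 tau)) / 2,

so a simulation can be pinned to an observed 4dTv peak x by inverting:
tau = -ln(1 - 2x)/4.  Per-site outcome probabilities are the standard
two-parameter transition probabilities; sampling is vectorized per branch.

A genome history is an ordered list of events, deepest first, each with its
total pairwise tau: a *speciation* clones the current focal lineage set into
an outgroup genome that evolves undisturbed to the present; a *WGD* turns
every focal lineage into `copies` subgenome copies (default 2; the bundled
hexaploid scenario uses 3, modeling three subgenomes that diverged at one
level — a modeling choice, since only the single observed paralog peak
constrains it).  Each post-WGD gene copy is lost independently with
probability `loss_prob`, so after one WGD the expected paralog-pair count is
n_genes*(1-loss_prob)^2.  Ancestral genes are random sense codons flanked by
ATG and a stop; evolved sequences may contain internal stops — only third
positions of four-fold families are read downstream, so coding validity is
deliberately not repaired.

Gene order is perfectly collinear across copies apart from losses; there are
no inversions, tandem arrays, or indels.  The hit table is emitted from the
truth (percent identity set to the model's expected sequence identity at the
pair's tau), optionally plus uniform-random decoy pairs (5% of true hits) to
exercise chaining noise tolerance.  Reproducibility: a single root seed;
every per-gene/per-branch stream is seeded by a SHA-256 hash of (seed, gene,
lineage, branch), so outputs are byte-identical across runs and independent
of iteration order.

Default study conditions mirror the three observed divergence levels:
paralog peak 0.042 and ortholog peaks 0.16 / 0.27, three subgenomes, two
outgroups.  The bundled scenario uses 160 ancestral genes of 240 codons (10
genes per chromosome, 5% loss); the WGD-recovery experiment uses 400 genes
of 300 codons (10% loss).  Gene lengths are chosen at the realistic scale of
grass coding sequences; at much shorter lengths (~100 codons) a pair has
only ~40 countable four-fold sites, so per-pair 4dTv is quantized at ~0.025
and the peak position inherits that grain.

## 4dTv computation

Pairs are aligned codon-aware: translate (standard code; internal stops
become `*` and align like residues), globally align the proteins (BLOSUM62,
affine gaps open 11 / extend 1, leftmost-gap tie-breaking), back-translate
so gaps come in whole codons.  A third position is a counted four-fold site
iff neither codon has a gap or ambiguity, both codons are in a four-fold
family (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN), and the first two codon
positions agree between the pair — the conservative convention, avoiding
third positions whose degeneracy class differs between the genes.  4dTv is
the raw transversion fraction over those sites (no multiple-hit correction
by default, matching the scale of the anchor values 0.042/0.16/0.27; a
Kimura-style corrected variant, -ln(1-2q)/2, is available behind a flag and
is undefined at q >= 0.5).  Pairs with zero four-fold sites are flagged
undefined and excluded downstream.  Amino-acid distances are p-distances
over gap-free columns with the Poisson correction -ln(1-p).

## Synteny chaining

Anchors carry gene-order ranks (coordinate-sorted indices per chromosome),
not base pairs — robust to gene-length variation.  Within one chromosome
pair, chains must advance ranks strictly in both genomes (rank_b descending
for inverted blocks), with rank gaps at most `max_gap` (default 10) on each
axis; score = 10 per anchor minus 1 per unit of rank gap per genome.  The
optimal chain is found by O(n^2) dynamic programming; maximal chains are
extracted greedily (best score, then forward orientation, then earliest
start, then longest), their anchors removed, and the process repeated;
chains under `min_anchors` (default 5) are discarded.  Anchors sharing a
rank (tandem-like duplicates) collapse to the best-scoring one before
chaining.  Each block's 4dTv is the median (mean behind a flag) of its
anchors' defined pair values — robust to a single outlier pair.

## Peak detection and dating

The block-level 4dTv values get a Gaussian KDE on a 512-point grid over
[0, max + 3h]; h is Silverman's rule (0.9 * min(sd, IQR/1.34) * n^(-1/5))
unless given explicitly, with a 0.01 fallback for zero-spread samples.  The
KDE is a direct kernel sum, so an absolute bandwidth and degenerate samples
are both well defined.  Peaks are interior local maxima whose prominence —
height minus the higher of the two *adjacent* flanking minima (boundary
density values where no interior minimum exists) — reaches 5% of the maximum
density.  Measuring against adjacent minima makes a near-flat density report
no peaks while a true mode keeps essentially its full height.  Peak
positions are reported at grid resolution (no parabolic refinement — a known
limitation; the grid step is max(values)/511, ~2e-3 for typical inputs and
well inside the tolerances used here).

The clock is two-lineage: both descendants accumulate divergence, so a
calibration anchor (x, t) gives rate = x/(2t) per lineage and a peak at
position p dates to p/(2*rate).  The two ortholog anchors (0.27, 46.7 Mya)
and (0.16, 27.9 Mya) are mutually consistent within 1% (cross-dating gives
27.67 and 47.08 Mya); the shallow paralog peak at 0.042 dates to ~7.3 Mya
under the deep anchor — the published ~7.8 likely reflects unrounded peak
positions, so this package reports dates only from explicit anchors.

## Family statistics

Domain over-representation uses the one-sided upper-tail hypergeometric
test, with the focal genome's n genes treated as a draw without replacement
from the union of all genomes' genes (focal included — the standard
one-set-vs-union convention; the paper-style "other genomes as background"
wording is ambiguous, so the universe is configurable by listing background
genomes).  No multiple-testing correction by default; Benjamini-Hochberg
behind a flag for scans.  Expansion profiles are within-family pairwise
amino-acid p-distances (pairs aligned as above), binned at width 0.02, with
the fraction below 0.05 reported as the recent-expansion signal.  The qPCR
fold change is 2^-ddCt from target/reference cycle thresholds in treatment
vs control.

## What the simulations do and do not show

Passing tests demonstrate that the statistics recover the divergence
structure the simulator put in: peak positions within tolerance of the
configured levels, correct paralog/ortholog ordering, chaining optimality
against exhaustive search, and closed-form agreement of the evolution model.
The simulator omits selection, codon bias, rate heterogeneity across sites
and lineages, indels, inversions, tandem duplication, fractionation bias
between subgenomes, and annotation error — so these results validate the
pipeline's arithmetic and bookkeeping, not the biological calibration of any
particular genome.  Peak positions on real data also depend on alignment
quality and on the unstated smoothing/counting conventions of any published
figure being compared against.

## Numerical and degenerate-input conventions

Zero-tau evolution returns the input unchanged; tau < 0, target 4dTv >= 0.5,
empty sequences, impossible count tables, non-positive clock inputs, and
sub-minimum configs raise ValueError.  Undefined statistics (no four-fold
sites, no defined block values, p = 1 Poisson correction) are flagged None/
NaN and excluded rather than coerced.  Densities need >= 2 values.  All TSVs
have headers and stable column order; writes are atomic (temp + rename); the
pipeline manifest records parameters, row counts and SHA-256 checksums of
every output, and identical config + seed reproduces identical checksums.
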