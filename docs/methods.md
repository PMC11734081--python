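# Methods

## The analysis model

`nlrkit` treats a genome-wide NLR survey as a deterministic pipeline
over InterProScan-style domain annotations. Its unit of analysis is a
protein with a set of InterPro accessions; every downstream quantity —
candidate membership, architecture class, co-occurrence combination,
unique-domain set — is a pure function of those accession sets under a
declared *role map*.

**Role map.** Roles are architectural slots: N (NB-ARC), L1–L4 (the
four tracked leucine-rich-repeat InterPro entries), C (N-terminal
coiled-coil) and T (TIR). The default map is
N = {IPR002182}, L1 = {IPR001611}, L2 = {IPR011713}, L3 = {IPR013210},
L4 = {IPR025875}, C = {IPR041118}, T = {IPR000157}. N and L1–L4 are
fixed by the mining protocol the package models. C and T have no single
canonical InterPro entry: IPR041118 (Rx-type N-terminal coiled-coil)
and IPR000157 (TIR) are the natural defaults and both occur in the
surveyed species' domain vocabularies, but they are deliberately
user-overridable (`roles.yaml`), and every classification records the
SHA-256-derived hash of the map in force so results are attributable to
a specific configuration. Role sets must be pairwise disjoint so one
accession never asserts two roles.

**Mining.** A protein is a candidate iff it carries ≥ 1 hit whose
InterPro accession is in N ∪ L1–L4; coordinates are ignored, since the
protocol being modelled keys on accession presence. Deduplication is
within-species by exact amino-acid string, keeping the
lexicographically smallest protein id; cross-species collapse is
deliberately avoided because it would conflate orthologs. Gene counts
are distinct gene ids among retained proteins, so transcript isoforms
inflate protein counts but not gene counts (proteins ≥ genes).

**Classification.** Flags (has_N, has_L with subtypes, has_C, has_T)
map to nine labels: the N-and-L group splits into NL/CNL/TNL, the
N-only group into N/CN/TN, the L-only group into L/CL/TL, and proteins
with neither become UNCLASSIFIED. When C and T are both present the
TIR variant wins — TIR is the stronger class determinant in this
family — and the call carries an ambiguity flag rather than inventing a
tenth class, keeping it auditable. The audit maps database-asserted
classes onto this vocabulary (CN→CN, … TNL→TNL); receptor-kinase-style
classes (LECRK, LYK, LYP, RLK, RLP, Other, T) have no NLR architecture
reading and are reported "not auditable" rather than force-mapped.

**Co-occurrence.** Combination counting is exact enumeration of
observed subsets of {N, L1–L4} (there are at most 2⁵−1), keyed by
concatenating roles in fixed order ("N", "L1L3", "NL1L2"). Percentages
use the profiled-candidate universe of the grouping. Absence
assertions (default: N+L3) scan parsed keys, not substrings.

**Set operations.** Per-group unique-domain sets retain pre-dedup hit
counts as provenance. All outputs are lexicographically ordered so
repeated runs are byte-identical.

**Difference scores and MDS.** For an aligned pair, the distance is
(# columns with different symbols) / (# columns where not both are
gaps). Gap-versus-residue counts as a difference and both-gap columns
are excluded — this is the reading of "proportion of sites that differ"
that keeps scores in [0, 1]; a pair with no eligible columns scores 0
with a warning. Classical (Torgerson) MDS double-centers −D²/2,
eigendecomposes, and scales eigenvectors by √λ. Only eigenvalues above
1e-9·max|λ| contribute coordinates; negative eigenvalues (non-Euclidean
residual) are retained in the reported spectrum. The sign convention —
largest-magnitude entry of each coordinate column positive — makes
coordinates reproducible. Goodness of fit is retained positive
eigenvalue mass over total positive mass. Cluster separation is the
mean silhouette (Euclidean, via scikit-learn); it quantifies separation
of given labels but does not count clusters, which in the surveyed
literature is a visual call with no stated algorithm.

**Aligner.** The built-in aligner is center-star: the center maximizes
the summed pairwise Needleman–Wunsch global score (ties by smallest
id; linear gap penalty, default match 1 / mismatch −1 / gap −2);
other sequences merge against it under "once a gap, always a gap".
Pairwise alignments come from Biopython's `PairwiseAligner`; the test
suite checks them against an independent dynamic-programming oracle.
Center-star is adequate at the package's scale (tens of sequences per
class); production alignments from an external aligner (e.g. MUSCLE or
MAFFT) can be imported as aligned FASTA and fed to the same distance
and MDS code.

**Genome summaries.** Windows are [i·w, (i+1)·w) from 0 to the last
gene end per chromosome; a gene belongs to the window containing its
start (simplest and order-stable; midpoint or overlap-split would move
few genes at the default 1 Mb window against typical gene lengths).
The trailing partial window and intermediate empty windows are
reported. Pearson correlations use the product-moment formula with a
two-sided p from the t distribution on n−2 degrees of freedom; the
sidedness is an explicit choice, as the surveyed report prints a single
p-value without stating it.

On the surveyed count table, the correlation of genome size against
NLR-protein count is r = −0.245, p = 0.525 (recomputed by
`scripts/acceptance.py`); note this pairing, not the annotated-genes
pairing, matches the r/p printed in the survey's prose.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Counts.** Class counts per species are allocated by deterministic
  largest-remainder rounding of the class-proportion vector over the
  emitted proteins (fractional-part ties break by label order), so unit
  tests assert exact counts; `sample=True` switches to multinomial
  draws for statistical tests. Transcript fan-out is either sampled
  from a declared distribution or pinned exactly when `n_proteins` is
  given (extra isoforms go to the first genes).
* **Hits.** Each protein receives exactly one accession per planted
  role (sampled from the role set) plus decoy accessions, each included
  with a per-protein probability. Decoy pools may not overlap role
  accessions — the generator validates this — so planted labels are
  recoverable with 100 % accuracy by construction. The nine-species
  preset draws decoys from the surveyed species' real unique-domain
  vocabularies, exercising the set-operation stages with realistic
  accession sets. N-carrying classes never plant L3, matching the
  co-occurrence structure the analysis is designed to detect.
* **Sequences.** Each class has a conserved motif (default 150
  residues) generated once per run; each species derives its own
  prototype by mutating the class motif at `species_divergence`
  (default 0.3), and each protein mutates its species prototype
  per-site at `divergence` (default 0.05), flanked by i.i.d.-uniform
  residues (default 25 per side). With these defaults within-cluster
  difference scores sit near 2·d·(19/20) ≈ 0.1 over motif columns while
  between-class scores approach the random expectation ≈ 0.95, so MDS
  separates planted clusters with silhouette well above 0.5.
* **Coordinates.** Genes are placed uniformly on a declared number of
  chromosomes (default 5 × 50 Mb); lengths are uniform in 2–8 kb.
* **Determinism.** All sampling flows through one
  `numpy.random.default_rng(seed)`; identical spec + seed give
  byte-identical outputs.

The `fabaceae9` preset mirrors the surveyed per-species protein/gene
totals (exactly at factor 1; the default factor 0.1 scales each species
with per-species rounding) and class proportions from the surveyed
class table, normalised over the seven classes it reports.

What the generator does **not** emulate: realistic protein evolution
(no substitution matrix, no indels within motifs), domain-coordinate
realism beyond validity, paralog cluster structure on chromosomes, or
correlated decoy co-occurrence. Passing recovery tests therefore show
the pipeline's bookkeeping and numerics are correct under the stated
model, not that the biological classification of any real proteome is
correct — on real data, classification fidelity is bounded by the
annotation quality and by the C/T role-map choice.

## Packaged fixtures

Three TSV fixtures transcribed from the published nine-species survey
(per-species unique-domain lists; per-species genome/gene/protein
counts; per-species class counts) ship inside the package and are
SHA-256-verified on load. The reference R-gene table is a synthetic
stand-in (the curated database export is not redistributable): it
reproduces the published class census (92 genes, 12 classes) and the
two worked audit accessions, with synthetic placeholders elsewhere;
likewise the per-class reference domain collection is a deterministic
synthetic reconstruction matching the published marginals (30 distinct
domains, 18 exclusive to one class, 12 shared, 60 memberships).

## Problem sizes and numerical choices

The test suite and acceptance script run the co-occurrence oracle on
100 random instances up to 1 000 profiles, MDS fidelity on random 2-D/
3-D clouds up to n = 50 (reconstruction tolerance 1e-9 at full rank),
planted-label recovery over 50 random single-species specs, and the
cluster-separation checks at n = 30 sequences (planted) and n = 200
points (null). The end-to-end pipeline examples use the preset at
factors 0.015–0.1. These sizes exercise every code path while keeping
a full run in seconds; all scale linearly (counting, set ops) or as
O(n²·L²) (center-star alignment), so larger runs are a matter of time,
not correctness.

Known limitations: center-star is a 2-approximation to optimal
multiple alignment and can misplace gaps relative to MUSCLE/MAFFT;
the difference score treats all substitutions equally; classical MDS
drops non-Euclidean structure (reported via the eigenvalue spectrum);
and the audit can only be as good as the declared class-vocabulary
mapping.
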