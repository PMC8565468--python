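# Methods

## Scope and model

`mitobias` studies the relationship between the *possible* synonymous
single-base changes in a mitochondrial coding genome and the changes
actually observed in a large population sample, and asks whether the gap is
better explained by mutational bias (transitions ≫ transversions) than by
selection on nucleotide choice. The pipeline has two halves:

1. **Human-style analysis** — exhaustive mutagenesis of one annotated
   reference genome, joined to a population variant table, summarized by
   degeneracy class.
2. **Cross-species analysis** — third-codon-position (P3) base usage and
   per-site Total Substitution Scores (TSS) across a panel of aligned
   genomes on a supplied rooted phylogeny.

Both halves run end to end on synthetic data with known ground truth; the
synthetic generators are first-class, tested code.

## The genetic code table

The vertebrate mitochondrial code (NCBI translation table 2) is authored
in-package as a family table: each of the 60 sense codons belongs to one
tRNA family, and each family is fourfold degenerate at P3, twofold-purine
(A/G) or twofold-pyrimidine (C/T). Leucine (L1 = TTR, L2 = CTN) and serine
(S1 = TCN, S2 = AGY) each carry two families, which is why degeneracy is a
family property, not an amino-acid property. Structural consequences used
throughout, each verified by exhaustive enumeration in the tests:

- 32 fourfold + 28 twofold sense codons; stops are TAA, TAG, AGA, AGG;
- the single synonymous P3 change at any twofold site is a transition;
- the only synonymous changes at codon positions 1–2 are the Leu
  TTR ↔ CTR first-position swaps (crossing the L1/L2 families).

The table is also shipped as `src/mitobias/data/mt_codon_table.tsv` and
diffed against Biopython's independent copy of table 2 in the test suite.

## Mutagenesis and merging

Coordinates are 1-based and inclusive on the reference (heavy) strand,
matching GenBank and the `chrM:<pos>` locus convention. Each CDS is
enumerated codon-wise on its coding strand; minus-strand genes report
complemented reference/alternative bases; circular wrap-around features are
supported; incomplete terminal codons and codons containing ambiguity
characters are skipped and counted in the run log.

Overlapping genes emit one record per gene. For genome-wide tallies a
substitution is classified synonymous only when it is synonymous in *every*
CDS containing it (conservative: a hidden non-synonymous consequence can
never be counted as synonymous). Stop↔stop codon changes satisfy
amino-acid equality and are flagged synonymous in the record table, but all
P3 degeneracy and diversity summaries exclude stop reference codons, since
degeneracy classes are defined for sense codons only.

The variant join key is (position, ref, alt); unmatched substitutions get
zero counts, and unmatched variants are reported as `non_coding` or
`ref_mismatch` rather than silently dropped. The carrier count of a variant
is homoplasmic + heteroplasmic carriers by default (a heteroplasmic carrier
is still a carrier); `hom_only` switches this. Frequency classes use a
single configured sample size for the release (default 195,983), with
boundaries closed on the lower side: absent (0), ultra-rare (< 0.01%), rare
(< 1%), low-frequency (< 5%), common (≥ 5%).

Site-level divergence summaries use only amino acids with a single
degeneracy mode (Leu/Ser excluded), and only *synonymous* P3 variants count
toward a site's observed-base set. SSNE composition and
count-distribution comparisons instead use the eight fourfold-capable amino
acids, Leu/Ser included via their families.

## Ancestral reconstruction and TSS

Two methods are provided for one site column on a rooted tree:

- **Fitch parsimony**, implemented as a unit-cost Sankoff dynamic program so
  multifurcating nodes are handled exactly. Ambiguity is resolved by fixed
  alphabetical order A < C < G < T at every choice point, making the
  assignment and therefore the TSS bit-reproducible. Gaps, `N` and missing
  leaves contribute the full state set.
- **Marginal ML** under a single-rate HKY model: per-node marginal
  posteriors from Felsenstein pruning (up-pass) plus an outside recursion
  (down-pass), with per-node rescaling against underflow. Branch lengths
  are taken as given, in expected substitutions per site; the rate matrix
  is scaled to one expected substitution per unit length at stationarity.
  Assignment is the per-node argmax with the same alphabetical tie-break;
  observed leaves keep their observed state; missing leaves get a uniform
  partial likelihood.

TSS = number of branches whose parent and child states differ; nothing is
counted above the root. Fitch is the default for TSS because it is
deterministic and verifiable against exhaustive enumeration; with Fitch
states the TSS equals the parsimony score and is a strict lower bound on
the true number of events. Consequently TSS *understates* substitution
counts as event density grows: in simulations the rank correlation with
truth is ≈ 0.99 at 0.02 events/site/branch, ≈ 0.92 at 0.07, and degrades
beyond that as parsimony saturates. The TSS-bearing simulations in the
tests and the acceptance script therefore run at a mean branch length of
0.05 (≈ 0.04 events/site/branch, 12 taxa, ~500 sites), where recovery is
reliable and runtimes are seconds.

Both reconstruction methods are validated against brute-force oracles:
parsimony against the exhaustive minimum over all 4^(internal nodes)
assignments on trees with ≤ 7 leaves, and the pruning likelihood against
direct summation over all internal assignments on ≤ 5 leaves (relative
tolerance 1e-9).

## I-P3 sites

An I-P3 is an alignment codon site whose positions 1–2 are identical and
gap-free in every taxon *and* whose tRNA family is constant across taxa
(this second condition matters for prefixes like TG-, AT-, CA-, AA-, GA-
and AG-, where P3 alone decides between two families, and it resolves
serine sites to S1 or S2). Sites where any taxon carries a stop codon are
rejected. Leucine is excluded by default because first-position degeneracy
mixes L1 and L2. A gap or ambiguity character at P3 excludes that taxon
from the observed-base set without disqualifying the site. Alignments are
first ungapped on the reference row, so all coordinates are reference codon
indices.

## Statistics

The two-sample Kolmogorov–Smirnov D is computed exactly from the two
empirical CDFs, ties included; the p-value uses the asymptotic Kolmogorov
distribution at effective size n₁n₂/(n₁+n₂). On heavily tied count data
this approximation is conservative, which is acceptable for the screening
role it plays here. Bonferroni correction multiplies each raw p by the
number of performed tests, capped at 1; sparse groups (< 2 observations)
and the `common` frequency class are excluded from testing, the latter
because it is too thinly populated to compare distributions. Reported
significance bands are ≤ 0.001, ≤ 0.01, ≤ 0.05, > 0.05.

## Synthetic data: what it emulates, and what it does not

`generate_toy_genome` lays out six genes (~1.8 kb total) mimicking mtDNA
architecture: one minus-strand gene (ND6-like), one overlapping pair in
shifted frames (ATP8/ATP6-like), one incomplete terminal codon, and a base
composition of A 0.31, C 0.31, G 0.13, T 0.25 loosely matching the mtDNA
coding strand. Gene bodies are stop-free random sense codons except where
an overlap frame forces arbitrary codons.

`simulate_variant_db` gives each possible substitution a Poisson carrier
count with mean λκ/(κ+2) for transitions and λ/(κ+2) for transversions,
then removes each non-synonymous carrier with probability `sel_nonsyn`.
Defaults: κ = 20 (a mammalian-mtDNA-scale transition bias), N = 195,983
samples, `sel_nonsyn` = 0.95, and per-site intensity λ = 10 mean carriers
per coding site — a scale at which a realistic minority of synonymous
transversions is never sampled. The homoplasmic/heteroplasmic split is a
drift-age *proxy*, not a mechanism: the heteroplasmic fraction decays
exponentially with carrier count (base 0.9, scale 20 carriers, floor 0.02),
reproducing qualitatively the observation that rare variants are more often
heteroplasmic. No coalescent structure, no haplotype linkage, no
within-individual segregation dynamics are modelled; passing tests
demonstrate pipeline correctness and estimator calibration under these
planted conditions, not demographic realism.

`simulate_evolution` runs a per-site Gillespie process under the scaled HKY
rates along each branch, recording every event (and whether it was a
transition) per site. The null-calibration analyses use λ = 3 for the
variant table so that both the `absent` and `ultra-rare` classes are
populated, and κ = 1 with `sel_nonsyn` = 0 so the compared groups are
exchangeable by construction.

A neutral simulation cannot reproduce one feature of real cross-species
data: real I-P3 sites exist *because* codon positions 1–2 are conserved by
purifying selection while P3 turns over freely. Under neutral evolution,
divergence deep enough to saturate P3 occupancy also destroys position-1–2
identity, so synthetic panels yield few I-P3 sites and low full-degeneracy
fractions. The synthetic cross-species run therefore validates mechanics
(site identification, TSS, test matrices), not the magnitude of
full-degeneracy percentages seen in real mammal panels.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; generated text outputs record the seed and a
config hash in `#` header comments, and fixed seeds give byte-identical
files.

## Numerical and design choices

- Deterministic output ordering everywhere (position, then alternative
  base, then gene) so runs diff cleanly; pipeline manifests record SHA-256
  digests of every table.
- Duplicate-CDS filtering removes *all* members of a duplicate group
  (configurable), matching the stricter reading of cross-panel duplicate
  removal.
- Start codons are translated literally by table 2 — no forced methionine —
  since the analysis concerns raw codon changes, not translation initiation.
- n_samples is a single configured denominator per database release, never
  inferred per row.
- The ML path exists for users who want model-based reconstruction, but it
  deliberately omits rate heterogeneity across sites and branch-length
  re-estimation; it is a single-rate HKY marginal reconstruction, nothing
  more.

## Known limitations

- No indels, multi-nucleotide variants, or RNA-gene (tRNA/rRNA)
  consequences; biallelic SNVs only.
- Alignment and tree inference are out of scope: per-gene codon alignments
  and a rooted newick tree are inputs.
- Fitch TSS is a lower bound and saturates at high event densities (see
  above); comparisons *between* sites at similar density are meaningful,
  absolute counts at deep divergence are not.
- The heteroplasmy model is a monotone proxy adequate for pipeline tests,
  not a population-genetic model of mtDNA segregation.
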