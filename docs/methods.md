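# Methods

This note documents the models implemented in `panplast`, the parameters
that matter, the numerical and design choices made where the methods'
verbal descriptions leave room, and what the synthetic fixtures do and do
not establish.

## MinHash sketching and genome distance

A genome's contigs (all replicons, chromosomes and plasmids alike) are
pooled into one set of canonical k-mers: for every window of k consecutive
bases, the lexicographic minimum of the k-mer and its reverse complement.
Windows containing any non-ACGT character are skipped (IUPAC ambiguity
codes are masked to N on input), and circular contigs are read linearly —
the at most k−1 wrap-around k-mers are deliberately ignored for simplicity;
at the default k = 18 this is negligible against genome-scale k-mer counts.

Each distinct canonical k-mer is packed into 2 bits per base (so k ≤ 31)
and hashed with a seedable splitmix64 finalizer; the sketch is the s
smallest distinct hash values. The contract is determinism given
(k, s, hash_seed) — the seed is stored in the sketch file — not
bit-compatibility with any other MinHash tool.

Jaccard similarity is estimated with the merged estimator: form the s
smallest values of the union of two sketches and count how many occur in
both. When s is at least the union of the two k-mer sets the estimate is
exact; otherwise its sampling standard deviation is ≈ √(j(1−j)/s). The
distance

    d = −(1/k) · ln(2j / (1+j))

inverts the expected k-mer survival under independent per-base substitution,
so d estimates per-base divergence and 1 − d behaves like ANI. j = 0 is
mapped to d = 1 (the formula diverges there) and d is clamped to [0, 1];
the species graph simply omits such pairs.

Defaults: k = 18, s = 5000, hash_seed = 42.

## Species clustering

Genomes are filtered on externally supplied quality estimates: removal
requires completion < 90% or contamination > 5%, so boundary values
(exactly 90 / exactly 5) survive. A genome without a quality record is an
error, never a silent default.

The species graph joins every kept pair with d ≤ 0.06. The edge weight is
1 − d, an ANI-like similarity chosen so that the 0.06 cutoff corresponds to
a 94% identity boundary; the clustering is insensitive to monotone
reweighting at this graph density. Louvain community detection (networkx,
resolution 1, fixed seed) yields the clusters; labels `SC<n>` are assigned
by decreasing cluster size with ties broken by the lexicographically
smallest member, making labels independent of input order. Louvain runs on
the global graph; since its local moves never cross connected components,
per-component runs would give identical results.

Neighbor joining is the classical Saitou–Nei agglomeration, exact on
additive matrices (verified to 1e−9 against the input path-length matrix,
and against scikit-bio's implementation). On non-additive inputs a negative
branch length is clamped to zero and its deficit moved to the sibling
branch, preserving the cherry's total length; at the final 3-node join,
where no sibling pairing exists, negatives are clamped to zero. Argmin
tie-breaks are row-major, hence deterministic.

## Gene families (80/80 single linkage)

Pairwise statistics come from a Smith–Waterman local alignment (Biopython's
PairwiseAligner: BLOSUM62, gap open 11 / extend 1, i.e. a gap of length L
costs 11 + (L−1)). Identity is matches / aligned columns with gap columns
kept in the denominator — this penalizes indel-riddled alignments and makes
the statistic exactly testable. Coverage is the aligned span over the full
sequence length, and **both** sequences must reach 80%: the symmetric
reading keeps the pass relation symmetric, which single-linkage clustering
requires. The coverage reference (longest, shortest, or both sequences) is
a genuine interpretation point; "both" is the strictest choice.

Among co-optimal alignments the aligner's first traceback is reported; the
test suite checks that the reported (identity, coverage) always belongs to
the set of co-optimal alignments enumerated by an independent full-traceback
Gotoh dynamic program, which is the property that matters downstream.

Candidate pairs are prefiltered by shared exact 4-mers. At the 80/80
operating point two passing sequences of ≥ 20 residues must share an exact
4-mer (80% identity over ≥ 16 aligned columns forces a run of ≥ 4 matches),
so the prefilter is conservative there; sub-4-residue sequences are paired
with everything. Families are connected components of the pass graph,
numbered `FAM<n>` by decreasing size then smallest member.

## Pangenome graph and partitioning

The presence/absence matrix binarizes per genome (paralogs collapse to one
occurrence). Construction refuses cohorts of fewer than 15 genomes — below
that the persistent/shell/cloud distinction is statistically meaningless —
unless explicitly overridden (logged).

Graph edges connect families whose genes are immediate neighbors on a
contig, weighted by the number of genomes exhibiting the adjacency (each
genome counts once per family pair); circular contigs close the loop, and
tandem copies of one family contribute no self-loop, since neighborhood
information is only informative *between* families.

The partition model is a K = 3 multivariate Bernoulli mixture: component k
has mixing weight π_k and per-genome presence probabilities ε_kg. The MRF
smoothing enters the E-step in mean-field form:

    r_ik ∝ π_k · ∏_g ε_kg^x_ig (1−ε_kg)^(1−x_ig) · exp( β Σ_j (w_ij/N) r_jk )

with N the number of genomes, followed by row normalization; the M-step is
the standard mixture update with ε clamped to [1e−3, 1−1e−3] to prevent
degenerate log-likelihoods. Mean-field coupling through neighbor
*responsibilities* (not hard labels) keeps the update smooth and reduces
the algorithm to exact EM at β = 0 — a testable limit in which the
log-likelihood is asserted non-decreasing at every iteration. The recorded
objective is the mixture log-likelihood plus the smoothness bonus
β Σ_edges (w_ij/N) ⟨r_i, r_j⟩.

Initialization is deterministic (ε rows 0.9 / 0.5 / 0.1 across all genomes,
π uniform, r uniform); a seeded `random_init` exists for robustness
checks. Iteration stops when the largest responsibility change falls below
1e−6 or after 500 rounds. After fitting, components are reordered by
decreasing mean ε and named persistent / shell / cloud; hard labels are the
responsibility argmax, with ties resolving toward the higher-occupancy
component by that ordering. Defaults: β = 0.5, K fixed at 3.

The strict core/variable table (families in all genomes vs the rest) is
computed directly from the matrix, independent of the model.

## RGP detection

Genes are tagged with their family's partition and walked per contig in
coordinate order. Scoring constants are +1 per shell/cloud gene and −3 per
persistent gene with a minimum segment score of 4: one persistent gene
interspersed in a strong variable region is tolerated, two consecutive ones
break it. The constants are CLI-exposed; only "score-based" and the 3 kb
rule are fixed by the method's definition, so the numeric values are this
package's choice.

The scan accumulates the running score; a segment closes when the score
drops to ≤ 0 or the contig ends, the candidate is the segment prefix at the
maximum (first peak on ties), and the walk resumes after the peak.
Candidates are trimmed of terminal persistent genes and reported when score
≥ 4 and genomic span — last gene end minus first gene start, excluding
flanking intergenic DNA, so the measure is reproducible from coordinates
alone — strictly exceeds 3000 bp (3001 qualifies, 3000 does not). The scan
provably selects, within each segment, the maximum-score window, and the
test suite checks equivalence against a greedy exhaustive enumeration of
all contiguous gene windows (ties: smallest end, then largest start — a
candidate never reaches back across a zero-crossing of the running score)
on random contigs of ≤ 50 genes. No merging of nearby regions beyond what
the score tolerance itself produces is attempted.

Circular contigs are scanned over a doubled gene list with shifted
coordinates; candidates must start in the first copy, are capped at one
full turn, and are deduplicated by gene content, so an origin-crossing
region is reported exactly once, with end > contig length indicating the
wrap.

Cross-strain matching reports 100 · |families(query) ∩ families(target)| /
|families(query)| against RGPs of the same species cluster. The denominator
is the query's family set — the wording of the percentage is ambiguous and
the query-side reading makes each query's matches comparable. Annotation
cross-links only count externally supplied (gene, category) flags per RGP;
no resistance/virulence/BGC prediction is performed here.

## Synthetic fixtures: what they emulate, what they do not

`simulate_species` draws one random root, per-species ancestors mutated at
`rate_between`, and members mutated at `rate_within` — independent
per-base substitutions, no indels, no rearrangements, no HGT. It exercises
the d ↔ divergence relation and the clustering threshold, not realistic
sequence evolution.

`simulate_protein_families` and `simulate_pangenome` give each family an
independent random prototype protein (between-family similarity is that of
unrelated random sequences, far below the 80/80 threshold) and mutate it at
5% within families, comfortably above it; family recovery on these fixtures
validates the clustering logic, not aligner sensitivity at the threshold
boundary.

`simulate_pangenome` plants occupancy by class — persistent 0.99, shell 0.5,
cloud 0.05 — with shell presence drawn once per genome per block of 30
families, a deliberately simple co-occurrence structure that gives the MRF
a signal to exploit. Every family is guaranteed at least one occurrence (an
all-absent draw is re-seeded into one random genome), keeping planted
per-partition counts exact and the presence matrix free of empty rows.
Present genes are laid on one linear contig per genome in a conserved
random backbone order with 100 bp intergenic gaps; gene length is 3× the
protein length. Islands are dedicated cloud families inserted contiguously
(50 bp internal gaps) at a random backbone slot of each carrier genome
(carrier probability 0.3), with protein lengths synthesized so the island's
genomic span matches the request. Nucleotide contig sequences are random
DNA — consistent in length with the gene layout but not coding for the
proteins — sufficient for format round-trips and sketching tests, not for
gene calling.

Consequently, passing tests demonstrate correctness of the algorithms under
their own model assumptions (independent Bernoulli occupancy, clean 80/80
separation, substitution-only divergence). They do not establish
performance on real data with annotation errors, fragmented assemblies,
mobile elements shared across species, or families near the 80/80 boundary.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which the statistical claims are
well-resolved: species clustering uses 3 species × 5 genomes of 100 kb
(rates 0.01 within / 0.2 between); divergence recovery uses 100 kb pairs at
rates 0.03 and 0.10 with k = 18, s = 5000; estimator concentration uses 100
replicates of 50 kb pairs at divergence 0.10 with s = 200, where the
estimator's sampling s.d. (~0.02) makes the ±0.05 band a ≥ 95% event; the
planted pangenome uses 30 genomes × 1000 families (300/300/400); RGP
fixtures use a 150-family persistent backbone with islands of 5.2 kb, 7 kb
and 2.1 kb (the last below the 3 kb rule, asserted rejected).

## Known limitations

- Sketches are genome-level only: no read streaming, no containment scores,
  no significance estimates on shared hash counts.
- The EM partitioner fixes K = 3; collections whose shell genome splits
  into multiple niches are still forced into one shell component.
- The mean-field MRF is an approximation; no exact inference or sampling
  over the label field is attempted, and the fitted β is never estimated
  from data.
- Family construction is all-vs-all within the 4-mer prefilter (quadratic);
  it is intended for single-species cohorts, not million-protein databases.
- RGP boundaries are gene-granular; intergenic island margins are not
  recovered, and composite islands separated by ≥ 2 persistent genes are
  reported as separate regions.
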