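# Methods

This note documents the models behind pcdhkit, the parameters that matter,
what the simulator does and does not emulate, and the numerical choices
made where the design was open.

## Locus simulator

**Ancestral gene.** A variable-exon protein is built from one master
extracellular-repeat consensus (default 110 aa): the six EC domains are
independent corruptions of it at 25% amino-acid replacement, followed by a
hydrophobic transmembrane segment (25 aa) and a tail (45 aa) — 730 aa in
total, deliberately above the 700-aa annotation cutoff, as real cPcdh
variable exons are. Deriving all six domains from one template is what
makes a single repeat profile detect all six repeats in descendants, the
property the annotation filter relies on. The CDS is obtained by uniform
reverse translation; the initiator ATG is held immutable during evolution
so the open reading frame the annotator must find cannot be silently
destroyed.

**Duplication trees.** Each cluster radiates on a random coalescent-shaped
bifurcating topology (exponential waiting times), rescaled so the
root-to-tip path equals `branch_scale` substitutions/site (default 0.15).
Clusters share one ancestral gene but first diverge from it along their own
branch of `cluster_divergence` (default 0.10) substitutions/site — tandem
clusters are ancient paralogs, and without this branch the inter-cluster
split would carry no phylogenetic signal.

**Codon evolution.** Mutations are proposed per nucleotide as a Poisson
process (expected `t × L` proposals on a branch of length `t`), with
transition:transversion bias `kappa` (default 2.0). Proposals creating stop
codons are rejected; nonsynonymous proposals are accepted with probability
`omega` of the protein domain they fall in (default 0.2 everywhere,
configurable per domain); synonymous proposals are always accepted. Each
branch records its realized number of accepted substitutions, which is what
the Jukes–Cantor consistency test conditions on. This is the simplest
generative model that yields domain-dependent dN/dS while leaving dS
unaffected by selection.

**Gene conversion.** The post-duplication epoch is one unit of time; the
number of events is Poisson(rate × n_pairs). Each event picks an ordered
(donor, acceptor) pair uniformly, a target domain from the allowed set
(length-weighted), a tract length from a truncated geometric (mean 30
codons, bounds [10, 80]) and copies the donor tract verbatim into the
acceptor. Events apply sequentially to tip sequences and are logged as
ground truth. No published rate or tract model exists for these events; the
defaults are exposed in the config and not asserted as biology. The
"strong conversion" study condition used in tests and the acceptance script
is 10 events/pair, chosen to emulate reference groups where the lowest
per-domain dS is driven close to zero (near-complete homogenization); the
statistic's job is only to separate that regime from the conversion-free
one.

**Locus layout.** Per isoform: an intergenic spacer (default 2500 bp, with
an in-frame TAA immediately 5' of the ATG so the ORF start is pinned), the
variable exon, a stop codon. Per cluster: the shared constant-exon CDS
(default 125 aa) split into three exons separated by fixed 200-bp neutral
introns. Decoy ORFs (default five of 350 aa) follow the last cluster. A
sample of the promoter PWM is planted at `motif_offset` (default −200)
upstream of every ATG; instances are rejection-sampled to score at least
60% of the PWM maximum, i.e. the simulator plants *functional* instances,
the way conserved elements persist under selection. All genes lie on the
plus strand; minus-strand handling in the analyses is exercised with
constructed inputs.

**Read simulation.** Fragments (default 300 bp) are drawn uniformly along
spliced transcripts; cluster sampling weights are
`FPKM_target × L_CE/1000 / p_overlap`, where `p_overlap` is the probability
a uniform fragment touches the constant exons, so that expected
constant-exon counts are proportional to `FPKM_target × L_CE`. Counting
therefore recovers the target abundance *vector up to one common scale*
(the library-size normalization); recovery checks compare
target-sum-normalized FPKM, which is also how cluster abundances are
compared across samples in practice.

**What the simulator does not emulate:** splice-site sequences and
alternative splicing, indels (paralogs stay colinear, so the identity map
is the alignment), sequencing errors and quality scores, strand mixtures,
diploidy, and inter-cluster gene conversion. Passing tests therefore show
the analyses are correct on substitution-only, well-behaved loci — they do
not certify performance on real assemblies with indels or fragmented gene
models.

## Annotation

Six-frame ORF scan: maximal ATG→stop ORFs (first ATG after the previous
in-frame stop), both strands, protein length counted with the initiator Met
and without the stop; the cutoff is ≥ 700 aa, with the 699/700 boundary
pinned by tests. ORFs must terminate in a stop codon. Overlapping ORFs in
different frames are all reported; deduplication only on identical
intervals. The cadherin-repeat filter slides a 20-row amino-acid log-odds
profile (built from the six EC templates, pseudocount 1, uniform
background) and takes greedy non-overlapping left-to-right matches with
score ≥ 0 bits; a model is kept iff it shows ≥ 6 repeats. Zero bits is a
conservative threshold: a random window's expected score is strongly
negative (≈ −window length × KL(background‖profile)), making false repeats
vanishingly rare, while true repeats at the simulated divergence score far
above it. A true positive in evaluation is an exact variable-exon interval
match.

## Identity

Needleman–Wunsch global alignment (BLOSUM62, gap open −10, extend −0.5 —
all configurable), identity = 100 × identities / alignment columns, so
terminal gaps count against identity. Domain slices are extracted before
alignment. Per-group tables average over all unordered within-group pairs;
groups of size < 2 yield NaN rather than an error. The "highly similar"
screen defaults to 90% over EC2–EC3. Whether such tables should be computed
from per-pair alignments or one MSA is a genuine choice; per-pair is the
default here (an MSA-free pipeline), and on the simulator's colinear
proteins the two coincide.

## dS and the conversion ratio

NG86 conventions are fixed by the toy cases in the test suite: per-position
synonymous-site fractions with denominators of 3 (stop-codon mutations
count as nonsynonymous, preserving S + N = 3 × codons), pathway averaging
over all orderings for multi-hit codons with stop-crossing pathways
excluded and re-weighted (if every pathway crosses a stop, all are used
with stop steps counted nonsynonymous), pairwise-complete codon deletion
for gaps/ambiguity, Jukes–Cantor correction, saturation at ps ≥ 3/4
(flagged, excluded from group means, visible in `n_pairs_used`). Group
means are over all unordered within-group pairs; the ratio is max/min of
the six per-domain means and is undefined (with a recorded reason) if any
mean is non-positive or undefined. Reported values are rounded to 2
decimals; computation is at full precision. NG86 replaces yn00-style
counting deliberately: it is fully specified, exactly testable by hand
enumeration, and monotone in the same signal; published magnitudes
estimated with yn00 are therefore approximated, not matched.

## Phylogeny

Poisson-corrected distances `d = −ln(1 − p)` with pairwise-complete column
deletion; `p ≥ 1` is a hard error (saturation). Neighbor joining follows
Saitou–Nei with the Q criterion; ties (within 1e-12) break by the
lexicographic order of the joined nodes' representative (minimum) leaf
labels, making topologies deterministic; negative branch estimates are
clamped to zero and counted on the tree. Additive matrices are recovered
exactly (tested to 1e-9 path-length reconstruction). Bootstrap resamples
alignment columns, defaults to 100 replicates, and reports support for the
full-data tree's internal splits. Monophyly is an edge query on the tree
rooted at an explicit outgroup. Maximum-likelihood inference is out of
scope; the substitution is recorded in the run manifest.

## Promoter motifs

Promoters are the `upstream_bp` (default 2000) bases 5' of the ATG on the
coding strand, truncated at contig edges. Discovery is EM over latent start
positions: ZOOPS by default (per-sequence occurrence prior γ learned by
EM), OOPS available; 0th-order background estimated from the input;
pseudocount 0.5. Seeding is MEME-style — candidate subsequence windows
(scaled with input size, 150–1000) are screened by how well a sharp PWM
built from each matches the data, and EM runs from the best `n_restarts`
distinct seeds. Because EM can lock onto a column-shifted copy of the
optimum, the best model is refined by hill-climbing over ±1–2 column
shifts (background fills vacated columns) until the objective stops
improving. The monotone quantity asserted per iteration is the MAP
objective (log-likelihood plus the Dirichlet log-prior implied by the
pseudocounts); the raw likelihood alone is not monotone once pseudocounts
regularize the M-step. Scanning reports log-odds hits above 60% of the
maximum achievable score (configurable), with offsets negative upstream
relative to the A of the ATG; only the coding strand is scanned unless
requested otherwise. CGCT-box presence is an exact substring query on the
consensus.

## Expression

A fragment counts for a cluster iff it is flagged unique and any of its
genomic blocks overlaps any constant exon of that cluster by at least
`min_overlap_bp` (default 1 — any overlap), at most once per cluster.
`total_mapped_fragments` is the number of distinct uniquely-mapped
fragments in the placement set. FPKM = count / ((L_CE/1000) ×
(total/10^6)); in single-read mode each read is a fragment (RPKM).
Constant exons of different clusters are disjoint by construction, so
HTSeq-style ambiguity classes reduce to per-cluster membership.

## Pipeline

One YAML config with `locus`, `reads` and `analysis` sections drives
simulate → annotate → identity → dsconv → tree → motifs → express. All
randomness flows from a single seed; per-stage seeds derive from it via
`SeedSequence`, so re-running with the same config and seed reproduces
identical output checksums (recorded, per stage, in `manifest.json`
together with the config hash and method substitutions). Schema validation
runs before any compute; a failing stage halts the run with its name.

## Problem sizes

Default test and acceptance problem sizes — clusters of 6–14 isoforms with
110-aa domains (~2.2-kb variable exons), 20 replicate loci per condition
for the statistical contrasts, 100 bootstrap replicates, 100k fragments for
expression — are the package's chosen working scale: large enough that the
contrasts (Mann–Whitney and sign tests at α = 0.01) are stable across
seeds, small enough that the full suite runs in well under a minute.

## Known limitations

- NG86 dS saturates quickly (undefined at ps ≥ 3/4); deeply diverged real
  paralog groups may lose pairs from domain means, and the ratio is then
  computed on fewer pairs (visible in `n_pairs_used`).
- The repeat filter's profile is simulator-derived; real-data use requires
  a user-supplied cadherin-repeat profile (e.g. built from curated EC
  domains), and its discrimination there is untested here.
- NJ + Poisson distances underestimate multiple hits relative to ML with
  rate heterogeneity; bootstrap values on deep splits should be read
  comparatively, not as posterior probabilities.
- ZOOPS-EM finds one motif per run; loci with several distinct promoter
  classes (as real cPcdh clusters have) need per-class runs or masking of
  the first motif.
- The expression module consumes placements; alignment ambiguity beyond
  the unique/multi flag (mapping quality, soft-clips) is not modeled.
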