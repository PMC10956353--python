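# Methods

## Problem and model

Benchmarking metagenome assemblers and binners needs communities with known
ground truth that still *look like* real environments. This package simulates
such communities by learning structure from real, classified samples rather
than by drawing species at random from a catalogue.

A sample's species set, written as seven-rank lineages (domain, phylum,
class, order, family, genus, species), forms a rooted multiway tree. Nodes
are **entity** or **non-entity**: all species and domains are entities, and an
intermediate taxon is an entity exactly when it has at least two direct
children in the tree. A taxon with a single community member carries no
information beyond that member, so evolutionary distances are defined only
between entity nodes; when non-entity nodes intervene, a *bypass edge*
records the distance between an entity node and its nearest entity ancestor.

### Anchoring taxa on the reference phylogeny

The reference provides a phylogeny with branch lengths whose leaves are
genome accessions. Each species is anchored at its representative leaf (the
lexicographically first accession carrying the species name). Each internal
entity node is anchored at the most recent common ancestor (MRCA) of its
community members' representative leaves, and the bypass distance between an
entity node and its nearest entity ancestor is the branch-length path between
their anchors. Because a descendant's member set is contained in its
ancestor's, anchors are nested and distances telescope: the sum of bypass
distances from a species to its domain equals leaf depth minus the domain
anchor's depth.

This anchoring was a genuinely open design point. An alternative we rejected
places each internal node at a height equal to half the maximum pairwise
patristic distance among its descendants. That rule assigns *one* height per
node, so every species in a genus would sit at the same distance from it: the
per-genus standard deviation would always be zero, the prolific mode's
reference window would collapse, and no search could distinguish sibling
species. MRCA anchoring keeps per-species distances distinct, is symmetric
and deterministic, and reproduces exact patristic distances on trees whose
topology mirrors the taxonomy.

## Subtree search

Given a sampled tree `T_sample` and the reference tree `T_ref` (the multiway
tree over all reference species), the search finds an injective, rank-aligned
assignment of sampled nodes to reference nodes minimizing the total
evolutionary-distance difference:

* **genus level (base case)** — sampled species are matched injectively to
  reference species of the candidate genus; the cost is the summed absolute
  difference of bypass distances `Σ |d_sam − d_ref|`;
* **higher levels** — sampled children are assigned injectively to reference
  children of the same rank; pairing cost is the optimal subtree cost plus
  `|Δ entity-distance|` when both nodes carry a bypass distance (non-entity
  nodes carry none and contribute nothing of their own);
* **root** — sampled domains pair with the same-named reference domains; a
  community is never matched across domains.

The original description of this search never writes the objective
explicitly; the additive form above is the one consistent with its recursive
base case. Two matchers are provided. `optimal` (default) solves each level's
assignment exactly with the Hungarian algorithm; `greedy` gives each sampled
child, in lexicographic order, its best unclaimed reference child, mirroring
a sequential first-fit reading of the search loop. Greedy cost is provably ≥
optimal cost and both are tested against `brute_force_subtree`, an
exhaustive enumerator over all injective level-wise mappings (size-guarded to
≤ 8 children per node and ≤ 40 species).

### Search modes

Target distances for the genus base case depend on the mode. In **accurate**
mode they are the sampled species distances unchanged. In **prolific** mode a
fair Bernoulli coin `p ~ B(1, 0.5)` is drawn once per sampled genus:

* `p = 1` — targets are resampled with replacement from the genus's sampled
  distances `d_real`;
* `p = 0` — targets are drawn from `d_nref = { y ∈ d_ref | u−σ ≤ y ≤ u+σ }`,
  the reference genus's distances filtered to within one (population)
  standard deviation of the sampled mean; if the window is empty the draw
  falls back to `d_real`.

Draws are cached by sampled-node path (and reference-node path for
window draws), so the cost of a candidate pairing does not depend on the
order in which the search visits it — a prerequisite for comparing the
recursive search against the exhaustive oracle, and for bit-reproducible
results under a fixed seed. Draws are with replacement; ties in matching are
broken by reference node name.

## Abundances and depths

For a chosen environment, all species relative abundances observed across its
samples are pooled. Given a simulated community of `n` species, `n` values
are drawn with replacement from the pool and the draw is rejected until its
raw sum lies within `ε` of 1 (default `ε = 0.25`, at most 1000 tries, then
the closest draw is kept with a warning); the accepted draw is normalized to
sum exactly to 1. The rejection step keeps normalization from distorting the
drawn distribution. When users supply their own profiles, a log-normal is
fitted by maximum likelihood (`μ, σ` = mean and population SD of
log-abundances) and sampled under the same contract.

Abundances map to per-genome fold-coverage depths linearly:
`depth_i = D · a_i / min(a)` (minimum-depth anchor) or
`depth_i = D · a_i / mean(a)` (mean-depth anchor). For each species the
requested number of distinct strain genomes is drawn uniformly without
replacement from the reference index (clamped, with a warning, when fewer
exist), and the species depth is split across strains by a symmetric
Dirichlet(1, …, 1) draw — the least-informative split, since the source
material assigns abundance per species, not per strain.

## Read generation

The internal generator writes ground-truth-annotated FASTQ without external
binaries: read count = `round(depth · L / mean_length)` (≥ 1), lengths
log-normal parameterized by mean/SD in bp (defaults: HiFi 10 ± 2 kb at error
rate 0.002 with substitution:insertion:deletion 6:50:54; ONT 20 ± 10 kb at
0.05 with 39:24:36 — internal conventions, not measured values), positions
uniform on either strand of a linear genome, and errors injected per base at
the configured rate. Names encode `genome_start_end_strand_serial` so
evaluation can recover the exact layout. The external backend emits a shell
script — pbsim3 (qshmm model) per genome at its strain depth, `samtools view`
SAM→BAM, and `ccs` for the HiFi platform — with a validated input/output
dependency closure; it never executes the tools.

## Synthetic fixtures: what they emulate and what they do not

The fixture generator stands in for a taxonomy release plus classified
environmental samples. Defaults (chosen once as desk-scale study conditions):
one domain, 6–8 families, 3–5 genera per family, 2–6 species per genus
(≈ 100 species), 1–3 strains per species created by point-mutating a species
ancestor at 1% divergence, genomes 8–12 kb, two environments × 3 samples of
45–55 species each with log-normal within-sample abundances, biased by a
sparse Dirichlet(0.3) preference over genera so environments have distinct
composition. Sample richness is deliberately matched to the 50-species
communities the tests simulate, so pooled relative-abundance draws sum near 1
and the rejection loop accepts quickly — the same coupling the learning step
produces on real data, where simulated richness is sampled from the same
environment as the pool.

The reference tree's topology mirrors the taxonomy (each taxon is one
multifurcating node; consecutive families are grouped pairwise into orders,
classes and phyla, which therefore sit at their parent's anchor), with
branch lengths drawn uniformly per edge, or rank-fixed heights in ultrametric
mode. Kraken2-style reports are written from integer read counts so the
report and the truth table encode identical profiles.

Passing tests on these fixtures demonstrate the algorithmic contracts —
search optimality, distance bookkeeping, abundance/depth arithmetic, read
ground truth, determinism — but not realism of sequence composition (no GC
skew or repeats), not taxonomy-scale performance (real references have
hundreds of thousands of leaves; the recursive search here is exact, not
engineered for that scale), and not classifier behaviour (reports are ideal,
with no misclassified or unclassified-at-species reads beyond what the parser
discards by construction).

## Numerical choices and degenerate inputs

* Population (not sample) standard deviation throughout, matching the search
  window's convention.
* Negative or missing branch lengths are clamped to 0 with a warning;
  anchor-path distances are clamped at ≥ 0.
* Children are ordered lexicographically everywhere; assignment ties resolve
  deterministically (candidate name order), so a fixed seed reproduces every
  output byte.
* A genus with a single species is matched through its bypass distance to the
  nearest entity ancestor; an empty reference window falls back to the
  sampled distances; a reference branch with too few children renders that
  pairing infeasible, and infeasibility at the root raises a
  "reference too small" error.
* Depth anchoring computes `value · (a / anchor)` so the anchoring species'
  depth equals the target exactly in floating point.
* User abundance tables that do not sum to 1 are normalized with a warning.

## Known limitations

* FastQ input is rejected by design: classification is out of scope, and the
  pipeline starts from classifier reports (or plain species tables).
* Reads are placed on linear genomes; no circularity, chimeras, or coupling
  between quality strings and error rate.
* The exhaustive search oracle, not the recursive search, is the component
  with hard size limits; the recursive search is polynomial per level but
  still enumerates genus-level assignment matrices, so very large references
  are out of intended scope.
* Strain choice is uniform; no weighting by assembly quality metadata.
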