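# mcss — taxonomy-guided microbial community simulation

`mcss` generates simulated metagenomic communities — species sets, relative
abundances, strain genomes and long reads with full ground truth — whose
*taxonomic structure is learned from real environmental samples*. It is aimed
at developers and evaluators of metagenome assemblers, binners and profilers
who need benchmark datasets that behave like gut, soil or marine communities
rather than like uniform draws from a genome catalogue.

## How it works

1. **Learn.** Each classified sample (a Kraken2 report or a plain
   `species<TAB>abundance` table) becomes a seven-rank multiway tree
   (domain → … → species). All species and domains are *entity* nodes, as is
   any intermediate taxon with ≥ 2 direct children; only entity nodes map to
   a position on the reference phylogeny (the MRCA of their members), and
   bypass edges record the evolutionary distance from each entity node to its
   nearest entity ancestor.
2. **Search.** One sampled tree `T_sample` is drawn and the reference
   multiway tree `T_ref` (all species of a GTDB-style taxonomy) is searched
   recursively for the subtree minimizing the total distance difference

   `min Σ_genus Σ_species |d_sam − d_ref|  (+ |Δd| for paired inner entities)`

   over injective, rank-aligned assignments. In **accurate** mode the target
   distances `d_sam` are the sampled distances; in **prolific** mode each
   genus flips a fair coin `p ~ B(1, 0.5)` and resamples its targets either
   from the sampled distances (`p = 1`) or from the reference distances
   filtered to `[u−σ, u+σ]` around the sampled mean (`p = 0`), widening the
   simulated diversity. The chosen subtree's species are the simulated
   community.
3. **Abundances and strains.** Species abundances are drawn from the
   environment's pooled per-sample abundances (rejection-resampled until the
   raw sum ≈ 1, then normalized), or from a fitted log-normal; per-species
   strain genomes are drawn uniformly from the reference index.
4. **Depths and reads.** Abundances scale linearly to fold-coverage depths
   anchored at a user-chosen minimum or mean; reads come from the built-in
   long-read generator (ground-truth read names, configurable error model)
   or as a ready-to-run pbsim3 → samtools → ccs command plan.

A bundled fixture generator creates a synthetic reference (taxonomy table,
phylogeny, strain genomes) and environment samples, so everything runs from a
single seed with no downloads.

## Worked example

```sh
mcss fixtures --seed 3 --out fx
# reference: 104 species, 218 genomes
# samples: 6 written to fx/samples

mcss simulate \
    --ref-taxonomy fx/reference/taxonomy.tsv \
    --ref-tree fx/reference/tree.nwk \
    --genomes fx/reference/genomes \
    --env-model fx/samples \
    --mode prolific --strains 2 --mean-depth 10 \
    --reads internal --seed 42 --out sim
# simulation written to sim
```

`sim/` then contains `manifest.tsv`, `abundance.tsv`, `mapping.tsv`,
`reads.fastq` and `run_log.json`. The log records what happened:

```json
"learn":  {"n_samples": 6, "pool_size": 286},
"search": {"mode": "prolific", "matching": "optimal", "min_dis": 0.54285,
           "n_species_sample": 45, "n_species_sim": 45},
"reads":  {"backend": "internal", "n_reads": 468}
```

A 45-species sample was drawn from the six learned trees; the search found a
45-species reference subtree at total distance difference 0.54285 (in
branch-length units; 0 would mean a perfect structural match, and prolific
mode deliberately perturbs targets to diversify the community). The manifest
lists one row per strain genome:

```
#mode=prolific	seed=42	environment=samples
#accession	species	lineage	abundance	depth	genome_path
ACC00000	D1_F1_G1_S1	d__D1;...;s__D1_F1_G1_S1	0.012612...	5.675547...	fx/reference/genomes/ACC00000.fasta
ACC00001	D1_F1_G1_S2	d__D1;...;s__D1_F1_G1_S2	0.020200...	3.348704...	fx/reference/genomes/ACC00001.fasta
```

Abundances sum to 1 across species; each species' depth (here anchored at a
mean of 10×) is split across its strains, and every FASTQ read name encodes
its source genome, coordinates and strand. Re-running with the same seed
reproduces every output byte.

The same pipeline runs on real inputs: a GTDB taxonomy TSV, the GTDB
reference tree, a directory of genome FASTAs, and your own Kraken2 reports
(raw FastQ is rejected — classify first). `--species-table` bypasses
learning and search entirely when you already know the community.

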