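"""Fully synthetic references and environment samples.

This generator stands in for a real taxonomy release and its classified
environmental samples so that the whole pipeline runs from nothing but a seed.
It emits a taxonomy table, a reference phylogeny whose topology mirrors the
taxonomy (every taxon is one multifurcating node), per-accession genome
FASTAs where strains are point-mutated copies of a species ancestor, and
per-environment Kraken2-style reports with matching ground-truth tables.
Environment structure comes from a sparse Dirichlet preference over genera,
giving each environment its own characteristic clades, and within-sample
abundances are log-normal.

Everything is reproducible from ``(config, seed)`` and every ground-truth
count is recorded in a JSON manifest.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .community_tree import CommunityTree, TreeNode

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FixtureConfig:
    """Knobs of the synthetic reference and sample generator."""

    n_domains: int = 1
    families_per_domain: tuple[int, int] = (6, 8)
    genera_per_family: tuple[int, int] = (3, 5)
    species_per_genus: tuple[int, int] = (2, 6)
    strains_per_species: tuple[int, int] = (1, 3)
    genome_length: tuple[int, int] = (8_000, 12_000)
    branch_scale: float = 0.1
    ultrametric: bool = False
    strain_divergence: float = 0.01
    environments: tuple[str, ...] = ("env_a", "env_b")
    n_samples: int = 3  # per environment
    species_per_sample: tuple[int, int] = (45, 55)
    abundance_mu: float = -4.0
    abundance_sigma: float = 0.8
    total_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "families_per_domain",
            "genera_per_family",
            "species_per_genus",
            "strains_per_species",
            "genome_length",
            "species_per_sample",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo, hi} invalid")
        if self.n_domains < 1 or self.n_samples < 1:
            raise ValueError("n_domains and n_samples must be >= 1")


def _randint(rng, lohi) -> int:
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1))


def _random_seq(rng, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng, seq: str, divergence: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    k = rng.binomial(arr.size, divergence)
    if k:
        pos = rng.choice(arr.size, size=k, replace=False)
        for p in pos:
            current = arr[p]
            choices = [b for b in _BASES.tolist() if b != current]
            arr[p] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def _grouped(n_items: int, group: int, label: str, domain: str) -> list[str]:
    """Assign n_items consecutive indices to groups of the given size."""
    return [f"{domain}_{label}{i // group + 1}" for i in range(n_items)]


def make_reference(config: FixtureConfig, out_dir, rng=None) -> dict:
    """Generate taxonomy.tsv, tree.nwk and genomes/ under ``out_dir``.

    Returns (and writes as ``reference_manifest.json``) a manifest with the
    ground-truth species index, lineages and genome lengths.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    out = Path(out_dir)
    genomes_dir = out / "genomes"
    genomes_dir.mkdir(parents=True, exist_ok=True)

    lineage_rows: list[tuple[str, str]] = []
    species_index: dict[str, list[str]] = {}
    genome_lengths: dict[str, int] = {}
    species_genus: dict[str, str] = {}
    acc_counter = 0

    # taxonomy + genomes
    domains = [f"D{i + 1}" for i in range(config.n_domains)]
    domain_families: dict[str, list[str]] = {}
    family_genera: dict[str, list[str]] = {}
    genus_species: dict[str, list[str]] = {}
    for dom in domains:
        n_fam = _randint(rng, config.families_per_domain)
        families = [f"{dom}_F{i + 1}" for i in range(n_fam)]
        domain_families[dom] = families
        orders = _grouped(n_fam, 2, "O", dom)
        classes = _grouped(n_fam, 4, "C", dom)
        phyla = _grouped(n_fam, 8, "P", dom)
        for fi, fam in enumerate(families):
            n_gen = _randint(rng, config.genera_per_family)
            genera = [f"{fam}_G{i + 1}" for i in range(n_gen)]
            family_genera[fam] = genera
            for gen in genera:
                n_sp = _randint(rng, config.species_per_genus)
                species_names = [f"{gen}_S{i + 1}" for i in range(n_sp)]
                genus_species[gen] = species_names
                for sp in species_names:
                    lineage = (
                        f"d__{dom};p__{phyla[fi]};c__{classes[fi]};o__{orders[fi]};"
                        f"f__{fam};g__{gen};s__{sp}"
                    )
                    species_genus[sp] = gen
                    n_strains = _randint(rng, config.strains_per_species)
                    length = _randint(rng, config.genome_length)
                    ancestor = _random_seq(rng, length)
                    accs = []
                    for _ in range(n_strains):
                        acc = f"ACC{acc_counter:05d}"
                        acc_counter += 1
                        accs.append(acc)
                        lineage_rows.append((acc, lineage))
                        genome = _mutate(rng, ancestor, config.strain_divergence)
                        with open(genomes_dir / f"{acc}.fasta", "w") as fh:
                            fh.write(f">{acc} {sp}\n")
                            for i in range(0, len(genome), 80):
                                fh.write(genome[i : i + 80] + "\n")
                        genome_lengths[acc] = length
                    species_index[sp] = accs

    taxonomy_path = out / "taxonomy.tsv"
    with open(taxonomy_path, "w") as fh:
        for acc, lineage in lineage_rows:
            fh.write(f"{acc}\t{lineage}\n")

    # reference tree: taxonomy-shaped multifurcations over representative leaves
    def edge(rank_height_parent: float, rank_height_child: float) -> float:
        if config.ultrametric:
            return rank_height_parent - rank_height_child
        return float(rng.uniform(0.5, 1.5) * config.branch_scale)

    h = {  # per-rank heights used in ultrametric mode
        "s": 0.0,
        "g": 1.0 * config.branch_scale,
        "f": 2.0 * config.branch_scale,
        "o": 3.0 * config.branch_scale,
        "c": 4.0 * config.branch_scale,
        "p": 5.0 * config.branch_scale,
        "d": 6.0 * config.branch_scale,
    }

    def genus_clade(gen: str) -> str:
        parts = [
            f"{species_index[sp][0]}:{edge(h['g'], h['s']):.6f}"
            for sp in genus_species[gen]
        ]
        return "(" + ",".join(parts) + ")"

    def family_clade(fam: str) -> str:
        parts = [f"{genus_clade(g)}:{edge(h['f'], h['g']):.6f}" for g in family_genera[fam]]
        return "(" + ",".join(parts) + ")"

    def domain_clade(dom: str) -> str:
        # orders/classes/phyla are unary groupings of families; collapse the
        # chain into one family->domain edge of the summed height difference
        parts = [f"{family_clade(f)}:{edge(h['d'], h['f']):.6f}" for f in domain_families[dom]]
        return "(" + ",".join(parts) + ")"

    if len(domains) == 1:
        newick = domain_clade(domains[0]) + ";"
    else:
        newick = (
            "("
            + ",".join(f"{domain_clade(d)}:{config.branch_scale:.6f}" for d in domains)
            + ");"
        )
    tree_path = out / "tree.nwk"
    tree_path.write_text(newick + "\n")

    manifest = {
        "config": asdict(config),
        "n_species": len(species_index),
        "n_accessions": acc_counter,
        "species_index": species_index,
        "genome_lengths": genome_lengths,
        "species_genus": species_genus,
        "genus_species": genus_species,
        "paths": {
            "taxonomy": str(taxonomy_path),
            "tree": str(tree_path),
            "genomes_dir": str(genomes_dir),
        },
    }
    with open(out / "reference_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _write_kraken_report(path, species_reads: dict[str, float], species_genus) -> None:
    total = sum(species_reads.values())
    by_genus: dict[str, list[str]] = {}
    for sp in sorted(species_reads):
        by_genus.setdefault(species_genus[sp], []).append(sp)
    taxid = 1
    with open(path, "w") as fh:
        fh.write(f"  0.00\t0\t0\tU\t0\tunclassified\n")
        fh.write(f"100.00\t{total}\t0\tR\t1\troot\n")
        for genus in sorted(by_genus):
            taxid += 1
            g_reads = sum(species_reads[sp] for sp in by_genus[genus])
            fh.write(
                f"{100 * g_reads / total:6.2f}\t{g_reads}\t0\tG\t{taxid}\t  {genus}\n"
            )
            for sp in by_genus[genus]:
                taxid += 1
                reads = species_reads[sp]
                fh.write(
                    f"{100 * reads / total:6.2f}\t{reads}\t{reads}\tS\t{taxid}\t    {sp}\n"
                )


def make_samples(reference_manifest: dict, config: FixtureConfig, out_dir, rng=None) -> dict:
    """Generate per-environment samples: Kraken2-style reports plus truth TSVs.

    Abundances are integer read-count fractions so the written report and the
    truth table encode exactly the same profile.
    """
    rng = np.random.default_rng((config.seed + 1) if rng is None else rng)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species_genus = reference_manifest["species_genus"]
    genus_species = reference_manifest["genus_species"]
    genera = sorted(genus_species)
    all_species = sorted(species_genus)

    samples = []
    for env in config.environments:
        preference = rng.dirichlet(np.full(len(genera), 0.3))
        weights = np.array(
            [preference[genera.index(species_genus[sp])] / len(genus_species[species_genus[sp]])
             for sp in all_species]
        )
        weights = weights / weights.sum()
        for k in range(config.n_samples):
            richness = min(_randint(rng, config.species_per_sample), len(all_species))
            # guard against degenerate weights leaving too few choosable species
            positive = int((weights > 0).sum())
            richness = min(richness, positive)
            chosen = rng.choice(len(all_species), size=richness, replace=False, p=weights)
            chosen_species = [all_species[i] for i in sorted(chosen)]
            raw = rng.lognormal(config.abundance_mu, config.abundance_sigma, richness)
            reads = np.maximum(1, np.round(raw / raw.sum() * config.total_reads)).astype(int)
            species_reads = dict(zip(chosen_species, reads.tolist()))
            total = sum(species_reads.values())
            sample_id = f"{env}_s{k + 1}"
            report = out / f"{sample_id}.report.txt"
            truth = out / f"{sample_id}.truth.tsv"
            _write_kraken_report(report, species_reads, species_genus)
            with open(truth, "w") as fh:
                for sp in chosen_species:
                    fh.write(f"{sp}\t{species_reads[sp] / total!r}\n")
            samples.append(
                {
                    "id": sample_id,
                    "environment": env,
                    "report": str(report),
                    "truth": str(truth),
                    "richness": richness,
                }
            )
    manifest = {"environments": list(config.environments), "samples": samples}
    with open(out / "samples_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def sample_entity_preserving_subset(tree: CommunityTree, rng) -> list[str]:
    """Pick a species subset of a classified tree that keeps every retained
    node's entity status unchanged.

    At every internal node with >= 2 children at least two are kept, so kept
    internal nodes stay entities; unary chains stay unary.  Domains may keep
    any non-empty subset.  The returned species set therefore embeds exactly
    into the source tree with identical bypass-distance structure.
    """
    rng = np.random.default_rng(rng)

    def rec(node: TreeNode) -> list[str]:
        if node.rank == "s":
            return [node.name]
        kids = node.children
        if len(kids) == 1:
            keep = kids
        else:
            lo = 1 if node.rank in ("root", "d") else 2
            k = int(rng.integers(lo, len(kids) + 1))
            idx = sorted(rng.choice(len(kids), size=k, replace=False).tolist())
            keep = [kids[i] for i in idx]
        out: list[str] = []
        for c in keep:
            out.extend(rec(c))
        return out

    return rec(tree.root)
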