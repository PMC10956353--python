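"""Assembly of the final simulated community.

For each species the requested number of distinct strain genomes is drawn
uniformly from the reference genome index, the species' sequencing depth is
partitioned across its strains by a symmetric Dirichlet split, and the whole
community is serialized to a tab-separated manifest that round-trips
losslessly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Strain:
    accession: str
    genome_path: str
    depth: float


@dataclass
class Member:
    species: str
    lineage: str
    abundance: float
    depth: float
    strains: list[Strain]


@dataclass
class CommunitySpec:
    """The simulated community: members with strains, plus run provenance."""

    members: list[Member]
    mode: str
    seed: int
    environment: str

    def __post_init__(self) -> None:
        if self.members:
            total = sum(m.abundance for m in self.members)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"member abundances must sum to 1 (got {total!r})")
        for m in self.members:
            if not m.strains:
                raise ValueError(f"member {m.species!r} has no strains")
            accs = [s.accession for s in m.strains]
            if len(accs) != len(set(accs)):
                raise ValueError(f"member {m.species!r} has duplicate accessions")

    @property
    def species(self) -> list[str]:
        return [m.species for m in self.members]

    @property
    def n_strains(self) -> int:
        return sum(len(m.strains) for m in self.members)


def select_strains(species: str, k: int, index: dict[str, list[str]], rng) -> list[str]:
    """Choose ``k`` distinct strain accessions for a species, uniformly.

    When fewer than ``k`` genomes exist, all of them are returned with a
    warning (the clamp rule).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    accessions = index.get(species)
    if not accessions:
        raise KeyError(f"species {species!r} not in genome index")
    accessions = sorted(accessions)
    if len(accessions) < k:
        warnings.warn(
            f"species {species!r}: requested {k} strains but only "
            f"{len(accessions)} genomes exist; using all",
            stacklevel=2,
        )
        return accessions
    rng = np.random.default_rng(rng)
    chosen = rng.choice(len(accessions), size=k, replace=False)
    return [accessions[i] for i in sorted(chosen)]


def split_strain_depths(depth: float, count: int, rng) -> np.ndarray:
    """Partition a species depth across strains by a Dirichlet(1,...,1) split."""
    if not depth > 0:
        raise ValueError("depth must be > 0")
    if count < 1:
        raise ValueError("count must be >= 1")
    if count == 1:
        return np.array([float(depth)])
    rng = np.random.default_rng(rng)
    weights = rng.dirichlet(np.ones(count))
    return depth * weights


def write_manifest(spec: CommunitySpec, path) -> None:
    """Write the community manifest TSV (one row per strain genome)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#mode={spec.mode}\tseed={spec.seed}\tenvironment={spec.environment}\n")
        fh.write("#accession\tspecies\tlineage\tabundance\tdepth\tgenome_path\n")
        for m in spec.members:
            for s in m.strains:
                fh.write(
                    f"{s.accession}\t{m.species}\t{m.lineage}\t"
                    f"{m.abundance!r}\t{s.depth!r}\t{s.genome_path}\n"
                )


def read_manifest(path) -> CommunitySpec:
    """Parse a manifest written by :func:`write_manifest` (lossless)."""
    mode = seed = environment = None
    members: dict[str, Member] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#mode="):
                fields = dict(f.split("=", 1) for f in line[1:].split("\t"))
                mode = fields["mode"]
                seed = int(fields["seed"])
                environment = fields["environment"]
                continue
            if line.startswith("#") or not line.strip():
                continue
            acc, species, lineage, abundance, depth, genome_path = line.split("\t")
            member = members.get(species)
            if member is None:
                member = Member(
                    species=species,
                    lineage=lineage,
                    abundance=float(abundance),
                    depth=0.0,
                    strains=[],
                )
                members[species] = member
            member.strains.append(Strain(acc, genome_path, float(depth)))
            member.depth += float(depth)
    if mode is None:
        raise ValueError(f"{path}: missing manifest header")
    return CommunitySpec(
        members=list(members.values()), mode=mode, seed=seed, environment=environment
    )
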