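"""Readers for the reference taxonomy, reference phylogeny and sample profiles.

The reference follows GTDB conventions: a tab-separated taxonomy table mapping
genome accessions to seven-rank lineage strings (``d__...;p__...;...;s__...``)
and a newick phylogeny with branch lengths whose leaves are genome accessions
(or species names).  Community profiles come either from Kraken2 report files
or from plain ``species<TAB>abundance`` tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

RANK_CODES = ("d", "p", "c", "o", "f", "g", "s")
RANK_LABELS = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


class TaxonomyParseError(ValueError):
    """Raised when a taxonomy table row cannot be interpreted."""


class ProfileParseError(ValueError):
    """Raised when a sample profile cannot be interpreted."""


@dataclass(frozen=True)
class Lineage:
    """A seven-rank taxonomic lineage, domain down to species.

    ``ranks`` is an ordered tuple of ``(rank_code, taxon_name)`` pairs in the
    canonical order domain, phylum, class, order, family, genus, species.
    Species and domain names must be non-empty; intermediate ranks may be
    blank (placeholder lineages occur in real taxonomies).
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        codes = tuple(code for code, _ in self.ranks)
        if codes != RANK_CODES:
            raise ValueError(f"lineage must have ranks {RANK_CODES}, got {codes}")
        if not self.name("s"):
            raise ValueError("species name must be non-empty")
        if not self.name("d"):
            raise ValueError("domain name must be non-empty")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        parts = [p.strip() for p in text.strip().split(";")]
        if len(parts) != 7:
            raise ValueError(f"expected 7 semicolon-separated ranks, got {len(parts)}")
        ranks = []
        for part, code in zip(parts, RANK_CODES):
            prefix = code + "__"
            if not part.startswith(prefix):
                raise ValueError(f"rank field {part!r} lacks prefix {prefix!r}")
            ranks.append((code, part[len(prefix):]))
        return cls(tuple(ranks))

    def name(self, code: str) -> str:
        for c, n in self.ranks:
            if c == code:
                return n
        raise KeyError(code)

    @property
    def species(self) -> str:
        return self.name("s")

    @property
    def genus(self) -> str:
        return self.name("g")

    @property
    def domain(self) -> str:
        return self.name("d")

    def to_string(self) -> str:
        return ";".join(f"{c}__{n}" for c, n in self.ranks)


def parse_taxonomy_table(path) -> dict[str, Lineage]:
    """Parse a GTDB-style ``accession<TAB>lineage`` table.

    Malformed rows raise :class:`TaxonomyParseError` naming the line number;
    duplicate accessions are an error.
    """
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TaxonomyParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            accession, lineage_str = parts
            if accession in lineages:
                raise TaxonomyParseError(f"{path}: line {lineno}: duplicate accession {accession!r}")
            try:
                lineages[accession] = Lineage.from_string(lineage_str)
            except ValueError as exc:
                raise TaxonomyParseError(f"{path}: line {lineno}: {exc}") from exc
    return lineages


def build_species_index(lineages: dict[str, Lineage]) -> dict[str, list[str]]:
    """Map each species name to the sorted list of accessions carrying it."""
    index: dict[str, list[str]] = {}
    for accession, lineage in lineages.items():
        index.setdefault(lineage.species, []).append(accession)
    return {sp: sorted(set(accs)) for sp, accs in sorted(index.items())}


class DistanceOracle:
    """Patristic distances over the leaves of a reference phylogeny.

    Beyond leaf-to-leaf distances the oracle can position a *taxon* — a set of
    member leaves — at the most recent common ancestor (MRCA) of those leaves,
    and measure path lengths between nested taxa.  Negative or missing branch
    lengths are clamped to zero (recorded in :attr:`warnings`).
    """

    def __init__(self, tree: dendropy.Tree):
        self.warnings: list[str] = []
        self._root_path: dict[str, list[int]] = {}  # leaf name -> node ids root..leaf
        self._mrca_cache: dict[frozenset, int] = {}
        self._depth_by_id: dict[int, float] = {}

        root = tree.seed_node
        # depth-first: record branch-length depth and root path per node
        stack = [(root, 0.0, [])]
        while stack:
            node, depth, path = stack.pop()
            length = node.edge.length
            if node is not root:
                if length is None:
                    length = 0.0
                if length < 0:
                    self.warnings.append(
                        f"negative branch length {length} clamped to 0"
                    )
                    length = 0.0
                depth = depth + length
            nid = id(node)
            self._depth_by_id[nid] = depth
            path = path + [nid]
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                self._root_path[str(label)] = path
            for child in node.child_nodes():
                stack.append((child, depth, path))

    @property
    def leaves(self) -> set[str]:
        return set(self._root_path)

    def leaf_depth(self, name: str) -> float:
        return self._depth_by_id[self._root_path[name][-1]]

    def _mrca_id(self, names) -> int:
        key = frozenset(names)
        if not key:
            raise ValueError("empty leaf set has no MRCA")
        cached = self._mrca_cache.get(key)
        if cached is not None:
            return cached
        try:
            paths = [self._root_path[n] for n in key]
        except KeyError as exc:
            raise KeyError(f"leaf {exc.args[0]!r} not in reference tree") from exc
        shortest = min(len(p) for p in paths)
        mrca = paths[0][0]
        for i in range(shortest):
            nid = paths[0][i]
            if all(p[i] == nid for p in paths):
                mrca = nid
            else:
                break
        self._mrca_cache[key] = mrca
        return mrca

    def mrca_depth(self, names) -> float:
        """Branch-length distance from the root to the MRCA of ``names``."""
        return self._depth_by_id[self._mrca_id(names)]

    def distance(self, a: str, b: str) -> float:
        """Patristic distance between two leaves (sum of path branch lengths)."""
        if a == b:
            if a not in self._root_path:
                raise KeyError(f"leaf {a!r} not in reference tree")
            return 0.0
        da = self.leaf_depth(a)
        db = self.leaf_depth(b)
        return da + db - 2.0 * self.mrca_depth((a, b))

    def anchor_distance(self, descendant_leaves, ancestor_leaves) -> float:
        """Path length between two nested taxa anchored at their MRCAs.

        ``descendant_leaves`` must be a subset of ``ancestor_leaves`` (the
        descendant taxon's MRCA then lies on or below the ancestor's), so the
        difference of root depths is the path length; clamped at >= 0 for
        robustness to degenerate inputs.
        """
        d = self.mrca_depth(descendant_leaves) - self.mrca_depth(ancestor_leaves)
        return max(0.0, d)


def parse_reference_tree(path, taxonomy: dict[str, Lineage] | None = None) -> DistanceOracle:
    """Load a newick reference tree into a :class:`DistanceOracle`.

    If a taxonomy is supplied, leaves absent from it (as accessions or species
    names) are recorded in ``oracle.warnings``.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    oracle = DistanceOracle(tree)
    if taxonomy is not None:
        known = set(taxonomy)
        known.update(lin.species for lin in taxonomy.values())
        for leaf in sorted(oracle.leaves - known):
            oracle.warnings.append(f"tree leaf {leaf!r} absent from taxonomy")
    return oracle


@dataclass
class SampleProfile:
    """Species-level relative abundances observed in one sample."""

    sample_id: str
    species_abundance: dict[str, float]

    def __post_init__(self) -> None:
        for sp, a in self.species_abundance.items():
            if not a > 0:
                raise ValueError(f"abundance for {sp!r} must be > 0, got {a}")
        total = sum(self.species_abundance.values())
        if total > 1.0 + 1e-6:
            raise ValueError(f"abundances sum to {total} > 1")

    @property
    def species(self) -> list[str]:
        return sorted(self.species_abundance)


def parse_kraken_report(path, sample_id: str | None = None) -> SampleProfile:
    """Parse a Kraken2 report into species-level relative abundances.

    Only rank-code ``S`` rows are retained; the abundance of each species is
    its clade read count divided by the total species-level clade reads, so
    unclassified and higher-rank mass is ignored.
    """
    if sample_id is None:
        sample_id = Path(path).stem
    counts: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ProfileParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated fields"
                )
            # standard 6-column layout; tolerate the 8-column minimizer variant
            clade_reads = parts[1]
            rank = parts[-3]
            name = parts[-1].lstrip(" ")
            if rank != "S":
                continue
            try:
                reads = float(clade_reads)
            except ValueError as exc:
                raise ProfileParseError(f"{path}: line {lineno}: bad read count") from exc
            if reads > 0:
                counts[name] = counts.get(name, 0.0) + reads
    if not counts:
        raise ProfileParseError(f"{path}: empty profile (no species-level rows)")
    total = sum(counts.values())
    return SampleProfile(sample_id, {sp: c / total for sp, c in counts.items()})


def parse_species_table(path, sample_id: str | None = None) -> SampleProfile:
    """Parse a plain ``species<TAB>abundance`` table."""
    if sample_id is None:
        sample_id = Path(path).stem
    abundance: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileParseError(
                    f"{path}: line {lineno}: expected species<TAB>abundance"
                )
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise ProfileParseError(f"{path}: line {lineno}: bad abundance") from exc
            if not math.isfinite(value) or value <= 0:
                raise ProfileParseError(f"{path}: line {lineno}: abundance must be > 0")
            abundance[parts[0]] = abundance.get(parts[0], 0.0) + value
    if not abundance:
        raise ProfileParseError(f"{path}: empty species table")
    return SampleProfile(sample_id, abundance)


@dataclass
class ReferenceDB:
    """The loaded reference: lineages, species-to-genome index and phylogeny."""

    lineages: dict[str, Lineage]
    species_index: dict[str, list[str]]
    distance_oracle: DistanceOracle
    _species_lineage: dict[str, Lineage] = field(default_factory=dict, repr=False)

    @classmethod
    def load(cls, taxonomy_path, tree_path) -> "ReferenceDB":
        lineages = parse_taxonomy_table(taxonomy_path)
        index = build_species_index(lineages)
        oracle = parse_reference_tree(tree_path, taxonomy=lineages)
        db = cls(lineages, index, oracle)
        for accession, lineage in lineages.items():
            db._species_lineage.setdefault(lineage.species, lineage)
        return db

    @property
    def species_names(self) -> list[str]:
        return sorted(self.species_index)

    def lineage_of_species(self, species: str) -> Lineage:
        try:
            return self._species_lineage[species]
        except KeyError as exc:
            raise KeyError(f"species {species!r} not in reference") from exc

    def species_lineages(self) -> dict[str, Lineage]:
        return dict(self._species_lineage)

    def representative(self, species: str) -> str:
        """Tree leaf anchoring a species: its lexicographically first accession.

        Falls back to the species name itself when the tree is keyed by
        species names rather than accessions.
        """
        accessions = self.species_index.get(species)
        if not accessions:
            raise KeyError(f"species {species!r} not in reference")
        leaves = self.distance_oracle.leaves
        for acc in accessions:
            if acc in leaves:
                return acc
        if species in leaves:
            return species
        raise KeyError(f"species {species!r} has no leaf in the reference tree")
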