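"""Multiway taxonomic trees of microbial communities.

A community (or the whole reference) is represented as a rooted multiway tree
whose levels are the seven taxonomic ranks.  Nodes are classified as *entity*
or *non-entity*: all species and domains are entities, and an intermediate
node is an entity exactly when it has two or more direct children.  Only
entity nodes map to a concrete position on the reference phylogeny — a taxon
with a single community member is indistinguishable from that member — so
evolutionary distances are recorded only between an entity node and its
nearest entity ancestor (a "bypass" edge when non-entity nodes intervene).

Each entity node is anchored at the most recent common ancestor, in the
reference phylogeny, of the representative leaves of its community member
species; the bypass distance is the branch-length path between the two
anchors.  Species-to-root distances are therefore additive along the entity
path.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .reference_io import DistanceOracle, Lineage

#: tree roles used throughout the pipeline
ROLES = ("T_real", "T_ref", "T_sample", "T_sim")


@dataclass
class TreeNode:
    name: str
    rank: str  # "root" or one of RANK_CODES
    children: list["TreeNode"] = field(default_factory=list)
    is_entity: bool | None = None
    entity_parent_distance: float | None = None
    path: str = ""

    def child(self, name: str) -> "TreeNode | None":
        for c in self.children:
            if c.name == name:
                return c
        return None

    def sort(self) -> None:
        self.children.sort(key=lambda c: c.name)
        for c in self.children:
            c.sort()


class CommunityTree:
    """A rooted multiway tree over the seven taxonomic ranks."""

    def __init__(self, root: TreeNode, role: str):
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        self.root = root
        self.role = role

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def species_nodes(self) -> list[TreeNode]:
        return [n for n in self.iter_nodes() if n.rank == "s"]

    def species(self) -> list[str]:
        return [n.name for n in self.species_nodes()]

    def find(self, path: str) -> TreeNode | None:
        for node in self.iter_nodes():
            if node.path == path:
                return node
        return None

    def to_indented(self) -> str:
        lines: list[str] = []

        def rec(node: TreeNode, depth: int) -> None:
            flag = "E" if node.is_entity else ("-" if node.is_entity is not None else "?")
            dist = "" if node.entity_parent_distance is None else f" d={node.entity_parent_distance:.6g}"
            lines.append(f"{'  ' * depth}{node.rank}:{node.name} [{flag}]{dist}")
            for c in node.children:
                rec(c, depth + 1)

        rec(self.root, 0)
        return "\n".join(lines)

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            label = node.name.replace(" ", "_")
            if not node.children:
                return label
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}){label}"

        return rec(self.root) + ";"


def build_tree(species_list, lineages: dict[str, Lineage], role: str) -> CommunityTree:
    """Build the multiway tree of a species set from their lineages.

    Internal nodes are merged along shared lineage prefixes; children are
    ordered lexicographically so recursion order is deterministic.
    """
    missing = sorted(sp for sp in species_list if sp not in lineages)
    if missing:
        raise KeyError(f"species without lineage: {missing}")
    root = TreeNode(name="", rank="root", path="")
    for sp in sorted(set(species_list)):
        lineage = lineages[sp]
        node = root
        for code, name in lineage.ranks:
            nxt = node.child(name)
            if nxt is None:
                path = f"{node.path}/{code}__{name}" if node.path else f"{code}__{name}"
                nxt = TreeNode(name=name, rank=code, path=path)
                node.children.append(nxt)
            elif nxt.rank != code:  # same name at different rank cannot merge
                raise ValueError(f"rank clash at {name!r}: {nxt.rank} vs {code}")
            node = nxt
    root.sort()
    return CommunityTree(root, role)


def classify_entities(tree: CommunityTree) -> CommunityTree:
    """Flag entity nodes: all species and domains, plus any node with >=2 children."""
    for node in tree.iter_nodes():
        if node.rank == "root":
            node.is_entity = False
        elif node.rank in ("d", "s"):
            node.is_entity = True
        else:
            node.is_entity = len(node.children) >= 2
    return tree


def _members(node: TreeNode, rep, cache: dict[str, tuple]) -> tuple:
    got = cache.get(node.path)
    if got is not None:
        return got
    if node.rank == "s":
        out = (rep(node.name),)
    else:
        out = tuple(m for c in node.children for m in _members(c, rep, cache))
    cache[node.path] = out
    return out


def annotate_distances(
    tree: CommunityTree,
    oracle: DistanceOracle,
    representatives=None,
) -> CommunityTree:
    """Attach entity-to-entity evolutionary distances to a classified tree.

    ``representatives`` maps species names to reference-tree leaf labels
    (identity by default, for trees keyed directly by species names).  Every
    entity node below the domain level receives ``entity_parent_distance``:
    the reference-phylogeny path length between its anchor (the MRCA of its
    member leaves) and the anchor of its nearest entity ancestor.  Domains
    and the super-root carry no distance.
    """
    if representatives is None:
        rep = lambda sp: sp  # noqa: E731
    elif callable(representatives):
        rep = representatives
    else:
        rep = representatives.__getitem__
    cache: dict[str, tuple] = {}

    missing = sorted(
        sp for sp in tree.species() if rep(sp) not in oracle.leaves
    )
    if missing:
        raise KeyError(f"species missing from distance oracle: {missing}")

    def visit(node: TreeNode, entity_anc: TreeNode | None) -> None:
        if node.rank == "root":
            node.entity_parent_distance = None
            nxt = None
        elif node.rank == "d":
            node.entity_parent_distance = None
            nxt = node
        elif node.is_entity:
            node.entity_parent_distance = oracle.anchor_distance(
                _members(node, rep, cache), _members(entity_anc, rep, cache)
            )
            nxt = node
        else:
            node.entity_parent_distance = None
            nxt = entity_anc
        for c in node.children:
            visit(c, nxt)

    visit(tree.root, None)
    return tree


def species_to_root_distance(tree: CommunityTree, species: str) -> float:
    """Sum of bypass distances along the entity path from a species to its domain."""
    target: list[TreeNode] = []

    def rec(node: TreeNode, path: list[TreeNode]) -> bool:
        path.append(node)
        if node.rank == "s" and node.name == species:
            target.extend(path)
            return True
        for c in node.children:
            if rec(c, path):
                return True
        path.pop()
        return False

    if not rec(tree.root, []):
        raise KeyError(f"species {species!r} not in tree")
    total = 0.0
    for node in target:
        if node.entity_parent_distance is not None:
            total += node.entity_parent_distance
    return total
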