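"""Recursive search for the reference subtree closest to a sampled community.

Given a sampled community tree and the reference multiway tree, the search
finds, level by level, an injective assignment of sampled nodes to reference
nodes of the same rank that minimizes the total difference in evolutionary
distance.  At the genus level (the two-layer base case) sampled species are
matched to reference species by the absolute difference of their bypass
distances; at higher levels the cost of pairing two internal nodes is the
optimal cost of their subtrees plus, when both nodes are entities, the
absolute difference of their own bypass distances.  The species of the chosen
subtree constitute the simulated community.

Two search modes control the target distances of the genus base case:

* **accurate** — targets are the sampled species distances unchanged, so the
  simulated community mirrors the sample as closely as the reference allows;
* **prolific** — per genus, a fair Bernoulli coin decides whether targets are
  resampled (with replacement) from the sampled distances or drawn from the
  reference distances filtered to within one standard deviation of the
  sampled mean, which widens the diversity of the simulated community.

Two matchers are provided: ``optimal`` solves the injective assignment
exactly (Hungarian algorithm / exhaustive at the base), while ``greedy``
assigns each sampled child its best unclaimed reference child in order, which
mirrors a sequential first-fit reading of the search loop.  Greedy can never
beat optimal; ``optimal`` is the default.
"""
from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._rng import as_seed, substream
from .community_tree import CommunityTree, TreeNode, classify_entities

INF = float("inf")

MODES = ("accurate", "prolific")
MATCHINGS = ("optimal", "greedy")


class MatchInfeasibleError(ValueError):
    """Raised when there are fewer reference candidates than sampled targets."""


class ReferenceTooSmallError(ValueError):
    """Raised when no feasible assignment exists at the root."""


@dataclass
class GenusDistanceStats:
    """Per-genus distance statistics driving the prolific-mode draws.

    ``u`` and ``sigma`` are the mean and population standard deviation of the
    sampled (real) species distances; ``d_nref`` is the reference distances
    filtered to the window [u - sigma, u + sigma].
    """

    u: float
    sigma: float
    d_real: np.ndarray
    d_nref: np.ndarray


def genus_stats(d_real, d_ref) -> GenusDistanceStats:
    d_real = np.asarray(d_real, dtype=float)
    d_ref = np.asarray(d_ref, dtype=float)
    if d_real.size == 0:
        raise ValueError("d_real must be non-empty")
    u = float(np.mean(d_real))
    sigma = float(np.std(d_real))  # population std
    mask = (d_ref >= u - sigma) & (d_ref <= u + sigma)
    return GenusDistanceStats(u=u, sigma=sigma, d_real=d_real, d_nref=d_ref[mask])


def flip_mode_coin(rng: np.random.Generator) -> int:
    """One draw from Bernoulli(0.5): the per-genus prolific-mode coin."""
    return int(rng.integers(0, 2))


class TargetDrawer:
    """Draws (and caches) per-genus target distances for a search run.

    All draws are keyed by the sampled node path (and, for reference-filtered
    draws, the reference node path) so the same targets are produced no
    matter in which order candidate pairings are evaluated — exhaustive and
    recursive searches over the same instance see identical targets.
    ``force_coin`` pins the prolific coin for diagnostic use.
    """

    def __init__(self, mode: str, seed: int = 0, force_coin: int | None = None):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.mode = mode
        self.seed = int(seed)
        self.force_coin = force_coin
        self._coins: dict[str, int] = {}
        self._draws: dict[tuple, np.ndarray] = {}

    def coin(self, sample_key: str) -> int:
        if self.force_coin is not None:
            return int(self.force_coin)
        got = self._coins.get(sample_key)
        if got is None:
            got = flip_mode_coin(substream(self.seed, "coin|" + sample_key))
            self._coins[sample_key] = got
        return got

    def targets(self, sample_key: str, ref_key: str, d_real, d_ref) -> np.ndarray:
        d_real = np.asarray(d_real, dtype=float)
        if self.mode == "accurate":
            return d_real
        n = d_real.size
        p = self.coin(sample_key)
        if p == 1:
            key = ("p1", sample_key)
            if key not in self._draws:
                rng = substream(self.seed, "p1|" + sample_key)
                self._draws[key] = rng.choice(d_real, size=n, replace=True)
            return self._draws[key]
        key = ("p0", sample_key, ref_key)
        if key not in self._draws:
            stats = genus_stats(d_real, d_ref)
            pool = stats.d_nref if stats.d_nref.size else stats.d_real
            rng = substream(self.seed, f"p0|{sample_key}|{ref_key}")
            self._draws[key] = rng.choice(pool, size=n, replace=True)
        return self._draws[key]


def match_genus(targets, candidates, method: str = "optimal"):
    """Injectively assign target distances to candidate species.

    ``candidates`` is a sequence of ``(name, distance)`` pairs.  Returns
    ``(cost, assignment)`` where ``assignment[i]`` is the index into the
    (name-sorted) candidate list matched to ``targets[i]`` and ``cost`` is
    the summed absolute distance difference.  Raises
    :class:`MatchInfeasibleError` when candidates are fewer than targets.
    """
    if method not in MATCHINGS:
        raise ValueError(f"method must be one of {MATCHINGS}, got {method!r}")
    targets = np.asarray(targets, dtype=float)
    cand = sorted(candidates, key=lambda nc: nc[0])
    if len(cand) < targets.size:
        raise MatchInfeasibleError(
            f"{targets.size} targets but only {len(cand)} candidates"
        )
    dists = np.array([c for _, c in cand], dtype=float)
    if targets.size == 0:
        return 0.0, []
    if method == "optimal":
        m = np.abs(targets[:, None] - dists[None, :])
        rows, cols = linear_sum_assignment(m)
        order = np.argsort(rows)
        assignment = [int(c) for c in cols[order]]
        cost = float(m[rows, cols].sum())
        return cost, assignment
    used: set[int] = set()
    assignment = []
    cost = 0.0
    for t in targets:
        best = None
        for j, (name, d) in enumerate(cand):
            if j in used:
                continue
            key = (abs(t - d), name)
            if best is None or key < best[0]:
                best = (key, j)
        used.add(best[1])
        assignment.append(best[1])
        cost += best[0][0]
    return float(cost), assignment


@dataclass
class SearchResult:
    """Outcome of a subtree search."""

    min_dis: float
    choice_node: dict[str, tuple[str, float]]  # sampled path -> (ref path, cost)
    t_sim: CommunityTree
    mode: str
    matching: str
    seed: int

    def species(self) -> list[str]:
        return self.t_sim.species()

    def write_mapping(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#min_dis\t{self.min_dis!r}\n")
            fh.write("#sampled_node\tchosen_reference_node\tcost\n")
            for sample_path in sorted(self.choice_node):
                ref_path, cost = self.choice_node[sample_path]
                fh.write(f"{sample_path}\t{ref_path}\t{cost!r}\n")


def sample_tree(real_trees, rng: np.random.Generator) -> CommunityTree:
    """Uniformly pick one real community tree and return a deep copy."""
    if not real_trees:
        raise ValueError("no real trees to sample from")
    idx = int(rng.integers(0, len(real_trees)))
    chosen = real_trees[idx]
    clone = CommunityTree(copy.deepcopy(chosen.root), "T_sample")
    return clone


def _epd_term(a: TreeNode, b: TreeNode) -> float:
    if a.entity_parent_distance is None or b.entity_parent_distance is None:
        return 0.0
    return abs(a.entity_parent_distance - b.entity_parent_distance)


def _species_dist(node: TreeNode) -> float:
    d = node.entity_parent_distance
    return 0.0 if d is None else d


def _genus_case(vs: TreeNode, vr: TreeNode, drawer: TargetDrawer, matching: str):
    sp_s = sorted(vs.children, key=lambda n: n.name)
    sp_r = sorted(vr.children, key=lambda n: n.name)
    if len(sp_r) < len(sp_s):
        return INF, None
    d_real = [_species_dist(n) for n in sp_s]
    d_ref = [_species_dist(n) for n in sp_r]
    targets = drawer.targets(vs.path, vr.path, d_real, d_ref)
    cand = [(n.name, _species_dist(n)) for n in sp_r]
    try:
        cost, assignment = match_genus(targets, cand, method=matching)
    except MatchInfeasibleError:
        return INF, None
    mapping = {vs.path: (vr.path, cost)}
    for i, j in enumerate(assignment):
        mapping[sp_s[i].path] = (sp_r[j].path, float(abs(targets[i] - _species_dist(sp_r[j]))))
    return cost, mapping


def _assign(children_s, children_r, pair_cost, matching: str):
    """Injective assignment of sampled children to reference children.

    ``pair_cost(i, j)`` returns the cost (possibly INF) of pairing sampled
    child i with reference child j.  Returns (total, pairs) or (INF, None).
    """
    n_s, n_r = len(children_s), len(children_r)
    if n_r < n_s:
        return INF, None
    m = np.empty((n_s, n_r))
    for i in range(n_s):
        for j in range(n_r):
            m[i, j] = pair_cost(i, j)
    if matching == "optimal":
        big = 1e18
        finite = np.where(np.isinf(m), big, m)
        rows, cols = linear_sum_assignment(finite)
        total = 0.0
        pairs = []
        for i, j in zip(rows, cols):
            if np.isinf(m[i, j]):
                return INF, None
            total += m[i, j]
            pairs.append((int(i), int(j)))
        return float(total), pairs
    # greedy: sampled children in lexicographic order grab their best
    # unclaimed reference child (ties broken by reference name)
    used: set[int] = set()
    total = 0.0
    pairs = []
    for i in range(n_s):
        best = None
        for j in range(n_r):
            if j in used or np.isinf(m[i, j]):
                continue
            key = (m[i, j], children_r[j].name)
            if best is None or key < best[0]:
                best = (key, j)
        if best is None:
            return INF, None
        used.add(best[1])
        total += best[0][0]
        pairs.append((i, best[1]))
    return float(total), pairs


def _pair_cost(vs: TreeNode, vr: TreeNode, drawer, matching, memo):
    key = (vs.path, vr.path)
    if key in memo:
        return memo[key]
    if vs.rank == "g":
        result = _genus_case(vs, vr, drawer, matching)
        memo[key] = result
        return result
    ch_s = sorted(vs.children, key=lambda n: n.name)
    ch_r = sorted(vr.children, key=lambda n: n.name)

    def cost_ij(i, j):
        sub, _ = _pair_cost(ch_s[i], ch_r[j], drawer, matching, memo)
        if sub == INF:
            return INF
        return sub + _epd_term(ch_s[i], ch_r[j])

    total, pairs = _assign(ch_s, ch_r, cost_ij, matching)
    if pairs is None:
        memo[key] = (INF, None)
        return memo[key]
    mapping = {vs.path: (vr.path, total)}
    for i, j in pairs:
        _, sub_map = _pair_cost(ch_s[i], ch_r[j], drawer, matching, memo)
        mapping.update(sub_map)
    memo[key] = (total, mapping)
    return memo[key]


def _prune_to_species(t_ref: CommunityTree, keep: set[str], role: str) -> CommunityTree:
    root = copy.deepcopy(t_ref.root)

    def rec(node: TreeNode) -> bool:
        if node.rank == "s":
            return node.name in keep
        node.children = [c for c in node.children if rec(c)]
        return bool(node.children)

    rec(root)
    tree = CommunityTree(root, role)
    for node in tree.iter_nodes():
        node.entity_parent_distance = None
    return classify_entities(tree)


def _finish(t_sample, t_ref, total, mapping, mode, matching, seed, oracle, representatives):
    chosen_species = {
        mapping[n.path][0].rsplit("/", 1)[-1].split("__", 1)[1]
        for n in t_sample.species_nodes()
    }
    t_sim = _prune_to_species(t_ref, chosen_species, "T_sim")
    if oracle is not None:
        from .community_tree import annotate_distances

        annotate_distances(t_sim, oracle, representatives)
    return SearchResult(
        min_dis=float(total),
        choice_node=mapping,
        t_sim=t_sim,
        mode=mode,
        matching=matching,
        seed=seed,
    )


def _root_pairs(t_sample: CommunityTree, t_ref: CommunityTree):
    """Same-domain pairing of the sampled and reference domain subtrees."""
    ref_domains = {c.name: c for c in t_ref.root.children}
    pairs = []
    for ds in sorted(t_sample.root.children, key=lambda n: n.name):
        dr = ref_domains.get(ds.name)
        if dr is None:
            raise ReferenceTooSmallError(
                f"reference too small: domain {ds.name!r} absent from reference"
            )
        pairs.append((ds, dr))
    return pairs


def get_subtree(
    t_sample: CommunityTree,
    t_ref: CommunityTree,
    mode: str = "accurate",
    matching: str = "optimal",
    seed=0,
    force_coin: int | None = None,
    oracle=None,
    representatives=None,
) -> SearchResult:
    """Search the reference tree for the closest-matching community subtree.

    Returns the minimal total distance difference (``min_dis``), the injective
    sampled-to-reference node assignment, and the simulated tree ``T_sim``
    built from the chosen reference species.  If ``oracle`` is given, ``T_sim``
    is re-annotated with bypass distances.
    """
    if matching not in MATCHINGS:
        raise ValueError(f"matching must be one of {MATCHINGS}, got {matching!r}")
    seed = as_seed(seed)
    drawer = TargetDrawer(mode, seed, force_coin=force_coin)
    memo: dict = {}
    total = 0.0
    mapping: dict[str, tuple[str, float]] = {}
    for ds, dr in _root_pairs(t_sample, t_ref):
        cost, sub_map = _pair_cost(ds, dr, drawer, matching, memo)
        if cost == INF:
            raise ReferenceTooSmallError(
                f"reference too small: no feasible assignment under domain {ds.name!r}"
            )
        total += cost
        mapping.update(sub_map)
    return _finish(t_sample, t_ref, total, mapping, mode, matching, seed, oracle, representatives)


def brute_force_subtree(
    t_sample: CommunityTree,
    t_ref: CommunityTree,
    mode: str = "accurate",
    seed=0,
    force_coin: int | None = None,
    max_children: int = 8,
    max_species: int = 40,
    oracle=None,
    representatives=None,
) -> SearchResult:
    """Exhaustive-enumeration oracle for :func:`get_subtree`.

    Enumerates every injective level-wise mapping and returns the global
    minimum.  Shares the per-node target-draw cache construction with
    :func:`get_subtree`, so with equal ``seed`` both searches score identical
    targets.  Refuses instances beyond the size guards.
    """
    for node in t_ref.iter_nodes():
        if len(node.children) > max_children:
            raise ValueError(
                f"instance too large for exhaustive search: node {node.path!r} "
                f"has {len(node.children)} > {max_children} children"
            )
    n_sp = len(t_ref.species())
    if n_sp > max_species:
        raise ValueError(
            f"instance too large for exhaustive search: {n_sp} > {max_species} species"
        )
    seed = as_seed(seed)
    drawer = TargetDrawer(mode, seed, force_coin=force_coin)
    memo: dict = {}

    def bf(vs: TreeNode, vr: TreeNode):
        key = (vs.path, vr.path)
        if key in memo:
            return memo[key]
        if vs.rank == "g":
            sp_s = sorted(vs.children, key=lambda n: n.name)
            sp_r = sorted(vr.children, key=lambda n: n.name)
            if len(sp_r) < len(sp_s):
                memo[key] = (INF, None)
                return memo[key]
            d_real = [_species_dist(n) for n in sp_s]
            d_ref = [_species_dist(n) for n in sp_r]
            targets = drawer.targets(vs.path, vr.path, d_real, d_ref)
            best = (INF, None)
            for perm in itertools.permutations(range(len(sp_r)), len(sp_s)):
                cost = sum(
                    abs(targets[i] - _species_dist(sp_r[j])) for i, j in enumerate(perm)
                )
                if cost < best[0]:
                    best = (cost, perm)
            if best[1] is None:
                memo[key] = (INF, None)
                return memo[key]
            mapping = {vs.path: (vr.path, float(best[0]))}
            for i, j in enumerate(best[1]):
                mapping[sp_s[i].path] = (
                    sp_r[j].path,
                    float(abs(targets[i] - _species_dist(sp_r[j]))),
                )
            memo[key] = (float(best[0]), mapping)
            return memo[key]
        ch_s = sorted(vs.children, key=lambda n: n.name)
        ch_r = sorted(vr.children, key=lambda n: n.name)
        if len(ch_r) < len(ch_s):
            memo[key] = (INF, None)
            return memo[key]
        best = (INF, None)
        for perm in itertools.permutations(range(len(ch_r)), len(ch_s)):
            total = 0.0
            for i, j in enumerate(perm):
                sub, _ = bf(ch_s[i], ch_r[j])
                if sub == INF:
                    total = INF
                    break
                total += sub + _epd_term(ch_s[i], ch_r[j])
            if total < best[0]:
                best = (total, perm)
        if best[1] is None:
            memo[key] = (INF, None)
            return memo[key]
        mapping = {vs.path: (vr.path, float(best[0]))}
        for i, j in enumerate(best[1]):
            _, sub_map = bf(ch_s[i], ch_r[j])
            mapping.update(sub_map)
        memo[key] = (float(best[0]), mapping)
        return memo[key]

    total = 0.0
    mapping: dict[str, tuple[str, float]] = {}
    for ds, dr in _root_pairs(t_sample, t_ref):
        cost, sub_map = bf(ds, dr)
        if cost == INF:
            raise ReferenceTooSmallError(
                f"reference too small: no feasible assignment under domain {ds.name!r}"
            )
        total += cost
        mapping.update(sub_map)
    return _finish(
        t_sample, t_ref, total, mapping, mode, "optimal", seed, oracle, representatives
    )
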