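"""Clone-phylogeny construction from per-sample cluster medians.

Two constraints shape the tree. The *sum rule* (pigeonhole): in any sample
the CCFs of a clone's daughters cannot sum past the parent's CCF. The
*crossing rule*: two clones whose CCF ordering flips between samples cannot
sit on one root-to-leaf path. Real read counts are noisy, so both rules are
scored with an absolute tolerance ``epsilon`` on the medians, and the tree
violating the fewest rules wins.

For small clone counts (K <= ``exhaustive_limit``) every rooted labelled
tree is enumerated through Prüfer sequences — K^(K-2) candidates — and
scored exactly. Above the limit a greedy insertion by descending clone size
followed by steepest-descent reparenting is used; it is a heuristic, but it
is validated against the exhaustive oracle on every small instance.

Tie-breaking among equal-violation trees: fewer crossing violations first,
then the size rule (a daughter with fewer mutations should hang below its
larger sibling, i.e. prefer trees with fewer small-parent/large-child
edges), then the lexicographically smallest parent vector.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cluster import CloneCluster
from .config import AnalysisConfig


@dataclass
class ViolationSummary:
    total: float
    sum_rule: int
    crossing: int
    sum_details: List[tuple] = field(default_factory=list)
    # (parent_label, sample, excess)
    crossing_details: List[tuple] = field(default_factory=list)
    # (label_b, label_c) pairs that must branch but sit on one path


@dataclass
class CloneTree:
    """A rooted clone phylogeny over a set of clusters."""

    clusters: List[CloneCluster]
    parent: Dict[str, Optional[str]]  # root maps to None
    violations: ViolationSummary

    def __post_init__(self) -> None:
        roots = [l for l, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        labels = {c.label for c in self.clusters}
        if set(self.parent) != labels:
            raise ValueError("parent relation does not span the clusters")
        # acyclicity: walking up from every node must reach the root
        for l in self.parent:
            seen = set()
            while l is not None:
                if l in seen:
                    raise ValueError("cycle in parent relation")
                seen.add(l)
                l = self.parent[l]

    @property
    def root(self) -> str:
        return next(l for l, p in self.parent.items() if p is None)

    def children(self, label: str) -> List[str]:
        return sorted(l for l, p in self.parent.items() if p == label)

    def descendants(self, label: str) -> List[str]:
        out, stack = [], [label]
        while stack:
            for ch in self.children(stack.pop()):
                out.append(ch)
                stack.append(ch)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b``."""
        p = self.parent[b]
        while p is not None:
            if p == a:
                return True
            p = self.parent[p]
        return False

    def by_label(self, label: str) -> CloneCluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(label)


def _median_map(clusters: Sequence[CloneCluster]) -> Dict[str, np.ndarray]:
    return {c.label: c.median_ccf for c in clusters}


def sum_rule_violations(parent: Dict[str, Optional[str]],
                        clusters: Sequence[CloneCluster],
                        epsilon: float) -> Tuple[int, List[tuple]]:
    """Count (node, sample) pairs where daughter CCFs outsum the parent.

    The boundary is inclusive: a children sum of exactly parent + epsilon
    is tolerated.
    """
    med = _median_map(clusters)
    samples = clusters[0].samples
    children: Dict[str, list] = {}
    for l, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(l)
    count, details = 0, []
    for node, kids in children.items():
        ksum = np.sum([med[k] for k in kids], axis=0)
        excess = ksum - med[node] - epsilon
        for j, e in enumerate(excess):
            if e > 1e-12:
                count += 1
                details.append((node, samples[j], float(e + epsilon)))
    return count, details


def crossing_constraints(clusters: Sequence[CloneCluster],
                         epsilon: float) -> set:
    """Unordered clone pairs whose CCF ordering flips between samples.

    Pair (B, C) is constrained iff B exceeds C by more than epsilon in one
    sample and C exceeds B by more than epsilon in another; such clones must
    branch. With a single sample the set is empty by definition.
    """
    out = set()
    for b, c in itertools.combinations(clusters, 2):
        d = b.median_ccf - c.median_ccf
        if (d > epsilon).any() and (d < -epsilon).any():
            out.add(frozenset((b.label, c.label)))
    return out


def _crossing_violations(parent: Dict[str, Optional[str]],
                         constraints: set) -> List[tuple]:
    """Constrained pairs placed on a single root-to-leaf path.

    Counted once per pair, however many samples exhibit the flip: the rule
    is a topological constraint, not a per-sample quantity.
    """
    anc: Dict[str, set] = {}
    for l in parent:
        s, p = set(), parent[l]
        while p is not None:
            s.add(p)
            p = parent[p]
        anc[l] = s
    bad = []
    for pair in constraints:
        b, c = tuple(pair)
        if b in anc[c] or c in anc[b]:
            bad.append(tuple(sorted((b, c))))
    return sorted(bad)


def score_tree(parent: Dict[str, Optional[str]],
               clusters: Sequence[CloneCluster],
               config: Optional[AnalysisConfig] = None) -> ViolationSummary:
    """Deterministically re-score any proposed parent relation."""
    config = config or AnalysisConfig()
    labels = {c.label for c in clusters}
    if set(parent) != labels:
        raise ValueError("tree does not span the clusters")
    eps = config.rule_epsilon
    n_sum, sum_details = sum_rule_violations(parent, clusters, eps)
    cross = _crossing_violations(parent, crossing_constraints(clusters, eps))
    total = n_sum + config.crossing_weight * len(cross)
    return ViolationSummary(total, n_sum, len(cross), sum_details, cross)


def _size_inversions(parent: Dict[str, Optional[str]],
                     sizes: Dict[str, int]) -> int:
    """Edges where the child carries more mutations than its parent."""
    return sum(1 for l, p in parent.items()
               if p is not None and sizes[l] > sizes[p])


def _prufer_to_parent(seq: Tuple[int, ...], k: int, root: int) -> List[int]:
    """Decode a Prüfer sequence into a parent vector rooted at ``root``."""
    if k == 1:
        return [-1]
    degree = [1] * k
    for v in seq:
        degree[v] += 1
    adj: List[List[int]] = [[] for _ in range(k)]
    edges = []
    heap = [i for i in range(k) if degree[i] == 1]
    heapq.heapify(heap)
    for v in seq:
        u = heapq.heappop(heap)
        edges.append((u, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(heap, v)
    u = heapq.heappop(heap)
    v = heapq.heappop(heap)
    edges.append((u, v))
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    par = [-2] * k
    par[root] = -1
    stack = [root]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if par[y] == -2:
                par[y] = x
                stack.append(y)
    return par


def _all_rooted_parent_vectors(k: int, root: int):
    """All k^(k-2) labelled trees on k nodes, rooted at ``root``."""
    if k == 1:
        yield [-1]
        return
    if k == 2:
        par = [-2, -2]
        par[root] = -1
        par[1 - root] = root
        yield par
        return
    for seq in itertools.product(range(k), repeat=k - 2):
        yield _prufer_to_parent(seq, k, root)


def _score_key(parent_vec: List[int], labels: List[str],
               clusters_sorted: List[CloneCluster],
               med: np.ndarray, sizes: List[int],
               constraints: List[Tuple[int, int]],
               eps: float, cross_w: float) -> tuple:
    """(total, crossing, size inversions, parent vector) — lower is better."""
    k, S = med.shape
    kid_sum = np.zeros_like(med)
    for child, p in enumerate(parent_vec):
        if p >= 0:
            kid_sum[p] += med[child]
    has_kids = np.zeros(k, dtype=bool)
    for p in parent_vec:
        if p >= 0:
            has_kids[p] = True
    n_sum = int(((kid_sum - med - eps) > 1e-12)[has_kids].sum())
    # ancestor closure
    anc = [set() for _ in range(k)]
    for i in range(k):
        p = parent_vec[i]
        while p >= 0:
            anc[i].add(p)
            p = parent_vec[p]
    n_cross = sum(1 for b, c in constraints if b in anc[c] or c in anc[b])
    inv = sum(1 for child, p in enumerate(parent_vec)
              if p >= 0 and sizes[child] > sizes[p])
    total = n_sum + cross_w * n_cross
    return (total, n_cross, inv, tuple(parent_vec))


def build_tree(clusters: Sequence[CloneCluster], truncal_label: str,
               config: Optional[AnalysisConfig] = None,
               method: str = "auto") -> CloneTree:
    """Find the clone tree with the fewest sum/crossing-rule violations.

    ``method``: "exhaustive" enumerates every rooted labelled tree,
    "greedy" uses size-ordered insertion plus local search, "auto" picks
    exhaustive for K <= ``config.exhaustive_limit``.
    """
    config = config or AnalysisConfig()
    clusters = sorted(clusters, key=lambda c: c.label)
    labels = [c.label for c in clusters]
    if truncal_label not in labels:
        raise ValueError(f"truncal label {truncal_label!r} not among clusters")
    k = len(labels)
    root = labels.index(truncal_label)
    med = np.stack([c.median_ccf for c in clusters])
    sizes = [c.size for c in clusters]
    eps = config.rule_epsilon
    cons = crossing_constraints(clusters, eps)
    cons_idx = [tuple(sorted(labels.index(x) for x in pair)) for pair in cons]

    def key_of(vec):
        return _score_key(vec, labels, clusters, med, sizes, cons_idx,
                          eps, config.crossing_weight)

    if method == "auto":
        method = "exhaustive" if k <= config.exhaustive_limit else "greedy"
    if method == "exhaustive":
        best = min(_all_rooted_parent_vectors(k, root), key=key_of)
    elif method == "greedy":
        best = _greedy_tree(k, root, sizes, med, cons_idx, eps,
                            config.crossing_weight, key_of,
                            seed=config.seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    parent = {labels[i]: (labels[p] if p >= 0 else None)
              for i, p in enumerate(best)}
    return CloneTree(list(clusters), parent, score_tree(parent, clusters, config))


def _partial_score(par: List[int], placed: List[int], med: np.ndarray,
                   constraints, eps: float, cross_w: float) -> float:
    """Violation total of the tree restricted to the placed clones."""
    pset = set(placed)
    kid_sum: Dict[int, np.ndarray] = {}
    for node in placed:
        p = par[node]
        if p >= 0:
            kid_sum.setdefault(p, np.zeros(med.shape[1]))
            kid_sum[p] += med[node]
    n_sum = 0
    for node, s in kid_sum.items():
        n_sum += int(((s - med[node] - eps) > 1e-12).sum())
    anc: Dict[int, set] = {}
    for node in placed:
        a, p = set(), par[node]
        while p >= 0:
            a.add(p)
            p = par[p]
        anc[node] = a
    n_cross = sum(1 for b, c in constraints
                  if b in pset and c in pset
                  and (b in anc[c] or c in anc[b]))
    return n_sum + cross_w * n_cross


def _greedy_tree(k: int, root: int, sizes: List[int], med: np.ndarray,
                 constraints, eps: float, cross_w: float, key_of,
                 seed: int = 0, n_restarts: int = 5) -> List[int]:
    """Greedy insertion plus steepest-descent reparenting, with restarts.

    Restart 0 inserts clones by descending total CCF — by the sum rule an
    ancestor's CCF dominates each descendant's in every sample, so
    high-CCF clones belong near the root and placing them first lets each
    insertion be scored on the tree built so far. Further restarts use
    seeded random insertion orders to escape local optima. The best tree
    across restarts by the full scoring key is returned; deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    others = [i for i in range(k) if i != root]
    best_par, best_key = None, None
    for restart in range(n_restarts):
        if restart == 0:
            order = sorted(others,
                           key=lambda i: (-float(med[i].sum()), i))
        else:
            order = list(rng.permutation(others))
        par = _grow_and_polish(k, root, order, med, constraints, eps,
                               cross_w, key_of)
        par = _plateau_escape(par, k, root, med, constraints, eps, cross_w,
                              key_of)
        kk = key_of(par)
        if best_key is None or kk < best_key:
            best_par, best_key = par, kk
    return best_par


def _violation_nodes(par: List[int], k: int, med: np.ndarray,
                     constraints, eps: float) -> List[int]:
    """Clones involved in current violations: candidates for plateau moves."""
    out = set()
    kid_sum: Dict[int, np.ndarray] = {}
    for child, p in enumerate(par):
        if p >= 0:
            kid_sum.setdefault(p, np.zeros(med.shape[1]))
            kid_sum[p] += med[child]
    for node, s in kid_sum.items():
        if ((s - med[node] - eps) > 1e-12).any():
            out.update(child for child, p in enumerate(par) if p == node)
    anc = [set() for _ in range(k)]
    for i in range(k):
        p = par[i]
        while p >= 0:
            anc[i].add(p)
            p = par[p]
    for b, c in constraints:
        if b in anc[c] or c in anc[b]:
            out.update((b, c))
    return sorted(out)


def _plateau_escape(par: List[int], k: int, root: int, med: np.ndarray,
                    constraints, eps: float, cross_w: float,
                    key_of) -> List[int]:
    """Sideways move + re-polish: escapes star-shaped local optima where no
    single reparenting lowers the violation count but a pair of moves does."""
    for _ in range(3):
        cur = key_of(par)
        if cur[0] == 0:
            break
        moved = False
        for node in _violation_nodes(par, k, med, constraints, eps):
            if node == root:
                continue
            desc = {x for x in range(k)
                    if node in _ancestors_of(par, x)}
            for cand_p in range(k):
                if cand_p == node or cand_p == par[node] or cand_p in desc:
                    continue
                trial = par[:]
                trial[node] = cand_p
                if key_of(trial)[0] > cur[0]:
                    continue
                trial = _steepest_descent(trial, k, root, key_of)
                if key_of(trial) < cur:
                    par, moved = trial, True
                    break
            if moved:
                break
        if not moved:
            break
    return par


def _ancestors_of(par: List[int], x: int) -> set:
    out, p = set(), par[x]
    while p >= 0:
        out.add(p)
        p = par[p]
    return out


def _grow_and_polish(k: int, root: int, order: List[int], med: np.ndarray,
                     constraints, eps: float, cross_w: float,
                     key_of) -> List[int]:
    placed = [root]
    par = [-2] * k
    par[root] = -1
    for node in order:
        best_p, best_score = None, None
        for p in placed:
            par[node] = p
            sc = _partial_score(par, placed + [node], med, constraints,
                                eps, cross_w)
            if best_score is None or sc < best_score:
                best_score, best_p = sc, p
        par[node] = best_p
        placed.append(node)
    return _steepest_descent(par, k, root, key_of)


def _steepest_descent(par: List[int], k: int, root: int, key_of) -> List[int]:
    """Move any node under any non-descendant while the key improves."""
    par = par[:]
    improved = True
    while improved:
        improved = False
        cur_key = key_of(par)
        for node in range(k):
            if node == root:
                continue
            # descendants of node (cannot become its parent)
            desc = set()
            for x in range(k):
                p = par[x]
                while p >= 0:
                    if p == node:
                        desc.add(x)
                        break
                    p = par[p]
            for cand_p in range(k):
                if cand_p == node or cand_p == par[node] or cand_p in desc:
                    continue
                trial = par[:]
                trial[node] = cand_p
                kk = key_of(trial)
                if kk < cur_key:
                    par, cur_key = trial, kk
                    improved = True
    return par


def to_edge_list(tree: CloneTree) -> List[Tuple[str, str]]:
    """(parent, child) pairs, root excluded, child-label order."""
    return [(p, l) for l, p in sorted(tree.parent.items()) if p is not None]


def to_newick(tree: CloneTree) -> str:
    """Newick string with clone letters as labels."""
    def fmt(label: str) -> str:
        kids = tree.children(label)
        if not kids:
            return label
        return "(" + ",".join(fmt(c) for c in kids) + ")" + label
    return fmt(tree.root) + ";"
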