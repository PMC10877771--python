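"""Clone identification: clustering loci in multi-sample CCF space.

Loci are clustered with a variational Bayesian Gaussian mixture (diagonal
covariance, Dirichlet-process weight prior so surplus components vanish),
undersized clusters are absorbed into their nearest neighbour, and each
clone is summarised by its per-sample median CCF — the clonal fraction —
and its mutation count. Labels are single letters assigned by descending
size (A is the largest clone).

The split/merge operations are the deterministic, audit-logged counterpart
of manual curation: every edit records what changed and why it is legal.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

from .config import AnalysisConfig


@dataclass
class CloneCluster:
    """A clone: a cluster of loci with a per-sample median CCF."""

    label: str
    samples: tuple
    member_loci: tuple
    median_ccf: np.ndarray  # aligned to samples

    def __post_init__(self) -> None:
        self.median_ccf = np.asarray(self.median_ccf, dtype=float)
        if self.median_ccf.shape != (len(self.samples),):
            raise ValueError("median_ccf shape mismatch with samples")

    @property
    def size(self) -> int:
        return len(self.member_loci)

    def median_for(self, sample: str) -> float:
        return float(self.median_ccf[self.samples.index(sample)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneCluster):
            return NotImplemented
        return (self.label == other.label
                and self.samples == other.samples
                and set(self.member_loci) == set(other.member_loci)
                and np.array_equal(self.median_ccf, other.median_ccf))


@dataclass
class Clustering:
    """Clustering result plus the audit trail of curation edits."""

    samples: tuple
    clusters: List[CloneCluster]
    audit: List[dict] = field(default_factory=list)

    def by_label(self, label: str) -> CloneCluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(f"no cluster labelled {label!r}")

    def assignments(self) -> Dict[str, str]:
        return {loc: c.label for c in self.clusters for loc in c.member_loci}


def _labels_by_size(clusters: Sequence[CloneCluster]) -> List[CloneCluster]:
    """Relabel clusters A, B, C, ... by descending size.

    Ties broken by descending median-CCF vector then by first member locus,
    so the labelling is deterministic and order-independent.
    """
    order = sorted(
        clusters,
        key=lambda c: (-c.size, tuple(-c.median_ccf), min(c.member_loci)))
    out = []
    for i, c in enumerate(order):
        label = _letter(i)
        out.append(CloneCluster(label, c.samples, c.member_loci, c.median_ccf))
    return out


def _letter(i: int) -> str:
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


def _medians(ccf: np.ndarray, members: Sequence[int]) -> np.ndarray:
    return np.median(ccf[list(members), :], axis=0)


def _bic_axis_split(vals: np.ndarray, min_size: int,
                    seed: int) -> Optional[np.ndarray]:
    """Boolean side mask if a 2-component 1-D mixture beats 1 by BIC."""
    from sklearn.mixture import GaussianMixture
    v = vals.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=seed).fit(v)
    g2 = GaussianMixture(2, random_state=seed, n_init=2).fit(v)
    if g2.bic(v) >= g1.bic(v):
        return None
    side = g2.predict(v) == 1
    if min(side.sum(), (~side).sum()) < min_size:
        return None
    return side


def cluster_ccfs(ccf_matrix, config: Optional[AnalysisConfig] = None) -> Clustering:
    """Cluster usable loci into clones in multi-sample CCF space.

    Three stages, all deterministic for a fixed seed:

    1. a variational Bayesian Gaussian mixture (up to
       ``config.max_mixture_components`` components, 1000 iterations,
       diagonal covariance, component-variance prior at the read-noise
       scale) over the usable rows of the CCF matrix;
    2. programmatic curation, replacing by-eye editing: clusters showing a
       BIC-supported bimodality along some sample axis whose parts separate
       by at least ``split_min_gap`` are split recursively, then clusters
       whose medians sit within ``merge_distance`` of each other (max over
       samples) — indistinguishable at the noise scale — are merged;
    3. clusters below ``min_cluster_size`` are absorbed into the nearest
       survivor (Euclidean distance of medians) and letter labels are
       assigned by descending size.
    """
    config = config or AnalysisConfig()
    idx = np.flatnonzero(ccf_matrix.usable)
    if idx.size < config.min_cluster_size:
        raise ValueError(
            f"only {idx.size} usable loci; need >= {config.min_cluster_size}")
    X = ccf_matrix.ccf[idx, :]
    S = X.shape[1]
    n_comp = min(config.max_mixture_components, idx.size)
    gmm = BayesianGaussianMixture(
        n_components=n_comp,
        covariance_type="diag",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=100.0,
        covariance_prior=np.full(S, config.mixture_covariance_prior),
        max_iter=1000,
        reg_covar=1e-4,
        random_state=config.seed,
    )
    comp = gmm.fit_predict(X)

    groups: Dict[int, list] = {}
    for row, k in enumerate(comp):
        groups.setdefault(int(k), []).append(row)

    # curation stage A: recursive BIC-supported splits along sample axes
    changed = True
    while changed:
        changed = False
        for k in sorted(groups):
            rows = np.array(groups[k])
            if len(rows) < 2 * config.min_cluster_size:
                continue
            for ax in range(S):
                side = _bic_axis_split(X[rows, ax],
                                       config.min_cluster_size, config.seed)
                if side is None:
                    continue
                gap = np.abs(np.median(X[rows[side]], axis=0)
                             - np.median(X[rows[~side]], axis=0)).max()
                if gap < config.split_min_gap:
                    continue
                groups[k] = list(rows[~side])
                groups[max(groups) + 1] = list(rows[side])
                changed = True
                break
            if changed:
                break

    # curation stage B: merge clusters indistinguishable at the noise scale
    med = {k: _medians(X, rows) for k, rows in groups.items()}
    while True:
        ks = sorted(groups)
        best = None
        for a, b in itertools.combinations(ks, 2):
            d = float(np.abs(med[a] - med[b]).max())
            if d < config.merge_distance and (best is None or d < best[0]):
                best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        groups[a] += groups.pop(b)
        med[a] = _medians(X, groups[a])
        med.pop(b)

    # absorb undersized clusters into the nearest big one
    big = [k for k, rows in groups.items()
           if len(rows) >= config.min_cluster_size]
    small = [k for k in groups if k not in big]
    if not big:
        # degenerate: pool everything into one cluster
        rows = sorted(r for rr in groups.values() for r in rr)
        groups, big, small = {0: rows}, [0], []
        med = {0: _medians(X, rows)}
    for k in small:
        tgt = min(big, key=lambda b: float(np.linalg.norm(med[b] - med[k])))
        groups[tgt].extend(groups.pop(k))
    loci = [ccf_matrix.loci[i] for i in idx]
    clusters = []
    for k in big:
        rows = groups[k]
        clusters.append(CloneCluster(
            label="?",
            samples=tuple(ccf_matrix.samples),
            member_loci=tuple(loci[r] for r in rows),
            median_ccf=_medians(X, rows)))
    return Clustering(tuple(ccf_matrix.samples), _labels_by_size(clusters))


def _recompute(clustering: Clustering, ccf_matrix,
               member_sets: List[tuple]) -> List[CloneCluster]:
    pos = {loc: i for i, loc in enumerate(ccf_matrix.loci)}
    out = []
    for members in member_sets:
        rows = [pos[m] for m in members]
        out.append(CloneCluster(
            "?", clustering.samples, tuple(members),
            np.median(ccf_matrix.ccf[rows, :], axis=0)))
    return _labels_by_size(out)


def merge_clusters(clustering: Clustering, ccf_matrix,
                   label_x: str, label_y: str) -> Clustering:
    """Merge two clones; medians recomputed over the pooled members."""
    if label_x == label_y:
        raise ValueError(f"cannot merge cluster {label_x!r} with itself")
    cx, cy = clustering.by_label(label_x), clustering.by_label(label_y)
    keep = [c.member_loci for c in clustering.clusters if c not in (cx, cy)]
    keep.append(tuple(cx.member_loci) + tuple(cy.member_loci))
    clusters = _recompute(clustering, ccf_matrix, keep)
    audit = clustering.audit + [{
        "op": "merge", "labels": [label_x, label_y],
        "sizes": [cx.size, cy.size]}]
    return Clustering(clustering.samples, clusters, audit)


def split_cluster(clustering: Clustering, ccf_matrix, label: str,
                  sample_axis: str, threshold: float,
                  config: Optional[AnalysisConfig] = None) -> Clustering:
    """Split a clone at a CCF threshold on one sample axis.

    Members with CCF <= threshold on the named sample form one part, the
    rest the other; both parts must reach ``min_cluster_size``.
    """
    config = config or AnalysisConfig()
    c = clustering.by_label(label)
    s = clustering.samples.index(sample_axis)
    pos = {loc: i for i, loc in enumerate(ccf_matrix.loci)}
    vals = np.array([ccf_matrix.ccf[pos[m], s] for m in c.member_loci])
    if not (vals.min() < threshold < vals.max()):
        raise ValueError(
            f"threshold {threshold} outside cluster CCF range "
            f"[{vals.min():.3f}, {vals.max():.3f}] on {sample_axis}")
    low = tuple(m for m, v in zip(c.member_loci, vals) if v <= threshold)
    high = tuple(m for m, v in zip(c.member_loci, vals) if v > threshold)
    if min(len(low), len(high)) < config.min_cluster_size:
        raise ValueError(
            f"split of {label!r} leaves a part below min_cluster_size "
            f"({len(low)} vs {len(high)})")
    keep = [cc.member_loci for cc in clustering.clusters if cc is not c]
    keep.extend([low, high])
    clusters = _recompute(clustering, ccf_matrix, keep)
    audit = clustering.audit + [{
        "op": "split", "label": label, "sample": sample_axis,
        "threshold": threshold, "sizes": [len(low), len(high)]}]
    return Clustering(clustering.samples, clusters, audit)


def identify_truncal(clusters: Sequence[CloneCluster],
                     config: Optional[AnalysisConfig] = None) -> str:
    """Label of the truncal (ancestral) clone.

    A sample is tumour-bearing when its largest cluster median reaches
    1 - delta. The truncal clone is clonal (median >= 1 - delta) in every
    tumour-bearing sample; among several qualifiers the largest wins.
    Truncality is defined by CCF, never by mutation count: the ancestral
    clone need not be the biggest cluster.
    """
    config = config or AnalysisConfig()
    if not clusters:
        raise ValueError("no clusters")
    thr = 1.0 - config.clonality_delta
    samples = clusters[0].samples
    bearing = [
        j for j in range(len(samples))
        if max(c.median_ccf[j] for c in clusters) >= thr]
    qualifiers = [
        c for c in clusters
        if all(c.median_ccf[j] >= thr for j in bearing)]
    if not qualifiers:
        raise ValueError("no truncal clone: no cluster is clonal in every "
                         "tumour-bearing sample")
    return max(qualifiers, key=lambda c: (c.size, c.label)).label
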