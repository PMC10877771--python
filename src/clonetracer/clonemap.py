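"""Per-sample clone compositions, spread direction, and seeding inference.

A clone map shows, for each sample, the nested composition of its clones —
the structure drawn as a sunburst, ancestral clone at the centre. Raw
cluster medians are first projected to the nearest tree-consistent vector
(clipped to [0, 1]; offending sibling sets scaled down proportionally so
children never outsum their parent), then three inferences are read off:

* *direction*: sample x gave rise to sample y when some clone is genuinely
  subclonal in x but clonal in y, and everything clonal in x persists in y
  (the clone-set nesting guard keeps sibling samples that share only the
  trunk from being ordered);
* *polyclonality*: a sample carrying two or more sibling subclones;
* *seeding*: the maximally-derived clones present in a metastasis sample —
  more than one branch present means multiple seeding events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cluster import CloneCluster
from .config import AnalysisConfig
from .tree import CloneTree


@dataclass
class Transition:
    source: str
    target: str
    supporting_clones: List[str]
    ambiguous: bool = False


@dataclass
class SeedingCall:
    met_sample: str
    clones: List[str]               # maximally-derived clones present
    multiple: bool
    candidate_sources: Dict[str, List[str]]  # clone -> primary samples


@dataclass
class CloneMap:
    """Per-sample nested clone composition plus inter-sample inferences."""

    samples: List[str]
    tree: CloneTree
    corrected: Dict[str, Dict[str, float]]  # sample -> clone -> CCF in [0,1]
    raw: Dict[str, Dict[str, float]]
    polyclonal: Dict[str, bool] = field(default_factory=dict)
    transitions: List[Transition] = field(default_factory=list)
    seeding: List[SeedingCall] = field(default_factory=list)

    def composition(self, sample: str,
                    delta: float = 0.10) -> Dict[str, List[str]]:
        """Present clones of a sample, as parent -> present children."""
        pres = {c for c, v in self.corrected[sample].items() if v > delta}
        return {c: [k for k in self.tree.children(c) if k in pres]
                for c in pres}


def correct_ccfs(clusters: Sequence[CloneCluster], tree: CloneTree
                 ) -> Dict[str, Dict[str, float]]:
    """Project raw medians onto the tree-consistent set, per sample.

    Values are clipped to [0, 1]; then, walking from the root down, any
    sibling set whose sum exceeds its parent's corrected value is scaled
    down proportionally. Already-consistent vectors pass through unchanged.
    """
    samples = clusters[0].samples
    med = {c.label: c.median_ccf for c in clusters}
    out: Dict[str, Dict[str, float]] = {}
    for j, s in enumerate(samples):
        vals = {l: float(np.clip(med[l][j], 0.0, 1.0)) for l in med}
        order = [tree.root]
        i = 0
        while i < len(order):
            node = order[i]
            i += 1
            kids = tree.children(node)
            order.extend(kids)
            if not kids:
                continue
            ksum = sum(vals[k] for k in kids)
            if ksum > vals[node] and ksum > 0:
                scale = vals[node] / ksum
                for k in kids:
                    vals[k] *= scale
        out[s] = vals
    return out


def classify_polyclonal(sample: str, cmap: CloneMap,
                        delta: float = 0.10) -> bool:
    """True iff some clone has >= 2 children present (CCF > delta)."""
    vals = cmap.corrected[sample]
    for label in vals:
        present_kids = [k for k in cmap.tree.children(label)
                        if vals.get(k, 0.0) > delta]
        if len(present_kids) >= 2:
            return True
    return False


def infer_transition(sample_x: str, sample_y: str, cmap: CloneMap,
                     config: Optional[AnalysisConfig] = None
                     ) -> Optional[Transition]:
    """Spread direction between two samples, or None.

    x gave rise to y when some clone's corrected CCF is strictly subclonal
    in x (between delta and 1 - delta) yet clonal in y (>= 1 - delta), and
    every clone clonal in x remains present (> delta) in y. If both
    directions qualify the call is ambiguous and None is returned (flagged
    on the map's transition log by callers that want it).
    """
    config = config or AnalysisConfig()
    d = config.clonality_delta
    for s in (sample_x, sample_y):
        if s not in cmap.corrected:
            raise KeyError(f"unknown sample {s!r}")

    def qualifies(a: str, b: str) -> List[str]:
        va, vb = cmap.corrected[a], cmap.corrected[b]
        support = [c for c in va
                   if d < va[c] < 1 - d and vb.get(c, 0.0) >= 1 - d]
        if not support:
            return []
        clonal_in_a = [c for c in va if va[c] >= 1 - d]
        if any(vb.get(c, 0.0) <= d for c in clonal_in_a):
            return []
        return support

    fwd = qualifies(sample_x, sample_y)
    rev = qualifies(sample_y, sample_x)
    if fwd and rev:
        return None
    if fwd:
        return Transition(sample_x, sample_y, sorted(fwd))
    if rev:
        return Transition(sample_y, sample_x, sorted(rev))
    return None


def infer_seeding(met_sample: str, cmap: CloneMap,
                  config: Optional[AnalysisConfig] = None,
                  primary_samples: Optional[Sequence[str]] = None
                  ) -> SeedingCall:
    """Source clones of a metastasis: maximally-derived clones present.

    Returns the present clones (CCF > delta) that have no present
    descendant; no returned clone is an ancestor of another, and more than
    one of them means multiple seeding events from distinct branches. For
    each clone the candidate source samples are the primary samples where
    it is present.
    """
    config = config or AnalysisConfig()
    d = config.clonality_delta
    vals = cmap.corrected[met_sample]
    present = {c for c, v in vals.items() if v > d}
    tips = sorted(
        c for c in present
        if not any(cmap.tree.is_ancestor(c, o) for o in present if o != c))
    primaries = list(primary_samples) if primary_samples is not None else [
        s for s in cmap.samples if s != met_sample]
    sources = {c: [s for s in primaries
                   if cmap.corrected[s].get(c, 0.0) > d] for c in tips}
    return SeedingCall(met_sample, tips, len(tips) > 1, sources)


def build_clone_map(clusters: Sequence[CloneCluster], tree: CloneTree,
                    sites: Optional[Dict[str, str]] = None,
                    config: Optional[AnalysisConfig] = None) -> CloneMap:
    """Assemble the full clone map with all per-cohort inferences.

    ``sites`` maps sample ids to anatomical sites; samples at lymph-node or
    "other" sites are treated as metastases for seeding inference, with the
    prostate samples as candidate sources.
    """
    config = config or AnalysisConfig()
    samples = list(clusters[0].samples)
    med = {c.label: c.median_ccf for c in clusters}
    raw = {s: {l: float(med[l][j]) for l in med}
           for j, s in enumerate(samples)}
    cmap = CloneMap(samples, tree, correct_ccfs(clusters, tree), raw)
    cmap.polyclonal = {
        s: classify_polyclonal(s, cmap, config.clonality_delta)
        for s in samples}
    for i, x in enumerate(samples):
        for y in samples[i + 1:]:
            t = infer_transition(x, y, cmap, config)
            if t is not None:
                cmap.transitions.append(t)
    if sites:
        primaries = [s for s in samples if sites.get(s) == "prostate"]
        for s in samples:
            if sites.get(s) in ("lymph_node", "other"):
                cmap.seeding.append(
                    infer_seeding(s, cmap, config,
                                  primary_samples=primaries or None))
    return cmap


def plot_sunburst(cmap: CloneMap, sample: str, ax=None,
                  delta: float = 0.10):
    """Nested ring chart of one sample's composition (ancestral centre)."""
    import matplotlib.pyplot as plt
    from matplotlib import cm

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vals = cmap.corrected[sample]
    labels = sorted(vals)
    colors = {l: cm.tab20(i % 20) for i, l in enumerate(labels)}

    def draw(label: str, depth: int, theta0: float, theta1: float):
        if vals.get(label, 0.0) <= delta:
            return
        ax.barh(depth, (theta1 - theta0), left=theta0, height=1.0,
                color=colors[label], edgecolor="white")
        ax.text((theta0 + theta1) / 2, depth, label,
                ha="center", va="center", fontsize=8)
        kids = [k for k in cmap.tree.children(label)
                if vals.get(k, 0.0) > delta]
        if not kids and vals[label] > 0:
            return
        width = theta1 - theta0
        parent_ccf = vals[label]
        t = theta0
        for k in kids:
            w = width * vals[k] / parent_ccf if parent_ccf > 0 else 0
            draw(k, depth + 1, t, t + w)
            t += w

    draw(cmap.tree.root, 0, 0.0, 2 * np.pi)
    ax.set_xlim(0, 2 * np.pi)
    ax.axis("off")
    ax.set_title(sample)
    return ax
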