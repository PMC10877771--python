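"""Per-branch mutational-signature attribution.

SNVs are grouped into bins — one per clone, or one per user-declared
subsection of the phylogenetic tree — and each bin is treated as its own
"sample": a 96-channel trinucleotide catalogue is built on the
pyrimidine-strand convention, summarised into the six conversion types
(C>A, C>G, C>T, T>A, T>C, T>G), and decomposed against a reference
signature matrix by non-negative least squares with iterative removal of
weights below a cutoff (0.06 by default), the behaviour of standard
refitting tools.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls

log = logging.getLogger(__name__)

SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CHANNELS_96: Tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SIX_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def channel_parts(channel: str) -> Tuple[str, str, str]:
    """(context, ref, alt) for a channel like ``A[C>T]G``."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def canonical_channel(context: str, ref: str, alt: str) -> str:
    """Map a mutation to its pyrimidine-strand 96-channel key.

    Purine-reference mutations are reverse-complemented, so complementary
    descriptions of the same event (e.g. ``TGA G>A`` and ``TCA C>T``) land
    in the same channel.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} not centred on ref {ref!r}")
    if ref in "CT":
        return f"{context[0]}[{ref}>{alt}]{context[2]}"
    rc = "".join(_COMP[b] for b in reversed(context))
    return f"{rc[0]}[{_COMP[ref]}>{_COMP[alt]}]{rc[2]}"


@dataclass
class MutationCatalogue:
    """96-channel mutation counts for one bin, with six-type proportions."""

    bin_id: str
    counts: np.ndarray  # (96,) non-negative ints in CHANNELS_96 order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,) or (self.counts < 0).any():
            raise ValueError("counts must be 96 non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def six_type(self) -> Dict[str, float]:
        """Proportions of the six conversion types (sum to 1 when non-empty)."""
        if self.total == 0:
            return {t: 0.0 for t in SIX_TYPES}
        by_type = self.counts.reshape(6, 16).sum(axis=1)
        return {t: float(v) / self.total for t, v in zip(SIX_TYPES, by_type)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96),
                         name=self.bin_id)


@dataclass
class SignatureExposure:
    """Signature weights for one bin; weights >= 0 and sum <= 1."""

    bin_id: str
    weights: Dict[str, float]
    residual_norm: float

    def __post_init__(self) -> None:
        for k, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {k}")
        if sum(self.weights.values()) > 1 + 1e-9:
            raise ValueError("weights sum above 1")


def assign_bins(assignments: Dict[str, str], tree, scheme: str = "per_clone",
                subsections: Optional[Sequence[Iterable[str]]] = None
                ) -> Dict[str, str]:
    """Map every assigned SNV to a signature bin.

    ``per_clone``: one bin per clone label. ``per_subsection``: bins are
    user-declared connected clone sets (e.g. ``["D", "GF", "HA", "BC",
    "IE"]``) that must partition the tree's clones; the bin id is the
    concatenated clone letters.
    """
    labels = {c.label for c in tree.clusters}
    if scheme == "per_clone":
        return dict(assignments)
    if scheme != "per_subsection":
        raise ValueError(f"unknown scheme {scheme!r}")
    if not subsections:
        raise ValueError("per_subsection requires subsections")
    clone_to_bin: Dict[str, str] = {}
    for sub in subsections:
        members = list(sub)
        bin_id = "".join(members)
        for m in members:
            if m in clone_to_bin:
                raise ValueError(f"clone {m!r} appears in multiple subsections")
            if m not in labels:
                raise ValueError(f"unknown clone {m!r} in subsection {bin_id}")
            clone_to_bin[m] = bin_id
        _check_connected(members, tree)
    missing = labels - set(clone_to_bin)
    if missing:
        raise ValueError(f"clones not covered by any subsection: "
                         f"{sorted(missing)}")
    return {locus: clone_to_bin[cl] for locus, cl in assignments.items()}


def _check_connected(members: List[str], tree) -> None:
    """A subsection must be connected in the (undirected) clone tree."""
    mset = set(members)
    if len(mset) <= 1:
        return
    # undirected adjacency restricted to the subsection
    adj = {m: set() for m in mset}
    for m in mset:
        p = tree.parent[m]
        if p in mset:
            adj[m].add(p)
            adj[p].add(m)
    seen, stack = {members[0]}, [members[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if seen != mset:
        raise ValueError(f"subsection {''.join(members)} is not connected "
                         f"in the tree")


def build_catalogue(records: Sequence, bin_map: Dict[str, str]
                    ) -> Tuple[Dict[str, MutationCatalogue], int]:
    """Per-bin 96-channel catalogues from context-annotated records.

    Records without a trinucleotide context are skipped; the skip count is
    returned alongside the catalogues.
    """
    counts: Dict[str, np.ndarray] = {}
    skipped = 0
    for r in records:
        bin_id = bin_map.get(r.locus_id)
        if bin_id is None:
            continue
        if r.context is None:
            skipped += 1
            continue
        ch = canonical_channel(r.context, r.ref, r.alt)
        counts.setdefault(bin_id, np.zeros(96, dtype=int))
        counts[bin_id][_CHANNEL_INDEX[ch]] += 1
    if skipped:
        log.info("skipped %d records without trinucleotide context", skipped)
    return ({b: MutationCatalogue(b, c) for b, c in sorted(counts.items())},
            skipped)


def fit_exposures(catalogue: MutationCatalogue, reference: pd.DataFrame,
                  cutoff: float = 0.06) -> SignatureExposure:
    """Signature weights by NNLS with iterative small-weight removal.

    The catalogue is normalised to channel proportions and regressed on the
    reference columns (each a probability vector over the 96 channels) under
    non-negativity. Signatures whose normalised weight falls below
    ``cutoff`` are removed and the remainder refitted, until stable; the
    final weights are rescaled so they sum to at most 1.
    """
    ref = reference.reindex(list(CHANNELS_96))
    if ref.isna().any().any():
        raise ValueError("reference is missing channels of the canonical 96")
    if catalogue.total == 0:
        raise ValueError("empty catalogue")
    if catalogue.total < 50:
        log.warning("bin %s has only %d SNVs; exposure fit may be unstable",
                    catalogue.bin_id, catalogue.total)
    p = catalogue.counts / catalogue.total
    active = list(ref.columns)
    while True:
        R = ref[active].to_numpy()
        w, _ = nnls(R, p)
        total = w.sum()
        if total <= 0:
            w_norm = w
        else:
            w_norm = w / total
        drop = [sig for sig, wn in zip(active, w_norm) if wn < cutoff]
        if not drop:
            break
        if len(drop) == len(active):
            # degenerate: keep only the best-supported signature
            best = active[int(np.argmax(w))]
            if active == [best]:
                break
            active = [best]
            continue
        active = [s for s in active if s not in drop]
    if w.sum() > 1:
        w = w / w.sum()
    resid = float(np.linalg.norm(ref[active].to_numpy() @ w - p))
    weights = {s: float(v) for s, v in zip(active, w) if v > 0}
    return SignatureExposure(catalogue.bin_id, weights, resid)
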