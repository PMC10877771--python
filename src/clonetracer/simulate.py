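"""Ground-truthed multi-region cohort simulator.

Emulates the statistical structure of multi-region prostate-cancer WGS
cohorts: per patient, 2-9 samples drawn from prostate, seminal-vesicle and
lymph-node sites; one truncal clone plus branching subclones; purities
0.10-0.90; tumour depth around 88x; clonal and subclonal copy-number
segments with optional whole-genome duplication; and branch-specific
trinucleotide signature mixtures.

Generative model
----------------
* Tree: uniformly random rooted labelled tree on K clones (root = clone 0),
  drawn through a uniform Prüfer sequence.
* Clone fractions: per sample, Dirichlet stick-breaking down the tree. At
  each clone the remaining cell mass is split between "stay in this clone"
  and its (non-zeroed) children, so parent CCF strictly exceeds the
  children's sum wherever sibling fractions are positive — the sum rule
  holds exactly by construction. Spatial restriction is modelled by zeroing
  whole subtrees in a sample with probability ``sparsity`` per clone.
* Reads: a mutation on clone c with multiplicity m (uniform on
  {1..n_major}) has expected VAF m*rho*CCF / (rho*n_t + (1-rho)*n_n);
  total depth is Poisson, alt reads binomial.
* Contexts: drawn from the branch's mixture over a signature reference.

Every generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import CnState, PuritySample, Segment, SegmentProfile, SnvRecord

# Approximate autosome lengths (bp), GRCh38 scale.
GENOME_GRCH38 = {
    "1": 248_956_000, "2": 242_193_000, "3": 198_295_000, "4": 190_215_000,
    "5": 181_538_000, "6": 170_806_000, "7": 159_346_000, "8": 145_139_000,
    "9": 138_395_000, "10": 133_797_000, "11": 135_087_000, "12": 133_275_000,
    "13": 114_364_000, "14": 107_044_000, "15": 101_991_000, "16": 90_338_000,
    "17": 83_257_000, "18": 80_373_000, "19": 58_618_000, "20": 64_444_000,
    "21": 46_710_000, "22": 50_818_000,
}

# A small genome for fast tests: 4 chromosomes, 100 Mb total.
GENOME_TOY = {"1": 40_000_000, "2": 30_000_000, "3": 20_000_000,
              "4": 10_000_000}


@dataclass
class SimTruth:
    """Everything the simulator knows that the pipeline must recover."""

    parent: List[int]                  # parent[i] = index, -1 for root
    samples: List[str]
    clone_fractions: np.ndarray        # (S, K): own-cell fraction per clone
    ccf_true: np.ndarray               # (S, K): subtree sums
    snv_assignment: List[int]          # clone index per simulated SNV
    purity: Dict[str, float]
    sites: Dict[str, str]
    depth: float
    seed: int
    signature_mixtures: Optional[np.ndarray] = None  # (K, n_sigs)

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    def children(self, i: int) -> List[int]:
        return [j for j, p in enumerate(self.parent) if p == i]

    def subtree(self, i: int) -> List[int]:
        out, stack = [i], [i]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return out


def simulate_tree(K: int, seed: int) -> List[int]:
    """Uniformly random rooted labelled tree on K clones, root = 0.

    Drawn through a uniform Prüfer sequence, so all K^(K-2) labelled trees
    are equally likely; the tree is then oriented away from clone 0.
    """
    if not (2 <= K <= 26):
        raise ValueError(f"K must be in [2, 26], got {K}")
    rng = np.random.default_rng(seed)
    if K == 2:
        return [-1, 0]
    seq = rng.integers(0, K, size=K - 2)
    from .tree import _prufer_to_parent
    return _prufer_to_parent(tuple(int(x) for x in seq), K, 0)


def simulate_ccfs(parent: Sequence[int], S: int, seed: int,
                  alpha: float = 1.0, sparsity: float = 0.3,
                  min_clone_fraction: float = 0.05,
                  min_separation: float = 0.2,
                  max_tries: int = 5000) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample clone fractions and true CCFs by tree stick-breaking.

    Returns ``(clone_fractions, ccf_true)``, both (S, K). Per sample, each
    non-root clone's subtree is zeroed with probability ``sparsity``
    (spatial restriction); surviving mass is split by Dirichlet(alpha)
    weights between a clone's own cells and its children, recursively.

    Fraction sets are redrawn until (a) every clone owns at least
    ``min_clone_fraction`` of some sample's cells, and (b) every clone
    pair's CCF vectors differ by at least ``min_separation`` in some
    sample. Both constraints make the simulated clones *bona fide* distinct
    populations: at the depths being emulated (~90x, per-locus CCF noise
    around 0.14 at typical purity) two clones closer than ~1.5 noise SDs in
    every sample are not meaningfully separate clones, and no method — nor
    the study's manual curation — would report them apart.
    """
    K = len(parent)
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    children = [[j for j, p in enumerate(parent) if p == i] for i in range(K)]

    def draw_sample() -> np.ndarray:
        zeroed = set()
        for i in range(1, K):
            if rng.random() < sparsity:
                zeroed.add(i)
        # propagate: a zeroed clone kills its whole subtree
        killed = set()
        for i in sorted(zeroed):
            stack = [i]
            while stack:
                x = stack.pop()
                if x in killed:
                    continue
                killed.add(x)
                stack.extend(children[x])
        frac = np.zeros(K)
        ccf = np.zeros(K)
        ccf[0] = 1.0
        stack = [0]
        while stack:
            i = stack.pop()
            kids = [c for c in children[i] if c not in killed]
            if not kids:
                frac[i] = ccf[i]
                continue
            w = rng.dirichlet(np.full(len(kids) + 1, alpha))
            frac[i] = ccf[i] * w[0]
            for c, wc in zip(kids, w[1:]):
                ccf[c] = ccf[i] * wc
                stack.append(c)
        return frac

    for _ in range(max_tries):
        fr = np.stack([draw_sample() for _ in range(S)])
        if not (fr.max(axis=0) >= min_clone_fraction).all():
            continue
        cc = _subtree_sums(parent, fr)
        sep = np.abs(cc[:, :, None] - cc[:, None, :]).max(axis=0)
        iu = np.triu_indices(K, k=1)
        if (sep[iu] >= min_separation).all():
            return fr, cc
    raise RuntimeError("could not draw detectable, separated clone "
                       "fractions; lower sparsity, min_clone_fraction or "
                       "min_separation")


def _subtree_sums(parent: Sequence[int], frac: np.ndarray) -> np.ndarray:
    """ccf_true[s, i] = sum of clone_fractions over i's subtree."""
    K = frac.shape[1]
    ccf = frac.copy()
    # children-before-parents order
    depth = [0] * K
    for i in range(K):
        p, d = parent[i], 0
        while p >= 0:
            d += 1
            p = parent[p]
        depth[i] = d
    for i in sorted(range(K), key=lambda x: -depth[x]):
        p = parent[i]
        if p >= 0:
            ccf[:, p] += ccf[:, i]
    return ccf


def simulate_segments(genome_spec: Dict[str, int], wgd: bool = False,
                      subclonal_fraction: float = 0.0,
                      clonal_perturb_prob: float = 0.0,
                      mean_segments_per_chrom: float = 3.0,
                      seed: int = 0,
                      sample_id: str = "sim") -> Tuple[SegmentProfile, float]:
    """Random allele-specific segmentation with optional WGD.

    The baseline state is 1+1 (2+2 under WGD). Each segment may have its
    clonal state perturbed by one copy with probability
    ``clonal_perturb_prob``; segments are then marked subclonal — a second
    state one copy away, with a random cell-fraction split — until the
    targeted fraction of bases is subclonal. Returns the profile and its
    length-weighted ploidy.
    """
    rng = np.random.default_rng(seed)
    base = (2, 2) if wgd else (1, 1)
    raw: List[Segment] = []
    for chrom, length in genome_spec.items():
        n_seg = 1 + rng.poisson(max(mean_segments_per_chrom - 1, 0))
        cuts = np.sort(rng.integers(2, length, size=n_seg - 1)) if n_seg > 1 \
            else np.array([], dtype=int)
        bounds = [1, *cuts.tolist(), length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            end = b - 1 if b != length else length
            nmaj, nmin = base
            if clonal_perturb_prob > 0 and rng.random() < clonal_perturb_prob:
                delta = int(rng.choice([-1, 1]))
                nmaj = max(nmaj + delta, nmin if delta < 0 else nmaj)
                nmaj = max(nmaj, 0)
            raw.append(Segment(chrom, a, end, CnState(nmaj, nmin, 1.0)))
    total = sum(s.length for s in raw)
    # mark random segments subclonal until the base-fraction target is hit
    if subclonal_fraction > 0:
        order = rng.permutation(len(raw))
        # greedy with skip: take segments that fit under the target, then
        # top up with the one that overshoots least
        chosen, acc = [], 0
        for idx in order:
            if (acc + raw[idx].length) / total <= subclonal_fraction:
                chosen.append(idx)
                acc += raw[idx].length
        if acc / total < subclonal_fraction:
            rest = [i for i in order if i not in chosen]
            if rest:
                top = min(rest, key=lambda i: raw[i].length)
                chosen.append(top)
        for idx in chosen:
            s = raw[idx]
            f1 = round(float(rng.uniform(0.2, 0.8)), 9)
            st1 = CnState(s.state1.n_major, s.state1.n_minor, f1)
            up = rng.random() < 0.5
            nmaj2 = s.state1.n_major + (1 if up else -1)
            nmin2 = s.state1.n_minor
            if nmaj2 < nmin2:
                nmin2 = nmaj2
            if nmaj2 < 0:
                nmaj2, nmin2 = s.state1.n_major + 1, s.state1.n_minor
            st2 = CnState(nmaj2, nmin2, round(1 - f1, 9))
            raw[idx] = Segment(s.chrom, s.start, s.end, st1, st2)
    profile = SegmentProfile(sample_id, raw)
    from .metrics import compute_ploidy
    return profile, compute_ploidy(profile)


def synthetic_signature_reference(n_signatures: int = 4, seed: int = 0,
                                  include_flat: bool = True) -> pd.DataFrame:
    """A small synthetic 96-channel signature reference (columns sum to 1).

    Synthetic stand-in for a COSMIC-style reference: sparse, peaked columns
    plus (optionally) one flat column emulating the near-uniform profile of
    homologous-recombination-deficiency signatures. Deterministic per seed.
    """
    from .signatures import CHANNELS_96
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(n_signatures):
        name = f"SIG{i + 1}"
        if include_flat and i == n_signatures - 1:
            w = rng.uniform(0.8, 1.2, size=96)
            name = "SIGFLAT"
        else:
            w = rng.gamma(0.3, 1.0, size=96) + 1e-4
        cols[name] = w / w.sum()
    return pd.DataFrame(cols, index=list(CHANNELS_96))


def _draw_positions(genome_spec: Dict[str, int], n: int,
                    rng: np.random.Generator,
                    seen: Optional[set] = None) -> List[Tuple[str, int]]:
    """n genome positions, length-weighted by chromosome, no repeats."""
    chroms = list(genome_spec)
    lens = np.array([genome_spec[c] for c in chroms], dtype=float)
    seen = seen if seen is not None else set()
    out: List[Tuple[str, int]] = []
    while len(out) < n:
        k = int(rng.choice(len(chroms), p=lens / lens.sum()))
        loc = (chroms[k], int(rng.integers(2, genome_spec[chroms[k]])))
        if loc in seen:
            continue
        seen.add(loc)
        out.append(loc)
    return out


def simulate_reads(parent: Sequence[int], ccf_true: np.ndarray,
                   samples: Sequence[str], purity: Dict[str, float],
                   profile: SegmentProfile, genome_spec: Dict[str, int],
                   n_snv_per_clone: Sequence[int], depth: float, seed: int,
                   signature_mixtures: Optional[np.ndarray] = None,
                   reference: Optional[pd.DataFrame] = None,
                   normal_cn: int = 2
                   ) -> Tuple[List[SnvRecord], List[int]]:
    """Simulate per-sample read counts for every clone's mutations.

    Returns ``(records, assignment)`` where ``assignment[i]`` is the clone
    index of record i. Multiplicity is drawn uniformly on {1..n_major} of
    the covering segment and resampled downward if the implied VAF exceeds
    1 in any sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    K = len(parent)
    records: List[SnvRecord] = []
    assignment: List[int] = []
    from .signatures import CHANNELS_96, channel_parts
    seen_positions: set = set()
    for clone in range(K):
        n = int(n_snv_per_clone[clone])
        if n < 1:
            raise ValueError("every clone needs >= 1 SNV")
        positions = _draw_positions(genome_spec, n, rng, seen_positions)
        if signature_mixtures is not None and reference is not None:
            p = reference.to_numpy() @ signature_mixtures[clone]
            p = p / p.sum()
            chan_idx = rng.choice(96, size=n, p=p)
        else:
            chan_idx = rng.integers(0, 96, size=n)
        for (chrom, pos), ci in zip(positions, chan_idx):
            seg = profile.find(chrom, pos)
            if seg is None:
                continue
            n_t = seg.tumour_total
            n_major = max(seg.n_major_max, 1)
            context, ref, alt = channel_parts(CHANNELS_96[int(ci)])
            m_choices = list(range(1, n_major + 1))
            rng.shuffle(m_choices)
            chosen = None
            for m in m_choices:
                vafs = np.array([
                    m * purity[s] * ccf_true[j, clone]
                    / (purity[s] * n_t + (1 - purity[s]) * normal_cn)
                    for j, s in enumerate(samples)])
                if (vafs <= 1.0 + 1e-12).all():
                    chosen = (m, np.clip(vafs, 0, 1))
                    break
            if chosen is None:
                raise ValueError(
                    f"no multiplicity yields VAF <= 1 at {chrom}:{pos} "
                    f"(n_t={n_t:.2f})")
            m, vafs = chosen
            totals = rng.poisson(depth, size=len(samples))
            alts = rng.binomial(totals, vafs)
            records.append(SnvRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                alt_reads=tuple(int(a) for a in alts),
                total_reads=tuple(int(t) for t in totals),
                somatic_score=float(np.float32(rng.uniform(8.0, 100.0))),
                context=context))
            assignment.append(clone)
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].chrom, records[i].pos))
    return [records[i] for i in order], [assignment[i] for i in order]


def simulate_cohort(K: int = 5, S: int = 3, n_snv_per_clone: int = 200,
                    depth: float = 88.0, purity: float | None = None,
                    sparsity: float = 0.3, alpha: float = 1.0,
                    wgd: bool = False, subclonal_cn_fraction: float = 0.0,
                    genome_spec: Optional[Dict[str, int]] = None,
                    sites: Optional[Sequence[str]] = None,
                    n_signatures: int = 4, seed: int = 0
                    ) -> Tuple[SimTruth, List[SnvRecord],
                               Dict[str, SegmentProfile], List[PuritySample]]:
    """End-to-end cohort: tree, CCFs, copy number, reads, metadata.

    ``purity=None`` draws each sample's purity uniformly on [0.10, 0.90]
    (the cohort's observed range); a float fixes all samples. Sample sites
    default to prostate for all but the last sample, which is a lymph node
    when S >= 3.
    """
    rng = np.random.default_rng(seed)
    genome_spec = genome_spec or GENOME_TOY
    parent = simulate_tree(K, seed=int(rng.integers(1 << 31)))
    frac, ccf_true = simulate_ccfs(
        parent, S, seed=int(rng.integers(1 << 31)), alpha=alpha,
        sparsity=sparsity)
    samples = [f"S{i + 1}" for i in range(S)]
    if sites is None:
        sites = ["prostate"] * S
        if S >= 3:
            sites = ["prostate"] * (S - 1) + ["lymph_node"]
    if purity is None:
        rho = {s: float(rng.uniform(0.10, 0.90)) for s in samples}
    else:
        rho = {s: float(purity) for s in samples}
    profile, ploidy = simulate_segments(
        genome_spec, wgd=wgd, subclonal_fraction=subclonal_cn_fraction,
        seed=int(rng.integers(1 << 31)))
    reference = synthetic_signature_reference(n_signatures,
                                              seed=int(rng.integers(1 << 31)))
    mix = rng.dirichlet(np.ones(n_signatures), size=K)
    records, assignment = simulate_reads(
        parent, ccf_true, samples, rho, profile, genome_spec,
        [n_snv_per_clone] * K, depth, seed=int(rng.integers(1 << 31)),
        signature_mixtures=mix, reference=reference)
    truth = SimTruth(
        parent=list(parent), samples=samples, clone_fractions=frac,
        ccf_true=ccf_true, snv_assignment=assignment,
        purity=rho, sites=dict(zip(samples, sites)), depth=depth, seed=seed,
        signature_mixtures=mix)
    profiles = {s: SegmentProfile(s, list(profile.segments))
                for s in samples}
    purities = [PuritySample(s, rho[s], ploidy, site)
                for s, site in zip(samples, sites)]
    return truth, records, profiles, purities
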