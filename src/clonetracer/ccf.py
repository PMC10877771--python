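"""Cancer-cell-fraction computation from raw allele counts.

For a variant with allele fraction f = alt/total in a sample of purity rho,
sitting on a segment with tumour total copy number n_t (fraction-weighted
over subclonal states) while normal cells carry n_n copies, the expected
allele fraction of a mutation on m chromosomal copies in a fraction CCF of
tumour cells is

    f = m * rho * CCF / (rho * n_t + (1 - rho) * n_n)

Inverting: m_hat = f * (rho*n_t + (1-rho)*n_n) / rho, the multiplicity is
m = clamp(round(m_hat), 1, n_major), and

    CCF = f * (rho*n_t + (1-rho)*n_n) / (m * rho).

CCFs above 1 are retained (clipping would bias cluster medians) and flagged
when they pass the configured ceiling.

The module also carries the surrounding housekeeping: the somatic-evidence
(TLOD) shortlist filter, purity refinement that pins the truncal cluster's
median CCF to 1, segment-level QC that spots over/under-corrected copy
number, and imputation of a consensus copy-number profile for samples whose
purity is too low to segment reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import AnalysisConfig
from .types import (CnState, PuritySample, Segment, SegmentProfile, SnvRecord,
                    _chrom_key)

log = logging.getLogger(__name__)


@dataclass
class CcfMatrix:
    """Loci x samples matrix of copy-number-corrected CCFs."""

    loci: List[str]
    samples: List[str]
    ccf: np.ndarray           # (L, S) float; NaN where unusable
    multiplicity: np.ndarray  # (L, S) int; 0 where unusable
    usable: np.ndarray        # (L,) bool: locus passed in every sample
    flagged: np.ndarray       # (L,) bool: some CCF above the clamp ceiling

    def locus_index(self, locus_id: str) -> int:
        return self.loci.index(locus_id)

    def usable_loci(self) -> List[str]:
        return [l for l, u in zip(self.loci, self.usable) if u]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.ccf, index=self.loci, columns=self.samples)


def filter_tlod(records: Sequence[SnvRecord],
                config: Optional[AnalysisConfig] = None) -> List[SnvRecord]:
    """Shortlist variants by somatic-evidence score (inclusive threshold)."""
    config = config or AnalysisConfig()
    kept = [r for r in records if r.somatic_score >= config.tlod_min]
    log.info("TLOD filter at %.3g: kept %d, removed %d",
             config.tlod_min, len(kept), len(records) - len(kept))
    return kept


def compute_ccf(alt_reads: int, total_reads: int, segment: Segment,
                purity: float,
                config: Optional[AnalysisConfig] = None
                ) -> Tuple[float, int, bool]:
    """CCF and multiplicity for one locus in one sample.

    Returns ``(ccf, m, flagged)``; raises on zero depth (callers mark the
    locus unusable instead of passing it here blindly).
    """
    config = config or AnalysisConfig()
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not (0 < purity <= 1):
        raise ValueError(f"purity {purity} not in (0, 1]")
    f = alt_reads / total_reads
    n_t = segment.tumour_total
    denom = purity * n_t + (1 - purity) * config.normal_cn
    m_hat = f * denom / purity
    m = int(np.clip(round(m_hat), 1, max(segment.n_major_max, 1)))
    ccf = f * denom / (m * purity)
    return ccf, m, ccf > config.ccf_clamp_flag


def compute_ccf_matrix(records: Sequence[SnvRecord], samples: Sequence[str],
                       profiles: Dict[str, SegmentProfile],
                       purities: Dict[str, float],
                       config: Optional[AnalysisConfig] = None) -> CcfMatrix:
    """CCFs for every locus in every sample.

    A locus with zero depth or no covering segment in *any* sample is kept
    in the matrix but marked unusable (never silently dropped).
    """
    config = config or AnalysisConfig()
    L, S = len(records), len(samples)
    ccf = np.full((L, S), np.nan)
    mult = np.zeros((L, S), dtype=int)
    usable = np.ones(L, dtype=bool)
    flagged = np.zeros(L, dtype=bool)
    for i, r in enumerate(records):
        for j, s in enumerate(samples):
            seg = profiles[s].find(r.chrom, r.pos)
            if seg is None or r.total_reads[j] <= 0:
                usable[i] = False
                continue
            c, m, fl = compute_ccf(r.alt_reads[j], r.total_reads[j], seg,
                                   purities[s], config)
            ccf[i, j], mult[i, j] = c, m
            flagged[i] |= fl
    return CcfMatrix([r.locus_id for r in records], list(samples),
                     ccf, mult, usable, flagged)


def _truncal_median_ccf(records: Sequence[SnvRecord], sample_index: int,
                        profile: SegmentProfile, rho: float,
                        config: AnalysisConfig) -> float:
    vals = []
    for r in records:
        seg = profile.find(r.chrom, r.pos)
        if seg is None or r.total_reads[sample_index] <= 0:
            continue
        c, _, _ = compute_ccf(r.alt_reads[sample_index],
                              r.total_reads[sample_index], seg, rho, config)
        vals.append(c)
    if not vals:
        raise ValueError("no usable truncal loci in sample")
    return float(np.median(vals))


def refine_purity(truncal_records: Sequence[SnvRecord], sample_index: int,
                  profile: SegmentProfile, purity: float,
                  config: Optional[AnalysisConfig] = None) -> float:
    """Adjust purity so the truncal cluster's median CCF equals 1.

    Solves for rho on (0, 1] by 1-D root finding on the median-CCF curve
    (median CCF is monotone decreasing in rho). When no root exists in the
    bracket the input purity is returned unchanged with a warning.
    """
    config = config or AnalysisConfig()
    if len(truncal_records) < config.min_cluster_size:
        raise ValueError(
            f"truncal cluster has {len(truncal_records)} members; need >= "
            f"{config.min_cluster_size}")

    def g(rho: float) -> float:
        return _truncal_median_ccf(truncal_records, sample_index, profile,
                                   rho, config) - 1.0

    lo, hi = 1e-3, 1.0
    glo, ghi = g(lo), g(hi)
    if abs(g(purity)) < 1e-9:
        return purity
    if glo * ghi > 0:
        log.warning("no purity root in (0, 1]; keeping rho = %.3f", purity)
        return purity
    return float(brentq(g, lo, hi, xtol=1e-6))


@dataclass(frozen=True)
class SegmentFlag:
    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str          # "overcorrected" | "undercorrected"
    deviation: float   # segment truncal median minus genome-wide median
    n_support: int


def segment_qc(ccf_matrix: CcfMatrix, records: Sequence[SnvRecord],
               profiles: Dict[str, SegmentProfile],
               truncal_loci: Iterable[str],
               config: Optional[AnalysisConfig] = None) -> List[SegmentFlag]:
    """Flag segments whose truncal CCFs disagree with the genome-wide level.

    Truncal mutations should sit at CCF ~ 1 everywhere; a segment whose
    truncal median falls short by more than ``qc_epsilon`` suggests an
    overcorrection (copy number called too high), one that overshoots
    suggests undercorrection (a missed gain, or a spurious loss). Segments
    with fewer than ``qc_min_support`` truncal SNVs are never flagged.
    """
    config = config or AnalysisConfig()
    truncal = set(truncal_loci)
    pos = {l: i for i, l in enumerate(ccf_matrix.loci)}
    rec_by_id = {r.locus_id: r for r in records}
    flags: List[SegmentFlag] = []
    for j, sample in enumerate(ccf_matrix.samples):
        rows = [pos[l] for l in truncal
                if l in pos and np.isfinite(ccf_matrix.ccf[pos[l], j])]
        if not rows:
            continue
        genome_med = float(np.median(ccf_matrix.ccf[rows, j]))
        for seg in profiles[sample].segments:
            inseg = [pos[l] for l in truncal if l in rec_by_id
                     and seg.contains(rec_by_id[l].chrom, rec_by_id[l].pos)
                     and np.isfinite(ccf_matrix.ccf[pos[l], j])]
            if len(inseg) < config.qc_min_support:
                continue
            dev = float(np.median(ccf_matrix.ccf[inseg, j])) - genome_med
            if dev < -config.qc_epsilon:
                flags.append(SegmentFlag(sample, seg.chrom, seg.start,
                                         seg.end, "overcorrected", dev,
                                         len(inseg)))
            elif dev > config.qc_epsilon:
                flags.append(SegmentFlag(sample, seg.chrom, seg.start,
                                         seg.end, "undercorrected", dev,
                                         len(inseg)))
    return flags


def _union_breakpoints(profiles: Sequence[SegmentProfile]) -> Dict[str, List[tuple]]:
    """Re-segment all profiles to the union of their breakpoints."""
    chroms: Dict[str, set] = {}
    for p in profiles:
        for seg in p.segments:
            chroms.setdefault(seg.chrom, set()).update(
                (seg.start, seg.end + 1))
    grid: Dict[str, List[tuple]] = {}
    for chrom, cuts in chroms.items():
        edges = sorted(cuts)
        grid[chrom] = [(a, b - 1) for a, b in zip(edges, edges[1:])]
    return grid


def impute_cn_profile(donor_profiles: Sequence[SegmentProfile],
                      donor_purities: Sequence[float],
                      target_sample: str) -> SegmentProfile:
    """Consensus copy-number profile for a sample that cannot be segmented.

    Donor profiles (typically the intra-prostatic samples) are re-cut to the
    union of their breakpoints; each unified segment takes the modal donor
    state, ties broken toward the donor with the highest purity. Subclonal
    donor segments contribute their majority-fraction state.
    """
    if len(donor_profiles) < 2:
        raise ValueError("need >= 2 donor profiles for imputation")
    grid = _union_breakpoints(donor_profiles)
    segments: List[Segment] = []
    for chrom in sorted(grid, key=_chrom_key):
        for start, end in grid[chrom]:
            mid = (start + end) // 2
            votes: Dict[tuple, list] = {}
            for p, rho in zip(donor_profiles, donor_purities):
                seg = p.find(chrom, mid)
                if seg is None:
                    continue
                st = seg.major_state
                votes.setdefault((st.n_major, st.n_minor), []).append(rho)
            if not votes:
                continue
            best = max(votes.items(),
                       key=lambda kv: (len(kv[1]), max(kv[1])))
            n_major, n_minor = best[0]
            segments.append(Segment(chrom, start, end,
                                    CnState(n_major, n_minor, 1.0)))
    # merge adjacent same-state segments back together
    merged: List[Segment] = []
    for seg in segments:
        if (merged and merged[-1].chrom == seg.chrom
                and merged[-1].end + 1 == seg.start
                and merged[-1].state1 == seg.state1):
            prev = merged.pop()
            seg = Segment(seg.chrom, prev.start, seg.end, seg.state1)
        merged.append(seg)
    return SegmentProfile(target_sample, merged)
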