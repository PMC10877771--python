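"""Genome-level summaries: ploidy, WGD, subclonality, arm imbalance, drivers.

Ploidy is the base-pair-length-weighted, fraction-weighted mean total copy
number of a sample's segments. A genome is called whole-genome doubled when
its ploidy strictly exceeds 3. Percent subclonality is the share of
analysed bases lying in segments that carry a second copy-number state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import SegmentProfile, SnvRecord, _chrom_key

# Approximate GRCh38 centromere midpoints (bp) for arm bookkeeping.
CENTROMERES_GRCH38 = {
    "1": 123_400_000, "2": 93_900_000, "3": 90_900_000, "4": 50_000_000,
    "5": 48_800_000, "6": 59_800_000, "7": 60_100_000, "8": 45_200_000,
    "9": 43_000_000, "10": 39_800_000, "11": 53_400_000, "12": 35_500_000,
    "13": 17_700_000, "14": 17_200_000, "15": 19_000_000, "16": 36_800_000,
    "17": 25_100_000, "18": 18_500_000, "19": 26_200_000, "20": 28_100_000,
    "21": 12_000_000, "22": 15_000_000,
}


def arm_table_for(profile: SegmentProfile,
                  centromeres: Optional[Dict[str, int]] = None
                  ) -> pd.DataFrame:
    """p/q arm boundaries for the chromosomes present in a profile.

    Arms are cut at the centromere midpoint (GRCh38 defaults, overridable);
    chromosome extents are taken from the profile's own segments.
    """
    centromeres = centromeres or CENTROMERES_GRCH38
    rows = []
    for chrom in profile.chromosomes():
        segs = [s for s in profile.segments if s.chrom == chrom]
        lo, hi = min(s.start for s in segs), max(s.end for s in segs)
        cen = centromeres.get(chrom)
        if cen is None or cen >= hi:
            cen = (lo + hi) // 2
        rows.append({"chrom": chrom, "arm": "p", "start": lo, "end": cen})
        rows.append({"chrom": chrom, "arm": "q", "start": cen + 1, "end": hi})
    return pd.DataFrame(rows)


@dataclass
class GenomeSummary:
    sample_id: str
    ploidy: float
    wgd: bool
    pct_subclonal: float
    telomeric_imbalance: List[tuple] = field(default_factory=list)
    driver_calls: Dict[str, str] = field(default_factory=dict)


def compute_ploidy(profile: SegmentProfile) -> float:
    """Length- and fraction-weighted mean total copy number."""
    total_len = profile.total_length
    if total_len == 0:
        raise ValueError("profile covers zero bases")
    acc = 0.0
    for s in profile.segments:
        acc += s.length * s.tumour_total
    return acc / total_len


def classify_wgd(ploidy: float) -> bool:
    """Whole-genome doubled iff ploidy strictly exceeds 3."""
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    return ploidy > 3.0


def percent_subclonality(profile: SegmentProfile) -> float:
    """Percent of analysed bases in segments with a second CN state."""
    total_len = profile.total_length
    if total_len == 0:
        raise ValueError("profile covers zero bases")
    sub = sum(s.length for s in profile.segments if s.subclonal)
    return 100.0 * sub / total_len


def telomeric_imbalance(profile: SegmentProfile,
                        arm_table: Optional[pd.DataFrame] = None
                        ) -> List[Tuple[str, str]]:
    """Allele imbalance at chromosome-arm ends.

    For each arm, the segment containing the telomeric end (arm start for
    p, arm end for q) is inspected via its majority-fraction state: minor
    copy number 0 with at least one major copy is LOH; a total above the
    sample's rounded ploidy is a gain. Interstitial events that do not
    reach the arm end are excluded by construction.
    """
    if arm_table is None:
        arm_table = arm_table_for(profile)
    baseline = round(compute_ploidy(profile))
    out: List[Tuple[str, str]] = []
    for _, row in arm_table.iterrows():
        tel_pos = int(row["start"]) if row["arm"] == "p" else int(row["end"])
        seg = profile.find(str(row["chrom"]), tel_pos)
        if seg is None:
            continue
        st = seg.major_state
        name = f"{row['chrom']}{row['arm']}"
        if st.n_minor == 0 and st.n_major >= 1:
            out.append((name, "LOH"))
        elif st.total > baseline:
            out.append((name, "gain"))
    return out


def classify_driver_cna(profile: SegmentProfile,
                        genes: Sequence[Tuple[str, int, int, str]]
                        ) -> Dict[str, str]:
    """Del/Amp/neutral call per gene from total copy number.

    ``genes`` are BED-style tuples (chrom, start0, end_exclusive, name).
    Each gene takes the segment with the largest overlap; that segment's
    majority-fraction state's total copy number is classified: < 2 is Del,
    > 2 is Amp, exactly 2 is neutral. Calls on subclonal segments are
    suffixed "(subclonal)". Genes overlapping no segment are "uncovered".
    """
    calls: Dict[str, str] = {}
    for chrom, start0, end_ex, name in genes:
        g_start, g_end = start0 + 1, end_ex  # to 1-based inclusive
        best, best_ov = None, 0
        for seg in profile.segments:
            if seg.chrom != chrom:
                continue
            ov = min(seg.end, g_end) - max(seg.start, g_start) + 1
            if ov > best_ov:
                best, best_ov = seg, ov
        if best is None:
            calls[name] = "uncovered"
            continue
        total = best.major_state.total
        call = "Del" if total < 2 else ("Amp" if total > 2 else "neutral")
        if best.subclonal:
            call += " (subclonal)"
        calls[name] = call
    return calls


def presence_set(records: Sequence[SnvRecord], sample_index: int,
                 min_alt: int = 3, min_vaf: float = 0.05) -> set:
    """Loci counted as present in one sample under the presence rule."""
    out = set()
    for r in records:
        t = r.total_reads[sample_index]
        if t > 0 and r.alt_reads[sample_index] >= min_alt \
                and r.alt_reads[sample_index] / t >= min_vaf:
            out.add(r.locus_id)
    return out


def unique_snv_distance(records: Sequence[SnvRecord], samples: Sequence[str],
                        sample_x: str, sample_y: str,
                        min_alt: int = 3, min_vaf: float = 0.05) -> int:
    """Evolutionary distance: SNVs uniquely present in either sample.

    The size of the symmetric difference of the two samples' presence sets
    (default rule: alt reads >= 3 and VAF >= 0.05).
    """
    try:
        ix, iy = samples.index(sample_x), samples.index(sample_y)
    except ValueError as e:
        raise KeyError(str(e)) from None
    px = presence_set(records, ix, min_alt, min_vaf)
    py = presence_set(records, iy, min_alt, min_vaf)
    return len(px ^ py)


def summarize_genome(profile: SegmentProfile,
                     arm_table: Optional[pd.DataFrame] = None,
                     genes: Optional[Sequence[tuple]] = None
                     ) -> GenomeSummary:
    """All genome-level metrics for one sample in one pass."""
    psi = compute_ploidy(profile)
    return GenomeSummary(
        sample_id=profile.sample_id,
        ploidy=psi,
        wgd=classify_wgd(psi),
        pct_subclonal=percent_subclonality(profile),
        telomeric_imbalance=telomeric_imbalance(profile, arm_table),
        driver_calls=classify_driver_cna(profile, genes) if genes else {})
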