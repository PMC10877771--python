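"""Readers and writers for every external format the pipeline touches.

VCF 4.2 (multi-sample, AD/DP per sample, somatic score in INFO) is read
through cyvcf2; Battenberg-style segment tables, purity tables, BED gene
lists and signature references go through pandas. Trees and clone maps are
serialised as schema-versioned JSON, with Newick and edge-list exports for
trees. Readers validate strictly and reject, never repair, malformed input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cluster import CloneCluster
from .clonemap import CloneMap, SeedingCall, Transition
from .config import AnalysisConfig
from .tree import CloneTree, ViolationSummary, to_edge_list, to_newick
from .types import (CnState, PuritySample, Segment, SegmentProfile,
                    SnvRecord, check_cohort)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class VcfReadResult:
    records: List[SnvRecord]
    samples: List[str]
    skipped_non_snv: int


def read_snv_vcf(path, sample_order: Optional[Sequence[str]] = None,
                 score_key: str = "TLOD",
                 score_reduction: str = "max") -> VcfReadResult:
    """Read a multi-sample somatic VCF into SnvRecords.

    One record per biallelic SNV; multiallelic rows are split into one
    record per alternate allele; non-SNV alleles are skipped and counted.
    Sample order comes from the header unless ``sample_order`` overrides
    it. A somatic score with one value per sample (joint calling dialect)
    is reduced by ``score_reduction`` ("max" or "min").
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if sample_order is not None:
        missing = set(sample_order) - set(header_samples)
        if missing:
            raise ValueError(f"samples not in VCF header: {sorted(missing)}")
        order = [header_samples.index(s) for s in sample_order]
        samples = list(sample_order)
    else:
        order = list(range(len(header_samples)))
        samples = header_samples

    records: List[SnvRecord] = []
    skipped = 0
    for n_row, v in enumerate(vcf, start=1):
        try:
            ad = v.format("AD")
            if ad is None:
                raise ValueError(
                    f"allelic-depth (AD) field missing for samples "
                    f"{header_samples}")
            dp = v.format("DP")
            score = v.INFO.get(score_key)
            if score is None:
                raise ValueError(f"INFO/{score_key} missing")
            if isinstance(score, (tuple, list, np.ndarray)):
                score = (max(score) if score_reduction == "max"
                         else min(score))
            ctx = v.INFO.get("CTX")
            for ai, alt in enumerate(v.ALT):
                if len(v.REF) != 1 or len(alt) != 1 or \
                        v.REF not in "ACGT" or alt not in "ACGT":
                    skipped += 1
                    continue
                alts, totals = [], []
                for si in order:
                    a = int(ad[si][ai + 1])
                    if a < 0:
                        raise ValueError(
                            f"AD missing for sample {header_samples[si]}")
                    if dp is not None and int(np.atleast_1d(dp[si])[0]) >= 0:
                        t = int(np.atleast_1d(dp[si])[0])
                    else:
                        t = int(sum(x for x in ad[si] if x > 0))
                    alts.append(a)
                    totals.append(max(t, a))
                records.append(SnvRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    alt_reads=tuple(alts), total_reads=tuple(totals),
                    somatic_score=float(score),
                    context=str(ctx) if ctx is not None else None))
        except ValueError:
            raise
        except Exception as e:  # malformed row
            raise ValueError(f"malformed VCF row {n_row} "
                             f"({v.CHROM}:{v.POS}): {e}") from e
    if skipped:
        log.info("skipped %d non-SNV alleles", skipped)
    check_cohort(records, samples)
    return VcfReadResult(records, samples, skipped)


def write_snv_vcf(records: Sequence[SnvRecord], samples: Sequence[str],
                  path, score_key: str = "TLOD") -> None:
    """Write records as a minimal VCF 4.2 with AD/DP and the somatic score."""
    check_cohort(records, samples)
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        f'##INFO=<ID={score_key},Number=1,Type=Float,'
        f'Description="Somatic evidence score">',
        '##INFO=<ID=CTX,Number=1,Type=String,'
        'Description="Trinucleotide context">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for r in records:
        # 9 significant digits: exact for scores stored at float32 precision
        info = f"{score_key}={r.somatic_score:.9g}"
        if r.context is not None:
            info += f";CTX={r.context}"
        cells = []
        for a, t in zip(r.alt_reads, r.total_reads):
            cells.append(f"{t - a},{a}:{t}")
        lines.append("\t".join([
            r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS",
            info, "AD:DP", *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


_SEG_COLS = ("chrom", "startpos", "endpos", "nMaj1", "nMin1", "frac1")
_SEG_COLS2 = ("nMaj2", "nMin2", "frac2")


def read_segments(path, sample_id: Optional[str] = None) -> SegmentProfile:
    """Read a Battenberg-style allele-specific segment table.

    Expects columns chrom, startpos, endpos, nMaj1, nMin1, frac1 and
    optionally nMaj2, nMin2, frac2 (blank for clonal rows). Overlapping
    segments and fraction sums away from 1 are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"chrom": str},
                     na_values=["NA"])
    missing = set(_SEG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    has2 = all(c in df.columns for c in _SEG_COLS2)
    segments = []
    for _, row in df.iterrows():
        st1 = CnState(int(row.nMaj1), int(row.nMin1), float(row.frac1))
        st2 = None
        if has2 and not pd.isna(row.nMaj2):
            st2 = CnState(int(row.nMaj2), int(row.nMin2), float(row.frac2))
        segments.append(Segment(str(row.chrom), int(row.startpos),
                                int(row.endpos), st1, st2))
    sid = sample_id if sample_id is not None else Path(path).stem
    return SegmentProfile(sid, segments)


def write_segments(profile: SegmentProfile, path) -> None:
    rows = []
    for s in profile.segments:
        row = {"chrom": s.chrom, "startpos": s.start, "endpos": s.end,
               "nMaj1": s.state1.n_major, "nMin1": s.state1.n_minor,
               "frac1": s.state1.fraction,
               "nMaj2": s.state2.n_major if s.state2 else "NA",
               "nMin2": s.state2.n_minor if s.state2 else "NA",
               "frac2": s.state2.fraction if s.state2 else "NA"}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_purity(path) -> List[PuritySample]:
    """Read a purity/ploidy table (sample_id, purity, ploidy, site)."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"sample_id", "purity", "ploidy"}
    if need - set(df.columns):
        raise ValueError(f"purity table missing {sorted(need - set(df.columns))}")
    out = []
    for _, row in df.iterrows():
        out.append(PuritySample(
            str(row.sample_id), float(row.purity), float(row.ploidy),
            str(row.site) if "site" in df.columns else "other"))
    return out


def write_purity(purities: Sequence[PuritySample], path) -> None:
    pd.DataFrame([{
        "sample_id": p.sample_id, "purity": p.purity,
        "ploidy": p.ploidy, "site": p.site} for p in purities]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path) -> List[Tuple[str, int, int, str]]:
    """Read a BED file (0-based half-open) of gene intervals."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {i}: fewer than 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"BED line {i}: end <= start")
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        out.append((chrom, start, end, name))
    return out


def read_signature_reference(path) -> pd.DataFrame:
    """Read a 96-channel x signatures reference; columns must sum to 1."""
    from .signatures import CHANNELS_96
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(CHANNELS_96):
        raise ValueError("reference rows do not match the canonical "
                         "96 trinucleotide channels")
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"signature columns not summing to 1: "
                         f"{list(bad.index)}")
    return df.reindex(list(CHANNELS_96))


def write_signature_reference(ref: pd.DataFrame, path) -> None:
    ref.to_csv(path, sep="\t")


def write_ccf_matrix(matrix, path) -> None:
    """CCF matrix TSV: loci x samples, with multiplicities and flags."""
    cols = {"locus": matrix.loci}
    for j, s in enumerate(matrix.samples):
        cols[f"ccf_{s}"] = matrix.ccf[:, j]
    for j, s in enumerate(matrix.samples):
        cols[f"m_{s}"] = matrix.multiplicity[:, j]
    cols["usable"] = matrix.usable.astype(int)
    cols["flagged"] = matrix.flagged.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def read_ccf_matrix(path):
    from .ccf import CcfMatrix
    df = pd.read_csv(path, sep="\t")
    samples = [c[4:] for c in df.columns if c.startswith("ccf_")]
    ccf = df[[f"ccf_{s}" for s in samples]].to_numpy(dtype=float)
    mult = df[[f"m_{s}" for s in samples]].to_numpy(dtype=int)
    return CcfMatrix(list(df["locus"]), samples, ccf, mult,
                     df["usable"].to_numpy(dtype=bool),
                     df["flagged"].to_numpy(dtype=bool))


# ---------------------------------------------------------------------------
# tree / clone-map JSON

def _tree_to_dict(tree: CloneTree) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "samples": list(tree.clusters[0].samples),
        "clones": [{
            "label": c.label,
            "members": list(c.member_loci),
            "median_ccf": [float(x) for x in c.median_ccf],
        } for c in tree.clusters],
        "parent": {l: p for l, p in tree.parent.items()},
        "violations": {
            "total": tree.violations.total,
            "sum_rule": tree.violations.sum_rule,
            "crossing": tree.violations.crossing,
            "sum_details": [list(d) for d in tree.violations.sum_details],
            "crossing_details": [list(d)
                                 for d in tree.violations.crossing_details],
        },
    }


def write_tree_json(tree: CloneTree, path) -> None:
    if not tree.clusters:
        raise ValueError("no clones")
    Path(path).write_text(json.dumps(_tree_to_dict(tree), indent=1))


def read_tree_json(path) -> CloneTree:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version "
                         f"{d.get('schema_version')}")
    return _tree_from_dict(d)


def write_tree_newick(tree: CloneTree, path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def write_tree_edges(tree: CloneTree, path) -> None:
    lines = ["parent\tchild"] + [f"{p}\t{c}" for p, c in to_edge_list(tree)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_clonemap_json(cmap: CloneMap, path) -> None:
    d = {
        "schema_version": SCHEMA_VERSION,
        "note": ("corrected CCFs are a least-squares tree-consistency "
                 "projection of raw cluster medians"),
        "samples": list(cmap.samples),
        "tree": _tree_to_dict(cmap.tree),
        "corrected": cmap.corrected,
        "raw": cmap.raw,
        "polyclonal": cmap.polyclonal,
        "transitions": [{
            "source": t.source, "target": t.target,
            "supporting_clones": t.supporting_clones,
            "ambiguous": t.ambiguous} for t in cmap.transitions],
        "seeding": [{
            "met_sample": s.met_sample, "clones": s.clones,
            "multiple": s.multiple,
            "candidate_sources": s.candidate_sources}
            for s in cmap.seeding],
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_clonemap_json(path) -> CloneMap:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version "
                         f"{d.get('schema_version')}")
    tree = _tree_from_dict(d["tree"])
    cmap = CloneMap(list(d["samples"]), tree, d["corrected"], d["raw"])
    cmap.polyclonal = {k: bool(v) for k, v in d["polyclonal"].items()}
    cmap.transitions = [Transition(t["source"], t["target"],
                                   t["supporting_clones"], t["ambiguous"])
                        for t in d["transitions"]]
    cmap.seeding = [SeedingCall(s["met_sample"], s["clones"], s["multiple"],
                                s["candidate_sources"])
                    for s in d["seeding"]]
    return cmap


def _tree_from_dict(d: dict) -> CloneTree:
    samples = tuple(d["samples"])
    clusters = [CloneCluster(c["label"], samples, tuple(c["members"]),
                             np.array(c["median_ccf"]))
                for c in d["clones"]]
    v = d["violations"]
    summary = ViolationSummary(
        v["total"], v["sum_rule"], v["crossing"],
        [tuple(x) for x in v["sum_details"]],
        [tuple(x) for x in v["crossing_details"]])
    return CloneTree(clusters, dict(d["parent"]), summary)
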