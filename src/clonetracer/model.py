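"""Model/Results façade over the reconstruction pipeline.

`CloneReconstruction` is built from the cohort's data (SNV records,
per-sample copy-number profiles, purity estimates); `fit()` runs the
pipeline — somatic-score filtering, CCF computation, optional purity
refinement against the truncal cluster, clone clustering, tree search and
clone-map inference — and returns a `CloneReconstructionResults` carrying
the estimates and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import ccf as ccf_mod
from . import clonemap as clonemap_mod
from . import cluster as cluster_mod
from . import tree as tree_mod
from .config import AnalysisConfig
from .types import PuritySample, SegmentProfile, SnvRecord


class CloneReconstruction:
    """Subclonal reconstruction model for one multi-region cohort.

    Parameters
    ----------
    records : list of SnvRecord
        Somatic SNVs with per-sample read counts.
    samples : sequence of str
        Ordered sample ids matching the records' count tuples.
    profiles : dict sample -> SegmentProfile
        Allele-specific copy-number segmentation per sample.
    purities : list of PuritySample
        Purity/ploidy/site per sample.
    config : AnalysisConfig, optional
    """

    def __init__(self, records: Sequence[SnvRecord], samples: Sequence[str],
                 profiles: Dict[str, SegmentProfile],
                 purities: Sequence[PuritySample],
                 config: Optional[AnalysisConfig] = None):
        self.records = list(records)
        self.samples = list(samples)
        self.profiles = dict(profiles)
        self.purities = {p.sample_id: p for p in purities}
        self.config = config or AnalysisConfig()
        for s in self.samples:
            if s not in self.profiles:
                raise ValueError(f"no segment profile for sample {s!r}")
            if s not in self.purities:
                raise ValueError(f"no purity estimate for sample {s!r}")

    @classmethod
    def from_files(cls, vcf_path, segment_paths: Dict[str, str],
                   purity_path, config: Optional[AnalysisConfig] = None
                   ) -> "CloneReconstruction":
        """Build the model straight from VCF / segment-TSV / purity-TSV."""
        from . import io
        config = config or AnalysisConfig()
        res = io.read_snv_vcf(vcf_path,
                              score_key=config.somatic_score_key,
                              score_reduction=config.score_reduction)
        profiles = {s: io.read_segments(p, sample_id=s)
                    for s, p in segment_paths.items()}
        purities = io.read_purity(purity_path)
        return cls(res.records, res.samples, profiles, purities, config)

    def fit(self, refine_purity: bool = True,
            tree_method: str = "auto") -> "CloneReconstructionResults":
        """Run the full reconstruction and return the results object."""
        cfg = self.config
        kept = ccf_mod.filter_tlod(self.records, cfg)
        rho = {s: self.purities[s].purity for s in self.samples}
        matrix = ccf_mod.compute_ccf_matrix(kept, self.samples,
                                            self.profiles, rho, cfg)
        clustering = cluster_mod.cluster_ccfs(matrix, cfg)
        truncal = cluster_mod.identify_truncal(clustering.clusters, cfg)
        refined = dict(rho)
        if refine_purity:
            truncal_ids = set(
                clustering.by_label(truncal).member_loci)
            truncal_recs = [r for r in kept if r.locus_id in truncal_ids]
            for j, s in enumerate(self.samples):
                refined[s] = ccf_mod.refine_purity(
                    truncal_recs, j, self.profiles[s], rho[s], cfg)
            if any(abs(refined[s] - rho[s]) > 1e-6 for s in self.samples):
                matrix = ccf_mod.compute_ccf_matrix(
                    kept, self.samples, self.profiles, refined, cfg)
                clustering = cluster_mod.cluster_ccfs(matrix, cfg)
                truncal = cluster_mod.identify_truncal(clustering.clusters,
                                                       cfg)
        ctree = tree_mod.build_tree(clustering.clusters, truncal, cfg,
                                    method=tree_method)
        sites = {s: self.purities[s].site for s in self.samples}
        cmap = clonemap_mod.build_clone_map(clustering.clusters, ctree,
                                            sites, cfg)
        qc = ccf_mod.segment_qc(
            matrix, kept, self.profiles,
            clustering.by_label(truncal).member_loci, cfg)
        return CloneReconstructionResults(
            model=self, records_used=kept, ccf_matrix=matrix,
            clustering=clustering, truncal_label=truncal, tree=ctree,
            clone_map=cmap, refined_purity=refined, qc_flags=qc)


@dataclass
class CloneReconstructionResults:
    """Fitted subclonal reconstruction: clones, tree, map, diagnostics."""

    model: CloneReconstruction
    records_used: list
    ccf_matrix: ccf_mod.CcfMatrix
    clustering: cluster_mod.Clustering
    truncal_label: str
    tree: tree_mod.CloneTree
    clone_map: clonemap_mod.CloneMap
    refined_purity: Dict[str, float]
    qc_flags: list = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.clustering.clusters)

    def summary(self) -> str:
        """Human-readable reconstruction summary."""
        m = self.model
        lines = []
        lines.append("Clone reconstruction summary")
        lines.append("=" * 60)
        lines.append(f"samples: {len(m.samples)}   "
                     f"SNVs used: {len(self.records_used)} "
                     f"(of {len(m.records)})   clones: {self.n_clones}")
        lines.append(f"truncal clone: {self.truncal_label}   "
                     f"tree violations: {self.tree.violations.total:g} "
                     f"(sum {self.tree.violations.sum_rule}, "
                     f"crossing {self.tree.violations.crossing})")
        lines.append("")
        head = "clone  size  parent " + "".join(
            f"{s:>10}" for s in m.samples)
        lines.append(head)
        lines.append("-" * len(head))
        for c in self.clustering.clusters:
            parent = self.tree.parent[c.label] or "-"
            row = f"{c.label:>5}  {c.size:>4}  {parent:>6} " + "".join(
                f"{v:>10.3f}" for v in c.median_ccf)
            lines.append(row)
        lines.append("")
        lines.append("purity (input -> refined):")
        for s in m.samples:
            lines.append(f"  {s}: {m.purities[s].purity:.3f} -> "
                         f"{self.refined_purity[s]:.3f}")
        if self.clone_map.transitions:
            lines.append("inferred spread:")
            for t in self.clone_map.transitions:
                lines.append(f"  {t.source} -> {t.target} "
                             f"(clones {', '.join(t.supporting_clones)})")
        poly = [s for s, p in self.clone_map.polyclonal.items() if p]
        if poly:
            lines.append(f"polyclonal samples: {', '.join(poly)}")
        for sd in self.clone_map.seeding:
            kind = "multiple seeding" if sd.multiple else "single seeding"
            lines.append(f"seeding into {sd.met_sample}: "
                         f"{', '.join(sd.clones)} ({kind})")
        if self.qc_flags:
            lines.append(f"segment QC flags: {len(self.qc_flags)}")
        return "\n".join(lines)
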