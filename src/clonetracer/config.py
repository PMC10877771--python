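"""Analysis configuration: every threshold the pipeline uses, in one place."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across the reconstruction pipeline.

    Parameters
    ----------
    tlod_min : float
        Minimum somatic-evidence score (Mutect2 TLOD dialect) for a variant
        to enter subclonal analysis. Inclusive: a score exactly equal to the
        threshold passes.
    normal_cn : int
        Copy number of the contaminating normal cells (2 for autosomes).
    ccf_clamp_flag : float
        CCF values above this are flagged as suspicious (likely copy-number
        mis-specification) but retained unclamped for clustering.
    rule_epsilon : float
        Absolute tolerance on cluster medians when scoring the sum rule and
        the crossing rule; absorbs read-sampling noise.
    clonality_delta : float
        "Clonal" means CCF >= 1 - clonality_delta; "present" means
        CCF > clonality_delta. Drives truncal identification, transition,
        polyclonality and seeding calls.
    min_cluster_size : int
        Clusters smaller than this are merged into their nearest neighbour.
    max_mixture_components : int
        Component cap for the variational Bayesian Gaussian mixture.
    mixture_covariance_prior : float
        Prior component variance for the mixture, set to the read-noise
        scale of CCFs (~0.14 SD at ninety-fold depth, so 0.02 variance);
        sklearn's default (the full-data variance) biases components broad
        and under-splits.
    merge_distance : float
        Clusters whose medians lie within this distance (max over samples)
        are indistinguishable at the noise scale and are merged.
    split_min_gap : float
        A curation split is accepted only when the two parts' medians
        differ by at least this much in some sample.
    signature_cutoff : float
        Exposure weights below this are zeroed and the fit repeated.
    qc_epsilon : float
        Deviation of a segment's truncal-CCF median from the genome-wide
        truncal median beyond which the segment is flagged by QC.
    exhaustive_limit : int
        Largest clone count for which tree search enumerates every rooted
        labelled tree; above it a greedy/local-search heuristic is used.
    somatic_score_key : str
        INFO key holding the somatic-evidence score in input VCFs.
    score_reduction : str
        How a multi-valued somatic score (one per sample from joint calling)
        is reduced to the per-variant scalar: "max" (default; calling was
        joint across samples) or "min".
    seed : int
        Random seed for every stochastic step (mixture initialisation).
    """

    tlod_min: float = 7.0
    normal_cn: int = 2
    ccf_clamp_flag: float = 1.2
    rule_epsilon: float = 0.05
    clonality_delta: float = 0.10
    min_cluster_size: int = 20
    max_mixture_components: int = 15
    mixture_covariance_prior: float = 0.02
    merge_distance: float = 0.10
    split_min_gap: float = 0.18
    signature_cutoff: float = 0.06
    qc_epsilon: float = 0.15
    qc_min_support: int = 10
    exhaustive_limit: int = 8
    somatic_score_key: str = "TLOD"
    score_reduction: str = "max"
    seed: int = 0
    crossing_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tlod_min < 0:
            raise ValueError("tlod_min must be >= 0")
        for name in ("rule_epsilon", "clonality_delta", "signature_cutoff",
                     "qc_epsilon"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ccf_clamp_flag <= 0:
            raise ValueError("ccf_clamp_flag must be positive")
        if self.normal_cn < 0:
            raise ValueError("normal_cn must be >= 0")
        if self.score_reduction not in ("max", "min"):
            raise ValueError("score_reduction must be 'max' or 'min'")
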