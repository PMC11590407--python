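"""Centroid-distance dysbiosis score with baseline-percentile thresholds.

The score quantifies how far a sample's community has moved away from a
reference (untreated) group relative to its own treatment group, directly
in dissimilarity space. For a sample x and groups R (reference) and T (the
sample's own treatment, or the pooled non-reference samples when x itself
is a reference sample):

    s(x) = d(x, centroid(R)) - d(x, centroid(T))

A score of zero means the sample lies at equal distance from both group
centroids; positive scores indicate displacement away from the reference
state (towards dysbiosis), negative scores a reference-like (normobiotic)
community.

Centroid distances are computed without coordinates via the Gower identity

    d^2(x, G) = (1/n) sum_{i in G} D^2(x, i) - (1/n^2) sum_{i<j in G} D^2(i, j)

which for a Euclidean-embeddable D equals the distance to the explicit
coordinate centroid. For non-Euclidean metrics (Bray-Curtis in particular)
the right-hand side can be negative; such values are clamped to zero and
flagged. A sample belonging to G is included in its own centroid by
default; a leave-one-out mode is available.

Classification thresholds are the 10th and 90th percentiles of the scores
of *all* samples at the baseline timepoint, when no treatment or time
effect is present: scores above the upper threshold are "dysbiotic", below
the lower threshold "normobiotic", and in between (boundaries included)
"intermediate".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import DissimilarityMatrix, beta_diversity, pcoa
from .tables import CountTable, to_relative

__all__ = [
    "CentroidDistance",
    "DysbiosisConfig",
    "DysbiosisReport",
    "ThresholdPair",
    "dist_to_centroid",
    "dysbiosis_scores",
    "baseline_thresholds",
    "classify_samples",
    "dysbiosis_pipeline",
]

LABELS = ("normobiotic", "intermediate", "dysbiotic")


@dataclass(frozen=True)
class CentroidDistance:
    sample_id: str
    group: str
    n_members: int
    squared_distance: float   # before clamping; may be negative
    distance: float           # sqrt(max(0, squared_distance))
    clamped: bool


def dist_to_centroid(dm: DissimilarityMatrix, sample: str, group, label: str = "") -> CentroidDistance:
    """Distance from a sample to the implicit centroid of a group.

    ``group`` is a collection of sample ids (it may include ``sample``
    itself, in which case the sample contributes to its own centroid).
    """
    members = list(group)
    if not members:
        raise ValueError("group is empty")
    xi = dm.index(sample)
    idx = np.array([dm.index(m) for m in members])
    d2 = dm.data**2
    n = len(idx)
    mean_to_group = d2[xi, idx].mean()
    within = d2[np.ix_(idx, idx)].sum() / 2.0  # sum over i<j
    sq = float(mean_to_group - within / n**2)
    clamped = sq < 0
    return CentroidDistance(
        sample_id=sample,
        group=label,
        n_members=n,
        squared_distance=sq,
        distance=float(np.sqrt(max(0.0, sq))),
        clamped=clamped,
    )


def dysbiosis_scores(
    dm: DissimilarityMatrix,
    metadata: pd.DataFrame,
    ref_group: str = "CON",
    per_timepoint: bool = True,
    include_self: bool = True,
) -> pd.DataFrame:
    """Per-sample dysbiosis scores against a reference treatment group.

    For each non-reference sample the comparison centroid is that of its own
    treatment group; for reference samples it is the pooled non-reference
    samples. With ``per_timepoint`` (the default) both centroids are
    restricted to samples of the same timepoint. ``include_self=False``
    switches to leave-one-out centroids.

    Returns a DataFrame indexed by sample id with treatment, timepoint_h,
    the two centroid distances, the score and clamping flags.
    """
    md = metadata.loc[list(dm.ids)]
    if ref_group not in set(md["treatment"]):
        raise ValueError(f"reference group {ref_group!r} absent from metadata")
    timepoints = sorted(md["timepoint_h"].unique())
    if per_timepoint:
        for tp in timepoints:
            at_tp = md[md["timepoint_h"] == tp]
            if not (at_tp["treatment"] == ref_group).any():
                raise ValueError(f"reference group {ref_group!r} empty at timepoint {tp}")
    rows = []
    for sample in dm.ids:
        trt = md.at[sample, "treatment"]
        tp = md.at[sample, "timepoint_h"]
        pool = md[md["timepoint_h"] == tp] if per_timepoint else md
        ref_members = list(pool.index[pool["treatment"] == ref_group])
        if trt == ref_group:
            comp_members = list(pool.index[pool["treatment"] != ref_group])
            comp_label = "non-reference"
        else:
            comp_members = list(pool.index[pool["treatment"] == trt])
            comp_label = str(trt)
        if not include_self:
            ref_members = [m for m in ref_members if m != sample]
            comp_members = [m for m in comp_members if m != sample]
        if not ref_members:
            raise ValueError(f"empty reference centroid for sample {sample!r}")
        if not comp_members:
            raise ValueError(f"empty comparison centroid for sample {sample!r}")
        d_ref = dist_to_centroid(dm, sample, ref_members, label=ref_group)
        d_comp = dist_to_centroid(dm, sample, comp_members, label=comp_label)
        rows.append(
            {
                "sample_id": sample,
                "treatment": trt,
                "timepoint_h": tp,
                "dist_ref": d_ref.distance,
                "dist_comp": d_comp.distance,
                "score": d_ref.distance - d_comp.distance,
                "clamped": d_ref.clamped or d_comp.clamped,
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if "individual" in md.columns:
        out.insert(0, "individual", md.loc[out.index, "individual"])
    return out


@dataclass(frozen=True)
class ThresholdPair:
    """Normobiosis (lower) and dysbiosis (upper) score thresholds."""

    lower: float
    upper: float
    lower_pct: float = 10.0
    upper_pct: float = 90.0
    baseline_timepoint: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper threshold")


def baseline_thresholds(
    baseline_scores,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    baseline_timepoint: float | None = None,
) -> ThresholdPair:
    """Percentile thresholds from pooled baseline scores.

    Percentiles use linear interpolation between closest ranks. All
    baseline samples (reference and treated alike) contribute.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 baseline scores")
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError(
            f"require 0 <= lower_pct < upper_pct <= 100, got ({lower_pct}, {upper_pct})"
        )
    lo, hi = np.percentile(scores, [lower_pct, upper_pct], method="linear")
    return ThresholdPair(float(lo), float(hi), lower_pct, upper_pct, baseline_timepoint)


def classify_samples(scores, thresholds: ThresholdPair) -> np.ndarray:
    """Three-way labels; values exactly on a threshold are intermediate."""
    s = np.asarray(scores, dtype=float)
    labels = np.full(s.shape, "intermediate", dtype=object)
    labels[s > thresholds.upper] = "dysbiotic"
    labels[s < thresholds.lower] = "normobiotic"
    return labels


@dataclass
class DysbiosisConfig:
    """Knobs of the dysbiosis pipeline.

    ``space`` selects how centroid distances are computed: "gower" applies
    the centroid identity directly to the dissimilarity matrix (default);
    "pcoa" first embeds samples by principal coordinates and measures
    Euclidean distances to explicit centroids there.
    """

    metric: str = "braycurtis"
    ref_group: str = "CON"
    baseline_timepoint: float = 0.0
    lower_pct: float = 10.0
    upper_pct: float = 90.0
    per_timepoint: bool = True
    include_self: bool = True
    space: str = "gower"

    def __post_init__(self) -> None:
        if self.space not in ("gower", "pcoa"):
            raise ValueError(f"unknown space {self.space!r}")


@dataclass
class DysbiosisReport:
    samples: pd.DataFrame      # per-sample scores + labels
    thresholds: ThresholdPair
    summary: pd.DataFrame      # per (treatment, timepoint) mean/sd/counts
    n_clamped: int
    config: DysbiosisConfig = field(default_factory=DysbiosisConfig)

    def dysbiotic_counts(self) -> pd.DataFrame:
        return self.summary[["n", "n_dysbiotic"]]


def _embed_to_euclidean(dm: DissimilarityMatrix) -> DissimilarityMatrix:
    """Euclidean distances between samples in PCoA (positive-axis) space."""
    coords = pcoa(dm).coordinates.to_numpy()
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix((D + D.T) / 2, dm.ids, metric=f"{dm.metric}-pcoa")


def dysbiosis_pipeline(
    counts: CountTable,
    metadata: pd.DataFrame,
    config: DysbiosisConfig | None = None,
) -> DysbiosisReport:
    """Relative abundance -> dissimilarity -> scores -> thresholds -> labels.

    Dissimilarities are computed once over all samples jointly; centroids
    are restricted per timepoint. Thresholds come from the scores of all
    samples at the baseline timepoint.
    """
    config = config or DysbiosisConfig()
    missing = [s for s in counts.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing}")
    rel = to_relative(counts) if counts.unit == "counts" else counts
    dm = beta_diversity(rel, config.metric)
    if config.space == "pcoa":
        dm = _embed_to_euclidean(dm)
    scores = dysbiosis_scores(
        dm,
        metadata,
        ref_group=config.ref_group,
        per_timepoint=config.per_timepoint,
        include_self=config.include_self,
    )
    at_baseline = scores[scores["timepoint_h"] == config.baseline_timepoint]
    if at_baseline.empty:
        raise ValueError(f"no samples at baseline timepoint {config.baseline_timepoint}")
    thresholds = baseline_thresholds(
        at_baseline["score"],
        config.lower_pct,
        config.upper_pct,
        baseline_timepoint=config.baseline_timepoint,
    )
    scores = scores.copy()
    scores["label"] = classify_samples(scores["score"], thresholds)
    summary = (
        scores.groupby(["treatment", "timepoint_h"])["score"]
        .agg(mean="mean", sd="std", n="size")
        .join(
            scores.assign(dys=scores["label"] == "dysbiotic")
            .groupby(["treatment", "timepoint_h"])["dys"]
            .sum()
            .rename("n_dysbiotic")
        )
    )
    return DysbiosisReport(
        samples=scores,
        thresholds=thresholds,
        summary=summary,
        n_clamped=int(scores["clamped"].sum()),
        config=config,
    )
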