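"""Two-round scaffold binning and quality screening.

Preliminary bins come from density clustering (DBSCAN) of standardized
(GC, log10 coverage, top tetranucleotide principal components) features,
constrained so that clustering never crosses phylum/class-level taxonomy
labels. Second-round screening re-applies the same criteria per scaffold
and additionally requires each scaffold to carry strictly more than 90%
paired (versus singleton) reads.

Bin completeness/contamination use a simplified single-copy marker tally
(fraction of expected families present / present in extra copies); this
deliberately ignores marker collocation and lineage-specific sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .profiler import tnf_matrix

__all__ = [
    "Bin",
    "BinningParams",
    "ScreenThresholds",
    "ScreenReport",
    "preliminary_bins",
    "screen_scaffolds",
    "refine",
    "marker_qc",
    "bin_summary",
]


@dataclass
class BinningParams:
    eps: float = 0.8  # DBSCAN radius in globally standardized feature units
    min_samples: int = 3
    n_pcs: int = 3  # tetranucleotide principal components kept
    assign_radius: float = 0.8  # unlabeled-scaffold attachment radius
    min_coverage: float = 1e-3  # floor before log10


@dataclass
class ScreenThresholds:
    paired_min: float = 0.90  # strict: fraction must exceed this to pass
    gc_tol: float = 5.0  # percentage points from bin median
    cov_tol: float = 0.5  # log10-fold from bin median
    tnf_percentile: float = 99.0
    tnf_median_factor: float = 3.0  # robust floor: reject only beyond 3x median distance


@dataclass
class Bin:
    bin_id: str
    scaffold_ids: list[str]
    total_length: int = 0
    gc_mean: float = 0.0
    gc_sd: float = 0.0
    coverage_median: float = 0.0
    taxonomy_label: str = ""
    status: str = "preliminary"


@dataclass
class ScreenReport:
    bin_id: str
    accepted: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)


def _bin_stats(bin_: Bin, profiles: pd.DataFrame) -> Bin:
    rows = profiles.set_index("scaffold_id").loc[bin_.scaffold_ids]
    bin_.total_length = int(rows["length"].sum())
    bin_.gc_mean = float(rows["gc_percent"].mean())
    bin_.gc_sd = float(rows["gc_percent"].std(ddof=0))
    bin_.coverage_median = float(rows["coverage"].median())
    labels = [l for l in rows["taxonomy_label"] if isinstance(l, str) and l]
    if labels:
        values, counts = np.unique(labels, return_counts=True)
        bin_.taxonomy_label = str(values[np.argmax(counts)])
    return bin_


def _feature_matrix(profiles: pd.DataFrame, params: BinningParams) -> np.ndarray:
    """Globally standardized (gc, log10 cov, TNF PCs) feature matrix.

    Global (not per-label-group) standardization keeps the DBSCAN radius
    meaningful even for label groups holding a single tight genome.
    """
    gc = profiles["gc_percent"].to_numpy(float)
    cov = np.log10(np.maximum(profiles["coverage"].to_numpy(float), params.min_coverage))
    tnf = tnf_matrix(profiles)
    n_pcs = min(params.n_pcs, tnf.shape[0], tnf.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(tnf)
    features = np.column_stack([gc, cov, pcs])
    center = features.mean(axis=0)
    scale = features.std(axis=0)
    # floor each scale at the typical within-genome noise level so a
    # community of one tight cluster is not inflated to unit variance
    floors = np.array([2.0, 0.2] + [0.02] * pcs.shape[1])
    scale = np.maximum(scale, floors)
    return (features - center) / scale


def preliminary_bins(
    profiles: pd.DataFrame,
    params: BinningParams | None = None,
) -> list[Bin]:
    """Taxonomy-constrained density clustering of scaffold profiles.

    Scaffolds are grouped by taxonomy label first; within each label group
    DBSCAN clusters the standardized features. Unlabeled scaffolds (and
    density-noise points) are attached to the nearest bin centroid within
    ``assign_radius``, else left unbinned. Each bin carries the majority
    label of its members.
    """
    if profiles.empty:
        raise ValueError("empty profile table")
    params = params or BinningParams()
    features = _feature_matrix(profiles, params)
    sids = profiles["scaffold_id"].to_numpy()
    labels = profiles["taxonomy_label"].fillna("").to_numpy()
    if not any(isinstance(l, str) and l for l in labels):
        warnings.warn("all scaffolds unlabeled: falling back to pure density clustering")

    members: list[list[int]] = []
    leftovers: list[int] = []
    for label in sorted({l for l in labels if l}) + [""]:
        group = np.flatnonzero(labels == label)
        if group.size == 0:
            continue
        if label == "":
            leftovers.extend(int(i) for i in group)
            continue
        clustering = DBSCAN(eps=params.eps, min_samples=min(params.min_samples, group.size)).fit(
            features[group]
        )
        for cluster_id in sorted(set(clustering.labels_)):
            idx = group[clustering.labels_ == cluster_id]
            if cluster_id == -1:
                leftovers.extend(int(i) for i in idx)
            else:
                members.append([int(i) for i in idx])
    if not members and leftovers:
        clustering = DBSCAN(eps=params.eps, min_samples=min(params.min_samples, len(leftovers))).fit(
            features[leftovers]
        )
        new_leftovers: list[int] = []
        for cluster_id in sorted(set(clustering.labels_)):
            idx = [leftovers[j] for j in np.flatnonzero(clustering.labels_ == cluster_id)]
            if cluster_id == -1:
                new_leftovers.extend(idx)
            else:
                members.append(idx)
        leftovers = new_leftovers

    centroids = np.array([features[m].mean(axis=0) for m in members]) if members else np.empty((0, features.shape[1]))
    for i in leftovers:
        if centroids.size == 0:
            continue
        distances = np.linalg.norm(centroids - features[i], axis=1)
        j = int(np.argmin(distances))
        if distances[j] <= params.assign_radius:
            members[j].append(i)

    members.sort(key=lambda m: min(sids[i] for i in m))
    bins = []
    for n, member_idx in enumerate(members):
        bin_ = Bin(bin_id=f"b{n + 1:03d}", scaffold_ids=sorted(sids[i] for i in member_idx))
        bins.append(_bin_stats(bin_, profiles))
    return bins


def screen_scaffolds(
    bin_: Bin,
    profiles: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> ScreenReport:
    """Per-scaffold quality screen; accepted/rejected partition the bin.

    Rejection reasons, checked in order: paired_fraction (must strictly
    exceed the 0.90 threshold; undefined fails), gc_outlier,
    coverage_outlier, composition_outlier (TNF distance from the bin
    centroid beyond both the 99th-percentile and a robust 3x-median guard),
    taxonomy_conflict (label disagrees with the bin majority).
    """
    thresholds = thresholds or ScreenThresholds()
    indexed = profiles.set_index("scaffold_id")
    missing = [s for s in bin_.scaffold_ids if s not in indexed.index]
    if missing:
        raise ValueError(f"profiles missing scaffolds: {missing}")
    rows = indexed.loc[bin_.scaffold_ids]
    gc_median = float(rows["gc_percent"].median())
    cov = np.log10(np.maximum(rows["coverage"].to_numpy(float), 1e-3))
    cov_median = float(np.median(cov))
    tnf = tnf_matrix(rows.reset_index())
    # componentwise median: robust to the very contaminants being screened
    centroid = np.median(tnf, axis=0)
    distances = np.linalg.norm(tnf - centroid, axis=1)
    tnf_cut = max(
        float(np.percentile(distances, thresholds.tnf_percentile)),
        thresholds.tnf_median_factor * float(np.median(distances)),
    )
    majority = bin_.taxonomy_label

    report = ScreenReport(bin_id=bin_.bin_id)
    for i, sid in enumerate(bin_.scaffold_ids):
        row = rows.iloc[i]
        pf = row["paired_fraction"]
        if pd.isna(pf) or pf <= thresholds.paired_min:
            report.rejected.append((sid, "paired_fraction"))
        elif abs(row["gc_percent"] - gc_median) > thresholds.gc_tol:
            report.rejected.append((sid, "gc_outlier"))
        elif abs(cov[i] - cov_median) > thresholds.cov_tol:
            report.rejected.append((sid, "coverage_outlier"))
        elif distances[i] > tnf_cut:
            report.rejected.append((sid, "composition_outlier"))
        elif majority and isinstance(row["taxonomy_label"], str) and row["taxonomy_label"] and row["taxonomy_label"] != majority:
            report.rejected.append((sid, "taxonomy_conflict"))
        else:
            report.accepted.append(sid)
    return report


def refine(
    bins: list[Bin],
    profiles: pd.DataFrame,
    alignments: pd.DataFrame | None = None,
    max_rounds: int = 2,
    thresholds: ScreenThresholds | None = None,
) -> tuple[list[Bin], list[ScreenReport]]:
    """Iterate screening until no scaffold is rejected or max_rounds.

    Without an external re-assembler the recruit/re-assemble step is a
    pass-through, so refinement is monotone: the accepted set of each bin
    never grows. Bins emptied by screening are dropped with a warning.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    reports: list[ScreenReport] = []
    current = [Bin(bin_id=b.bin_id, scaffold_ids=list(b.scaffold_ids)) for b in bins]
    for b, original in zip(current, bins):
        b.taxonomy_label = original.taxonomy_label
    for _ in range(max_rounds):
        any_rejection = False
        survivors: list[Bin] = []
        round_reports: list[ScreenReport] = []
        for bin_ in current:
            report = screen_scaffolds(_bin_stats(bin_, profiles), profiles, thresholds)
            round_reports.append(report)
            if report.rejected:
                any_rejection = True
            if not report.accepted:
                warnings.warn(f"bin {bin_.bin_id} emptied by screening; dropped")
                continue
            bin_.scaffold_ids = sorted(report.accepted)
            survivors.append(bin_)
        current = survivors
        reports = round_reports
        if not any_rejection:
            break
    for bin_ in current:
        _bin_stats(bin_, profiles)
        bin_.status = "screened"
    return current, reports


def marker_qc(
    bin_: Bin,
    annotations: pd.DataFrame,
    marker_set: list[str],
) -> tuple[float, float]:
    """Simplified single-copy-marker completeness and contamination.

    completeness = 100 x (#families present at least once) / |marker_set|;
    contamination = 100 x sum_f max(0, copies_f - 1) / |marker_set|.
    """
    if not marker_set:
        raise ValueError("marker_set is empty")
    known = set(marker_set)
    unknown = set(annotations["marker_family"]) - known
    if unknown:
        raise ValueError(f"annotations name unknown families: {sorted(unknown)}")
    in_bin = annotations[annotations["scaffold_id"].isin(set(bin_.scaffold_ids))]
    copies = in_bin["marker_family"].value_counts()
    present = int((copies >= 1).sum())
    extra = int((copies - 1).clip(lower=0).sum())
    return 100.0 * present / len(marker_set), 100.0 * extra / len(marker_set)


def bin_summary(
    bins: list[Bin],
    profiles: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    marker_set: list[str] | None = None,
) -> pd.DataFrame:
    """Per-bin report: id, total length, %GC, scaffold count, completeness,
    contamination (simplified marker tally), majority taxonomy."""
    rows = []
    for bin_ in bins:
        _bin_stats(bin_, profiles)
        completeness = contamination = float("nan")
        if annotations is not None and marker_set:
            completeness, contamination = marker_qc(bin_, annotations, marker_set)
        rows.append(
            {
                "bin_id": bin_.bin_id,
                "total_length": bin_.total_length,
                "pct_gc": round(bin_.gc_mean, 1),
                "n_scaffolds": len(bin_.scaffold_ids),
                "completeness": round(completeness, 1) if completeness == completeness else completeness,
                "contamination": round(contamination, 1) if contamination == contamination else contamination,
                "taxonomy": bin_.taxonomy_label,
                "status": bin_.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bin_id", "total_length", "pct_gc", "n_scaffolds", "completeness", "contamination", "taxonomy", "status"],
    )
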