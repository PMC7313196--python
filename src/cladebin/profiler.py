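"""Per-scaffold features for binning and screening.

Four signals drive scaffold binning in a low-diversity holobiont
metagenome: percent GC, tetranucleotide composition, fold-coverage from
read mapping, and the fraction of mapped reads whose mate also mapped.
An optional per-scaffold taxonomy label (phylum/class rank path from
protein-similarity classification) constrains clustering downstream.

Coordinates are 0-based half-open; coverage uses aligned bases rather
than read counts, making it read-length independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScaffoldProfile",
    "AlignmentRecord",
    "gc_percent",
    "tetranucleotide_profile",
    "canonical_kmer_classes",
    "coverage_depth",
    "paired_fraction",
    "profile_table",
    "tnf_matrix",
    "plot_feature_space",
    "UndefinedValueError",
    "MIN_SCAFFOLD_LEN",
]

MIN_SCAFFOLD_LEN = 10_000

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class UndefinedValueError(ValueError):
    """A feature is undefined for this input (e.g. no unambiguous bases)."""


@dataclass
class AlignmentRecord:
    """One read placed on a scaffold (or unmapped)."""

    read_id: str
    mate: int
    scaffold_id: str | None
    position: int
    aligned_length: int
    identity: float
    pair_status: str  # "paired" | "singleton"
    ambiguous: bool = False


@dataclass
class ScaffoldProfile:
    scaffold_id: str
    length: int
    gc_percent: float
    tnf: np.ndarray
    coverage: float
    paired_fraction: float  # NaN when no reads map
    taxonomy_label: str | None = None


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def gc_percent(seq: str) -> float:
    """100 x (G+C) / (A+C+G+T), ambiguity characters excluded entirely."""
    codes = _encode(seq)
    valid = codes >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedValueError("no unambiguous bases")
    n_gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return 100.0 * n_gc / n_valid


def canonical_kmer_classes(k: int = 4) -> tuple[np.ndarray, list[str]]:
    """Map each of the 4^k k-mer codes to a reverse-complement-canonical
    class index; returns (code -> class array, class name list).

    For k=4 there are 136 classes: 16 self-complementary + 120 pooled pairs.
    """
    n = 4**k
    codes = np.arange(n)
    digits = np.stack([(codes // 4**(k - 1 - i)) % 4 for i in range(k)])  # base at each position
    rc_digits = 3 - digits[::-1]
    rc_codes = sum(rc_digits[i] * 4**(k - 1 - i) for i in range(k))
    canon = np.minimum(codes, rc_codes)
    class_codes = np.unique(canon)
    class_index = np.full(n, -1, dtype=np.int64)
    class_index[class_codes] = np.arange(len(class_codes))
    lookup = class_index[canon]
    bases = "ACGT"
    names = ["".join(bases[(c // 4**(k - 1 - i)) % 4] for i in range(k)) for c in class_codes]
    return lookup, names


_CANON4, CANONICAL_TETRAMERS = canonical_kmer_classes(4)


def tetranucleotide_profile(seq: str, k: int = 4) -> np.ndarray:
    """Canonical k-mer frequency vector (k=4: 136 components, sums to 1).

    Overlapping k-mers containing an ambiguity character are skipped; each
    k-mer is pooled with its reverse complement.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    lookup = _CANON4 if k == 4 else canonical_kmer_classes(k)[0]
    codes = _encode(seq).astype(np.int64)
    n_windows = len(codes) - k + 1
    window_codes = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for i in range(k):
        col = codes[i : i + n_windows]
        valid &= col >= 0
        window_codes = window_codes * 4 + np.where(col >= 0, col, 0)
    kept = window_codes[valid]
    if kept.size == 0:
        raise UndefinedValueError("no unambiguous k-mers")
    counts = np.bincount(lookup[kept], minlength=int(lookup.max()) + 1).astype(float)
    return counts / counts.sum()


def _as_frame(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    return pd.DataFrame([vars(a) for a in alignments])


def coverage_depth(alignments, scaffold_id: str, scaffold_length: int) -> float:
    """Fold coverage: sum of aligned bases on the scaffold / its length."""
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    frame = _as_frame(alignments)
    if frame.empty:
        return 0.0
    mapped = frame[frame["scaffold_id"] == scaffold_id]
    return float(mapped["aligned_length"].sum()) / scaffold_length


def paired_fraction(alignments, scaffold_id: str) -> float:
    """Fraction of records mapped to the scaffold whose pair_status is paired."""
    frame = _as_frame(alignments)
    mapped = frame[frame["scaffold_id"] == scaffold_id] if not frame.empty else frame
    if mapped.empty:
        raise UndefinedValueError(f"no reads mapped to {scaffold_id}")
    return float((mapped["pair_status"] == "paired").mean())


def profile_table(
    scaffolds: dict[str, str],
    alignments=None,
    labels: pd.DataFrame | None = None,
    min_len: int = MIN_SCAFFOLD_LEN,
) -> pd.DataFrame:
    """One ScaffoldProfile row per scaffold passing the length filter.

    Columns: scaffold_id, length, gc_percent, coverage, paired_fraction
    (NaN when no reads map), taxonomy_label, and tnf_000..tnf_135.
    Label rows naming unknown scaffolds are ignored with a warning.
    """
    label_map: dict[str, str] = {}
    if labels is not None:
        known = set(scaffolds)
        for _, row in labels.iterrows():
            sid = row["scaffold_id"]
            if sid not in known:
                warnings.warn(f"label for unknown scaffold {sid!r} ignored")
                continue
            value = row["taxonomy_label"]
            if isinstance(value, str) and value:
                label_map[sid] = value

    frame = _as_frame(alignments) if alignments is not None else pd.DataFrame()
    if not frame.empty:
        agg = frame.dropna(subset=["scaffold_id"]).groupby("scaffold_id").agg(
            aligned=("aligned_length", "sum"),
            paired=("pair_status", lambda s: (s == "paired").mean()),
        )
    else:
        agg = pd.DataFrame(columns=["aligned", "paired"])

    rows = []
    tnfs = []
    for sid in sorted(scaffolds):
        seq = scaffolds[sid]
        if len(seq) < min_len:
            continue
        aligned = float(agg.loc[sid, "aligned"]) if sid in agg.index else 0.0
        paired = float(agg.loc[sid, "paired"]) if sid in agg.index else float("nan")
        rows.append(
            {
                "scaffold_id": sid,
                "length": len(seq),
                "gc_percent": gc_percent(seq),
                "coverage": aligned / len(seq),
                "paired_fraction": paired,
                "taxonomy_label": label_map.get(sid, ""),
            }
        )
        tnfs.append(tetranucleotide_profile(seq))
    table = pd.DataFrame(rows, columns=["scaffold_id", "length", "gc_percent", "coverage", "paired_fraction", "taxonomy_label"])
    if rows:
        tnf_frame = pd.DataFrame(np.vstack(tnfs), columns=[f"tnf_{i:03d}" for i in range(len(tnfs[0]))])
        table = pd.concat([table.reset_index(drop=True), tnf_frame], axis=1)
    return table


def tnf_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Extract the TNF block of a profile table as a dense array."""
    cols = [c for c in profiles.columns if c.startswith("tnf_")]
    return profiles[cols].to_numpy()


def plot_feature_space(profiles: pd.DataFrame, ax=None):
    """GC vs log10 coverage scatter colored by taxonomy label (the classic
    holobiont binning view: discrete clusters per community member)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = profiles["taxonomy_label"].fillna("").replace("", "unlabeled")
    for label, group in profiles.assign(_label=labels).groupby("_label"):
        cov = group["coverage"].clip(lower=1e-3)
        ax.scatter(group["gc_percent"], np.log10(cov), s=12, label=str(label))
    ax.set_xlabel("GC (%)")
    ax.set_ylabel("log10 coverage")
    ax.legend(fontsize=7)
    return ax
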