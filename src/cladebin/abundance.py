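"""Community composition by two routes, plus environmental 16S filters.

Metagenomic route: unambiguously mapped reads (100% identity by default)
are assigned to the bin/taxon owning their scaffold; the ``classified``
metric normalizes over mapped reads, the ``total`` metric over all reads
with the remainder reported as unclassified. Amplicon route: each ASV is
matched to the best MAG 16S gene at >= 97% identity over the full ASV
length, and per-sample relative abundances are normalized by total sample
reads. The two estimators disagree predictably: read recruitment
under-represents small genomes, amplicons over-report multi-copy 16S
taxa.

Environmental matching screens full-length 16S queries against reference
sets with blastn-style filters: minimum alignment length 360 nt, maximum
e-value 1e-7 (Karlin-Altschul, ungapped nucleotide constants lambda=1.28,
K=0.46 for +1/-2 scoring), and tiered identity floors (97% species, 95%
genus, 90% distant relatives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import spearmanr

from .relatedness import alignment_identity

__all__ = [
    "MatchFilter",
    "metagenomic_abundance",
    "amplicon_abundance",
    "environmental_match",
    "compare_metrics",
    "plot_composition",
    "KARLIN_ALTSCHUL",
]

# ungapped nucleotide Karlin-Altschul constants for +1/-2 scoring
KARLIN_ALTSCHUL = {"lambda": 1.28, "K": 0.46, "match": 1, "mismatch": -2}


@dataclass
class MatchFilter:
    """Filters for environmental 16S database matches."""

    min_align_len: int = 360
    max_evalue: float = 1e-7
    min_identity: float = 97.0  # tiers: 97 species, 95 genus, 90 distant

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.min_align_len <= 0:
            raise ValueError("min_align_len must be positive")


ABUNDANCE_COLUMNS = ["sample_id", "taxon_group", "metric", "relative_abundance"]


def metagenomic_abundance(
    alignments: pd.DataFrame,
    bins: dict[str, set[str]],
    bin_taxon: dict[str, str] | None = None,
    n_total_reads: int | None = None,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Per-taxon read-recruitment shares from an alignment table.

    ``bins`` maps bin_id -> scaffold-id set and must be disjoint.
    Ambiguously placed reads count as unclassified. Rows are emitted under
    metric ``read_recruitment_classified`` (sums to 1 over taxa) and
    ``read_recruitment_total`` (sums to 1 together with ``unclassified``).
    """
    bin_membership: dict[str, str] = {}
    for bin_id in sorted(bins):
        for sid in bins[bin_id]:
            if sid in bin_membership:
                raise ValueError(f"bins overlap on scaffold {sid!r}")
            bin_membership[sid] = bin_id
    bin_taxon = bin_taxon or {b: b for b in bins}
    mapped = alignments.dropna(subset=["scaffold_id"])
    assigned = mapped[~mapped["ambiguous"].astype(bool)]
    assigned = assigned[assigned["scaffold_id"].isin(bin_membership)]
    taxa = assigned["scaffold_id"].map(bin_membership).map(bin_taxon)
    counts = taxa.value_counts().sort_index()
    n_classified = int(counts.sum())
    n_total = n_total_reads if n_total_reads is not None else len(alignments)
    rows = []
    for taxon, count in counts.items():
        rows.append(
            {
                "sample_id": sample_id,
                "taxon_group": taxon,
                "metric": "read_recruitment_classified",
                "relative_abundance": count / n_classified if n_classified else 0.0,
            }
        )
    for taxon, count in counts.items():
        rows.append(
            {
                "sample_id": sample_id,
                "taxon_group": taxon,
                "metric": "read_recruitment_total",
                "relative_abundance": count / n_total if n_total else 0.0,
            }
        )
    rows.append(
        {
            "sample_id": sample_id,
            "taxon_group": "unclassified",
            "metric": "read_recruitment_total",
            "relative_abundance": (n_total - n_classified) / n_total if n_total else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def _asv_identity(asv: str, reference: str) -> float:
    """Best semi-global identity of the full ASV inside the reference."""
    result = edlib.align(asv.upper(), reference.upper(), mode="HW", task="distance")
    distance = result["editDistance"]
    if distance < 0:
        return 0.0
    return 100.0 * (len(asv) - distance) / len(asv)


def amplicon_abundance(
    asv_table: pd.DataFrame,
    mag_ssu_set: dict[str, list[str] | str],
    min_identity: float = 97.0,
) -> pd.DataFrame:
    """Assign ASVs to MAG 16S genes and normalize per sample.

    ``mag_ssu_set`` maps taxon_group -> 16S sequence(s). Each ASV goes to
    the best-identity group at >= min_identity over the full ASV length
    (ties to the lexicographically lower group); unassigned ASVs pool
    under ``unassigned``. Shares are computed per sample after dividing by
    that sample's total read count.
    """
    if asv_table.empty:
        return pd.DataFrame(columns=ABUNDANCE_COLUMNS)
    references = {
        group: [seqs] if isinstance(seqs, str) else list(seqs)
        for group, seqs in mag_ssu_set.items()
    }
    assignment: dict[str, str] = {}
    for seq in sorted(set(asv_table["sequence"])):
        best_group, best_identity = "unassigned", -1.0
        for group in sorted(references):
            identity = max(_asv_identity(seq, ref) for ref in references[group])
            if identity > best_identity + 1e-12:
                best_group, best_identity = group, identity
        if best_identity < min_identity:
            best_group = "unassigned"
        assignment[seq] = best_group
    rows = []
    for sample_id, sample in asv_table.groupby("sample_id"):
        total = float(sample["count"].sum())
        grouped = sample.assign(_group=sample["sequence"].map(assignment)).groupby("_group")["count"].sum()
        for group in sorted(grouped.index):
            rows.append(
                {
                    "sample_id": sample_id,
                    "taxon_group": group,
                    "metric": "amplicon",
                    "relative_abundance": float(grouped[group]) / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = float(KARLIN_ALTSCHUL["match"])
    aligner.mismatch_score = float(KARLIN_ALTSCHUL["mismatch"])
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = "local"
    return aligner


def environmental_match(
    query_ssu: str,
    reference_ssu_set: dict[str, str],
    match_filter: MatchFilter | None = None,
) -> pd.DataFrame:
    """Local-alignment screen of one 16S query against a reference set.

    Returns retained matches (ref_id, identity, align_len, evalue, score);
    the e-value uses the Karlin-Altschul form E = K * m * n * exp(-lambda*S)
    with the module's fixed ungapped nucleotide constants, recorded in
    ``DataFrame.attrs['karlin_altschul']``.
    """
    match_filter = match_filter or MatchFilter()
    aligner = _local_aligner()
    rows = []
    m = len(query_ssu)
    for ref_id in sorted(reference_ssu_set):
        reference = reference_ssu_set[ref_id]
        alignments = aligner.align(query_ssu.upper(), reference.upper())
        if len(alignments) == 0:
            continue
        alignment = alignments[0]
        identity, columns, _, _ = alignment_identity(alignment)
        score = float(alignment.score)
        evalue = KARLIN_ALTSCHUL["K"] * m * len(reference) * math.exp(-KARLIN_ALTSCHUL["lambda"] * score)
        if columns < match_filter.min_align_len:
            continue
        if evalue > match_filter.max_evalue:
            continue
        if identity < match_filter.min_identity:
            continue
        rows.append(
            {
                "ref_id": ref_id,
                "identity": identity,
                "align_len": columns,
                "evalue": evalue,
                "score": score,
            }
        )
    out = pd.DataFrame(rows, columns=["ref_id", "identity", "align_len", "evalue", "score"])
    out.attrs["karlin_altschul"] = dict(KARLIN_ALTSCHUL)
    return out


def compare_metrics(
    table: pd.DataFrame,
    ssu_copies: dict[str, int] | None = None,
    genome_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Concordance of amplicon vs read-recruitment shares per sample.

    Returns one row per (sample, taxon) with both shares, their
    difference, the sample's Spearman rank correlation, and a flag naming
    expected discordance sources (multi-copy 16S, atypical genome size).
    Samples missing one of the two metrics are skipped.
    """
    rows = []
    for sample_id, sample in table.groupby("sample_id"):
        reads = sample[sample["metric"] == "read_recruitment_classified"]
        amplicon = sample[sample["metric"] == "amplicon"]
        amplicon = amplicon[amplicon["taxon_group"] != "unassigned"]
        if reads.empty or amplicon.empty:
            continue
        merged = pd.merge(
            reads[["taxon_group", "relative_abundance"]].rename(columns={"relative_abundance": "reads"}),
            amplicon[["taxon_group", "relative_abundance"]].rename(columns={"relative_abundance": "amplicon"}),
            on="taxon_group",
            how="outer",
        ).fillna(0.0)
        if len(merged) < 2 or merged["reads"].nunique() < 2 or merged["amplicon"].nunique() < 2:
            rho = float("nan")
        else:
            rho = float(spearmanr(merged["reads"], merged["amplicon"]).statistic)
        sizes = [genome_sizes[t] for t in merged["taxon_group"] if genome_sizes and t in genome_sizes]
        median_size = float(np.median(sizes)) if sizes else float("nan")
        for _, row in merged.iterrows():
            flags = []
            taxon = row["taxon_group"]
            if ssu_copies and ssu_copies.get(taxon, 1) > 1:
                flags.append("multi_copy_16s")
            if genome_sizes and taxon in genome_sizes and median_size == median_size:
                if genome_sizes[taxon] > 1.5 * median_size or genome_sizes[taxon] < median_size / 1.5:
                    flags.append("atypical_genome_size")
            rows.append(
                {
                    "sample_id": sample_id,
                    "taxon_group": taxon,
                    "reads": row["reads"],
                    "amplicon": row["amplicon"],
                    "difference": row["amplicon"] - row["reads"],
                    "spearman_rho": rho,
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "taxon_group", "reads", "amplicon", "difference", "spearman_rho", "flags"],
    )


def plot_composition(table: pd.DataFrame, metric: str = "amplicon", ax=None):
    """Stacked per-sample composition bars for one metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    subset = table[table["metric"] == metric]
    pivot = subset.pivot_table(
        index="sample_id", columns="taxon_group", values="relative_abundance", fill_value=0.0
    )
    bottom = np.zeros(len(pivot))
    for taxon in pivot.columns:
        ax.bar(pivot.index, pivot[taxon], bottom=bottom, label=str(taxon))
        bottom += pivot[taxon].to_numpy()
    ax.set_ylabel("relative abundance")
    ax.set_title(metric)
    ax.legend(fontsize=7)
    return ax
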