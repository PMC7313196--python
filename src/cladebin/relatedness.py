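"""Pairwise genome relatedness and threshold-based taxonomic rank calls.

Average amino acid identity (AAI) is the unweighted mean identity over
reciprocal-best-hit (RBH) protein pairs between two proteomes, computed
from global BLOSUM62 alignments with affine gaps (open 11, extend 1).
16S rRNA gene identity uses a global nucleotide alignment with free
terminal gaps; internal gap columns count in the denominator, and the
value is undefined when the aligned span is shorter than 360 nt.

Rank calls follow AAI threshold bands (species >= 95, genus >= 65,
family >= 45 by default) with 16S identity as tie-breaker below the
family band and as sole evidence when AAI is undefined; boundaries are
inclusive (a value exactly at a threshold classifies to the higher rank).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "RankThresholds",
    "RelatednessResult",
    "GenomeData",
    "reciprocal_best_hits",
    "aai",
    "ssu_identity",
    "assign_rank",
    "ssu_rank",
    "identity_matrix",
    "alignment_identity",
]

_RANK_ORDER = {
    "same_species": 5,
    "same_genus": 4,
    "same_family": 3,
    "same_order": 2,
    "novel_above_order": 1,
    "indeterminate": 0,
}


@dataclass
class RankThresholds:
    """Rank boundary guidelines (percent identity), all inclusive."""

    aai_species: float = 95.0
    aai_genus: float = 65.0
    aai_family: float = 45.0
    ssu_species: float = 97.0
    ssu_genus: float = 94.5
    ssu_order_floor: float = 86.5

    def __post_init__(self):
        if not self.aai_species > self.aai_genus > self.aai_family:
            raise ValueError("AAI thresholds must decrease species > genus > family")


@dataclass
class RelatednessResult:
    genome_a: str
    genome_b: str
    aai: float  # NaN when undefined
    n_rbh: int
    ssu_identity: float  # NaN when undefined
    rank_call: str
    ssu_rank_call: str


@dataclass
class GenomeData:
    """Inputs per genome: a predicted proteome and/or a 16S gene."""

    proteome: dict[str, str] | None = None
    ssu: str | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # free terminal gaps: the shared span decides identity
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.88 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def alignment_identity(alignment) -> tuple[float, int, int, int]:
    """Identity over alignment columns excluding terminal gaps.

    Returns (percent identity, n_columns, span_a, span_b) where spans are
    the residues of each sequence inside the non-terminal region and
    internal gap columns count in the column denominator.
    """
    s1, s2 = str(alignment[0]), str(alignment[1])
    both = [i for i in range(len(s1)) if s1[i] != "-" and s2[i] != "-"]
    if not both:
        return 0.0, 0, 0, 0
    start, end = both[0], both[-1]
    columns = end - start + 1
    matches = sum(1 for i in range(start, end + 1) if s1[i] == s2[i] and s1[i] != "-")
    span_a = sum(1 for i in range(start, end + 1) if s1[i] != "-")
    span_b = sum(1 for i in range(start, end + 1) if s2[i] != "-")
    return 100.0 * matches / columns, columns, span_a, span_b


def _best_hits(
    proteome_a: dict[str, str], proteome_b: dict[str, str], aligner
) -> dict[str, str]:
    """Best hit in b for each a-protein by alignment score; ties break to
    the lexicographically smallest b-protein id."""
    ids_b = sorted(proteome_b)
    best: dict[str, str] = {}
    for name_a in sorted(proteome_a):
        seq_a = proteome_a[name_a]
        scores = [aligner.score(seq_a, proteome_b[nb]) for nb in ids_b]
        best[name_a] = ids_b[int(np.argmax(scores))]
    return best


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_identity: float = 30.0,
    min_cov: float = 0.7,
) -> list[tuple[str, str, float]]:
    """Mutual best-hit protein pairs passing identity/coverage floors.

    Returns [(id_a, id_b, percent identity), ...]. Coverage is the aligned
    (non-terminal) span divided by each protein's length; both proteins
    must pass.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    aligner = _protein_aligner()
    forward = _best_hits(proteome_a, proteome_b, aligner)
    backward = _best_hits(proteome_b, proteome_a, aligner)
    pairs = []
    for name_a, name_b in forward.items():
        if backward.get(name_b) != name_a:
            continue
        alignment = aligner.align(proteome_a[name_a], proteome_b[name_b])[0]
        identity, _, span_a, span_b = alignment_identity(alignment)
        if identity < min_identity:
            continue
        if span_a / len(proteome_a[name_a]) < min_cov or span_b / len(proteome_b[name_b]) < min_cov:
            continue
        pairs.append((name_a, name_b, identity))
    return pairs


def aai(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_rbh: int = 20,
    min_identity: float = 30.0,
    min_cov: float = 0.7,
) -> tuple[float, int]:
    """AAI: unweighted mean identity over RBH pairs; (NaN, n) below min_rbh.

    Symmetric by construction: RBH pairs are mutual and each pair's
    identity comes from a single global alignment.
    """
    pairs = reciprocal_best_hits(proteome_a, proteome_b, min_identity, min_cov)
    if len(pairs) < min_rbh:
        warnings.warn(f"only {len(pairs)} RBH pairs (<{min_rbh}): AAI undefined")
        return float("nan"), len(pairs)
    return float(np.mean([p[2] for p in pairs])), len(pairs)


def ssu_identity(seq_a: str, seq_b: str, min_len: int = 360) -> float:
    """Global 16S identity over the shared span; NaN below min_len span."""
    if min(len(seq_a), len(seq_b)) == 0:
        return float("nan")
    aligner = _nucleotide_aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    identity, columns, _, _ = alignment_identity(alignment)
    if columns < min_len:
        return float("nan")
    return identity


def ssu_rank(ssu: float, thresholds: RankThresholds | None = None) -> str:
    """Rank call from 16S identity alone."""
    thresholds = thresholds or RankThresholds()
    if ssu != ssu:  # NaN
        return "indeterminate"
    if ssu >= thresholds.ssu_species:
        return "same_species"
    if ssu >= thresholds.ssu_genus:
        return "same_genus"
    if ssu >= thresholds.ssu_order_floor:
        return "same_order"
    return "novel_above_order"


def assign_rank(
    aai_value: float,
    ssu_value: float,
    thresholds: RankThresholds | None = None,
) -> str:
    """Highest rank whose AAI threshold is met (inclusive); 16S identity is
    the tie-breaker below the family band and sole evidence when AAI is
    undefined. Both undefined -> indeterminate."""
    thresholds = thresholds or RankThresholds()
    aai_defined = aai_value == aai_value
    ssu_defined = ssu_value == ssu_value
    if not aai_defined and not ssu_defined:
        return "indeterminate"
    if not aai_defined:
        return ssu_rank(ssu_value, thresholds)
    if aai_value >= thresholds.aai_species:
        return "same_species"
    if aai_value >= thresholds.aai_genus:
        return "same_genus"
    if aai_value >= thresholds.aai_family:
        return "same_family"
    if ssu_defined and ssu_value >= thresholds.ssu_order_floor:
        return "same_order"
    return "novel_above_order"


def identity_matrix(
    genomes: dict[str, GenomeData],
    thresholds: RankThresholds | None = None,
    min_rbh: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, list[RelatednessResult]]:
    """All-pairs AAI/16S matrices (self-diagonal 100) and rank-call table."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    thresholds = thresholds or RankThresholds()
    ids = sorted(genomes)
    aai_mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    ssu_mat = aai_mat.copy()
    np.fill_diagonal(aai_mat.values, 100.0)
    np.fill_diagonal(ssu_mat.values, 100.0)
    results: list[RelatednessResult] = []
    for ga, gb in itertools.combinations(ids, 2):
        a, b = genomes[ga], genomes[gb]
        aai_value, n_rbh = (float("nan"), 0)
        if a.proteome and b.proteome:
            aai_value, n_rbh = aai(a.proteome, b.proteome, min_rbh=min_rbh)
        ssu_value = float("nan")
        if a.ssu and b.ssu:
            ssu_value = ssu_identity(a.ssu, b.ssu)
        result = RelatednessResult(
            genome_a=ga,
            genome_b=gb,
            aai=aai_value,
            n_rbh=n_rbh,
            ssu_identity=ssu_value,
            rank_call=assign_rank(aai_value, ssu_value, thresholds),
            ssu_rank_call=ssu_rank(ssu_value, thresholds),
        )
        results.append(result)
        aai_mat.loc[ga, gb] = aai_mat.loc[gb, ga] = aai_value
        ssu_mat.loc[ga, gb] = ssu_mat.loc[gb, ga] = ssu_value
    table = pd.DataFrame(
        [
            {
                "genome_a": r.genome_a,
                "genome_b": r.genome_b,
                "aai": r.aai,
                "n_rbh": r.n_rbh,
                "ssu_identity": r.ssu_identity,
                "rank_call": r.rank_call,
                "ssu_rank_call": r.ssu_rank_call,
            }
            for r in results
        ]
    )
    return aai_mat, ssu_mat, table
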