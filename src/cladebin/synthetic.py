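"""Synthetic holobiont communities with known ground truth.

Emulates a low-diversity sponge-holobiont metagenome: one dominant
high-coverage genome plus several lower-abundance genomes spanning a wide GC
and coverage range, host-like contaminant scaffolds of distinct nucleotide
composition but bacteria-like coverage, planted single-copy marker families
and multi-copy 16S genes, paired-end reads with a controllable singleton
rate, and a V4-V5-style amplicon count table.

Genomes are i.i.d. nucleotides at a target GC plus planted loci, so genomes
are mutually non-homologous outside the planted 16S genes; the host
contaminant uses a first-order Markov chain with a strong dinucleotide bias,
making it separable by composition but not by GC or coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CommunityConfig",
    "CommunityTruth",
    "default_config",
    "generate_genomes",
    "fragment_genomes",
    "simulate_reads",
    "simulate_amplicons",
    "taxonomy_labels",
    "marker_annotations",
    "random_proteome",
    "mutate_proteome",
    "reverse_complement",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default phylum/class-level labels mirroring a cyanobacterium-dominated
# sponge community; two genomes share Alphaproteobacteria and must be split
# on GC/coverage, exercising within-label clustering.
DEFAULT_LABELS = (
    "Cyanobacteria",
    "Bacteroidetes",
    "Alphaproteobacteria",
    "Alphaproteobacteria",
    "Gammaproteobacteria",
    "Oligoflexia",
)
HOST_LABEL = "Eukaryota;Porifera"
HOST_ID = "host"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CommunityConfig:
    """Parameters of a synthetic community.

    ``abundances`` are cell fractions summing to 1 over the bacterial
    genomes; read pairs are allocated proportionally to
    ``abundance x genome length``, so the fold-coverage of genome *i* is
    ``depth_total x abundances[i]``.

    ``singleton_rate`` is the expected fraction of emitted reads whose mate
    was discarded before output (community-wide paired read fraction is then
    ``1 - singleton_rate``).
    """

    n_genomes: int = 6
    genome_length: int = 200_000
    gc_targets: tuple[float, ...] = (0.47, 0.40, 0.55, 0.62, 0.45, 0.30)
    abundances: tuple[float, ...] = (0.60, 0.20, 0.10, 0.06, 0.035, 0.005)
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    depth_total: float = 20.0
    singleton_rate: float = 0.05
    error_rate: float = 0.002
    n_16s_copies: int | tuple[int, ...] = 2  # scalar, or one count per genome
    n_marker_families: int = 100
    marker_length: int = 900
    ssu_length: int = 1500
    host_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if len(self.gc_targets) != self.n_genomes:
            raise ValueError("gc_targets length must equal n_genomes")
        if len(self.abundances) != self.n_genomes:
            raise ValueError("abundances length must equal n_genomes")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        for name in ("singleton_rate", "error_rate", "host_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= g <= 1.0 for g in self.gc_targets):
            raise ValueError("gc_targets must be fractions in [0, 1]")
        if self.n_genomes < 1 or self.genome_length < 1:
            raise ValueError("n_genomes and genome_length must be positive")


def default_config(**overrides) -> CommunityConfig:
    """The default desk-scale community; keyword overrides applied on top."""
    config = replace(CommunityConfig(), **overrides)
    config.validate()
    return config


@dataclass
class CommunityTruth:
    """Ground truth of a generated community: the acceptance oracle."""

    config: CommunityConfig
    genomes: dict[str, str]
    true_abundance: dict[str, float]
    # genome_id -> list of (marker_family_id, genome-coordinate span)
    marker_loci_genomic: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)
    ssu_loci_genomic: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)
    scaffolds: dict[str, str] = field(default_factory=dict)
    scaffold_origin: dict[str, str] = field(default_factory=dict)
    # scaffold-coordinate loci, populated by fragment_genomes
    marker_loci: dict[str, list[tuple[str, str, tuple[int, int]]]] = field(default_factory=dict)
    ssu_loci: dict[str, list[tuple[str, str, tuple[int, int]]]] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    ssu_templates: dict[str, str] = field(default_factory=dict)

    def genome_ids(self) -> list[str]:
        return [g for g in self.genomes if g != HOST_ID]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # replace with a uniformly chosen different base
        arr[hits] = _BASES[(np.searchsorted(_BASES, arr[hits]) + rng.integers(1, 4, hits.size)) % 4]
    return arr.tobytes().decode()


def _host_sequence(rng: np.random.Generator, length: int) -> str:
    """Order-1 Markov chain with CpG depletion and AA/TT enrichment.

    GC lands near the middle of the bacterial range so that the host is
    separable by tetranucleotide composition rather than GC or coverage.
    """
    #                to:  A     C     G     T
    transition = np.array(
        [
            [0.42, 0.16, 0.18, 0.24],  # from A
            [0.30, 0.22, 0.03, 0.45],  # from C (CpG depleted)
            [0.26, 0.24, 0.22, 0.28],  # from G
            [0.24, 0.18, 0.16, 0.42],  # from T
        ]
    )
    cumulative = transition.cumsum(axis=1)
    draws = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    state = int(rng.integers(4))
    for i in range(length):
        state = int(np.searchsorted(cumulative[state], draws[i]))
        states[i] = state
    return _BASES[states].tobytes().decode()


def generate_genomes(config: CommunityConfig) -> CommunityTruth:
    """Generate genomes with planted single-copy markers and 16S genes.

    16S copies within a genome stay >=99% identical (0.3% divergence from a
    per-genome template); between genomes the templates diverge ~8% each from
    a shared ancestor, keeping inter-genome identity well under 90%.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"g{i + 1}" for i in range(config.n_genomes)]

    ssu_ancestor = _random_sequence(rng, config.ssu_length, 0.54)
    genomes: dict[str, str] = {}
    marker_loci: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    ssu_loci: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    ssu_templates: dict[str, str] = {}

    copies = config.n_16s_copies
    copies_per_genome = list(copies) if isinstance(copies, (tuple, list)) else [copies] * config.n_genomes
    if len(copies_per_genome) != config.n_genomes:
        raise ValueError("n_16s_copies tuple length must equal n_genomes")
    max_planted = config.n_marker_families * config.marker_length + max(copies_per_genome) * config.ssu_length
    if max_planted >= config.genome_length:
        raise ValueError("genome_length too small for planted marker/16S loci")

    for gid, gc, n_copies in zip(genome_ids, config.gc_targets, copies_per_genome):
        n_planted = config.n_marker_families + n_copies
        # compensate backbone GC for the planted 16S copies (fixed ~54% GC)
        # so the whole genome lands on the configured target
        ssu_fraction = n_copies * config.ssu_length / config.genome_length
        backbone_gc = min(1.0, max(0.0, (gc - 0.54 * ssu_fraction) / (1 - ssu_fraction)))
        backbone = _random_sequence(rng, config.genome_length, backbone_gc)
        template = _mutate(rng, ssu_ancestor, 0.08)
        ssu_templates[gid] = template
        # evenly spaced, non-overlapping planting positions
        slot = config.genome_length // n_planted
        marker_seqs = [
            _random_sequence(rng, config.marker_length, backbone_gc)
            for _ in range(config.n_marker_families)
        ]
        ssu_seqs = [_mutate(rng, template, 0.003) for _ in range(n_copies)]
        # 16S copies interleaved at spread slots (dispersed rRNA operons);
        # markers fill the remaining slots
        ssu_slots = {
            int(round(x))
            for x in np.linspace(0, n_planted - 1, n_copies + 2)[1:-1]
        }
        while len(ssu_slots) < n_copies:  # degenerate rounding collision
            ssu_slots.add(len(ssu_slots))
        loci: list[tuple[str, str]] = []  # (name, sequence) per slot
        marker_iter = iter(enumerate(marker_seqs))
        ssu_iter = iter(enumerate(ssu_seqs))
        for idx in range(n_planted):
            if idx in ssu_slots:
                j, seq = next(ssu_iter)
                loci.append((f"ssu{j + 1}", seq))
            else:
                j, seq = next(marker_iter)
                loci.append((f"m{j + 1:03d}", seq))
        arr = bytearray(backbone.encode())
        markers: list[tuple[str, tuple[int, int]]] = []
        ssus: list[tuple[str, tuple[int, int]]] = []
        for idx, (name, locus) in enumerate(loci):
            start = idx * slot
            arr[start : start + len(locus)] = locus.encode()
            span = (start, start + len(locus))
            if name.startswith("m"):
                markers.append((name, span))
            else:
                ssus.append((name, span))
        genomes[gid] = arr.decode()
        marker_loci[gid] = markers
        ssu_loci[gid] = ssus

    if config.host_fraction > 0:
        host_len = int(round(config.host_fraction * config.n_genomes * config.genome_length))
        genomes[HOST_ID] = _host_sequence(rng, host_len)

    return CommunityTruth(
        config=config,
        genomes=genomes,
        true_abundance=dict(zip(genome_ids, config.abundances)),
        marker_loci_genomic=marker_loci,
        ssu_loci_genomic=ssu_loci,
        ssu_templates=ssu_templates,
    )


def fragment_genomes(
    truth: CommunityTruth,
    min_len: int = 10_000,
    mean_len: int = 20_000,
    seed: int | None = None,
) -> dict[str, str]:
    """Partition each genome into scaffolds >= min_len covering it exactly.

    Each genome is cut into ``n = max(1, round(length / mean_len))`` pieces;
    the slack above ``n * min_len`` is split at sorted uniform breakpoints, so
    pieces are never shorter than ``min_len`` and sum exactly to the genome
    length (``mean_len == genome length`` gives identity fragmentation).
    Planted loci are re-expressed in scaffold coordinates, each attributed to
    the scaffold containing its midpoint.
    """
    if not 0 < min_len <= mean_len:
        raise ValueError("require 0 < min_len <= mean_len")
    config = truth.config
    if mean_len > max(len(s) for s in truth.genomes.values()):
        raise ValueError("mean_len exceeds genome length")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    truth.scaffolds = {}
    truth.scaffold_origin = {}
    truth.marker_loci = {gid: [] for gid in truth.genome_ids()}
    truth.ssu_loci = {gid: [] for gid in truth.genome_ids()}

    for gid, genome in truth.genomes.items():
        length = len(genome)
        n_pieces = max(1, round(length / mean_len))
        while n_pieces > 1 and n_pieces * min_len > length:
            n_pieces -= 1
        slack = length - n_pieces * min_len
        cuts = np.sort(rng.integers(0, slack + 1, size=n_pieces - 1)) if n_pieces > 1 else np.array([], dtype=int)
        bounds = [0]
        for i, cut in enumerate(cuts):
            bounds.append((i + 1) * min_len + int(cut))
        bounds.append(length)
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            sid = f"{gid}_s{i + 1:02d}"
            truth.scaffolds[sid] = genome[start:end]
            truth.scaffold_origin[sid] = gid
            if gid == HOST_ID:
                continue
            for name, (lo, hi) in truth.marker_loci_genomic[gid]:
                mid = (lo + hi) // 2
                if start <= mid < end:
                    truth.marker_loci[gid].append((name, sid, (max(lo, start) - start, min(hi, end) - start)))
            for name, (lo, hi) in truth.ssu_loci_genomic[gid]:
                mid = (lo + hi) // 2
                if start <= mid < end:
                    truth.ssu_loci[gid].append((name, sid, (max(lo, start) - start, min(hi, end) - start)))
    return truth.scaffolds


def _scaffold_weights(truth: CommunityTruth) -> tuple[list[str], np.ndarray]:
    """Per-scaffold read-pair sampling weights: abundance x scaffold length.

    Host scaffolds get a weight matching the median bacterial genome
    coverage, so the contaminant is not separable by coverage depth.
    """
    abundances = truth.true_abundance
    host_abundance = float(np.median(list(abundances.values())))
    sids = sorted(truth.scaffolds)
    weights = np.array(
        [
            (host_abundance if truth.scaffold_origin[s] == HOST_ID else abundances[truth.scaffold_origin[s]])
            * len(truth.scaffolds[s])
            for s in sids
        ]
    )
    return sids, weights


def simulate_reads(
    truth: CommunityTruth,
    config: CommunityConfig | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate paired-end reads; returns (R1 records, R2 records).

    Forward-reverse orientation, insert ~ Normal(insert_mean, insert_sd)
    truncated to [read_length, scaffold length]; substitution errors at
    ``error_rate``; a fraction ``2s/(1+s)`` of pairs lose one mate so that
    the singleton read fraction is ``s``. Populates ``truth.read_origin``
    keyed by read id (without mate suffix).
    """
    config = config or truth.config
    if not truth.scaffolds:
        raise ValueError("no scaffolds: run fragment_genomes first")
    R = config.read_length
    shortest = min(len(s) for s in truth.scaffolds.values())
    if R > shortest:
        raise ValueError("read_length exceeds shortest scaffold")
    rng = np.random.default_rng(config.seed + 2)

    sids, weights = _scaffold_weights(truth)
    total_bases = config.depth_total * sum(
        truth.true_abundance[g] * len(truth.genomes[g]) for g in truth.genome_ids()
    )
    if truth.config.host_fraction > 0 and HOST_ID in truth.genomes:
        host_abundance = float(np.median(list(truth.true_abundance.values())))
        total_bases += config.depth_total * host_abundance * len(truth.genomes[HOST_ID])
    # inflate by (1 + singleton_rate): mate discarding removes a fraction
    # s/(1+s) of reads, so emitted depth still matches depth_total
    n_pairs = int(round(total_bases * (1 + config.singleton_rate) / (2 * R)))

    choices = rng.choice(len(sids), size=n_pairs, p=weights / weights.sum())
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    drop_pair_rate = 2 * config.singleton_rate / (1 + config.singleton_rate)
    drops = rng.random(n_pairs) < drop_pair_rate
    drop_which = rng.integers(0, 2, size=n_pairs)

    r1_records: list[tuple[str, str]] = []
    r2_records: list[tuple[str, str]] = []
    truth.read_origin = {}
    for i in range(n_pairs):
        sid = sids[choices[i]]
        seq = truth.scaffolds[sid]
        insert = int(round(inserts[i]))
        insert = max(R, min(insert, len(seq)))
        start = int(rng.integers(0, len(seq) - insert + 1))
        fwd = seq[start : start + R]
        rev = reverse_complement(seq[start + insert - R : start + insert])
        if config.error_rate > 0:
            fwd = _mutate(rng, fwd, config.error_rate)
            rev = _mutate(rng, rev, config.error_rate)
        rid = f"r{i + 1:07d}"
        truth.read_origin[rid] = (truth.scaffold_origin[sid], sid, start)
        emit_r1 = not (drops[i] and drop_which[i] == 0)
        emit_r2 = not (drops[i] and drop_which[i] == 1)
        if emit_r1:
            r1_records.append((f"{rid}/1", fwd))
        if emit_r2:
            r2_records.append((f"{rid}/2", rev))
    return r1_records, r2_records


def simulate_amplicons(
    truth: CommunityTruth,
    region: tuple[int, int] = (515, 926),
    n_reads: int = 50_000,
    seed: int | None = None,
    sample_id: str = "S1",
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Multinomial ASV count table over the planted 16S copies.

    The default region mirrors a V4-V5 amplicon (515F/926R primer span on
    the 16S template). Each 16S copy contributes its exact planted
    subsequence with probability proportional to
    ``true_abundance x n_16s_copies``; identical subsequences collapse into
    one ASV. Columns: sample_id, asv_id, sequence, count.
    """
    lo, hi = region
    config = truth.config
    if not (0 <= lo < hi <= config.ssu_length):
        raise ValueError("amplicon region outside the 16S template")
    if not truth.ssu_loci_genomic:
        raise ValueError("no 16S loci: run generate_genomes first")
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)

    sequences: list[str] = []
    weights: list[float] = []
    for gid in truth.genome_ids():
        genome = truth.genomes[gid]
        for _, (start, end) in truth.ssu_loci_genomic[gid]:
            if end - start >= hi:
                sequences.append(genome[start + lo : start + hi])
                weights.append(truth.true_abundance[gid])
    probabilities = np.array(weights) / np.sum(weights)
    counts = rng.multinomial(n_reads, probabilities)

    collapsed: dict[str, int] = {}
    for seq, count in zip(sequences, counts):
        if error_rate > 0 and count > 0:
            seq = _mutate(rng, seq, error_rate)
        collapsed[seq] = collapsed.get(seq, 0) + int(count)
    rows = [
        {"sample_id": sample_id, "asv_id": f"asv{i + 1:03d}", "sequence": seq, "count": n}
        for i, (seq, n) in enumerate(sorted(collapsed.items()))
    ]
    return pd.DataFrame(rows, columns=["sample_id", "asv_id", "sequence", "count"])


def taxonomy_labels(
    truth: CommunityTruth,
    labels: tuple[str, ...] = DEFAULT_LABELS,
    label_fraction: float = 0.9,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-scaffold taxonomy labels, the stand-in for protein-similarity
    classification of scaffolds against a reference database.

    A random ``1 - label_fraction`` of bacterial scaffolds is left
    unlabeled, mimicking scaffolds without confident database matches.
    Host scaffolds are always labeled (host DNA is readily recognised).
    Columns: scaffold_id, taxonomy_label (empty when unlabeled).
    """
    config = truth.config
    if len(labels) < config.n_genomes:
        raise ValueError("need one label per genome")
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    by_genome = dict(zip([f"g{i + 1}" for i in range(config.n_genomes)], labels))
    by_genome[HOST_ID] = HOST_LABEL
    rows = []
    for sid in sorted(truth.scaffold_origin):
        gid = truth.scaffold_origin[sid]
        label = by_genome[gid]
        if gid != HOST_ID and rng.random() > label_fraction:
            label = ""
        rows.append({"scaffold_id": sid, "taxonomy_label": label})
    return pd.DataFrame(rows, columns=["scaffold_id", "taxonomy_label"])


def marker_annotations(truth: CommunityTruth) -> pd.DataFrame:
    """Flatten planted marker loci into (scaffold_id, marker_family) rows."""
    rows = []
    for gid in truth.genome_ids():
        for family, sid, _span in truth.marker_loci.get(gid, []):
            rows.append({"scaffold_id": sid, "marker_family": family})
    return pd.DataFrame(rows, columns=["scaffold_id", "marker_family"])


def random_proteome(
    n_proteins: int = 30, length: int = 200, seed: int = 0
) -> dict[str, str]:
    """Random amino-acid sequences, for relatedness benchmarks."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    return {
        f"p{i + 1:03d}": alphabet[rng.integers(0, len(alphabet), size=length)].tobytes().decode()
        for i in range(n_proteins)
    }


def mutate_proteome(proteome: dict[str, str], rate: float, seed: int = 0) -> dict[str, str]:
    """Substitute a fraction `rate` of residues with a different amino acid."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, seq in proteome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(arr.size) < rate)
        for i in hits:
            current = chr(arr[i])
            options = AMINO_ACIDS.replace(current, "")
            arr[i] = ord(options[rng.integers(0, len(options))])
        out[name] = arr.tobytes().decode()
    return out
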