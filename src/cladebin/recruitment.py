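"""End-to-end read mapping and bin-matched read-pair recruitment.

The mapper is an exact-k-mer seed index with ungapped full-length
extension: every read is placed over its whole length (no clipping),
identity is matches / read length, and only placements at or above a
configurable identity floor are reported. At a 100% identity floor the
contract reduces to exact full-length substring matching on either
strand, which is bit-reproducible.

Pair recruitment gathers, for each bin, every read pair with at least one
mate mapped to a bin scaffold and completes the pair from the input FASTQ
records, producing read sets ready for targeted re-assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import reverse_complement

__all__ = ["KmerIndex", "build_index", "map_reads", "read_sam", "recruit_pairs", "RecruitmentResult"]

ALIGNMENT_COLUMNS = [
    "read_id",
    "mate",
    "scaffold_id",
    "position",
    "aligned_length",
    "identity",
    "pair_status",
    "ambiguous",
]


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 integer codes of all k-windows; -1 where ambiguous."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        out = out * 4 + np.where(col >= 0, col, 0)
    out[~valid] = -1
    return out


class KmerIndex:
    """Exact k-mer seed index over the forward strand of each scaffold.

    k-mers are packed into base-4 integers (k <= 31) and grouped once with
    a single argsort, so index build is vectorised. Reverse-strand
    placements are found by also seeding the reverse complement of each
    read. Candidate lists are deterministic for a given input.
    """

    def __init__(self, scaffolds: dict[str, str], k: int = 16):
        if not 11 <= k <= 31:
            raise ValueError("seed length k must be in [11, 31]")
        if len(set(scaffolds)) != len(scaffolds):
            raise ValueError("duplicate scaffold ids")
        self.k = k
        self.scaffold_ids = sorted(scaffolds)
        self.encoded = {
            sid: _BASE_CODE[np.frombuffer(scaffolds[sid].upper().encode(), dtype=np.uint8)]
            for sid in self.scaffold_ids
        }
        code_blocks, sid_blocks, pos_blocks = [], [], []
        for idx, sid in enumerate(self.scaffold_ids):
            kmers = _kmer_codes(self.encoded[sid], k)
            keep = kmers >= 0
            code_blocks.append(kmers[keep])
            sid_blocks.append(np.full(int(keep.sum()), idx, dtype=np.int32))
            pos_blocks.append(np.flatnonzero(keep).astype(np.int32))
        if scaffolds and not any(b.size for b in code_blocks):
            warnings.warn("k longer than every scaffold: empty index")
        all_codes = np.concatenate(code_blocks) if code_blocks else np.empty(0, dtype=np.int64)
        all_sids = np.concatenate(sid_blocks) if sid_blocks else np.empty(0, dtype=np.int32)
        all_pos = np.concatenate(pos_blocks) if pos_blocks else np.empty(0, dtype=np.int32)
        order = np.argsort(all_codes, kind="stable")
        self._codes = all_codes[order]
        self._sids = all_sids[order]
        self._pos = all_pos[order]

    def lookup_code(self, code: int) -> list[tuple[str, int]]:
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        return [
            (self.scaffold_ids[self._sids[i]], int(self._pos[i])) for i in range(lo, hi)
        ]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        codes = _BASE_CODE[np.frombuffer(kmer.upper().encode(), dtype=np.uint8)]
        packed = _kmer_codes(codes, self.k)
        if packed.size != 1 or packed[0] < 0:
            return []
        return self.lookup_code(int(packed[0]))


def build_index(scaffolds: dict[str, str], k: int = 16) -> KmerIndex:
    return KmerIndex(scaffolds, k=k)


def _mismatches(index: KmerIndex, sid: str, start: int, read_codes: np.ndarray) -> int:
    ref = index.encoded[sid]
    return int(np.count_nonzero(ref[start : start + read_codes.size] != read_codes))


def map_reads(
    reads: dict[str, str],
    index: KmerIndex,
    min_identity: float = 100.0,
) -> pd.DataFrame:
    """Map reads end-to-end; returns an alignment table.

    Best placement by identity; ties broken by lowest (scaffold_id,
    position); a read whose best identity is shared by several distinct
    placements is flagged ambiguous. pair_status is 'paired' when the
    read's mate (same id base, other /1 or /2 suffix) also mapped in this
    run, else 'singleton'.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    k = index.k
    rows: list[dict] = []
    mapped_mates: dict[str, set[int]] = {}
    for name in sorted(reads):
        seq = reads[name].upper()
        if not seq:
            warnings.warn(f"empty read {name!r} skipped")
            continue
        length = len(seq)
        max_mm = int(np.floor(length * (1 - min_identity / 100.0) + 1e-9))
        best: tuple[int, str, int] | None = None  # (mismatches, scaffold, position)
        n_best = 0
        seen: set[tuple[str, int, int]] = set()
        for strand, oriented in ((0, seq), (1, reverse_complement(seq))):
            codes = _BASE_CODE[np.frombuffer(oriented.encode(), dtype=np.uint8)]
            if length < k:
                continue
            seed_codes = _kmer_codes(codes, k)
            # non-overlapping seeds: with <= max_mm substitutions at least one
            # seed is clean whenever (max_mm + 1) * k <= length
            offsets = list(range(0, length - k + 1, k))
            if offsets[-1] != length - k:
                offsets.append(length - k)
            for offset in offsets:
                code = int(seed_codes[offset])
                if code < 0:
                    continue
                for sid, pos in index.lookup_code(code):
                    start = pos - offset
                    if start < 0 or start + length > index.encoded[sid].size:
                        continue
                    key = (sid, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = _mismatches(index, sid, start, codes)
                    if mm > max_mm:
                        continue
                    candidate = (mm, sid, start)
                    if best is None or candidate[0] < best[0]:
                        best, n_best = candidate, 1
                    elif candidate[0] == best[0]:
                        n_best += 1
                        if (candidate[1], candidate[2]) < (best[1], best[2]):
                            best = candidate
        if best is None:
            continue
        mm, sid, start = best
        base, _, mate = name.rpartition("/")
        mate_no = int(mate) if base else 1
        base = base or name
        mapped_mates.setdefault(base, set()).add(mate_no)
        rows.append(
            {
                "read_id": base,
                "mate": mate_no,
                "scaffold_id": sid,
                "position": start,
                "aligned_length": length,
                "identity": 100.0 * (length - mm) / length,
                "pair_status": "singleton",
                "ambiguous": n_best > 1,
            }
        )
    frame = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    if not frame.empty:
        both = {rid for rid, mates in mapped_mates.items() if len(mates) == 2}
        frame.loc[frame["read_id"].isin(both), "pair_status"] = "paired"
    return frame


def read_sam(path) -> pd.DataFrame:
    """Import an externally produced SAM file as an alignment table.

    Identity is derived from the NM tag when present (100 x (1 - NM/len));
    pair_status follows the mate-unmapped flag. Secondary and supplementary
    records are skipped (the table holds one placement per read).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            length = rec.query_alignment_length or (len(rec.query_sequence or "") or 0)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            rows.append(
                {
                    "read_id": rec.query_name,
                    "mate": 2 if rec.is_read2 else 1,
                    "scaffold_id": rec.reference_name,
                    "position": rec.reference_start,
                    "aligned_length": length,
                    "identity": 100.0 * (1 - nm / length) if length else 0.0,
                    "pair_status": "singleton" if (not rec.is_paired or rec.mate_is_unmapped) else "paired",
                    "ambiguous": False,
                }
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


@dataclass
class RecruitmentResult:
    """Reads recruited to one bin, with completed mates."""

    bin_id: str
    recruited_read_ids: set[str] = field(default_factory=set)  # full ids with /1 /2
    n_pairs_complete: int = 0
    n_mates_rescued: int = 0
    r1: list[tuple[str, str]] = field(default_factory=list)
    r2: list[tuple[str, str]] = field(default_factory=list)


def recruit_pairs(
    alignments: pd.DataFrame,
    bin_scaffolds: set[str],
    reads_r1: dict[str, str],
    reads_r2: dict[str, str],
    bin_id: str = "bin",
) -> RecruitmentResult:
    """Recruit every pair with >= 1 mate mapped to a bin scaffold.

    Both mates are emitted whenever both exist in the input files; a mate
    present in the input but not itself mapped to the bin counts as
    rescued. Pairs with neither mate mapped to the bin are absent.
    """
    if not bin_scaffolds:
        raise ValueError("bin has no scaffolds")
    result = RecruitmentResult(bin_id=bin_id)
    hits = alignments[alignments["scaffold_id"].isin(bin_scaffolds)]
    mapped_to_bin: dict[str, set[int]] = {}
    for _, row in hits.iterrows():
        mapped_to_bin.setdefault(row["read_id"], set()).add(int(row["mate"]))
    by_base_r1 = {name.rpartition("/")[0] or name: (name, seq) for name, seq in reads_r1.items()}
    by_base_r2 = {name.rpartition("/")[0] or name: (name, seq) for name, seq in reads_r2.items()}
    for rid in sorted(mapped_to_bin):
        mates = mapped_to_bin[rid]
        rec1 = by_base_r1.get(rid)
        rec2 = by_base_r2.get(rid)
        if rec1:
            result.r1.append(rec1)
            result.recruited_read_ids.add(rec1[0])
        if rec2:
            result.r2.append(rec2)
            result.recruited_read_ids.add(rec2[0])
        if rec1 and rec2:
            result.n_pairs_complete += 1
            if 1 not in mates or 2 not in mates:
                result.n_mates_rescued += 1
    return result
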