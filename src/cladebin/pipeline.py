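"""End-to-end driver: simulate -> profile -> bin -> recruit -> screen ->
qc -> rank -> abundance, with a reproducibility manifest.

All randomness flows from the single community seed; generator stages
derive per-stage seeds as seed + stage offset, so identical configuration
reproduces byte-identical outputs (checksummed in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, abundance as ab, io, profiler, recruitment, relatedness, synthetic
from . import binning as binmod

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config", "STAGES"]

log = logging.getLogger("cladebin")

STAGES = ["simulate", "profile", "bin", "recruit", "screen", "qc", "rank", "abundance"]


@dataclass
class FragmentParams:
    min_len: int = 10_000
    mean_len: int = 20_000


@dataclass
class ProfileParams:
    min_scaffold_len: int = 10_000
    map_min_identity: float = 95.0
    seed_k: int = 16


@dataclass
class RecruitParams:
    min_identity: float = 100.0


@dataclass
class AmpliconParams:
    region_start: int = 515
    region_end: int = 926
    n_reads: int = 50_000


@dataclass
class PipelineConfig:
    community: synthetic.CommunityConfig = field(default_factory=synthetic.CommunityConfig)
    fragment: FragmentParams = field(default_factory=FragmentParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    binning: binmod.BinningParams = field(default_factory=binmod.BinningParams)
    screen: binmod.ScreenThresholds = field(default_factory=binmod.ScreenThresholds)
    recruit: RecruitParams = field(default_factory=RecruitParams)
    amplicon: AmpliconParams = field(default_factory=AmpliconParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        self.community.validate()
        if self.fragment.min_len > self.fragment.mean_len:
            raise ValueError("fragment.min_len must not exceed mean_len")
        if not 0 < self.profile.map_min_identity <= 100:
            raise ValueError("profile.map_min_identity must be in (0, 100]")
        if not 0 < self.recruit.min_identity <= 100:
            raise ValueError("recruit.min_identity must be in (0, 100]")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(_to_plain(config), handle, sort_keys=True)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    def build(cls, block):
        block = dict(block or {})
        for fld in dataclasses.fields(cls):
            if fld.name in block and isinstance(fld.default, tuple):
                block[fld.name] = tuple(block[fld.name])
        return cls(**block)

    config = PipelineConfig(
        community=build(synthetic.CommunityConfig, data.get("community")),
        fragment=build(FragmentParams, data.get("fragment")),
        profile=build(ProfileParams, data.get("profile")),
        binning=build(binmod.BinningParams, data.get("binning")),
        screen=build(binmod.ScreenThresholds, data.get("screen")),
        recruit=build(RecruitParams, data.get("recruit")),
        amplicon=build(AmpliconParams, data.get("amplicon")),
        log_level=data.get("log_level", "INFO"),
    )
    config.validate()
    return config


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    The manifest (also written to ``manifest.json``) records, per stage,
    the parameters used and a sha256 checksum of every output file.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.community.seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, params, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": _to_plain(params),
            "outputs": {f.name: _checksum(f) for f in sorted(files)},
        }
        log.info("stage %s complete: %d outputs", stage, len(files))

    # --- simulate -------------------------------------------------------
    truth = synthetic.generate_genomes(config.community)
    synthetic.fragment_genomes(truth, config.fragment.min_len, config.fragment.mean_len)
    r1, r2 = synthetic.simulate_reads(truth)
    labels = synthetic.taxonomy_labels(truth)
    annotations = synthetic.marker_annotations(truth)
    asv_table = synthetic.simulate_amplicons(
        truth,
        region=(config.amplicon.region_start, config.amplicon.region_end),
        n_reads=config.amplicon.n_reads,
    )
    io.write_fasta(out / "genomes.fasta", truth.genomes)
    io.write_fasta(out / "scaffolds.fasta", truth.scaffolds)
    io.write_fastq(out / "reads_R1.fastq", r1)
    io.write_fastq(out / "reads_R2.fastq", r2)
    io.write_table(
        out / "scaffold_origin.tsv",
        pd.DataFrame(
            [{"scaffold_id": s, "genome_id": g} for s, g in sorted(truth.scaffold_origin.items())]
        ),
    )
    io.write_table(
        out / "true_abundance.tsv",
        pd.DataFrame(
            [{"genome_id": g, "abundance": a} for g, a in sorted(truth.true_abundance.items())]
        ),
    )
    io.write_table(out / "labels.tsv", labels)
    io.write_table(out / "marker_annotations.tsv", annotations)
    io.write_table(out / "asv_table.tsv", asv_table)
    record(
        "simulate",
        config.community,
        [
            out / name
            for name in [
                "genomes.fasta",
                "scaffolds.fasta",
                "reads_R1.fastq",
                "reads_R2.fastq",
                "scaffold_origin.tsv",
                "true_abundance.tsv",
                "labels.tsv",
                "marker_annotations.tsv",
                "asv_table.tsv",
            ]
        ],
    )

    # --- profile --------------------------------------------------------
    index = recruitment.build_index(truth.scaffolds, k=config.profile.seed_k)
    reads = dict(r1) | dict(r2)
    alignments = recruitment.map_reads(reads, index, min_identity=config.profile.map_min_identity)
    profiles = profiler.profile_table(
        truth.scaffolds, alignments, labels, min_len=config.profile.min_scaffold_len
    )
    io.write_table(out / "alignments.tsv", alignments)
    io.write_table(out / "profiles.tsv", profiles)
    record("profile", config.profile, [out / "alignments.tsv", out / "profiles.tsv"])

    # --- bin ------------------------------------------------------------
    bins = binmod.preliminary_bins(profiles, config.binning)
    membership = pd.DataFrame(
        [{"bin_id": b.bin_id, "scaffold_id": s} for b in bins for s in b.scaffold_ids]
    )
    io.write_table(out / "bin_membership.tsv", membership)
    record("bin", config.binning, [out / "bin_membership.tsv"])

    # --- recruit --------------------------------------------------------
    reads_r1, reads_r2 = dict(r1), dict(r2)
    recruit_files = []
    recruit_stats = []
    for b in bins:
        result = recruitment.recruit_pairs(
            alignments, set(b.scaffold_ids), reads_r1, reads_r2, bin_id=b.bin_id
        )
        path1, path2 = out / f"recruited_{b.bin_id}_R1.fastq", out / f"recruited_{b.bin_id}_R2.fastq"
        io.write_fastq(path1, result.r1)
        io.write_fastq(path2, result.r2)
        recruit_files += [path1, path2]
        recruit_stats.append(
            {
                "bin_id": b.bin_id,
                "n_reads": len(result.recruited_read_ids),
                "n_pairs_complete": result.n_pairs_complete,
                "n_mates_rescued": result.n_mates_rescued,
            }
        )
    io.write_table(out / "recruitment_stats.tsv", pd.DataFrame(recruit_stats))
    record("recruit", config.recruit, recruit_files + [out / "recruitment_stats.tsv"])

    # --- screen ---------------------------------------------------------
    screened, reports = binmod.refine(bins, profiles, alignments, thresholds=config.screen)
    report_rows = [
        {"bin_id": r.bin_id, "scaffold_id": sid, "decision": "accepted", "reason": ""}
        for r in reports
        for sid in r.accepted
    ] + [
        {"bin_id": r.bin_id, "scaffold_id": sid, "decision": "rejected", "reason": reason}
        for r in reports
        for sid, reason in r.rejected
    ]
    io.write_table(out / "screen_report.tsv", pd.DataFrame(report_rows).sort_values(["bin_id", "scaffold_id"]))
    io.write_table(
        out / "screened_membership.tsv",
        pd.DataFrame([{"bin_id": b.bin_id, "scaffold_id": s} for b in screened for s in b.scaffold_ids]),
    )
    record("screen", config.screen, [out / "screen_report.tsv", out / "screened_membership.tsv"])

    # --- qc -------------------------------------------------------------
    marker_set = [f"m{i + 1:03d}" for i in range(config.community.n_marker_families)]
    summary = binmod.bin_summary(screened, profiles, annotations, marker_set)
    io.write_table(out / "bin_summary.tsv", summary)
    record("qc", {"marker_set_size": len(marker_set)}, [out / "bin_summary.tsv"])

    # --- rank -----------------------------------------------------------
    bin_ssu: dict[str, str] = {}
    for b in screened:
        for gid in truth.genome_ids():
            for _name, sid, (lo, hi) in truth.ssu_loci.get(gid, []):
                if sid in b.scaffold_ids and b.bin_id not in bin_ssu:
                    bin_ssu[b.bin_id] = truth.scaffolds[sid][lo:hi]
    rank_files = []
    if len(bin_ssu) >= 2:
        genome_data = {bid: relatedness.GenomeData(ssu=seq) for bid, seq in bin_ssu.items()}
        _aai_mat, ssu_mat, rank_table = relatedness.identity_matrix(genome_data)
        ssu_mat.round(2).to_csv(out / "ssu_identity_matrix.tsv", sep="\t")
        io.write_table(out / "rank_calls.tsv", rank_table)
        rank_files = [out / "ssu_identity_matrix.tsv", out / "rank_calls.tsv"]
    record("rank", {"n_bins_with_ssu": len(bin_ssu)}, rank_files)

    # --- abundance ------------------------------------------------------
    strict = recruitment.map_reads(reads, index, min_identity=config.recruit.min_identity)
    bin_scaffolds = {b.bin_id: set(b.scaffold_ids) for b in screened}
    bin_taxon = {b.bin_id: (b.taxonomy_label or b.bin_id) for b in screened}
    read_table_ = ab.metagenomic_abundance(
        strict, bin_scaffolds, bin_taxon, n_total_reads=len(reads)
    )
    taxon_ssu: dict[str, list[str]] = {}
    for bid, seq in bin_ssu.items():
        if bid in bin_taxon:
            taxon_ssu.setdefault(bin_taxon[bid], []).append(seq)
    amplicon_table = ab.amplicon_abundance(asv_table, taxon_ssu)
    combined = pd.concat([read_table_, amplicon_table], ignore_index=True)
    concordance = ab.compare_metrics(combined)
    io.write_table(out / "abundance.tsv", combined)
    io.write_table(out / "concordance.tsv", concordance)
    record("abundance", config.recruit, [out / "abundance.tsv", out / "concordance.tsv"])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
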