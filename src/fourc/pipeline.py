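"""End-to-end workflows tying the stages together.

Two modes mirror the two library chemistries:

* **sonication** — paired-end end-tag alignments -> junction calling ->
  unique-site merging and singleton filtering -> window z-scores with
  permutation FDR (±1 Mb inter / ±200 kb intra) -> enriched domains;
* **enzyme** — primer-anchored reads -> reduced restriction-site genome ->
  ligated-site counts -> segment (inter) and sliding-window (intra)
  z-scores with permutation FDR -> enriched domains.

Everything is deterministic given the configuration (which embeds the
seed); rerunning a pipeline writes byte-identical artifacts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .genome import BaitRegion, GenomeLayout
from .sonication import (
    CategoryTally,
    call_junction_reads,
    filter_singletons,
    merge_into_sites,
    proximal_distance_profile,
)
from .stats import (
    cluster_domains,
    enzyme_inter_scores,
    enzyme_intra_scores,
    enzyme_permutation_fdr,
    permutation_fdr,
    positions_by_chrom,
    window_zscores,
)


@dataclass(frozen=True)
class SonicationParams:
    """Thresholds of the sonication workflow; defaults are the published values."""

    min_distance: int = 300
    proximal_max: int = 10_000
    merge_gap: int = 100
    min_support: int = 2
    inter_half_width: int = 1_000_000
    intra_half_width: int = 200_000
    n_perm: int = 100
    fdr_inter: float = 0.05
    fdr_intra: float = 0.20
    cluster_radius_inter: int = 1_000_000
    cluster_radius_intra: int = 200_000
    seed: int = 0


@dataclass(frozen=True)
class EnzymeParams:
    """Thresholds of the enzyme workflow; defaults are the published values."""

    motif: str = "AAGCTT"
    max_primer_mismatches: int = 0
    site_tolerance: int = 5
    sites_per_segment: int = 500
    intra_window_sites: int = 100
    intra_background_sites: int = 3_000
    n_perm: int = 100
    fdr_inter: float = 0.05
    fdr_intra: float = 0.20
    cluster_radius_inter: int = 1_000_000
    cluster_radius_intra: int = 200_000
    seed: int = 0


@dataclass
class SonicationResult:
    tally: CategoryTally
    junctions: pd.DataFrame
    sites_raw: pd.DataFrame
    sites: pd.DataFrame  # singleton-filtered
    trans_scores: pd.DataFrame
    trans_domains: pd.DataFrame
    intra_scores: pd.DataFrame
    intra_domains: pd.DataFrame


def run_sonication(
    tags: pd.DataFrame,
    bait: BaitRegion,
    layout: GenomeLayout,
    params: SonicationParams = SonicationParams(),
) -> SonicationResult:
    """Full sonication-mode analysis of one replicate's tag alignments."""
    junctions, tally = call_junction_reads(
        tags, bait, layout, params.min_distance, params.proximal_max
    )
    distal = junctions[junctions["klass"] != "proximal"]
    sites_raw = merge_into_sites(distal, params.merge_gap)
    sites = filter_singletons(sites_raw, params.min_support)

    trans_sites = sites[sites["klass"] == "trans"]
    trans_scores = window_zscores(trans_sites, params.inter_half_width, layout)
    trans_scores = permutation_fdr(
        trans_scores, layout, params.inter_half_width, params.n_perm, params.seed
    )
    trans_domains = cluster_domains(
        trans_scores, params.fdr_inter, params.cluster_radius_inter
    )

    intra_sites = sites[sites["klass"] == "distal_cis"]
    intra_scores = window_zscores(intra_sites, params.intra_half_width, layout)
    intra_scores = permutation_fdr(
        intra_scores, layout, params.intra_half_width, params.n_perm, params.seed + 1
    )
    intra_domains = cluster_domains(
        intra_scores, params.fdr_intra, params.cluster_radius_intra
    )
    return SonicationResult(
        tally, junctions, sites_raw, sites, trans_scores, trans_domains, intra_scores, intra_domains
    )


@dataclass
class EnzymeResult:
    n_reads: int
    n_primer_matched: int
    n_unassigned: int
    ligated: object  # LigatedSiteCounts
    inter_scores: pd.DataFrame
    inter_domains: pd.DataFrame
    intra_scores: pd.DataFrame
    intra_domains: pd.DataFrame


def run_enzyme(
    reads: list[tuple[str, str]],
    genome: dict[str, str],
    primer: str,
    params: EnzymeParams = EnzymeParams(),
) -> EnzymeResult:
    """Full enzyme-mode analysis of primer-anchored reads over a genome."""
    from .enzyme import (
        assign_to_restriction_sites,
        build_restriction_map,
        parse_primer_anchored_reads,
        place_reads_exact,
    )

    rmap = build_restriction_map(genome, params.motif)
    trimmed, _discarded = parse_primer_anchored_reads(
        reads, primer, params.max_primer_mismatches
    )
    alignments = place_reads_exact(trimmed, genome)
    ligated, unassigned = assign_to_restriction_sites(alignments, rmap, params.site_tolerance)

    inter = enzyme_inter_scores(ligated, params.sites_per_segment)
    inter = enzyme_permutation_fdr(
        inter,
        ligated,
        params.n_perm,
        params.seed,
        mode="inter",
        sites_per_segment=params.sites_per_segment,
    )
    inter_domains = cluster_domains(inter, params.fdr_inter, params.cluster_radius_inter)

    intra = enzyme_intra_scores(
        ligated, params.intra_window_sites, params.intra_background_sites
    )
    intra = enzyme_permutation_fdr(
        intra,
        ligated,
        params.n_perm,
        params.seed + 1,
        mode="intra",
        window_sites=params.intra_window_sites,
        background_sites=params.intra_background_sites,
    )
    intra_domains = cluster_domains(intra, params.fdr_intra, params.cluster_radius_intra)
    return EnzymeResult(
        len(reads), len(trimmed), unassigned, ligated, inter, inter_domains, intra, intra_domains
    )


def compare_domains(domains_a: pd.DataFrame, domains_b: pd.DataFrame) -> dict:
    """Replicate/method overlap of enriched domains (>= 1 bp intersection).

    Reports counts from both directions plus the Venn-style breakdown used
    for replicate-overlap figures.
    """

    def overlaps(row, other: pd.DataFrame) -> bool:
        sub = other[other["chrom"] == row.chrom]
        return bool(((sub["start"] < row.end) & (row.start < sub["end"])).any())

    a_hits = sum(overlaps(r, domains_b) for r in domains_a.itertuples(index=False))
    b_hits = sum(overlaps(r, domains_a) for r in domains_b.itertuples(index=False))
    return {
        "a_total": len(domains_a),
        "b_total": len(domains_b),
        "a_overlapping_b": int(a_hits),
        "b_overlapping_a": int(b_hits),
        "a_only": len(domains_a) - int(a_hits),
        "b_only": len(domains_b) - int(b_hits),
    }


def _domains_to_table(domains: pd.DataFrame) -> pd.DataFrame:
    out = domains.drop(columns=["members"]).copy()
    return out


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def sonication_report(result: SonicationResult, seed: int) -> dict:
    """JSON-ready summary whose every number traces to a stage output."""
    sites = result.sites
    report = {
        "mode": "sonication",
        "seed": seed,
        "category_tally": result.tally.as_dict(),
        "n_sites_raw": len(result.sites_raw),
        "n_sites_filtered": len(sites),
        "n_sites_trans": int((sites["klass"] == "trans").sum()),
        "n_sites_distal_cis": int((sites["klass"] == "distal_cis").sum()),
        "n_trans_domains": len(result.trans_domains),
        "n_intra_domains": len(result.intra_domains),
    }
    report["config_hash"] = _config_hash(report)
    return report


def write_sonication_artifacts(
    result: SonicationResult, out_dir: str | Path, seed: int = 0
) -> dict:
    """Write sites (BED), scores (TSV), domains (TSV) and the JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_sites_bed(result.sites, out / "sites.bed")
    io.write_tsv(
        pd.DataFrame([result.tally.as_dict()]).T.reset_index().set_axis(
            ["category", "count"], axis=1
        ),
        out / "category_tally.tsv",
    )
    io.write_tsv(result.trans_scores, out / "trans_scores.tsv")
    io.write_tsv(_domains_to_table(result.trans_domains), out / "trans_domains.tsv")
    io.write_tsv(result.intra_scores, out / "intra_scores.tsv")
    io.write_tsv(_domains_to_table(result.intra_domains), out / "intra_domains.tsv")
    report = sonication_report(result, seed)
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report


def run_sonication_files(
    tags_path: str | Path,
    chrom_sizes: str | Path,
    bait_chrom: str,
    primer_fwd: int,
    primer_rev: int,
    out_dir: str | Path,
    params: SonicationParams = SonicationParams(),
) -> dict:
    """File-level sonication pipeline: read inputs, run, write artifacts."""
    for p in (tags_path, chrom_sizes):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    layout = GenomeLayout.from_chrom_sizes(chrom_sizes)
    bait = BaitRegion.from_primers(bait_chrom, primer_fwd, primer_rev, layout)
    tags = io.read_tag_alignments(tags_path)
    result = run_sonication(tags, bait, layout, params)
    return write_sonication_artifacts(result, out_dir, params.seed)
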