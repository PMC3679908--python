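"""Replicate-concordance metrics and sequencing-depth titration.

Reproducibility of inter-chromosomal interactions between biological
replicates is measured two ways: the Pearson correlation of per-bin site
counts (2 Mb bins by default, roughly the span of 500 six-cutter sites;
1 Mb / 500 kb and 250 / 125-site variants probe resolution), and *coverage*
— the fraction of one replicate's sites lying within 10 kb of the other's.
The depth titration subsamples read pairs at a ladder of fractions and
reruns the full site-calling pipeline at each depth, tracing how both
metrics saturate with sequencing depth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enzyme import LigatedSiteCounts
from .genome import BaitRegion, GenomeLayout
from .sonication import call_junction_reads, filter_singletons, merge_into_sites

TITRATION_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 0.90, 1.00)


@dataclass
class BinnedTrack:
    """Per-bin site counts; bins tile each chromosome exactly (last bin short)."""

    mode: str  # "bp_bins" | "restriction_site_bins"
    bin_size: int
    values: dict[str, np.ndarray]

    def concatenated(self, exclude: Sequence[str] = ()) -> np.ndarray:
        skip = set(exclude)
        parts = [v for c, v in self.values.items() if c not in skip]
        return np.concatenate(parts) if parts else np.array([])

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.values.values()))


def bin_sites(
    sites: pd.DataFrame | Mapping[str, np.ndarray] | LigatedSiteCounts,
    layout: GenomeLayout | None = None,
    bin_size_bp: int | None = None,
    sites_per_bin: int | None = None,
) -> BinnedTrack:
    """Count interacting sites per genomic bin.

    Base-pair mode (``bin_size_bp``, e.g. 2 Mb / 1 Mb / 500 kb) bins site
    positions over a :class:`GenomeLayout`; restriction-site mode
    (``sites_per_bin``, e.g. 500 / 250 / 125) bins distinct ligated sites of
    a :class:`LigatedSiteCounts` by site ordinal.
    """
    if isinstance(sites, LigatedSiteCounts):
        if sites_per_bin is None:
            raise ValueError("sites_per_bin required for ligated-site input")
        from .enzyme import segment_counts

        seg = segment_counts(sites, sites_per_bin)
        return BinnedTrack("restriction_site_bins", sites_per_bin, seg)

    if bin_size_bp is None or layout is None:
        raise ValueError("bin_size_bp and layout required for positional input")
    if isinstance(sites, pd.DataFrame):
        from .stats import positions_by_chrom

        sites = positions_by_chrom(sites)
    values: dict[str, np.ndarray] = {}
    for chrom, L in layout:
        n_bins = -(-L // bin_size_bp)
        counts = np.zeros(n_bins, dtype=int)
        if chrom in sites and len(sites[chrom]):
            idx = np.asarray(sites[chrom]) // bin_size_bp
            np.add.at(counts, idx, 1)
        values[chrom] = counts
    return BinnedTrack("bp_bins", bin_size_bp, values)


def track_correlation(
    a: BinnedTrack,
    b: BinnedTrack,
    scope: str = "all",
    bait_chrom: str | None = None,
) -> float:
    """Pearson correlation of two binned tracks.

    ``scope="trans_only"`` drops every bin on the bait chromosome (the
    inter-chromosomal analysis concerns the other chromosomes). Returns NaN
    when either track is constant (correlation undefined) rather than
    fabricating concordance.
    """
    if a.mode != b.mode or a.bin_size != b.bin_size or list(a.values) != list(b.values):
        raise ValueError("tracks have mismatched binning")
    exclude: tuple[str, ...] = ()
    if scope == "trans_only":
        if bait_chrom is None:
            raise ValueError("trans_only scope requires bait_chrom")
        exclude = (bait_chrom,)
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    x, y = a.concatenated(exclude), b.concatenated(exclude)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def site_coverage(
    reference: pd.DataFrame, query: pd.DataFrame, radius: int = 10_000
) -> float:
    """Fraction of query sites within ``radius`` of a reference site.

    Proximity is measured between representative positions on the same
    chromosome; the metric is asymmetric (query against reference). NaN for
    an empty query.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if len(query) == 0:
        return float("nan")
    from .stats import positions_by_chrom

    ref = positions_by_chrom(reference)
    hits = 0
    for chrom, grp in query.groupby("chrom", sort=False):
        qpos = grp["rep_pos"].to_numpy()
        if chrom not in ref:
            continue
        rpos = ref[chrom]
        idx = np.searchsorted(rpos, qpos)
        left = np.abs(qpos - rpos[np.clip(idx - 1, 0, len(rpos) - 1)])
        right = np.abs(qpos - rpos[np.clip(idx, 0, len(rpos) - 1)])
        hits += int((np.minimum(left, right) <= radius).sum())
    return hits / len(query)


def _call_sites(
    tags: pd.DataFrame,
    bait: BaitRegion,
    layout: GenomeLayout,
    merge_gap: int = 100,
    min_support: int = 2,
) -> pd.DataFrame:
    junctions, _ = call_junction_reads(tags, bait, layout)
    distal = junctions[junctions["klass"] != "proximal"]
    return filter_singletons(merge_into_sites(distal, merge_gap), min_support)


def subsample_read_pairs(tags: pd.DataFrame, fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Keep a round(f * n) subset of read pairs, without replacement."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return tags
    ids = tags["read_id"].unique()
    size = round(fraction * len(ids))
    keep = set(rng.choice(ids, size=size, replace=False))
    return tags[tags["read_id"].isin(keep)].reset_index(drop=True)


def depth_titration(
    tags_br1: pd.DataFrame,
    tags_br2: pd.DataFrame,
    bait: BaitRegion,
    layout: GenomeLayout,
    fractions: Sequence[float] = TITRATION_FRACTIONS,
    seed: int = 0,
    bin_size_bp: int = 2_000_000,
    coverage_radius: int = 10_000,
) -> pd.DataFrame:
    """Subsample read pairs of both replicates and re-derive concordance.

    For each fraction f, round(f * n) read pairs are drawn without
    replacement (deterministically per seed and fraction, so duplicate
    collapse and the singleton filter respond to depth), junction calling
    and site merging are rerun, and the 2 Mb-bin trans Pearson correlation
    plus both coverage directions are reported.
    """
    rows = []
    for i, f in enumerate(fractions):
        rng1 = np.random.default_rng([seed, i, 1])
        rng2 = np.random.default_rng([seed, i, 2])
        s1 = _call_sites(subsample_read_pairs(tags_br1, f, rng1), bait, layout)
        s2 = _call_sites(subsample_read_pairs(tags_br2, f, rng2), bait, layout)
        t1 = bin_sites(s1, layout, bin_size_bp=bin_size_bp)
        t2 = bin_sites(s2, layout, bin_size_bp=bin_size_bp)
        r = track_correlation(t1, t2, scope="trans_only", bait_chrom=bait.chrom)
        rows.append(
            (
                f,
                site_coverage(s1, s2, coverage_radius),
                site_coverage(s2, s1, coverage_radius),
                r,
                len(s1),
                len(s2),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fraction",
            "coverage_br2_in_br1",
            "coverage_br1_in_br2",
            "pearson_r",
            "n_sites_br1",
            "n_sites_br2",
        ],
    )
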