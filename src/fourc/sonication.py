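"""Junction-read detection for sonication-based 4C-Seq.

The library fragments sequenced from a sonication 4C experiment fall into
four categories: reads wholly inside the bait locus, reads wholly inside an
interacting region, reads spanning the ligation junction between the two,
and genomic/circular-DNA contamination. Junctions are detected by mapping a
short end tag (default 20 bp) from each mate independently: a read pair is a
junction read when one uniquely mapped tag lies inside the bait region and
the other uniquely mapped tag lies more than ``min_distance`` (300 bp) away
on the same chromosome, or on a different chromosome.

Junction reads are classified *proximal* (same chromosome, 300 bp < d <=
10 kb; dominated by self-ligation), *distal_cis* (d > 10 kb) or *trans*.
Distal tags within ``merge_gap`` (100 bp) of each other are presumed PCR
duplicates of a single ligation event and merged into one unique interacting
site; sites supported by a single read are discarded as background.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .genome import BaitRegion, GenomeLayout, UnknownChromosomeError

JUNCTION_COLUMNS = ["read_id", "bait_pos", "distal_chrom", "distal_pos", "distance", "klass"]
SITE_COLUMNS = ["chrom", "start", "end", "rep_pos", "support", "klass"]


@dataclass
class CategoryTally:
    """Counts of read pairs by category (the four library categories plus filters)."""

    bait_only: int = 0
    distal_only: int = 0
    junction_proximal: int = 0
    junction_distal_cis: int = 0
    junction_trans: int = 0
    excluded_short: int = 0
    non_unique: int = 0
    malformed: int = 0

    @property
    def junction_total(self) -> int:
        return self.junction_proximal + self.junction_distal_cis + self.junction_trans

    @property
    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_end_tags(
    read_pairs: Iterable[tuple[str, str, str]], tag_length: int = 20
) -> tuple[list[tuple[str, str, str]], int]:
    """Take the first ``tag_length`` bases of each mate as its end tag.

    ``read_pairs`` yields ``(read_id, forward_seq, reverse_seq)``. Reads
    shorter than ``tag_length`` are skipped and counted. Alignment of the
    tags is delegated to an external aligner; this only prepares tag records
    and is bypassed when pre-aligned tags are supplied.

    Returns ``(tags, n_skipped)`` with tags as ``(read_id, end_label, tag)``.
    """
    tags: list[tuple[str, str, str]] = []
    skipped = 0
    for read_id, fwd, rev in read_pairs:
        for end, seq in (("forward", fwd), ("reverse", rev)):
            if len(seq) < tag_length:
                skipped += 1
                continue
            tags.append((read_id, end, seq[:tag_length]))
    return tags, skipped


def _boundary_distance(
    chrom: np.ndarray, pos: np.ndarray, bait: BaitRegion
) -> np.ndarray:
    """Distance from positions to the nearest base of the bait region (inf trans)."""
    d = np.full(len(pos), np.inf)
    same = chrom == bait.chrom
    p = pos[same]
    d_same = np.where(
        p < bait.start,
        bait.start - p,
        np.where(p >= bait.end, p - (bait.end - 1), 0),
    ).astype(float)
    d[same] = d_same
    return d


def call_junction_reads(
    tags: pd.DataFrame,
    bait: BaitRegion,
    layout: GenomeLayout,
    min_distance: int = 300,
    proximal_max: int = 10_000,
    distance_mode: Literal["bait_boundary", "tag"] = "bait_boundary",
) -> tuple[pd.DataFrame, CategoryTally]:
    """Pair end tags by read id and call/classify junction reads.

    A pair is a junction read when exactly one uniquely mapped tag lies in
    the bait and the other uniquely mapped tag is more than ``min_distance``
    away (or on another chromosome). The junction distance ``d`` is measured
    from the bait-region boundary to the distal tag's 5' position by default
    (``distance_mode="bait_boundary"``); ``"tag"`` measures tag-to-tag.

    Returns the junction table (columns :data:`JUNCTION_COLUMNS`; distance
    is inf for trans) and a :class:`CategoryTally` in which every input pair
    is counted exactly once.
    """
    unknown = set(tags["chrom"]) - set(layout.names)
    if unknown:
        raise UnknownChromosomeError(sorted(unknown)[0])

    tally = CategoryTally()
    if tags.empty:
        return pd.DataFrame(columns=JUNCTION_COLUMNS), tally

    df = tags.sort_values(["read_id", "end"], kind="mergesort")
    sizes = df.groupby("read_id", sort=False).size()
    dup_mask = df.duplicated(subset=["read_id", "end"], keep=False)
    bad_ids = set(sizes.index[sizes != 2]) | set(df.loc[dup_mask, "read_id"])
    tally.malformed = len(bad_ids)
    good = df[~df["read_id"].isin(bad_ids)]
    if good.empty:
        return pd.DataFrame(columns=JUNCTION_COLUMNS), tally

    fwd = good[good["end"] == "forward"].set_index("read_id")
    rev = good[good["end"] == "reverse"].set_index("read_id")
    rev = rev.loc[fwd.index]  # same ids by construction

    def in_bait(side: pd.DataFrame) -> np.ndarray:
        return (
            (side["chrom"].to_numpy() == bait.chrom)
            & (side["pos"].to_numpy() >= bait.start)
            & (side["pos"].to_numpy() < bait.end)
        )

    uniq = fwd["unique"].to_numpy() & rev["unique"].to_numpy()
    fin, rin = in_bait(fwd), in_bait(rev)

    tally.non_unique = int((~uniq).sum())
    tally.bait_only = int((uniq & fin & rin).sum())
    tally.distal_only = int((uniq & ~fin & ~rin).sum())

    cand = uniq & (fin ^ rin)
    bait_pos = np.where(fin, fwd["pos"].to_numpy(), rev["pos"].to_numpy())[cand]
    distal_chrom = np.where(fin, rev["chrom"].to_numpy(), fwd["chrom"].to_numpy())[cand]
    distal_pos = np.where(fin, rev["pos"].to_numpy(), fwd["pos"].to_numpy())[cand]
    read_ids = fwd.index.to_numpy()[cand]

    if distance_mode == "bait_boundary":
        d = _boundary_distance(distal_chrom, distal_pos, bait)
    elif distance_mode == "tag":
        d = np.where(
            distal_chrom == bait.chrom,
            np.abs(distal_pos - bait_pos).astype(float),
            np.inf,
        )
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")

    trans = distal_chrom != bait.chrom
    short = ~trans & (d <= min_distance)
    proximal = ~trans & (d > min_distance) & (d <= proximal_max)
    distal_cis = ~trans & (d > proximal_max)

    tally.excluded_short = int(short.sum())
    tally.junction_proximal = int(proximal.sum())
    tally.junction_distal_cis = int(distal_cis.sum())
    tally.junction_trans = int(trans.sum())

    klass = np.select(
        [trans, distal_cis, proximal], ["trans", "distal_cis", "proximal"], default=""
    )
    keep = trans | distal_cis | proximal
    junctions = pd.DataFrame(
        {
            "read_id": read_ids[keep],
            "bait_pos": bait_pos[keep].astype(int),
            "distal_chrom": distal_chrom[keep],
            "distal_pos": distal_pos[keep].astype(int),
            "distance": d[keep],
            "klass": klass[keep],
        }
    ).sort_values(["distal_chrom", "distal_pos", "read_id"], kind="mergesort")
    return junctions.reset_index(drop=True), tally


def merge_into_sites(junctions: pd.DataFrame, merge_gap: int = 100) -> pd.DataFrame:
    """Collapse distal junction tags into unique interacting sites.

    Single-linkage clustering per chromosome: consecutive sorted tag
    positions at most ``merge_gap`` apart join one cluster (BED merge
    semantics), each cluster becoming one site whose ``support`` is the
    number of member junction reads. Input must contain only distal_cis and
    trans junctions.
    """
    if junctions.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    if (junctions["klass"] == "proximal").any():
        raise ValueError("merge_into_sites expects only distal_cis/trans junctions")

    rows = []
    for chrom, grp in junctions.groupby("distal_chrom", sort=True):
        pos = np.sort(grp["distal_pos"].to_numpy())
        klass = grp["klass"].iloc[0]
        breaks = np.nonzero(np.diff(pos) > merge_gap)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        for s, e in zip(starts, ends):
            lo, hi = int(pos[s]), int(pos[e]) + 1
            rows.append((chrom, lo, hi, (lo + hi - 1) // 2, e - s + 1, klass))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return sites.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def filter_singletons(sites: pd.DataFrame, min_support: int = 2) -> pd.DataFrame:
    """Drop sites supported by fewer than ``min_support`` reads (default: singletons)."""
    return sites[sites["support"] >= min_support].reset_index(drop=True)


def proximal_distance_profile(
    junctions: pd.DataFrame,
    bin_width: int,
    min_distance: int = 300,
    proximal_max: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of proximal junction distances over (300 bp, 10 kb].

    Self-ligation dominates this range with a continuous decay from 300 bp
    to ~2 kb. Returns ``(counts, bin_edges)``; the total count equals the
    number of proximal junctions supplied.
    """
    prox = junctions[junctions["klass"] == "proximal"]
    n_bins = (proximal_max - min_distance) // bin_width + 1
    edges = min_distance + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(prox["distance"].to_numpy(), bins=edges)
    return counts, edges
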