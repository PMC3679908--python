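"""Synthetic 4C-Seq datasets with ground truth.

The generator emulates the statistical structure the pipeline assumes for a
sonication 4C library of a single ~1 kb bait:

* **proximal self-ligation**: junction events on the bait chromosome at
  300 bp-2 kb from the bait boundary, with a truncated-exponential distance
  decay (scale 500 bp) — the dominant junction class (~90% of junctions);
* **background distal events**: uniform over the non-bait genome (trans
  chromosomes, and the bait chromosome beyond the 10 kb proximal cutoff);
* **planted enriched domains**: intervals holding extra events at a density
  multiple of the background, the recoverable ground truth;
* **PCR duplication**: each ligation event is sequenced as a geometric
  number of read pairs whose distal tags jitter within ±50 bp, so
  duplicates always merge under the 100 bp rule;
* **noise read pairs**: bait-only pairs and genomic-contamination pairs
  (both tags outside the bait), the non-junction library categories.

Two pseudo-replicates share the planted domains but redraw all events
independently. Every read pair traces to an event id; the truth tables make
category tallies and site recovery exactly checkable. Event positions keep
guard margins (mutual separation, distance from class boundaries) so that
duplicate jitter can never move a read across a classification threshold —
round trips are exact by construction, not probabilistically.

Enzyme-mode and ChIP-Seq fixture generators cover the HindIII workflow and
the enrichment statistics. All alignments are emitted directly (no external
aligner needed); the enzyme mode emits reads over a toy genome small enough
for exact-match placement.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import PeakSet
from .genome import BaitRegion, GenomeLayout, GenomicInterval
from .io import tags_frame

EVENT_COLUMNS = ["event_id", "chrom", "pos", "klass", "origin", "n_duplicates"]


@dataclass(frozen=True)
class PlantedDomain:
    """An interval carrying ``n_events`` extra ligation events."""

    interval: GenomicInterval
    n_events: int


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the sonication-mode simulator."""

    layout: GenomeLayout
    bait: BaitRegion
    n_proximal_events: int = 4_500
    proximal_scale: float = 500.0
    proximal_min: int = 300
    proximal_decay_max: int = 2_000
    n_background_distal: int = 400
    planted_domains: tuple[PlantedDomain, ...] = ()
    duplicate_mean: float = 3.0
    duplicate_jitter: int = 50
    noise_bait_only: float = 0.30
    noise_distal_only: float = 0.05
    min_event_separation: int = 301
    proximal_cutoff: int = 10_000
    seed: int = 0

    def density_multiplier(self, domain: PlantedDomain) -> float:
        """Planted event density relative to the uniform background density."""
        bg_space = self.layout.total_length() - (self.bait.end - self.bait.start)
        bg_density = self.n_background_distal / bg_space
        return (domain.n_events / len(domain.interval)) / bg_density


@dataclass
class ReplicateTruth:
    events: pd.DataFrame
    tally: dict[str, int]


@dataclass
class SimTruth:
    planted_domains: tuple[PlantedDomain, ...]
    replicates: list[ReplicateTruth]


def default_layout() -> GenomeLayout:
    return GenomeLayout(
        [
            ("chr1", 100_000_000),
            ("chr2", 100_000_000),
            ("chr3", 100_000_000),
            ("chr4", 100_000_000),
            ("chr17", 95_000_000),
        ]
    )


def default_config(seed: int = 0, planted: bool = True) -> SimConfig:
    """The default study conditions: bait on chr17, three planted 1 Mb trans domains."""
    layout = default_layout()
    bait = BaitRegion.from_primers("chr17", 30_000_000, 30_000_200, layout)
    domains: tuple[PlantedDomain, ...] = ()
    if planted:
        domains = (
            PlantedDomain(GenomicInterval("chr1", 40_000_000, 41_000_000), 35),
            PlantedDomain(GenomicInterval("chr2", 70_000_000, 71_000_000), 35),
            PlantedDomain(GenomicInterval("chr3", 20_000_000, 21_000_000), 35),
        )
    return SimConfig(layout=layout, bait=bait, planted_domains=domains, seed=seed)


def _validate(cfg: SimConfig) -> None:
    margin = cfg.proximal_decay_max + cfg.duplicate_jitter + 1
    L_bait = cfg.layout.length(cfg.bait.chrom)
    if cfg.bait.start < margin or cfg.bait.end + margin > L_bait:
        raise ValueError("bait too close to a chromosome end for proximal events")
    guard = cfg.proximal_cutoff + cfg.duplicate_jitter + 1
    for dom in cfg.planted_domains:
        dom.interval.validate(cfg.layout)
        if dom.interval.chrom == cfg.bait.chrom:
            if dom.interval.start < cfg.bait.end + guard and dom.interval.end > cfg.bait.start - guard:
                raise ValueError(f"planted domain {dom.interval} overlaps the bait neighborhood")
    if not 0 <= cfg.noise_bait_only + cfg.noise_distal_only < 1:
        raise ValueError("noise fractions must sum to < 1")


def _truncated_exp_distances(
    n: int, rng: np.random.Generator, a: int, b: int, scale: float, floor: int
) -> np.ndarray:
    """Truncated-exponential distances on [a, b], resampled to respect ``floor``."""
    out = np.empty(n, dtype=int)
    need = np.ones(n, dtype=bool)
    z = 1.0 - np.exp(-(b - a) / scale)
    while need.any():
        u = rng.random(int(need.sum()))
        d = np.floor(a - scale * np.log(1.0 - u * z)).astype(int)
        d = np.minimum(d, b)
        out[need] = d
        need = out < floor
    return out


def _draw_separated(
    n: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    registry: dict[str, list[int]],
    chrom: str,
    separation: int,
    exclude: tuple[int, int] | None = None,
    max_tries: int = 100_000,
) -> list[int]:
    """Uniform positions in [lo, hi) kept >= separation from registered ones."""
    taken = registry.setdefault(chrom, [])
    out: list[int] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("event placement too dense for the separation constraint")
        p = int(rng.integers(lo, hi))
        if exclude is not None and exclude[0] <= p < exclude[1]:
            continue
        i = bisect.bisect_left(taken, p)
        if i > 0 and p - taken[i - 1] < separation:
            continue
        if i < len(taken) and taken[i] - p < separation:
            continue
        bisect.insort(taken, p)
        out.append(p)
    return out


def _simulate_replicate(cfg: SimConfig, rng: np.random.Generator, prefix: str):
    bait, layout = cfg.bait, cfg.layout
    jitter = cfg.duplicate_jitter
    registry: dict[str, list[int]] = {}

    ev_chrom: list[str] = []
    ev_pos: list[int] = []
    ev_klass: list[str] = []
    ev_origin: list[str] = []

    # planted domains, in config order
    for di, dom in enumerate(cfg.planted_domains):
        iv = dom.interval
        lo = max(iv.start, jitter)
        hi = min(iv.end, layout.length(iv.chrom) - jitter)
        pos = _draw_separated(
            dom.n_events, lo, hi, rng, registry, iv.chrom, cfg.min_event_separation
        )
        ev_chrom += [iv.chrom] * dom.n_events
        ev_pos += pos
        ev_klass += ["trans" if iv.chrom != bait.chrom else "distal_cis"] * dom.n_events
        ev_origin += [f"domain{di}"] * dom.n_events

    # uniform background over the non-bait genome, beyond the proximal cutoff
    guard = cfg.proximal_cutoff + jitter + 1
    chroms = list(layout.names)
    weights = np.array([layout.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=cfg.n_background_distal, p=weights)
    for i in range(cfg.n_background_distal):
        chrom = chroms[picks[i]]
        L = layout.length(chrom)
        exclude = None
        if chrom == bait.chrom:
            exclude = (bait.start - guard, bait.end + guard)
        pos = _draw_separated(
            1, jitter, L - jitter, rng, registry, chrom, cfg.min_event_separation, exclude
        )[0]
        ev_chrom.append(chrom)
        ev_pos.append(pos)
        ev_klass.append("trans" if chrom != bait.chrom else "distal_cis")
        ev_origin.append("background")

    # proximal self-ligation decay; floor keeps jittered reads above the 300 bp rule
    d = _truncated_exp_distances(
        cfg.n_proximal_events,
        rng,
        cfg.proximal_min,
        cfg.proximal_decay_max,
        cfg.proximal_scale,
        floor=cfg.proximal_min + jitter + 1,
    )
    side = rng.integers(0, 2, size=cfg.n_proximal_events)
    prox_pos = np.where(side == 0, bait.start - d, bait.end - 1 + d)
    ev_chrom += [bait.chrom] * cfg.n_proximal_events
    ev_pos += [int(p) for p in prox_pos]
    ev_klass += ["proximal"] * cfg.n_proximal_events
    ev_origin += ["proximal"] * cfg.n_proximal_events

    n_events = len(ev_pos)
    ev_chrom_a = np.array(ev_chrom)
    ev_pos_a = np.array(ev_pos)
    ev_klass_a = np.array(ev_klass)
    dup = rng.geometric(1.0 / cfg.duplicate_mean, size=n_events)

    events = pd.DataFrame(
        {
            "event_id": [f"{prefix}e{i}" for i in range(n_events)],
            "chrom": ev_chrom_a,
            "pos": ev_pos_a,
            "klass": ev_klass_a,
            "origin": ev_origin,
            "n_duplicates": dup,
        }
    )

    # expand events into read pairs
    idx = np.repeat(np.arange(n_events), dup)
    n_pairs = len(idx)
    distal_pos = ev_pos_a[idx] + rng.integers(-jitter, jitter + 1, size=n_pairs)
    bait_pos = rng.integers(bait.start, bait.end, size=n_pairs)
    bait_is_fwd = rng.integers(0, 2, size=n_pairs).astype(bool)
    strands = np.array(["+", "-"])
    read_ids = np.array(
        [f"{prefix}e{e}.{j}" for e, j in zip(idx, _dup_index(dup))], dtype=object
    )

    blocks = []
    blocks.append(
        pd.DataFrame(
            {
                "read_id": read_ids,
                "end": np.where(bait_is_fwd, "forward", "reverse"),
                "chrom": bait.chrom,
                "pos": bait_pos,
                "strand": strands[rng.integers(0, 2, size=n_pairs)],
                "unique": True,
            }
        )
    )
    blocks.append(
        pd.DataFrame(
            {
                "read_id": read_ids,
                "end": np.where(bait_is_fwd, "reverse", "forward"),
                "chrom": ev_chrom_a[idx],
                "pos": distal_pos,
                "strand": strands[rng.integers(0, 2, size=n_pairs)],
                "unique": True,
            }
        )
    )

    # noise pairs, as fractions of the total library
    f_noise = cfg.noise_bait_only + cfg.noise_distal_only
    total = round(n_pairs / (1.0 - f_noise)) if f_noise > 0 else n_pairs
    n_bait_only = round(total * cfg.noise_bait_only)
    n_distal_only = round(total * cfg.noise_distal_only)

    if n_bait_only:
        ids = np.array([f"{prefix}nb{i}" for i in range(n_bait_only)], dtype=object)
        for end in ("forward", "reverse"):
            blocks.append(
                pd.DataFrame(
                    {
                        "read_id": ids,
                        "end": end,
                        "chrom": bait.chrom,
                        "pos": rng.integers(bait.start, bait.end, size=n_bait_only),
                        "strand": strands[rng.integers(0, 2, size=n_bait_only)],
                        "unique": True,
                    }
                )
            )
    if n_distal_only:
        ids = np.array([f"{prefix}nd{i}" for i in range(n_distal_only)], dtype=object)
        c_idx = rng.choice(len(chroms), size=n_distal_only, p=weights)
        p1 = np.empty(n_distal_only, dtype=int)
        for i in range(n_distal_only):
            chrom = chroms[c_idx[i]]
            L = layout.length(chrom)
            while True:
                p = int(rng.integers(0, L - 300))
                if not bait.contains(chrom, p) and not bait.contains(chrom, p + 299):
                    break
            p1[i] = p
        offset = rng.integers(0, 200, size=n_distal_only)
        for end, pos in (("forward", p1), ("reverse", p1 + offset)):
            blocks.append(
                pd.DataFrame(
                    {
                        "read_id": ids,
                        "end": end,
                        "chrom": np.array(chroms, dtype=object)[c_idx],
                        "pos": pos,
                        "strand": strands[rng.integers(0, 2, size=n_distal_only)],
                        "unique": True,
                    }
                )
            )

    tags = pd.concat(blocks, ignore_index=True)
    tags["pos"] = tags["pos"].astype(int)

    tally = {
        "bait_only": n_bait_only,
        "distal_only": n_distal_only,
        "junction_proximal": int(dup[ev_klass_a == "proximal"].sum()),
        "junction_distal_cis": int(dup[ev_klass_a == "distal_cis"].sum()),
        "junction_trans": int(dup[ev_klass_a == "trans"].sum()),
        "excluded_short": 0,
        "non_unique": 0,
        "malformed": 0,
    }
    return tags, ReplicateTruth(events=events, tally=tally)


def _dup_index(dup_counts: np.ndarray) -> np.ndarray:
    """0..k-1 within each event's duplicate block."""
    if len(dup_counts) == 0:
        return np.array([], dtype=int)
    total = int(dup_counts.sum())
    out = np.arange(total)
    starts = np.repeat(np.concatenate(([0], np.cumsum(dup_counts)[:-1])), dup_counts)
    return out - starts


def simulate_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Two pseudo-replicate tag-alignment sets plus ground truth.

    Replicates share the planted domains but draw all events independently;
    bit-reproducible for a given config (including its seed).
    """
    _validate(cfg)
    tags1, truth1 = _simulate_replicate(cfg, np.random.default_rng([cfg.seed, 1]), "r1")
    tags2, truth2 = _simulate_replicate(cfg, np.random.default_rng([cfg.seed, 2]), "r2")
    return tags1, tags2, SimTruth(cfg.planted_domains, [truth1, truth2])


# ---------------------------------------------------------------------------
# enzyme mode


@dataclass(frozen=True)
class EnzymeSimConfig:
    """Study conditions for the enzyme-mode (HindIII) simulator."""

    chrom_sites: tuple[tuple[str, int], ...] = (("chr17", 1_200), ("chr3", 800))
    spacing: tuple[int, int] = (250, 600)  # spacer length range between sites
    motif: str = "AAGCTT"
    primer: str = "GTTAGCCTAGGT"
    read_tail: int = 30  # post-primer bases, starting at the ligated site
    ligated_fraction: float = 0.10
    reads_per_site_mean: float = 2.0
    n_contaminants: int = 100
    planted_clusters: tuple[tuple[str, int, int], ...] = ()  # (chrom, start ordinal, n sites)
    seed: int = 0


@dataclass
class EnzymeTruth:
    ligated: dict[str, np.ndarray]  # local ordinals chosen per chromosome
    reads_per_site: dict[str, np.ndarray]  # aligned to ligated ordinals


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_enzyme_dataset(
    cfg: EnzymeSimConfig,
) -> tuple[list[tuple[str, str]], dict[str, str], EnzymeTruth]:
    """Primer-prefixed FASTQ-style reads over a toy genome, with truth.

    The toy genome plants the restriction motif at randomized spacings (a
    few hundred bp); reads for chosen ligated sites are the primer followed
    by ``read_tail`` genomic bases starting at the site. Contaminant reads
    (no primer) are appended. Sites whose tail sequence is not unique in the
    genome are never chosen, so exact-match placement recovers the truth
    set exactly.
    """
    from .enzyme import build_restriction_map

    rng = np.random.default_rng(cfg.seed)
    if not cfg.motif or set(cfg.motif.upper()) - set("ACGT"):
        raise ValueError("motif must be ACGT text")

    genome: dict[str, str] = {}
    for chrom, n_sites in cfg.chrom_sites:
        parts = []
        for _ in range(n_sites):
            parts.append(_random_sequence(int(rng.integers(*cfg.spacing)), rng))
            parts.append(cfg.motif)
        parts.append(_random_sequence(int(rng.integers(*cfg.spacing)), rng))
        genome[chrom] = "".join(parts)

    rmap = build_restriction_map(genome, cfg.motif)
    if rmap.total_sites == 0:
        raise ValueError("motif absent from the toy genome")

    ligated: dict[str, np.ndarray] = {}
    reads_per_site: dict[str, np.ndarray] = {}
    reads: list[tuple[str, str]] = []
    counter = 0
    for chrom in rmap.chromosomes():
        sites = rmap.sites[chrom]
        L = len(genome[chrom])
        usable = [
            i
            for i, p in enumerate(sites)
            if p + cfg.read_tail <= L
            and sum(g.count(genome[chrom][p : p + cfg.read_tail]) for g in genome.values()) == 1
        ]
        chosen: list[int] = []
        for cchrom, start_ord, n_in in cfg.planted_clusters:
            if cchrom == chrom:
                chosen += [i for i in range(start_ord, start_ord + n_in) if i in set(usable)]
        n_bg = round(cfg.ligated_fraction * len(sites))
        pool = [i for i in usable if i not in set(chosen)]
        chosen += list(rng.choice(pool, size=min(n_bg, len(pool)), replace=False))
        chosen = sorted(set(chosen))
        k = rng.geometric(1.0 / cfg.reads_per_site_mean, size=len(chosen))
        for ordinal, nreads in zip(chosen, k):
            p = sites[ordinal]
            tail = genome[chrom][p : p + cfg.read_tail]
            for _ in range(int(nreads)):
                reads.append((f"lig{counter}", cfg.primer + tail))
                counter += 1
        ligated[chrom] = np.array(chosen, dtype=int)
        reads_per_site[chrom] = k.astype(int)

    for i in range(cfg.n_contaminants):
        seq = _random_sequence(len(cfg.primer) + cfg.read_tail, rng)
        if seq.startswith(cfg.primer):
            alt = "A" if seq[0] != "A" else "C"
            seq = alt + seq[1:]
        reads.append((f"cont{i}", seq))

    return reads, genome, EnzymeTruth(ligated, reads_per_site)


# ---------------------------------------------------------------------------
# ChIP-Seq fixtures


def simulate_chip_fixtures(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    multiplier: float,
    n_tags: int = 100_000,
    seed: int = 0,
    peak_halfwidth: int = 1_000,
    peak_fraction: float = 1.0,
    restrict_chrom: str | None = None,
    half_window: int = 1_000,
) -> tuple[PeakSet, dict[str, np.ndarray], int, dict[str, np.ndarray], int]:
    """Peaks and treatment/background tag sets around the given sites.

    Treatment tag density inside ±``half_window`` of the sites is
    ``multiplier`` times the uniform rate (multiplier 1 means treatment and
    background are statistically identical); the background is uniform.
    Both tag sets contain exactly ``n_tags`` positions. Returns
    ``(peaks, treatment_tags, treatment_total, background_tags,
    background_total)`` with tags as sorted per-chromosome arrays.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [restrict_chrom] if restrict_chrom else list(layout.names)
    lengths = np.array([layout.length(c) for c in chroms], dtype=float)
    G = lengths.sum()
    probs = lengths / G

    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["rep_pos"].to_numpy()
    in_scope = np.isin(site_chrom, chroms)
    s_chrom, s_pos = site_chrom[in_scope], site_pos[in_scope]
    A = len(s_pos) * 2 * half_window

    n_peaks = round(peak_fraction * len(s_pos))
    intervals = [
        GenomicInterval(c, max(0, p - peak_halfwidth), p + peak_halfwidth)
        for c, p in zip(s_chrom[:n_peaks], s_pos[:n_peaks])
    ]
    peaks = PeakSet.from_intervals("synthetic", intervals)

    def uniform(n: int) -> tuple[np.ndarray, np.ndarray]:
        ci = rng.choice(len(chroms), size=n, p=probs)
        pos = (rng.random(n) * lengths[ci]).astype(int)
        return ci, pos

    n_extra = round(n_tags * (multiplier - 1) * A / (G + (multiplier - 1) * A))
    n_uniform = n_tags - n_extra

    def collect(ci: np.ndarray, pos: np.ndarray, extra_c=None, extra_p=None):
        tags: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        for j, c in enumerate(chroms):
            tags[c].append(pos[ci == j])
        if extra_c is not None:
            for c in chroms:
                tags[c].append(extra_p[extra_c == c])
        return {c: np.sort(np.concatenate(v)) for c, v in tags.items()}

    ci, pos = uniform(n_uniform)
    extra_c = extra_p = None
    if n_extra:
        pick = rng.integers(0, len(s_pos), size=n_extra)
        extra_c = s_chrom[pick]
        extra_p = s_pos[pick] + rng.integers(-half_window, half_window, size=n_extra)
    treatment = collect(ci, pos, extra_c, extra_p)

    bci, bpos = uniform(n_tags)
    background = collect(bci, bpos)
    return peaks, treatment, n_tags, background, n_tags
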