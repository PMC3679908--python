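"""Enrichment statistics for interacting sites.

The null model is a uniform scatter of interacting sites along each
chromosome: random collision of the bait with chromatin should produce
sites at a density proportional to chromosome length. For every interacting
site *i* on chromosome W (length ``L_W``, holding ``n_W`` sites), the number
of sites within a window of half-width ``h`` around the site (its possibly
end-truncated length ``l``) is counted as ``C``; with expectation
``mu = n_W * l / L_W`` and per-base success probability ``p = mu / l``, the
enrichment score is::

    z = (C - mu) / sqrt(mu * (1 - p))

Significance is assigned by an empirical permutation FDR: site positions
are redrawn uniformly per chromosome (100 permutations by default), z is
recomputed at the permuted sites, and the FDR at an observed z is the mean
number of permuted z-scores at least as large, divided by the number of
observed z-scores at least as large, step-up monotonized over descending z.
Sites passing the FDR threshold (5% inter-chromosomal, 20% intra) seed
enriched interacting domains: all sites within the clustering radius of a
positive site are grouped, and overlapping domains are merged.

Enzyme-mode variants score segments of 500 restriction sites (inter) or
sliding 100-site windows against a 3,000-site local background (intra),
with the same z formula in restriction-site units.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .enzyme import LigatedSiteCounts, segment_sizes
from .genome import GenomeLayout

SCORE_COLUMNS = ["chrom", "pos", "C", "mu", "p", "z", "q"]
DOMAIN_COLUMNS = ["chrom", "start", "end", "n_members", "n_positive", "min_q", "members"]


def positions_by_chrom(sites: pd.DataFrame, pos_col: str = "rep_pos") -> dict[str, np.ndarray]:
    """Sorted per-chromosome position arrays from a site table."""
    return {
        chrom: np.sort(grp[pos_col].to_numpy())
        for chrom, grp in sites.groupby("chrom", sort=True)
    }


def _window_stats(
    pos: np.ndarray, anchors: np.ndarray, L: int, half_width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Counts and moments for windows of +/- half_width around each anchor.

    Windows are truncated at chromosome ends; ``l`` is the actual number of
    bases covered, so expectations are not deflated at the edges. The focal
    site itself is included in ``C``.
    """
    n = len(pos)
    lo = np.maximum(0, anchors - half_width)
    hi = np.minimum(L - 1, anchors + half_width)
    l = (hi - lo + 1).astype(float)
    C = np.searchsorted(pos, hi, side="right") - np.searchsorted(pos, lo, side="left")
    mu = n * l / L
    p = mu / l
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mu > 0, (C - mu) / np.sqrt(mu * (1 - p)), np.nan)
    return C.astype(int), mu, p, z


def window_zscores(
    sites: Mapping[str, np.ndarray] | pd.DataFrame,
    half_width: int,
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Per-site window z-scores (half_width 1 Mb inter, 200 kb intra).

    ``sites`` is either a site table (``chrom``/``rep_pos`` columns) or a
    mapping of chromosome name to sorted positions. Chromosomes with no
    sites are skipped. Returns a frame with :data:`SCORE_COLUMNS` (q unset).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if isinstance(sites, pd.DataFrame):
        sites = positions_by_chrom(sites)
    frames = []
    for chrom in layout.names:
        if chrom not in sites or len(sites[chrom]) == 0:
            continue
        pos = np.sort(np.asarray(sites[chrom]))
        L = layout.length(chrom)
        C, mu, p, z = _window_stats(pos, pos, L, half_width)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "C": C, "mu": mu, "p": p, "z": z, "q": np.nan}
            )
        )
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def empirical_fdr(obs_z: np.ndarray, null_z: np.ndarray, n_perm: int) -> np.ndarray:
    """Empirical FDR of each observed z against a pooled permutation null.

    raw FDR at z_i = (mean permuted z-scores >= z_i per permutation) /
    (observed z-scores >= z_i), capped at 1, then step-up monotonized over
    descending z (q at rank k = min raw FDR at rank >= k).
    """
    obs_z = np.asarray(obs_z, dtype=float)
    null_sorted = np.sort(np.asarray(null_z, dtype=float))
    null_ge = (len(null_sorted) - np.searchsorted(null_sorted, obs_z, side="left")) / n_perm
    obs_sorted = np.sort(obs_z)
    obs_ge = len(obs_z) - np.searchsorted(obs_sorted, obs_z, side="left")
    raw = np.minimum(1.0, null_ge / obs_ge)
    order = np.argsort(-obs_z, kind="stable")
    raw_desc = raw[order]
    q_desc = np.minimum.accumulate(raw_desc[::-1])[::-1]
    q = np.empty_like(raw)
    q[order] = q_desc
    return q


def _attach_q(scores: pd.DataFrame, null_by_chrom: Mapping[str, np.ndarray], n_perm: int) -> pd.DataFrame:
    scores = scores.copy()
    q = np.full(len(scores), np.nan)
    for chrom, grp in scores.groupby("chrom", sort=False):
        z = grp["z"].to_numpy()
        valid = ~np.isnan(z)
        if valid.any() and chrom in null_by_chrom:
            qs = np.full(len(z), np.nan)
            qs[valid] = empirical_fdr(z[valid], null_by_chrom[chrom], n_perm)
            q[grp.index.to_numpy()] = qs
    scores["q"] = q
    return scores


def permutation_fdr(
    scores: pd.DataFrame,
    layout: GenomeLayout,
    half_width: int,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach permutation FDR values to window z-scores.

    Per chromosome, each permutation redraws the same number of site
    positions uniformly over the chromosome and recomputes z at every
    permuted site; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    null_by_chrom: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        grp = scores[scores["chrom"] == chrom]
        n = len(grp)
        if n == 0:
            continue
        L = layout.length(chrom)
        null = np.empty(n_perm * n)
        for k in range(n_perm):
            pos = np.sort(rng.integers(0, L, size=n))
            _, _, _, z = _window_stats(pos, pos, L, half_width)
            null[k * n : (k + 1) * n] = z
        null_by_chrom[chrom] = null
    return _attach_q(scores, null_by_chrom, n_perm)


def select_positive_sites(scores: pd.DataFrame, fdr_threshold: float) -> pd.DataFrame:
    """Sites whose permutation FDR is at most the threshold (5% inter / 20% intra)."""
    return scores[scores["q"] <= fdr_threshold].reset_index(drop=True)


def cluster_domains(
    scores: pd.DataFrame, fdr_threshold: float, cluster_radius: int
) -> pd.DataFrame:
    """Group sites around FDR-positive sites into enriched interacting domains.

    Every site within ``cluster_radius`` of a positive site joins that
    site's domain; overlapping domains on a chromosome are merged
    transitively. The domain span covers all member sites (half-open).
    Returns :data:`DOMAIN_COLUMNS` with ``members`` a tuple of positions.
    """
    rows = []
    for chrom, grp in scores.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        q = grp["q"].to_numpy()[order]
        pmask = q <= fdr_threshold
        if not pmask.any():
            continue
        intervals = []
        for p in pos[pmask]:
            members = pos[(pos >= p - cluster_radius) & (pos <= p + cluster_radius)]
            intervals.append((int(members.min()), int(members.max()) + 1))
        intervals.sort()
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = (pos >= s) & (pos < e)
            rows.append(
                (
                    chrom,
                    s,
                    e,
                    int(inside.sum()),
                    int((inside & pmask).sum()),
                    float(np.nanmin(q[inside])),
                    tuple(int(x) for x in pos[inside]),
                )
            )
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def enzyme_inter_scores(
    ligated: LigatedSiteCounts, sites_per_segment: int = 500
) -> pd.DataFrame:
    """Segment z-scores for enzyme-mode inter-chromosomal interactions.

    Each chromosome's restriction sites are cut into consecutive runs of
    ``sites_per_segment``; C is the number of distinct ligated sites in a
    segment, the expectation is the chromosome's ligated-site total scaled
    by the segment's share of its restriction sites. ``pos`` anchors a
    segment at its first restriction site.
    """
    from .enzyme import segment_counts

    seg = segment_counts(ligated, sites_per_segment)
    sizes = segment_sizes(ligated.rmap, sites_per_segment)
    rows = []
    for chrom in ligated.rmap.chromosomes():
        n_sites = ligated.rmap.n_sites(chrom)
        total = ligated.n_ligated(chrom)
        site_pos = ligated.rmap.sites[chrom]
        for i, (C, l) in enumerate(zip(seg[chrom], sizes[chrom])):
            mu = total * l / n_sites if n_sites else 0.0
            p = mu / l
            z = (C - mu) / np.sqrt(mu * (1 - p)) if mu > 0 else np.nan
            rows.append(
                (chrom, int(site_pos[i * sites_per_segment]), int(C), mu, p, z, np.nan)
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def _sliding_ordinal_stats(
    mask: np.ndarray, window_sites: int, background_sites: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """C, mu, p, z per restriction-site ordinal for the sliding intra model."""
    n = len(mask)
    csum = np.concatenate(([0], np.cumsum(mask.astype(int))))
    idx = np.arange(n)

    def window(width: int) -> tuple[np.ndarray, np.ndarray]:
        # centered on the anchor, truncated at chromosome ends
        lo = np.maximum(0, idx - width // 2)
        hi = np.minimum(n, idx + (width - width // 2))
        return csum[hi] - csum[lo], (hi - lo).astype(float)

    C, w_actual = window(window_sites)
    bgC, bg_actual = window(background_sites)
    mu = bgC * w_actual / bg_actual
    p = mu / w_actual
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mu > 0, (C - mu) / np.sqrt(mu * (1 - p)), np.nan)
    return C.astype(int), mu, p, z


def enzyme_intra_scores(
    ligated: LigatedSiteCounts, window_sites: int = 100, background_sites: int = 3000
) -> pd.DataFrame:
    """Sliding-window z-scores for enzyme-mode intra-chromosomal interactions.

    For each restriction-site ordinal: C = ligated sites among the
    ``window_sites`` sites centered on the anchor; the expectation comes
    from the ``background_sites`` centered sites (both windows truncated at
    chromosome ends, expectations scaled by actual window sizes).
    """
    if background_sites < window_sites:
        raise ValueError("background_sites must be >= window_sites")
    rows = []
    for chrom in ligated.rmap.chromosomes():
        mask = ligated.ligated_mask(chrom)
        if len(mask) == 0:
            continue
        C, mu, p, z = _sliding_ordinal_stats(mask, window_sites, background_sites)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": ligated.rmap.sites[chrom],
                    "C": C,
                    "mu": mu,
                    "p": p,
                    "z": z,
                    "q": np.nan,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def enzyme_permutation_fdr(
    scores: pd.DataFrame,
    ligated: LigatedSiteCounts,
    n_perm: int = 100,
    seed: int = 0,
    mode: str = "inter",
    sites_per_segment: int = 500,
    window_sites: int = 100,
    background_sites: int = 3000,
) -> pd.DataFrame:
    """Permutation FDR for enzyme-mode scores via uniform redraw of ligated ordinals.

    Each permutation redraws, per chromosome, the same number of ligated
    ordinals uniformly without replacement among that chromosome's
    restriction sites and recomputes the z statistic.
    """
    rng = np.random.default_rng(seed)
    null_by_chrom: dict[str, np.ndarray] = {}
    for chrom in ligated.rmap.chromosomes():
        n_sites = ligated.rmap.n_sites(chrom)
        k = ligated.n_ligated(chrom)
        if n_sites == 0 or k == 0:
            continue
        nulls = []
        for _ in range(n_perm):
            mask = np.zeros(n_sites, dtype=bool)
            mask[rng.choice(n_sites, size=k, replace=False)] = True
            if mode == "inter":
                # direct segment recount on the permuted mask
                n_seg = -(-n_sites // sites_per_segment)
                seg = np.array(
                    [
                        mask[i * sites_per_segment : (i + 1) * sites_per_segment].sum()
                        for i in range(n_seg)
                    ]
                )
                sizes = np.full(n_seg, sites_per_segment)
                if n_sites % sites_per_segment:
                    sizes[-1] = n_sites % sites_per_segment
                mu = k * sizes / n_sites
                p = mu / sizes
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.where(mu > 0, (seg - mu) / np.sqrt(mu * (1 - p)), np.nan)
            else:
                _, _, _, z = _sliding_ordinal_stats(mask, window_sites, background_sites)
            nulls.append(z[~np.isnan(z)])
        null_by_chrom[chrom] = np.concatenate(nulls) if nulls else np.array([])
    return _attach_q(scores, null_by_chrom, n_perm)
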