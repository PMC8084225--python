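"""Quantile schemes and per-tree derived quantities.

All subdivisions of the data are equal-count ("equal quantiles") so every bin
carries the same statistical power: focal-tree size quartiles within species,
annular-biomass quintiles, phylogenetic-distance quantiles over species pairs
(with tie shuffling across replicates), within-stratum normalized growth
rates, and the small/large median split of annular trees that die.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "basal_area",
    "equal_count_bins",
    "focal_size_quantiles",
    "annular_biomass_quintiles",
    "PhyloBinning",
    "phylo_quantiles",
    "normalized_growth",
    "split_dead_small_large",
]


def basal_area(stem_dbhs) -> float:
    """Summed cross-sectional area (cm^2) at 1.3 m: sum of pi*(d/2)^2 over stems."""
    total = 0.0
    for d in stem_dbhs:
        if d < 0:
            raise ValueError(f"negative dbh {d}")
        total += math.pi * (d / 2.0) ** 2
    return total


def equal_count_bins(values: np.ndarray, n_bins: int, rng=None) -> np.ndarray:
    """Equal-count bin ids (0..n_bins-1); ties broken by rng so occupancy differs by <= 1.

    Fewer values than bins: rank-based assignment with ties sharing the lower bin.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if n < n_bins:
        order = np.argsort(values, kind="stable")
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        # ties share the lowest rank among equal values
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            out[i] = int(np.min(ranks[values == values[i]]))
        return out
    tiebreak = rng.random(n) if rng is not None else np.zeros(n)
    order = np.lexsort((tiebreak, values))
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def focal_size_quantiles(diameters: np.ndarray, species_idx: np.ndarray,
                         n_bins: int = 4, rng=None) -> np.ndarray:
    """Within-species equal-count size bins of focal diameters (quartiles by default)."""
    diameters = np.asarray(diameters, dtype=float)
    species_idx = np.asarray(species_idx)
    out = np.empty(diameters.size, dtype=np.int64)
    for s in np.unique(species_idx):
        m = species_idx == s
        out[m] = equal_count_bins(diameters[m], n_bins, rng)
    return out


def annular_biomass_quintiles(summed_areas: np.ndarray, rng=None, n_bins: int = 5) -> np.ndarray:
    """Equal-count bins of focal-tree-level summed annular basal areas."""
    return equal_count_bins(summed_areas, n_bins, rng)


@dataclass
class PhyloBinning:
    """Replicate-specific assignment of species pairs to phylogenetic-distance quantiles."""

    n_bins: int
    bin_of_pair: np.ndarray    # (S, S) int, -1 for pairs outside the focal/annular sets
    mid_ma: np.ndarray         # (n_bins,) mean pair distance per bin
    edges_ma: np.ndarray       # (n_bins, 2) min/max pair distance per bin

    def bin_containing(self, ma: float) -> int:
        """Bin whose distance span contains ``ma`` (nearest span if between bins)."""
        lo, hi = self.edges_ma[:, 0], self.edges_ma[:, 1]
        inside = np.flatnonzero((lo <= ma) & (ma <= hi))
        if inside.size:
            return int(inside[0])
        return int(np.argmin(np.minimum(np.abs(lo - ma), np.abs(hi - ma))))


def phylo_quantiles(D: np.ndarray, n_bins: int, rng,
                    focal_species=None, annular_species=None) -> PhyloBinning:
    """Equal-count quantiles of focal-annular species-pair divergence times.

    Units are unordered species pairs (conspecific pairs included at 0 Ma).
    Pairs sharing a distance are ordered at random per replicate, so ties
    straddling a bin boundary land in adjacent bins in different replicates.
    Conspecific (0 Ma) pairs are pinned to bin 0.
    """
    D = np.asarray(D, dtype=float)
    S = D.shape[0]
    fs = np.arange(S) if focal_species is None else np.asarray(sorted(focal_species))
    as_ = np.arange(S) if annular_species is None else np.asarray(sorted(annular_species))
    ii, jj = np.meshgrid(fs, as_, indexing="ij")
    a, b = np.minimum(ii.ravel(), jj.ravel()), np.maximum(ii.ravel(), jj.ravel())
    pairs = np.unique(np.stack([a, b], axis=1), axis=0)
    dist = D[pairs[:, 0], pairs[:, 1]]
    n_pairs = pairs.shape[0]
    if n_bins < 2:
        raise ValueError("need at least 2 phylogenetic quantiles")
    if n_bins > n_pairs:
        raise ValueError(f"{n_bins} quantiles exceed {n_pairs} species pairs")

    order = np.lexsort((rng.random(n_pairs), dist))
    bins = np.empty(n_pairs, dtype=np.int64)
    bins[order] = (np.arange(n_pairs) * n_bins) // n_pairs
    bins[dist == 0.0] = 0  # conspecific anchor class, never shuffled across the first edge

    bin_of_pair = np.full((S, S), -1, dtype=np.int64)
    bin_of_pair[pairs[:, 0], pairs[:, 1]] = bins
    bin_of_pair[pairs[:, 1], pairs[:, 0]] = bins
    mid = np.zeros(n_bins)
    edges = np.zeros((n_bins, 2))
    for k in range(n_bins):
        dk = dist[bins == k]
        if dk.size:
            mid[k] = dk.mean()
            edges[k] = (dk.min(), dk.max())
    return PhyloBinning(n_bins=n_bins, bin_of_pair=bin_of_pair, mid_ma=mid, edges_ma=edges)


def normalized_growth(raw_growth: np.ndarray, species_idx: np.ndarray,
                      start_dbh: np.ndarray, n_deciles: int = 10,
                      min_stratum: int = 10, rng=None) -> np.ndarray:
    """Growth rates as SD units within (species x start-diameter decile) strata.

    Strata are within-species equal-count deciles of start-of-interval
    diameter; deciles with fewer than ``min_stratum`` trees are collapsed into
    their neighbors.  Strata of size 1 or zero spread normalize to 0.
    The result is invariant under per-species affine rescaling of the raw rates.
    """
    raw_growth = np.asarray(raw_growth, dtype=float)
    out = np.zeros(raw_growth.size)
    species_idx = np.asarray(species_idx)
    for s in np.unique(species_idx):
        m = np.flatnonzero(species_idx == s)
        n = m.size
        k = max(1, min(n_deciles, n // max(min_stratum, 1)))
        dec = equal_count_bins(start_dbh[m], k, rng)
        for d in np.unique(dec):
            idx = m[dec == d]
            g = raw_growth[idx]
            sd = g.std(ddof=0)
            if idx.size < 2 or sd == 0.0:
                out[idx] = 0.0
            else:
                out[idx] = (g - g.mean()) / sd
    return out


def split_dead_small_large(last_dbh: np.ndarray, species_idx: np.ndarray, rng=None) -> np.ndarray:
    """Median split of trees that died, per species: 0 = small, 1 = large.

    Odd counts place the median tree in the small group, so group sizes per
    species differ by at most one.
    """
    last_dbh = np.asarray(last_dbh, dtype=float)
    species_idx = np.asarray(species_idx)
    out = np.zeros(last_dbh.size, dtype=np.int64)
    for s in np.unique(species_idx):
        m = np.flatnonzero(species_idx == s)
        n = m.size
        tiebreak = rng.random(n) if rng is not None else np.zeros(n)
        order = np.lexsort((tiebreak, last_dbh[m]))
        n_small = (n + 1) // 2
        out[m[order[n_small:]]] = 1
    return out
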