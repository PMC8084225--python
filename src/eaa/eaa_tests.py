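"""The six equal-area-annulus neighborhood tests and their shuffle null models.

Each test compares an observed focal-annular statistic with a Monte Carlo null
in which one focal-tree attribute is repeatedly permuted *within species*
(within a census interval), leaving positions, species identities and all
annular properties untouched:

    1  focal survivor size   vs summed annular survivor basal area   (NDD: negative)
    2  focal survivor size   vs annular recruit fraction             (NDD: negative)
    3  focal survivor size   vs annular mortality fraction           (NDD: positive)
    4  focal growth (normalized within species) vs annular basal area (NDD: negative)
    5  focal recruits        vs annular recruit fraction             (NDD: higher)
    6  focal deaths (small/large) vs annular mortality fraction      (NDD: higher)

Cells are indexed by (annulus x phylogenetic-distance quantile x focal group).
Each census interval is analyzed in ``replicates`` tie-shuffled phylogenetic
binnings of ``iterations`` null draws each; a z-score is reported per
replicate against its own null and, pooled over all replicates' draws, as the
headline value to which Benjamini-Hochberg adjustment is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from . import binning as _binning
from . import geometry as _geometry
from .io import ALIVE, DEAD, RECRUIT, PhyloDistances, PlotArrays, PlotCensus

log = logging.getLogger(__name__)

POOLED = -1  # replicate index of pooled-null summary rows

TEST_DIRECTIONS = {1: -1, 2: -1, 3: +1, 4: -1, 5: +1, 6: +1}  # expected z sign under NDD


@dataclass
class EAAConfig:
    """Run configuration for the annulus tests."""

    total_area: float = 500.0          # m^2 spanned by the annuli around each focal tree
    n_annuli: int = 10
    n_phylo_quantiles: int = 5
    n_focal_quantiles: int = 4         # focal size quartiles (tests 1-3)
    n_biomass_quantiles: int = 5       # annular biomass quintiles (test 4)
    growth_deciles: int = 10
    replicates: int = 10               # tie-shuffled phylo binnings per census interval
    iterations: int = 100              # null draws per replicate
    alpha: float = 0.05
    edge_mode: str = "weight"          # "weight" (1/fraction_inside) or "drop"
    drop_threshold: float = 0.5
    annular_dead_subset: str = "all"   # test 3: "all", "small" or "large" annular deaths
    seed: int = 0
    tie_seed: int | None = None        # separate stream for quantile tie shuffling
    focal_species: tuple[str, ...] | None = None    # keep-lists; None = all species
    annular_species: tuple[str, ...] | None = None


@dataclass
class TestResult:
    """Long-format z-score table plus run metadata."""

    test_id: int
    table: pd.DataFrame
    config: EAAConfig
    n_undefined: int = 0

    def pooled(self) -> pd.DataFrame:
        return self.table[self.table["replicate"] == POOLED].reset_index(drop=True)

    def replicate_rows(self) -> pd.DataFrame:
        return self.table[self.table["replicate"] != POOLED].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Neighborhood tables
# ---------------------------------------------------------------------------


@dataclass
class NeighborhoodTable:
    """Edge-weighted focal x annulus x annular-species tables for one interval.

    Category tables have shape (n_focal, n_annuli, n_species); invariant
    n_rec + n_dead_small + n_dead_large + n_surv <= n_total (recruits counted
    at interval end, deaths among trees alive at the start).
    """

    focal: np.ndarray            # global tree indices of candidate focal trees
    weights: np.ndarray          # (nf, A) edge weights (NaN = dropped focal)
    ba_surv: np.ndarray          # summed basal area (cm^2) of annular survivors
    n_end: np.ndarray            # annular trees present at interval end
    n_rec: np.ndarray            # annular recruits
    n_alive0: np.ndarray         # annular trees alive at interval start
    n_dead: np.ndarray
    n_dead_small: np.ndarray
    n_dead_large: np.ndarray
    n_surv: np.ndarray
    # focal attributes (aligned with `focal`)
    species: np.ndarray
    start_dbh: np.ndarray
    is_survivor: np.ndarray
    is_present_end: np.ndarray
    is_alive_start: np.ndarray
    is_recruit_end: np.ndarray
    died_group: np.ndarray       # -1 not died, 0 small, 1 large
    raw_growth: np.ndarray       # dbh increment per interval (NaN unless survivor)
    # pair-level view (for the joint fate-relabeling nulls of tests 5/6)
    pair_f: np.ndarray = None    # local (focal-array) index of the focal member
    pair_j: np.ndarray = None    # local index of the annular member
    pair_ring: np.ndarray = None  # 0-based ring index
    pair_w: np.ndarray = None    # edge weight of (focal, ring)


def build_neighborhood(plot, D: PhyloDistances, system, census_interval: int,
                       config: EAAConfig | None = None) -> NeighborhoodTable:
    """Assemble the per-focal annular category tables for one census interval."""
    config = config or EAAConfig()
    arrays = plot if isinstance(plot, PlotArrays) else plot.arrays()
    missing = set(arrays.species_list) - set(D.species_list)
    if missing:
        raise ValueError(f"species without phylogenetic distances: {sorted(missing)}")
    c0, c1 = census_interval, census_interval + 1
    if c1 >= arrays.status.shape[0]:
        raise ValueError(f"census interval {census_interval} needs census {c1}")

    present0 = arrays.present(c0)
    present1 = arrays.present(c1)
    candidate = present0 | present1
    focal = np.flatnonzero(candidate)
    nf = focal.size
    A = system.n_annuli
    S = len(arrays.species_list)

    # neighbor categories (evaluated on all candidate trees)
    surv = present0 & present1
    rec = arrays.status[c1] == RECRUIT
    dead = present0 & (arrays.status[c1] == DEAD)
    dead_idx = np.flatnonzero(dead)
    died_group_all = np.full(arrays.xy.shape[0], -1, dtype=np.int64)
    if dead_idx.size:
        died_group_all[dead_idx] = _binning.split_dead_small_large(
            arrays.dbh[c0, dead_idx], arrays.species_idx[dead_idx])

    weights = _geometry.edge_weights(arrays.xy[focal], system, _plot_rect(plot, arrays),
                                     mode=config.edge_mode, drop_threshold=config.drop_threshold)

    nb = np.flatnonzero(candidate)
    tree = cKDTree(arrays.xy[nb])
    hits = tree.query_ball_point(arrays.xy[focal], r=system.r_max)
    f_rep = np.repeat(np.arange(nf), [len(h) for h in hits])
    j_loc = np.concatenate(hits) if nf else np.zeros(0, dtype=int)
    j_glob = nb[j_loc]
    keep = j_glob != focal[f_rep]  # a tree is never its own neighbor
    f_rep, j_glob = f_rep[keep], j_glob[keep]
    d = np.hypot(*(arrays.xy[j_glob] - arrays.xy[focal[f_rep]]).T)
    keep = d < system.r_max
    f_rep, j_glob, d = f_rep[keep], j_glob[keep], d[keep]
    ann = np.maximum(np.searchsorted(system.radii, d, side="right"), 1) - 1  # 0-based ring

    w = weights[f_rep, ann]
    sp_j = arrays.species_idx[j_glob]
    flat = (f_rep * A + ann) * S + sp_j

    def table(mask, values=None) -> np.ndarray:
        out = np.zeros(nf * A * S)
        sel = mask[j_glob]
        v = w[sel] if values is None else w[sel] * values[j_glob[sel]]
        np.add.at(out, flat[sel], v)
        return out.reshape(nf, A, S)

    alive0_mask = present0
    raw_growth = np.where(surv[focal], arrays.dbh[c1, focal] - arrays.dbh[c0, focal], np.nan)

    return NeighborhoodTable(
        focal=focal,
        weights=weights,
        ba_surv=table(surv, arrays.basal[c0]),
        n_end=table(present1),
        n_rec=table(rec),
        n_alive0=table(alive0_mask),
        n_dead=table(dead),
        n_dead_small=table(dead & (died_group_all == 0)),
        n_dead_large=table(dead & (died_group_all == 1)),
        n_surv=table(surv),
        species=arrays.species_idx[focal],
        start_dbh=arrays.dbh[c0, focal],
        is_survivor=surv[focal],
        is_present_end=present1[focal],
        is_alive_start=present0[focal],
        is_recruit_end=rec[focal],
        died_group=died_group_all[focal],
        raw_growth=raw_growth,
        pair_f=f_rep,
        pair_j=np.searchsorted(focal, j_glob),
        pair_ring=ann,
        pair_w=w,
    )


def _plot_rect(plot, arrays: PlotArrays):
    if isinstance(plot, PlotCensus):
        return plot.rect
    xy = arrays.xy
    return (0.0, 0.0, float(np.ceil(xy[:, 0].max() + 1e-9)), float(np.ceil(xy[:, 1].max() + 1e-9)))


def collapse_to_bins(table: np.ndarray, focal_species: np.ndarray,
                     bin_of_pair: np.ndarray, n_bins: int,
                     annular_mask: np.ndarray | None = None) -> np.ndarray:
    """(nf, A, S) annular-species table -> (nf, A, B) phylogenetic-bin table.

    Pairs with bin -1 are dropped; ``annular_mask`` (S,) additionally drops
    neighbor species removed from the annular set (the pair binning itself is
    symmetric in the species, removal as annular is directional).
    """
    nf, A, S = table.shape
    out = np.zeros((nf, A, n_bins))
    for s in np.unique(focal_species):
        rows = np.flatnonzero(focal_species == s)
        bins = bin_of_pair[s]
        ind = np.zeros((S, n_bins))
        ok = bins >= 0
        if annular_mask is not None:
            ok = ok & annular_mask
        ind[np.flatnonzero(ok), bins[ok]] = 1.0
        block = table[rows].reshape(rows.size * A, S) @ ind
        out[rows] = block.reshape(rows.size, A, n_bins)
    return out


# ---------------------------------------------------------------------------
# Observed statistics and null shuffles
# ---------------------------------------------------------------------------


def _onehot(labels: np.ndarray, n_groups: int) -> np.ndarray:
    return (labels[None, :] == np.arange(n_groups)[:, None]).astype(float)


def group_mean(V: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Per-group mean of per-focal cell values; NaN for empty groups."""
    counts = onehot.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (onehot @ V.reshape(V.shape[0], -1)) / counts[:, None]


def group_fraction(num: np.ndarray, den: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Pooled per-group fraction; NaN where the pooled denominator is zero."""
    n = onehot @ num.reshape(num.shape[0], -1)
    d = onehot @ den.reshape(den.shape[0], -1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d > 0, n / d, np.nan)


def within_species_permutation(species: np.ndarray, rng) -> np.ndarray:
    """A permutation of 0..n-1 that only moves indices within a species."""
    perm = np.arange(species.size)
    for s in np.unique(species):
        block = np.flatnonzero(species == s)
        perm[block] = block[rng.permutation(block.size)]
    return perm


def null_shuffle(test_id: int, attribute: np.ndarray, species: np.ndarray, rng) -> np.ndarray:
    """Shuffle the test's focal attribute within species (sizes for tests 1-3,
    normalized growth for test 4, demographic-fate labels for tests 5-6)."""
    if test_id not in TEST_DIRECTIONS:
        raise ValueError(f"unknown test id {test_id}")
    return attribute[within_species_permutation(species, rng)]


def bh_adjust(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level alpha (NaNs never rejected)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return out


# ---------------------------------------------------------------------------
# Per-test cell machinery
# ---------------------------------------------------------------------------


@dataclass
class _CellProblem:
    """Observed statistic plus a closure that evaluates one null iteration."""

    observed: np.ndarray         # (G, A, B)
    null_iteration: "callable"
    group_labels: list[str]


def _size_test_problem(test_id: int, nh: NeighborhoodTable, C: dict, config: EAAConfig,
                       focal_keep: np.ndarray, scheme_rng) -> _CellProblem | None:
    rows = np.flatnonzero(nh.is_survivor & focal_keep & ~np.isnan(nh.weights[:, 0]))
    if rows.size == 0:
        return None
    species = nh.species[rows]
    q = _binning.focal_size_quantiles(nh.start_dbh[rows], species,
                                      config.n_focal_quantiles, scheme_rng)
    G = config.n_focal_quantiles
    if test_id == 1:
        V = C["ba_surv"][rows]
        stat = lambda labels: group_mean(V, _onehot(labels, G))  # noqa: E731
    else:
        if test_id == 2:
            num, den = C["n_rec"][rows], C["n_end"][rows]
        else:
            key = {"all": "n_dead", "small": "n_dead_small", "large": "n_dead_large"}[config.annular_dead_subset]
            num, den = C[key][rows], C["n_alive0"][rows]
        stat = lambda labels: group_fraction(num, den, _onehot(labels, G))  # noqa: E731

    def null_iter(rng):
        return stat(q[within_species_permutation(species, rng)])

    return _CellProblem(observed=stat(q).reshape(G, *C["ba_surv"].shape[1:]),
                        null_iteration=lambda rng: null_iter(rng).reshape(G, *C["ba_surv"].shape[1:]),
                        group_labels=[f"size_q{i + 1}" for i in range(G)])


def _growth_test_problem(nh: NeighborhoodTable, C: dict, config: EAAConfig,
                         focal_keep: np.ndarray, scheme_rng) -> _CellProblem | None:
    surv_rows = np.flatnonzero(nh.is_survivor & focal_keep & ~np.isnan(nh.weights[:, 0]))
    if surv_rows.size == 0:
        return None
    species = nh.species[surv_rows]
    growth = _binning.normalized_growth(nh.raw_growth[surv_rows], species,
                                        nh.start_dbh[surv_rows],
                                        n_deciles=config.growth_deciles, rng=scheme_rng)
    # only the smallest size quintile of focal trees is examined
    quint = _binning.focal_size_quantiles(nh.start_dbh[surv_rows], species, 5, scheme_rng)
    small = np.flatnonzero(quint == 0)
    if small.size == 0:
        return None
    V = C["ba_surv"][surv_rows][small]          # (ns, A, B)
    g = growth[small]
    sp_small = species[small]
    ns, A, B = V.shape
    G = config.n_biomass_quantiles

    # per (annulus, bin) cell: biomass quintiles among focals with neighbors there,
    # focals with none form the comparison group
    member_masks = np.zeros((G + 1, A * B, ns))   # last slot = comparison group
    for a in range(A):
        for b in range(B):
            v = V[:, a, b]
            has = np.flatnonzero(v > 0)
            member_masks[G, a * B + b, v == 0] = 1.0
            if has.size:
                mq = _binning.annular_biomass_quintiles(v[has], scheme_rng, G)
                member_masks[mq, a * B + b, has] = 1.0
    counts = member_masks.sum(axis=2)

    def stat(gvals):
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (member_masks @ gvals) / counts
        return (means[:G] - means[G][None, :]).reshape(G, A, B)

    def null_iter(rng):
        return stat(g[within_species_permutation(sp_small, rng)])

    return _CellProblem(observed=stat(g), null_iteration=null_iter,
                        group_labels=[f"biomass_q{i + 1}" for i in range(G)])


def _fate_test_problem(test_id: int, nh: NeighborhoodTable, pair_bins: list[np.ndarray],
                       n_bins: int, n_annuli: int, focal_keep: np.ndarray,
                       annular_keep: np.ndarray | None = None) -> _CellProblem | None:
    """Tests 5/6: annular fate fractions around focal trees sharing that fate.

    The fate statistic is quadratic in the demographic labels — every tree
    appears on both the focal and the annular side — so the null relabels
    fates within species *once per draw* and re-evaluates both sides jointly
    (the "positions shuffled within species" null), at pair level.
    """
    if test_id == 5:
        pool = nh.is_present_end
        labels = nh.is_recruit_end.astype(np.int64)         # 1 = recruit
        names, groups = ["recruits"], [1]
    else:
        pool = nh.is_alive_start
        labels = np.where(nh.died_group >= 0, nh.died_group, 2)  # 0/1 dead small/large, 2 other
        names, groups = ["died_small", "died_large"], [0, 1]
    w_ok = ~np.isnan(nh.weights[:, 0])
    if not np.any(pool & focal_keep & w_ok):
        return None

    f, j = nh.pair_f, nh.pair_j
    sel_base = pool[f] & pool[j] & focal_keep[f] & w_ok[f]
    if annular_keep is not None:
        sel_base = sel_base & annular_keep[nh.species[j]]
    n_cells = n_annuli * n_bins
    cells, wts, pf, pj = [], [], [], []
    keys, wts = [], []
    for pb in pair_bins:
        sel = np.flatnonzero(sel_base & (pb >= 0))
        keys.append(sel * n_cells + nh.pair_ring[sel] * n_bins + pb[sel])
        wts.append(nh.pair_w[sel] / len(pair_bins))
    # tie shuffling moves few pairs between bins: merge duplicate (pair, cell) entries
    key = np.concatenate(keys)
    wt_all = np.concatenate(wts)
    ukey, inv = np.unique(key, return_inverse=True)
    wt = np.bincount(inv, weights=wt_all)
    orig = ukey // n_cells
    cell = (ukey % n_cells).astype(np.int64)
    ff = f[orig]
    jj = j[orig]

    pool_idx = np.flatnonzero(pool)
    species_pool = nh.species[pool_idx]

    def stat(lab):
        out = np.empty((len(groups), n_annuli, n_bins))
        lab_f, lab_j = lab[ff], lab[jj]
        j_in = (lab_j == 1) if test_id == 5 else (lab_j <= 1)
        for gi, g in enumerate(groups):
            f_in = lab_f == g
            num = np.bincount(cell, weights=wt * (f_in & j_in), minlength=n_cells)
            den = np.bincount(cell, weights=wt * f_in, minlength=n_cells)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[gi] = np.where(den > 0, num / den, np.nan).reshape(n_annuli, n_bins)
        return out

    def null_iter(rng):
        lab = labels.copy()
        perm = within_species_permutation(species_pool, rng)
        lab[pool_idx] = labels[pool_idx][perm]
        return stat(lab)

    return _CellProblem(observed=stat(labels), null_iteration=null_iter, group_labels=names)


def pair_bins_for(nh: NeighborhoodTable, binning: "_binning.PhyloBinning") -> np.ndarray:
    """Per-pair phylogenetic bin for one tie-shuffle replicate (-1 = excluded)."""
    return binning.bin_of_pair[nh.species[nh.pair_f], nh.species[nh.pair_j]]


def observed_statistic(test_id: int, nh: NeighborhoodTable, C: dict, config: EAAConfig,
                       scheme_rng=None, focal_keep: np.ndarray | None = None,
                       pair_bins=None) -> np.ndarray:
    """Observed per-cell statistic (G, n_annuli, n_phylo_bins) for one test."""
    prob = _make_problem(test_id, nh, C, config,
                         focal_keep if focal_keep is not None else np.ones(nh.focal.size, bool),
                         scheme_rng or np.random.default_rng(0), pair_bins)
    if prob is None:
        raise ValueError("empty focal set")
    return prob.observed


def _make_problem(test_id, nh, C, config, focal_keep, scheme_rng, pair_bins=None,
                  annular_keep=None):
    if test_id in (1, 2, 3):
        return _size_test_problem(test_id, nh, C, config, focal_keep, scheme_rng)
    if test_id == 4:
        return _growth_test_problem(nh, C, config, focal_keep, scheme_rng)
    if test_id in (5, 6):
        return _fate_test_problem(test_id, nh, pair_bins, config.n_phylo_quantiles,
                                  config.n_annuli, focal_keep, annular_keep)
    raise ValueError(f"unknown test id {test_id}")


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def _species_keep_mask(species_list, keep, species_idx) -> np.ndarray:
    if keep is None:
        return np.ones(species_idx.size, dtype=bool)
    keep_idx = {species_list.index(s) for s in keep}
    return np.isin(species_idx, list(keep_idx))


def run_test(test_id: int, plot, D: PhyloDistances, config: EAAConfig | None = None) -> TestResult:
    """Run one annulus test across all census intervals of a plot.

    Per census interval and tie-shuffle replicate: a fresh phylogenetic-bin
    assignment, ``iterations`` within-species shuffles, and a z-score per
    (annulus, bin, focal group) cell against that replicate's null.  Pooled
    rows (replicate -1) score the replicate-averaged observed statistic
    against all replicates' null draws and carry the BH-adjusted flags.
    """
    config = config or EAAConfig()
    arrays = plot if isinstance(plot, PlotArrays) else plot.arrays()
    n_censuses = arrays.status.shape[0]
    if n_censuses < 2:
        raise ValueError("at least two censuses are required")
    system = _geometry.build_annulus_system(config.total_area, config.n_annuli)
    if D.species_list != arrays.species_list:
        D = _reorder_distances(D, arrays.species_list)

    ss = np.random.SeedSequence([config.seed, test_id])
    null_rng = np.random.default_rng(ss.spawn(1)[0])
    tie_entropy = config.tie_seed if config.tie_seed is not None else config.seed + 10_007
    tie_rng = np.random.default_rng(np.random.SeedSequence([tie_entropy, test_id]))
    scheme_rng = np.random.default_rng(ss.spawn(2)[1])

    S = len(arrays.species_list)
    f_idx = None if config.focal_species is None else \
        sorted(arrays.species_list.index(s) for s in config.focal_species)
    a_idx = None if config.annular_species is None else \
        sorted(arrays.species_list.index(s) for s in config.annular_species)
    if f_idx is not None and len(f_idx) == 0:
        raise ValueError("focal species filter is empty")
    if a_idx is not None and len(a_idx) == 0:
        raise ValueError("annular species filter is empty")
    annular_mask = None
    if a_idx is not None:
        annular_mask = np.zeros(S, dtype=bool)
        annular_mask[a_idx] = True

    table_keys = ("ba_surv", "n_end", "n_rec", "n_alive0", "n_dead",
                  "n_dead_small", "n_dead_large")
    rows: list[pd.DataFrame] = []
    n_undef = 0
    for c in range(n_censuses - 1):
        nh = build_neighborhood(arrays, D, system, c, config)
        focal_keep = _species_keep_mask(arrays.species_list, config.focal_species, nh.species)
        C_sum: dict[str, np.ndarray] = {}
        mids = []
        all_pair_bins: list[np.ndarray] = []
        group_labels: list[str] = []
        pairwise = test_id in (5, 6)
        for rep in range(config.replicates):
            pb = _binning.phylo_quantiles(D.D, config.n_phylo_quantiles, tie_rng, f_idx, a_idx)
            C = {} if pairwise else \
                {k: collapse_to_bins(getattr(nh, k), nh.species, pb.bin_of_pair, pb.n_bins,
                                     annular_mask)
                 for k in table_keys}
            rep_pair_bins = [pair_bins_for(nh, pb)] if pairwise else None
            if pairwise:
                all_pair_bins.extend(rep_pair_bins)
            prob = _make_problem(test_id, nh, C, config, focal_keep, scheme_rng,
                                 rep_pair_bins, annular_mask)
            if prob is None:
                raise ValueError("focal set is empty for this test and interval")
            group_labels = prob.group_labels
            draws = np.stack([prob.null_iteration(null_rng) for _ in range(config.iterations)])
            null_mean = np.nanmean(draws, axis=0)
            null_sd = np.nanstd(draws, axis=0, ddof=1)
            obs = prob.observed
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (obs - null_mean) / null_sd
            defined = np.isfinite(z)
            n_undef += int((~defined).sum())
            rows.append(_to_rows(test_id, c, rep, system, pb, group_labels,
                                 obs, null_mean, null_sd, z, defined))
            if not pairwise:
                for k in table_keys:
                    C_sum[k] = C_sum.get(k, 0.0) + C[k]
            mids.append(pb.mid_ma)

        # headline z: statistic on replicate-averaged bin tables (tied pairs get
        # fractional membership) against the full replicates x iterations null,
        # pushed through the identical pipeline — exact permutation calibration
        C_bar = {k: v / config.replicates for k, v in C_sum.items()}
        prob = _make_problem(test_id, nh, C_bar, config, focal_keep, scheme_rng,
                             all_pair_bins if pairwise else None, annular_mask)
        n_pooled = config.replicates * config.iterations
        draws = np.stack([prob.null_iteration(null_rng) for _ in range(n_pooled)])
        null_mean = np.nanmean(draws, axis=0)
        null_sd = np.nanstd(draws, axis=0, ddof=1)
        pooled_obs = prob.observed
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (pooled_obs - null_mean) / null_sd
        defined = np.isfinite(z)
        p = np.where(defined, 2.0 * norm.sf(np.abs(np.where(defined, z, 0.0))), np.nan)
        flags = bh_adjust(p.ravel(), config.alpha).reshape(p.shape)
        pb_mid = np.mean(np.stack(mids), axis=0)
        pooled_pb = _binning.PhyloBinning(n_bins=config.n_phylo_quantiles,
                                          bin_of_pair=np.zeros((S, S), dtype=np.int64),
                                          mid_ma=pb_mid, edges_ma=np.zeros((config.n_phylo_quantiles, 2)))
        rows.append(_to_rows(test_id, c, POOLED, system, pooled_pb, group_labels,
                             pooled_obs, null_mean, null_sd, z, defined, p=p, bh=flags))

    table = pd.concat(rows, ignore_index=True)
    return TestResult(test_id=test_id, table=table, config=config, n_undefined=n_undef)


def _to_rows(test_id, census, rep, system, pb, group_labels, obs, null_mean, null_sd,
             z, defined, p=None, bh=None) -> pd.DataFrame:
    G, A, B = obs.shape
    gi, ai, bi = np.meshgrid(np.arange(G), np.arange(A), np.arange(B), indexing="ij")
    df = pd.DataFrame({
        "test": test_id,
        "census": census,
        "replicate": rep,
        "annulus": ai.ravel() + 1,
        "phylo_bin": bi.ravel() + 1,
        "phylo_mid_ma": pb.mid_ma[bi.ravel()],
        "focal_group": np.asarray(group_labels, dtype=object)[gi.ravel()],
        "observed": obs.ravel(),
        "null_mean": null_mean.ravel(),
        "null_sd": null_sd.ravel(),
        "z": z.ravel(),
        "p": (p.ravel() if p is not None else np.nan),
        "bh_significant": (bh.ravel() if bh is not None else False),
        "defined": defined.ravel(),
    })
    return df


def _reorder_distances(D: PhyloDistances, species_list) -> PhyloDistances:
    idx = [D.species_list.index(s) for s in species_list]
    return PhyloDistances(list(species_list), D.D[np.ix_(idx, idx)])


def run_tests(test_ids, plot, D, config: EAAConfig | None = None) -> dict[int, TestResult]:
    return {t: run_test(t, plot, D, config) for t in test_ids}
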