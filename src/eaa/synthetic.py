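"""Seedable synthetic forest dynamics plots with known ground truth.

The generator emulates the structure of a censused forest plot: a rectangular
window, log-series-like species abundances, Thomas-cluster conspecific spatial
pattern, an ultrametric (Yule) species phylogeny, and multi-census demography
(recruitment at the 1 cm dbh threshold, diameter growth, mortality).  Neighbor
interaction effects are *planted* explicitly: each effect multiplies the
log-scale demographic rates of a tree by ``strength`` times an interaction
index

    I_i = sum_j (BA_j / BA_ref) * exp(-d_ij / spatial_scale) * W[sp_i, sp_j]

summed over living neighbors j, where W is either the smooth phylogenetic
kernel exp(-Ma / phylo_scale) or an explicit species-pair weight matrix
(allelopathy, interaction valleys).  NDD effects suppress recruitment and
growth and raise mortality near large, related neighbors; PDD mirrors that.
Burn-in intervals before the first recorded census let the planted effects
shape the standing spatial/size structure, so clustering signatures (not just
dynamic rates) carry the interaction signal.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, replace

import dendropy
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import logser

from .io import PhyloDistances, PlotCensus, StemRecord, infer_statuses

BA_REF_CM2 = math.pi * 25.0  # basal area of a 10 cm dbh tree: index unit

_PROB_EPS = 1e-6  # modulated probabilities are clamped to [eps, 1-eps], with counts logged


@dataclass
class InteractionEffect:
    """One planted neighbor interaction.

    kind "ndd" suppresses recruitment/growth and raises mortality of trees
    with large related neighborhoods; "pdd" is the mirror image;
    "allelopathy" is an NDD-signed effect carried by an explicit donor ->
    susceptible pair-weight matrix, ignoring phylogenetic proximity.
    strength 0 is exactly null.
    """

    kind: str                           # "ndd" | "pdd" | "allelopathy"
    strength: float
    spatial_scale: float = 5.0          # m, exponential decay of the kernel
    phylo_scale: float | None = 50.0    # Ma; None requires pair_weights
    pair_weights: np.ndarray | None = None  # (S, S) overrides the phylo kernel
    target: str = "all"                 # "recruitment" | "mortality" | "growth" | "all"

    @property
    def sign(self) -> float:
        if self.kind in ("ndd", "allelopathy"):
            return 1.0
        if self.kind == "pdd":
            return -1.0
        raise ValueError(f"unknown effect kind {self.kind!r}")

    def applies_to(self, target: str) -> bool:
        return self.target in ("all", target)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic plot."""

    width: float = 100.0
    height: float = 100.0
    n_species: int = 20
    n_trees: int = 2000                 # target initial stem count (0.2 trees/m^2 default)
    logseries_p: float = 0.99           # log-series abundance shape
    abundances: tuple[int, ...] | None = None  # explicit per-species counts (overrides log-series)
    spatial_pattern: str = "thomas"     # "thomas" (clustered) or "csr" (uniform)
    cluster_sigma: float = 5.0          # Thomas process offspring spread (m)
    offspring_per_parent: float = 10.0
    yule_birth_rate: float = 1.0
    root_depth_ma: float = 300.0
    phylogeny_newick: str | None = None  # overrides the simulated Yule tree
    species_names: tuple[str, ...] | None = None  # rank order = abundance order
    n_censuses: int = 2
    burn_in: int = 2                    # intervals simulated before the first recorded census
    interval_years: float = 5.0
    mortality_rate: float = 0.10        # baseline per-interval death probability
    recruitment_rate: float = 0.30      # per-capita recruit candidates per interval
    establishment_prob: float = 0.8     # baseline candidate establishment probability
    recruit_sigma: float = 5.0          # propagule spread around the parent (m)
    recruit_placement: str = "parent"   # "parent" (spatially explicit) or "uniform"
    growth_mean: float = 1.0            # cm per interval
    growth_sd: float = 0.5
    initial_dbh_scale: float = 6.0      # gamma scale of initial dbh above 1 cm
    effects: tuple[InteractionEffect, ...] = ()
    null_pairs: tuple[tuple[str, str], ...] = ()   # pairs whose interaction weight is zeroed
    seed: int = 0


@dataclass
class SimulationResult:
    plot: PlotCensus
    distances: PhyloDistances
    newick: str
    ground_truth: dict


# ---------------------------------------------------------------------------
# Config manipulation
# ---------------------------------------------------------------------------


def plant_allelopathy(config: SimulationConfig, donor: str, susceptible: tuple[str, ...],
                      strength: float, immune: tuple[str, ...] = (),
                      target: str = "all", spatial_scale: float = 8.0) -> SimulationConfig:
    """Add a donor-species allelopathic effect suppressing the listed susceptibles.

    The effect ignores phylogenetic proximity: any susceptible growing near
    large donors is suppressed; ``immune`` species are never affected even if
    listed as susceptible.
    """
    if donor in susceptible:
        raise ValueError("donor species cannot be in the susceptible set")
    names = species_names(config)
    W = np.zeros((len(names), len(names)))
    di = names.index(donor)
    for s in susceptible:
        if s in immune:
            continue
        W[names.index(s), di] = 1.0
    eff = InteractionEffect(kind="allelopathy", strength=strength, pair_weights=W,
                            phylo_scale=None, target=target, spatial_scale=spatial_scale)
    return replace(config, effects=config.effects + (eff,))


def plant_pair_null(config: SimulationConfig, species_pairs) -> SimulationConfig:
    """Zero the interaction weight for the listed species pairs (a planted 'valley')."""
    names = species_names(config)
    for a, b in species_pairs:
        if a not in names or b not in names:
            raise ValueError(f"unknown species in pair ({a}, {b})")
    return replace(config, null_pairs=config.null_pairs + tuple((a, b) for a, b in species_pairs))


def species_names(config: SimulationConfig) -> list[str]:
    if config.species_names is not None:
        return list(config.species_names)
    return [f"S{i + 1:02d}" for i in range(config.n_species)]


# ---------------------------------------------------------------------------
# Phylogeny and abundances
# ---------------------------------------------------------------------------


def _simulate_phylogeny(config: SimulationConfig, names, rng) -> tuple[str, PhyloDistances]:
    from .io import distances_from_newick

    if config.phylogeny_newick is not None:
        newick = config.phylogeny_newick
    elif len(names) == 1:
        newick = f"({names[0]}:{config.root_depth_ma});"
    else:
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=config.yule_birth_rate, death_rate=0.0,
            num_extant_tips=len(names), rng=_random.Random(int(rng.integers(2**31))))
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= config.root_depth_ma / depth
        for leaf, name in zip(tree.leaf_node_iter(), names):
            leaf.taxon.label = name
        newick = tree.as_string(schema="newick").strip()
    return newick, distances_from_newick(newick, mode="strict_ultrametric")


def _abundances(config: SimulationConfig, rng) -> np.ndarray:
    """Species abundances, descending with species rank (log-series by default)."""
    S = config.n_species
    if config.abundances is not None:
        if len(config.abundances) != S:
            raise ValueError("abundances length must equal n_species")
        return np.asarray(config.abundances, dtype=int)
    w = np.sort(logser.rvs(config.logseries_p, size=S, random_state=rng))[::-1].astype(float)
    counts = np.maximum(np.round(w / w.sum() * config.n_trees).astype(int), 5)
    return counts


# ---------------------------------------------------------------------------
# Interaction machinery
# ---------------------------------------------------------------------------


def _effect_weight_matrix(eff: InteractionEffect, D: np.ndarray, names,
                          null_pairs) -> np.ndarray:
    if eff.pair_weights is not None:
        W = np.array(eff.pair_weights, dtype=float)
    else:
        W = np.exp(-D / eff.phylo_scale)
    for a, b in null_pairs:
        ia, ib = names.index(a), names.index(b)
        W[ia, ib] = W[ib, ia] = 0.0
    return W


class _Interactions:
    """Evaluates planted interaction indices against the living community."""

    def __init__(self, config: SimulationConfig, D: np.ndarray, names):
        self.effects = [e for e in config.effects if e.strength != 0.0]
        self.W = [_effect_weight_matrix(e, D, names, config.null_pairs) for e in self.effects]
        self.cutoff = max((4.0 * e.spatial_scale for e in self.effects), default=0.0)

    def log_modifiers(self, target: str, xy_sub, sp_sub, xy_live, sp_live, ba_live,
                      tree=None, self_index=None) -> np.ndarray:
        """Sum of signed strength * index over effects hitting ``target``.

        The returned value is subtracted from log recruitment/growth and added
        to log mortality.  ``self_index`` maps subject rows to rows of the
        living arrays so a tree never interacts with itself.
        """
        out = np.zeros(len(xy_sub))
        active = [(e, W) for e, W in zip(self.effects, self.W) if e.applies_to(target)]
        if not active or len(xy_live) == 0:
            return out
        tree = tree or cKDTree(xy_live)
        hits = tree.query_ball_point(xy_sub, r=self.cutoff)
        i_rep = np.repeat(np.arange(len(xy_sub)), [len(h) for h in hits])
        j = np.concatenate(hits) if len(xy_sub) else np.zeros(0, dtype=int)
        if self_index is not None:
            keep = j != self_index[i_rep]
            i_rep, j = i_rep[keep], j[keep]
        d = np.hypot(*(xy_live[j] - xy_sub[i_rep]).T)
        ba = ba_live[j] / BA_REF_CM2
        for eff, W in active:
            contrib = ba * np.exp(-d / eff.spatial_scale) * W[sp_sub[i_rep], sp_live[j]]
            term = np.zeros(len(xy_sub))
            np.add.at(term, i_rep, contrib)
            out += eff.sign * eff.strength * term
        return out


def _basal(dbh: np.ndarray) -> np.ndarray:
    return math.pi * (dbh / 2.0) ** 2


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_plot(config: SimulationConfig) -> SimulationResult:
    """Simulate a censused plot; all draws come from the config seed."""
    rng = np.random.default_rng(config.seed)
    names = species_names(config)
    if len(names) != config.n_species:
        raise ValueError("species_names length must equal n_species")
    newick, distances = _simulate_phylogeny(config, names, rng)
    if sorted(distances.species_list) != sorted(names):
        raise ValueError("phylogeny tip labels do not match the species set")
    order = [distances.species_list.index(s) for s in names]
    D = distances.D[np.ix_(order, order)]
    inter = _Interactions(config, D, names)

    counts = _abundances(config, rng)
    xs, ys, sps = [], [], []
    for s, n_s in enumerate(counts):
        if config.spatial_pattern == "csr":
            x = rng.uniform(0, config.width, n_s)
            y = rng.uniform(0, config.height, n_s)
        else:
            n_par = max(1, int(round(n_s / config.offspring_per_parent)))
            px = rng.uniform(0, config.width, n_par)
            py = rng.uniform(0, config.height, n_par)
            parent = rng.integers(0, n_par, n_s)
            x = px[parent] + rng.normal(0, config.cluster_sigma, n_s)
            y = py[parent] + rng.normal(0, config.cluster_sigma, n_s)
            bad = (x < 0) | (x >= config.width) | (y < 0) | (y >= config.height)
            x[bad] = rng.uniform(0, config.width, bad.sum())
            y[bad] = rng.uniform(0, config.height, bad.sum())
        xs.append(x); ys.append(y); sps.append(np.full(n_s, s))
    x = np.concatenate(xs); y = np.concatenate(ys); sp = np.concatenate(sps)
    n0 = x.size
    dbh = np.minimum(1.0 + rng.gamma(1.0, config.initial_dbh_scale, n0), 120.0)
    alive = np.ones(n0, dtype=bool)
    xy = np.stack([x, y], axis=1)

    clamp_count = 0
    # per-tree recorded dbh trajectories; None while unborn/after death
    history: list[list[float | None]] = [[] for _ in range(n0)]

    def record():
        for i in range(len(history)):
            history[i].append(float(dbh[i]) if alive[i] else None)

    def step():
        nonlocal xy, sp, dbh, alive, clamp_count, history
        live = np.flatnonzero(alive)
        xy_l, sp_l, ba_l = xy[live], sp[live], _basal(dbh[live])
        tree = cKDTree(xy_l) if live.size else None

        # mortality
        mod_m = inter.log_modifiers("mortality", xy_l, sp_l, xy_l, sp_l, ba_l,
                                    tree=tree, self_index=np.arange(live.size))
        p_die = config.mortality_rate * np.exp(mod_m)
        clamped = (p_die < _PROB_EPS) | (p_die > 1 - _PROB_EPS)
        clamp_count += int(clamped.sum())
        p_die = np.clip(p_die, _PROB_EPS, 1 - _PROB_EPS)
        dies = rng.random(live.size) < p_die
        alive[live[dies]] = False

        # growth of survivors (against the pre-mortality community)
        surv = live[~dies]
        mod_g = inter.log_modifiers("growth", xy[surv], sp[surv], xy_l, sp_l, ba_l,
                                    tree=tree, self_index=np.flatnonzero(~dies))
        incr = rng.normal(config.growth_mean - mod_g, config.growth_sd)
        dbh[surv] += np.maximum(incr, 0.0)

        # recruitment: propagules near surviving conspecific adults, thinned by the kernel
        new_xy, new_sp = [], []
        for s in range(config.n_species):
            adults = surv[sp[surv] == s]
            if adults.size == 0:
                continue
            n_cand = rng.poisson(config.recruitment_rate * adults.size)
            if n_cand == 0:
                continue
            if config.recruit_placement == "uniform":
                cand = np.stack([rng.uniform(0, config.width, n_cand),
                                 rng.uniform(0, config.height, n_cand)], axis=1)
            else:
                parents = rng.choice(adults, n_cand)
                cand = xy[parents] + rng.normal(0, config.recruit_sigma, (n_cand, 2))
                ok = ((cand[:, 0] >= 0) & (cand[:, 0] < config.width)
                      & (cand[:, 1] >= 0) & (cand[:, 1] < config.height))
                cand = cand[ok]
            if cand.size == 0:
                continue
            mod_r = inter.log_modifiers("recruitment", cand, np.full(len(cand), s),
                                        xy_l, sp_l, ba_l, tree=tree)
            p_est = config.establishment_prob * np.exp(-mod_r)
            clamped = (p_est < _PROB_EPS) | (p_est > 1 - _PROB_EPS)
            clamp_count += int(clamped.sum())
            p_est = np.clip(p_est, _PROB_EPS, 1 - _PROB_EPS)
            est = rng.random(len(cand)) < p_est
            if est.sum():
                new_xy.append(cand[est])
                new_sp.append(np.full(int(est.sum()), s))
        if new_xy:
            add_xy = np.concatenate(new_xy)
            add_sp = np.concatenate(new_sp)
            n_new = add_xy.shape[0]
            depth = len(history[0]) if history else 0
            history.extend([[None] * depth for _ in range(n_new)])
            xy = np.concatenate([xy, add_xy])
            sp = np.concatenate([sp, add_sp])
            dbh = np.concatenate([dbh, 1.0 + rng.exponential(0.5, n_new)])
            alive = np.concatenate([alive, np.ones(n_new, dtype=bool)])

    for _ in range(config.burn_in):
        step()  # burn-in intervals shape the standing structure but are not recorded
    record()
    for _ in range(config.n_censuses - 1):
        step()
        record()

    records = []
    for i, h in enumerate(history):
        if all(v is None for v in h):
            continue
        dbh_by_census = [None if v is None else (v,) for v in h]
        records.append(StemRecord(
            tree_id=f"t{i:06d}", species=names[sp[i]], x=float(xy[i, 0]), y=float(xy[i, 1]),
            dbh_by_census=dbh_by_census, status_by_census=infer_statuses(dbh_by_census)))
    plot = PlotCensus(width=config.width, height=config.height, n_censuses=config.n_censuses,
                      interval_years=config.interval_years, records=records,
                      species_list=names)
    ground_truth = {
        "seed": config.seed,
        "effects": [
            {"kind": e.kind, "strength": e.strength, "spatial_scale": e.spatial_scale,
             "phylo_scale": e.phylo_scale, "target": e.target,
             "explicit_pairs": e.pair_weights is not None}
            for e in config.effects],
        "null_pairs": list(config.null_pairs),
        "clamped_probabilities": clamp_count,
        "n_recorded_trees": len(records),
        "species_counts": {names[s]: int((sp == s).sum()) for s in range(config.n_species)},
    }
    return SimulationResult(plot=plot, distances=PhyloDistances(names, D),
                            newick=newick, ground_truth=ground_truth)
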