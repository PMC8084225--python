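"""Reference synthetic communities with planted, recoverable interaction effects.

Each builder returns a fully specified :class:`~eaa.synthetic.SimulationConfig`
(and, where useful, metadata about the planted structure).  They are the
study conditions used by the demonstration suite and the acceptance script:

* a neutral community for null calibration (CSR positions, uniform
  recruitment, demography independent of the neighborhood);
* single-channel conspecific negative density dependence (mortality,
  recruitment, or growth) for direction-recovery checks;
* an allelopathic community: one phylogenetically distant donor suppresses
  recruitment and growth of all species except one immune species;
* an interaction "valley": species pairs around 111 Ma that do not interact,
  anchored by two abundant implicated pairs, with designated shoulder classes
  so the valley is resolvable at desk scale.

Plot sizes here are deliberately modest (a few m-ha, ~3-15 thousand stems)
so a full analysis runs in seconds to a couple of minutes; real forest
dynamics plots are one to two orders of magnitude larger.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (InteractionEffect, SimulationConfig, plant_allelopathy,
                        plant_pair_null)

__all__ = [
    "neutral_community",
    "conspecific_ndd_community",
    "allelopathy_community",
    "valley_community",
]


def neutral_community(seed: int, **overrides) -> SimulationConfig:
    """A no-effect plot in which every attribute is independent of the neighborhood.

    Positions are completely random (no conspecific clustering) and recruits
    are placed uniformly, so demographic labels are exchangeable within
    species against position — the regime in which every shuffle null is
    exactly calibrated.
    """
    kw = dict(seed=seed, spatial_pattern="csr", recruit_placement="uniform")
    kw.update(overrides)
    return SimulationConfig(**kw)


_CONSPECIFIC = {
    # per-channel planted strengths: strong enough to recover at a ~2 m-ha
    # plot, weak enough that the community persists (odds multipliers of
    # roughly 2-4 at a typical conspecific neighborhood index)
    "mortality": dict(strength=0.4, spatial_scale=3.0),
    "recruitment": dict(strength=0.15, spatial_scale=5.0),
    "growth": dict(strength=0.1, spatial_scale=5.0),
}


def conspecific_ndd_community(target: str, seed: int, **overrides) -> SimulationConfig:
    """Clustered community with conspecific-only NDD on one demographic channel.

    The phylogenetic kernel is the identity matrix (conspecific pairs only),
    so the planted signal is confined to the zero-distance quantile.
    """
    if target not in _CONSPECIFIC:
        raise ValueError(f"target must be one of {sorted(_CONSPECIFIC)}")
    n_species = overrides.pop("n_species", 20)
    eff = InteractionEffect(kind="ndd", pair_weights=np.eye(n_species),
                            phylo_scale=None, target=target, **_CONSPECIFIC[target])
    kw = dict(seed=seed, width=140.0, height=140.0, n_trees=3900, burn_in=3,
              n_species=n_species, effects=(eff,))
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# Allelopathy: a distant donor, one immune species
# ---------------------------------------------------------------------------

_ALLELO_SUSCEPTIBLE = tuple(f"S{i:02d}" for i in range(1, 13))
_ALLELO_NAMES = ("IMM", "DON") + _ALLELO_SUSCEPTIBLE


def _allelo_newick() -> str:
    # angiosperm ladder (immune + susceptibles, 20-150 Ma) vs a 300 Ma donor
    items = [
        ("(IMM:20,S01:20)", 20, 35), ("S02", 0, 35), ("(S03:28,S04:28)", 28, 55),
        ("S05", 0, 70), ("(S06:45,S07:45)", 45, 90), ("S08", 0, 105),
        ("(S09:60,S10:60)", 60, 120), ("S11", 0, 135), ("S12", 0, 150),
    ]
    tree, depth = items[0][0], items[0][1]
    for sub, sub_depth, attach in items[1:]:
        tree = f"({tree}:{attach - depth},{sub}:{attach - sub_depth})"
        depth = attach
    return f"({tree}:150,DON:300);"


def allelopathy_community(seed: int, spatial_scale: float = 5.0,
                          recruit_strength: float = 0.45,
                          growth_strength: float = 0.30, **overrides):
    """Donor species 300 Ma from a 13-species angiosperm clade; the most
    abundant angiosperm is immune.  Returns (config, meta) where meta names
    the donor, immune species and susceptible set."""
    ab = (1400, 1400) + (300,) * 12
    kw = dict(seed=seed, width=200.0, height=200.0, n_trees=sum(ab), burn_in=2,
              n_species=len(_ALLELO_NAMES), species_names=_ALLELO_NAMES,
              abundances=ab, phylogeny_newick=_allelo_newick())
    kw.update(overrides)
    cfg = SimulationConfig(**kw)
    cfg = plant_allelopathy(cfg, "DON", _ALLELO_SUSCEPTIBLE, strength=recruit_strength,
                            immune=("IMM",), target="recruitment", spatial_scale=spatial_scale)
    cfg = plant_allelopathy(cfg, "DON", _ALLELO_SUSCEPTIBLE, strength=growth_strength,
                            immune=("IMM",), target="growth", spatial_scale=spatial_scale)
    meta = {"donor": "DON", "immune": "IMM", "susceptible": _ALLELO_SUSCEPTIBLE,
            "donor_distance_ma": 300.0, "n_phylo_quantiles": 6}
    return cfg, meta


# ---------------------------------------------------------------------------
# Interaction valley at ~111 Ma
# ---------------------------------------------------------------------------


def _ladder_clade(prefix: str, n: int, lo: float, hi: float) -> tuple[str, float]:
    joins = np.linspace(lo, hi, n - 1)
    tree, depth = f"{prefix}1", 0.0
    for i, d in enumerate(joins):
        tree = f"({tree}:{d - depth},{prefix}{i + 2}:{d})"
        depth = d
    return tree, float(joins[-1])


def _valley_newick() -> str:
    P, pdep = _ladder_clade("P", 7, 15, 30)
    Q, qdep = _ladder_clade("Q", 7, 16, 32)
    V, vdep = _ladder_clade("V", 8, 17, 34)
    W, wdep = _ladder_clade("W", 8, 18, 36)
    T, tdep = _ladder_clade("T", 8, 19, 38)
    U, udep = _ladder_clade("U", 8, 20, 40)
    pq = f"({P}:{95 - pdep},{Q}:{95 - qdep})"      # 49 pairs at 95 (lower shoulder)
    vw = f"({V}:{111 - vdep},{W}:{111 - wdep})"    # 64 pairs at 111 (the valley class)
    tu = f"({T}:{125 - tdep},{U}:{125 - udep})"    # 64 pairs at 125 (upper shoulder)
    abc = "((A:72,B:72):40,C:112)"                 # the implicated abundant triple
    t = f"({pq}:{170 - 95},{vw}:{170 - 111})"
    t = f"({t}:{200 - 170},{tu}:{200 - 125})"
    t = f"({t}:{212 - 200},{abc}:{212 - 112})"
    t = f"({t}:{260 - 212},O1:260)"
    t = f"({t}:{300 - 260},O2:300)"
    return t + ";"


VALLEY_NULL_PAIRS = tuple([("A", "C"), ("B", "C")] +
                          [(f"V{i}", f"W{j}") for i in (1, 2, 3, 4, 5) for j in range(1, 9)])
VALLEY_MOVE_PAIRS = (("A", "B"), ("A", "C"), ("B", "C"))


def valley_community(seed: int, **overrides):
    """Community with a planted non-interaction 'valley' at ~111 Ma.

    A smooth phylogenetically-kernelled NDD effect suppresses focal-tree
    growth, but the two abundant implicated pairs (A-C, B-C at 112 Ma) and
    most of the V x W clade-pair class (111 Ma) have their interaction weight
    zeroed.  The growth channel carries the demonstration because its
    continuous response gives by far the best per-quantile signal-to-noise at
    desk scale.  Abundant anchor species (P1, Q1 at 95 Ma; T1, U1 at 125 Ma)
    give the shoulder quantiles enough statistical mass to resolve the valley.
    Returns (config, meta); meta carries the pair lists and the quantile
    count the community is designed for.
    """
    from .io import distances_from_newick

    newick = _valley_newick()
    tips = distances_from_newick(newick).species_list
    names = ["A", "B", "C"] + [s for s in tips if s not in ("A", "B", "C")]
    abundant = {"A": 2000, "B": 1700, "C": 1400, "P1": 800, "Q1": 800, "T1": 800, "U1": 800}
    ab = tuple(abundant.get(s, 150) for s in names)
    eff = InteractionEffect(kind="ndd", strength=0.45, spatial_scale=4.0,
                            phylo_scale=200.0, target="growth")
    kw = dict(seed=seed, width=220.0, height=220.0, n_trees=sum(ab), burn_in=2,
              n_species=len(names), species_names=tuple(names), abundances=ab,
              phylogeny_newick=newick, effects=(eff,),
              growth_mean=2.0, growth_sd=0.8)
    kw.update(overrides)
    cfg = plant_pair_null(SimulationConfig(**kw), VALLEY_NULL_PAIRS)
    meta = {"null_pairs": VALLEY_NULL_PAIRS, "move_pairs": VALLEY_MOVE_PAIRS,
            "valley_ma": 111.0, "new_valley_ma": 50.0, "n_phylo_quantiles": 20,
            "valley_probe": ("V6", "W6"), "shoulder_lo": ("P1", "Q1"),
            "shoulder_hi": ("T4", "U4")}
    return cfg, meta
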