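"""Intervention protocols: phylogenetic-distance manipulation and species subsetting.

Two controls probe what drives a feature of the z-surfaces: (a) deliberately
rewriting the divergence times of implicated species pairs and re-running the
analysis (a feature that tracks the pairs must move with them), and (b)
re-running with chosen species removed from the focal set, the annular set,
or both (removal semantics are independent: a species removed as focal still
counts as a neighbor unless also removed as annular).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .eaa_tests import EAAConfig, TestResult, run_test
from .io import PhyloDistances
from .smoothing import SmoothFit, locate_extrema


def manipulate_distances(D: PhyloDistances, pairs, new_ma: float) -> PhyloDistances:
    """Set the divergence time of the listed species pairs to ``new_ma`` (both mirrors).

    Ultrametricity is deliberately not enforced: the point of the control is
    to move pairs to a distance the rest of the tree does not imply.
    """
    if new_ma < 0:
        raise ValueError("new distance must be nonnegative")
    out = D.copy()
    for a, b in pairs:
        ia, ib = out.index(a), out.index(b)
        out.D[ia, ib] = out.D[ib, ia] = new_ma
    return out


def subset_run(plot, D: PhyloDistances, test_ids, config: EAAConfig | None = None,
               focal_keep=None, annular_keep=None) -> dict[int, TestResult]:
    """Re-run tests with independent focal / annular species keep-lists.

    Quantile schemes (focal sizes, biomass, phylogenetic bins) are recomputed
    on the subset.  Raises if either resulting set would be empty.
    """
    config = config or EAAConfig()
    if focal_keep is not None and len(tuple(focal_keep)) == 0:
        raise ValueError("focal keep-list is empty")
    if annular_keep is not None and len(tuple(annular_keep)) == 0:
        raise ValueError("annular keep-list is empty")
    cfg = replace(config,
                  focal_species=None if focal_keep is None else tuple(focal_keep),
                  annular_species=None if annular_keep is None else tuple(annular_keep))
    return {t: run_test(t, plot, D, cfg) for t in test_ids}


def compare_curves(fit_before: SmoothFit, fit_after: SmoothFit) -> dict:
    """Pointwise difference of two curve fits on a common grid.

    Returns the difference with propagated bands, the grid regions where the
    band excludes zero, and extrema gained/lost between the fits.
    """
    if fit_before.is_surface or fit_after.is_surface:
        raise ValueError("compare_curves expects curve fits")
    if fit_before.grid.shape != fit_after.grid.shape or \
            not np.allclose(fit_before.grid, fit_after.grid):
        raise ValueError("fits are not on a common grid")
    diff = fit_after.fitted - fit_before.fitted
    se = np.sqrt(fit_after.se**2 + fit_before.se**2)
    lo, hi = diff - 1.96 * se, diff + 1.96 * se
    sig = (lo > 0) | (hi < 0)
    regions = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((float(fit_before.grid[start]), float(fit_before.grid[i - 1])))
            start = None
    if start is not None:
        regions.append((float(fit_before.grid[start]), float(fit_before.grid[-1])))

    before_ext = locate_extrema(fit_before)
    after_ext = locate_extrema(fit_after)

    def _unmatched(src, other):
        span = float(fit_before.grid[-1] - fit_before.grid[0]) or 1.0
        return [e for e in src
                if not any(o["kind"] == e["kind"] and abs(o["x"] - e["x"]) < 0.05 * span
                           for o in other)]

    return {
        "grid": fit_before.grid,
        "difference": diff,
        "lower": lo,
        "upper": hi,
        "significant_regions": regions,
        "new_extrema": _unmatched(after_ext, before_ext),
        "lost_extrema": _unmatched(before_ext, after_ext),
    }
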