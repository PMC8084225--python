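"""Census tables, phylogenies, species distance matrices, and result files.

The canonical census dialect is one row per tree with wide per-census columns:

    tree_id,species,gx,gy,dbh_1,status_1,dbh_2,status_2,...

Multi-stem diameters are semicolon-joined inside one dbh cell ("12.1;3.4").
Plot dimensions and the census interval ride in a leading comment line:

    # width=100 height=100 interval_years=5

Statuses are ``prior`` (below the 1 cm census threshold), ``recruit`` (first
census at >= 1 cm dbh), ``alive`` and ``dead`` (absorbing).  When status
columns are absent they are inferred from dbh presence: first census with a
dbh is ``recruit``, dbh present thereafter is ``alive``, dbh absent after
presence is ``dead``.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATUSES = ("prior", "recruit", "alive", "dead")
PRIOR, RECRUIT, ALIVE, DEAD = range(4)
_STATUS_CODE = {s: i for i, s in enumerate(STATUSES)}

MIN_DBH_CM = 1.0  # census threshold: stems >= 1 cm dbh at 1.3 m height


@dataclass
class StemRecord:
    """One tagged tree: position plus per-census stem diameters and status."""

    tree_id: str
    species: str
    x: float
    y: float
    dbh_by_census: list[tuple[float, ...] | None]
    status_by_census: list[str]

    def basal_area(self, census: int) -> float:
        """Summed cross-sectional area (cm^2) over stems at the given census."""
        d = self.dbh_by_census[census]
        if d is None:
            return 0.0
        return float(sum(math.pi * (s / 2.0) ** 2 for s in d))

    def total_dbh(self, census: int) -> float | None:
        """Diameter of the equivalent single stem (cm): sqrt of summed d^2."""
        d = self.dbh_by_census[census]
        if d is None:
            return None
        return float(math.sqrt(sum(s * s for s in d)))


@dataclass
class PlotCensus:
    """A rectangular, repeatedly censused plot: [0, width) x [0, height) meters."""

    width: float
    height: float
    n_censuses: int
    interval_years: float
    records: list[StemRecord]
    species_list: list[str]
    rejected_records: int = 0

    def __post_init__(self) -> None:
        present = {r.species for r in self.records}
        missing = present - set(self.species_list)
        if missing:
            raise ValueError(f"species in records but not species_list: {sorted(missing)}")

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.width, self.height)

    def arrays(self) -> "PlotArrays":
        return PlotArrays.from_plot(self)


@dataclass
class PlotArrays:
    """Columnar view of a PlotCensus used by the neighborhood engine."""

    xy: np.ndarray              # (n, 2) meters
    species_idx: np.ndarray     # (n,) index into species_list
    status: np.ndarray          # (n_censuses, n) status codes
    dbh: np.ndarray             # (n_censuses, n) equivalent single-stem dbh, NaN absent
    basal: np.ndarray           # (n_censuses, n) summed basal area cm^2, 0 absent
    species_list: list[str]
    tree_ids: list[str]

    @classmethod
    def from_plot(cls, plot: PlotCensus) -> "PlotArrays":
        n = len(plot.records)
        sp_index = {s: i for i, s in enumerate(plot.species_list)}
        xy = np.empty((n, 2))
        spi = np.empty(n, dtype=np.int64)
        status = np.empty((plot.n_censuses, n), dtype=np.int8)
        dbh = np.full((plot.n_censuses, n), np.nan)
        basal = np.zeros((plot.n_censuses, n))
        ids = []
        for j, rec in enumerate(plot.records):
            xy[j] = (rec.x, rec.y)
            spi[j] = sp_index[rec.species]
            ids.append(rec.tree_id)
            for c in range(plot.n_censuses):
                status[c, j] = _STATUS_CODE[rec.status_by_census[c]]
                td = rec.total_dbh(c)
                if td is not None:
                    dbh[c, j] = td
                    basal[c, j] = rec.basal_area(c)
        return cls(xy=xy, species_idx=spi, status=status, dbh=dbh, basal=basal,
                   species_list=list(plot.species_list), tree_ids=ids)

    def present(self, census: int) -> np.ndarray:
        s = self.status[census]
        return (s == RECRUIT) | (s == ALIVE)


@dataclass
class PhyloDistances:
    """Pairwise species divergence times: Ma back to the last common ancestor."""

    species_list: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.species_list)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(self.D, self.D.T, rtol=0, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise ValueError("distances must be nonnegative")

    def index(self, species: str) -> int:
        return self.species_list.index(species)

    def get(self, a: str, b: str) -> float:
        return float(self.D[self.index(a), self.index(b)])

    def copy(self) -> "PhyloDistances":
        return PhyloDistances(list(self.species_list), self.D.copy())


# ---------------------------------------------------------------------------
# Status inference
# ---------------------------------------------------------------------------


def infer_statuses(dbh_by_census: list[tuple[float, ...] | None]) -> list[str]:
    """prior* -> recruit -> alive* -> dead: inferred from dbh presence."""
    out: list[str] = []
    seen = False
    for d in dbh_by_census:
        if d is not None:
            out.append("alive" if seen else "recruit")
            seen = True
        else:
            out.append("dead" if seen else "prior")
    return out


def _validate_statuses(statuses: list[str], dbh: list[tuple[float, ...] | None]) -> None:
    allowed_next = {"prior": {"prior", "recruit"}, "recruit": {"alive", "dead"},
                    "alive": {"alive", "dead"}, "dead": {"dead"}}
    for s in statuses:
        if s not in _STATUS_CODE:
            raise ValueError(f"unknown status token {s!r}")
    for a, b in zip(statuses, statuses[1:]):
        if b not in allowed_next[a]:
            raise ValueError(f"status sequence {statuses} violates prior*->recruit->alive*->dead")
    for s, d in zip(statuses, dbh):
        if s in ("prior", "dead") and d is not None:
            raise ValueError(f"dbh present for status {s!r}")
        if d is not None and any(x < MIN_DBH_CM for x in d) and sum(x * x for x in d) < MIN_DBH_CM**2:
            raise ValueError("recorded tree below the 1 cm census threshold")


# ---------------------------------------------------------------------------
# Census read / write
# ---------------------------------------------------------------------------


def _parse_dbh_cell(cell) -> tuple[float, ...] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    return tuple(float(tok) for tok in str(cell).split(";"))


def read_census(path, *, sep: str = ",") -> PlotCensus:
    """Read a census table in the canonical dialect.

    Records with coordinates outside [0, width) x [0, height) are rejected and
    counted on ``PlotCensus.rejected_records``; unknown status tokens raise.
    """
    header_meta: dict[str, float] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("census file must start with a '# width=... height=...' header line")
        for tok in first.lstrip("#").split():
            k, _, v = tok.partition("=")
            header_meta[k] = float(v)
        body = fh.read()
    width = header_meta["width"]
    height = header_meta["height"]
    interval_years = header_meta.get("interval_years", 5.0)
    df = pd.read_csv(_io.StringIO(body), sep=sep, dtype={"tree_id": str, "species": str})

    dbh_cols = sorted([c for c in df.columns if c.startswith("dbh_")], key=lambda c: int(c.split("_")[1]))
    status_cols = sorted([c for c in df.columns if c.startswith("status_")], key=lambda c: int(c.split("_")[1]))
    n_cens = len(dbh_cols)
    if n_cens == 0:
        raise ValueError("no dbh_<i> columns found")
    has_status = bool(status_cols)
    if has_status and len(status_cols) != n_cens:
        raise ValueError("status_<i> columns do not match dbh_<i> columns")

    records: list[StemRecord] = []
    rejected = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        x, y = float(row["gx"]), float(row["gy"])
        if not (0.0 <= x < width and 0.0 <= y < height):
            rejected += 1
            continue
        dbh = [_parse_dbh_cell(row[c]) for c in dbh_cols]
        if has_status:
            statuses = [str(row[c]).strip() for c in status_cols]
        else:
            statuses = infer_statuses(dbh)
        _validate_statuses(statuses, dbh)
        records.append(StemRecord(tree_id=str(row["tree_id"]), species=str(row["species"]),
                                  x=x, y=y, dbh_by_census=dbh, status_by_census=statuses))
    if rejected:
        log.warning("read_census: rejected %d records with out-of-plot coordinates", rejected)
    species = sorted({r.species for r in records})
    return PlotCensus(width=width, height=height, n_censuses=n_cens,
                      interval_years=interval_years, records=records,
                      species_list=species, rejected_records=rejected)


def write_census(plot: PlotCensus, path, *, sep: str = ",") -> None:
    """Write a PlotCensus in the canonical dialect (round-trips with read_census)."""
    rows = []
    for rec in plot.records:
        row: dict[str, object] = {"tree_id": rec.tree_id, "species": rec.species,
                                  "gx": repr(rec.x), "gy": repr(rec.y)}
        for c in range(plot.n_censuses):
            d = rec.dbh_by_census[c]
            row[f"dbh_{c + 1}"] = "" if d is None else ";".join(repr(v) for v in d)
            row[f"status_{c + 1}"] = rec.status_by_census[c]
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# width={plot.width!r} height={plot.height!r} interval_years={plot.interval_years!r}\n")
        df.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Phylogenies and distance matrices
# ---------------------------------------------------------------------------


def distances_from_newick(tree_text: str, mode: str = "strict_ultrametric") -> PhyloDistances:
    """Species pairwise divergence times from a time-calibrated Newick tree.

    mode="strict_ultrametric": distances are depths of the most recent common
    ancestor below the present; leaf depths must agree to 1e-6 relative.
    mode="half_patristic": half the path length between the two leaves (equal
    to the MRCA depth on an ultrametric tree, defined for any tree).
    """
    if mode not in ("strict_ultrametric", "half_patristic"):
        raise ValueError(f"unknown mode {mode!r}")
    tree = dendropy.Tree.get(data=tree_text, schema="newick")
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    if mode == "strict_ultrametric":
        depths = np.array([leaf.distance_from_root() for leaf in tree.leaf_node_iter()])
        ref = depths.max()
        if ref > 0 and np.any(np.abs(depths - ref) > 1e-6 * ref):
            raise ValueError("tree is not ultrametric (leaf depths differ by > 1e-6 relative)")
    D = np.zeros((n, n))
    if n > 1:
        pdm = tree.phylogenetic_distance_matrix()
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = 0.5 * pdm.patristic_distance(taxa[i], taxa[j])
    return PhyloDistances(labels, D)


def read_distance_matrix(path) -> PhyloDistances:
    """Species x species CSV matrix of Ma-to-LCA (first column = species codes)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns must list the same species")
    return PhyloDistances([str(s) for s in df.index], df.to_numpy(dtype=float))


def write_distance_matrix(d: PhyloDistances, path) -> None:
    pd.DataFrame(d.D, index=d.species_list, columns=d.species_list).to_csv(path, float_format="%.17g")


def sample_genus_level_distances(d: PhyloDistances, species_to_genus: dict[str, str],
                                 genus_lca_depth: dict[str, float],
                                 genus_only: set[str], rng) -> PhyloDistances:
    """Resolve genus-only species pairs by uniform sampling back to the genus LCA.

    For each within-genus pair where at least one member lacks species-level
    placement, the divergence is drawn uniformly on (0, genus LCA depth];
    cross-genus entries are left untouched.  Draws are reproducible from rng.
    """
    for s in d.species_list:
        if s not in species_to_genus:
            raise ValueError(f"species {s!r} has no genus assignment")
    out = d.copy()
    sl = d.species_list
    for i in range(len(sl)):
        for j in range(i + 1, len(sl)):
            a, b = sl[i], sl[j]
            if species_to_genus[a] != species_to_genus[b]:
                continue
            if a in genus_only or b in genus_only:
                depth = genus_lca_depth[species_to_genus[a]]
                u = rng.uniform(0.0, depth)
                val = depth - u if u == 0.0 else u  # open at 0, closed at depth
                out.D[i, j] = out.D[j, i] = val
    return out


# ---------------------------------------------------------------------------
# Long-format result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["test", "census", "replicate", "annulus", "phylo_bin", "phylo_mid_ma",
                  "focal_group", "observed", "null_mean", "null_sd", "z", "p",
                  "bh_significant", "defined"]


def write_results(result, path) -> None:
    """Write a TestResult (or bare results frame) as a long-format CSV.

    One row per (test, census, replicate, annulus, phylo bin, focal group);
    replicate -1 holds the pooled-null summary rows.
    """
    df = result if isinstance(result, pd.DataFrame) else result.table
    df = df.reindex(columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Reference data
# ---------------------------------------------------------------------------


def phytophylo_coverage() -> pd.DataFrame:
    """Species-level coverage of each forest dynamics plot in the Phytophylo
    megaphylogeny (counts of species found / not found, plus the published
    coverage fraction), with the fraction recomputed from the counts."""
    from importlib import resources

    with resources.files("eaa.data").joinpath("phytophylo_coverage.csv").open() as fh:
        df = pd.read_csv(fh)
    df["fraction"] = df["species_found"] / (df["species_found"] + df["species_not_found"])
    return df
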