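"""Area graphs, stratified counts, indirect standardization, SMRs and funnel plots.

Small-area mortality analyses start from deaths and person-years stratified by
age class and calendar year.  Expected counts under *internal* indirect
standardization are obtained by applying the stratum-specific rates of the whole
study region to each area's person-years, so that the regional totals of
observed and expected deaths coincide by construction.  The standardized
mortality ratio (SMR) is then O/E, and exact one-sided Poisson tail
probabilities provide the funnel-plot control limits used to flag areas in
excess of chance variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DISEASES = ("P", "O")

__all__ = [
    "DISEASES",
    "AreaGraph",
    "BivariateAreaData",
    "SMRRecord",
    "read_adjacency",
    "read_counts",
    "compute_expected",
    "compute_smr",
    "funnel_pvalue",
    "funnel_band",
    "select_signal_areas",
    "smr_table",
]


@dataclass(frozen=True)
class AreaGraph:
    """Adjacency structure of the study areas.

    Parameters
    ----------
    area_ids
        Ordered unique area identifiers; index positions are used throughout
        the package as the canonical area order.
    edges
        Unordered, deduplicated pairs of *indices* into ``area_ids``.
        No self-loops.
    """

    area_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at area {self.area_ids[a]!r}")
            if not (0 <= a < self.n_areas and 0 <= b < self.n_areas):
                raise ValueError("edge index out of range")
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.area_ids)})

    @classmethod
    def from_id_pairs(cls, area_ids, id_pairs) -> "AreaGraph":
        """Build from id pairs, symmetrizing and deduplicating."""
        area_ids = tuple(str(a) for a in area_ids)
        index = {a: i for i, a in enumerate(area_ids)}
        if len(index) != len(area_ids):
            raise ValueError("duplicate area ids")
        seen: set[tuple[int, int]] = set()
        for a, b in id_pairs:
            a, b = str(a), str(b)
            for x in (a, b):
                if x not in index:
                    raise ValueError(f"unknown area id in edge: {x!r}")
            if a == b:
                raise ValueError(f"self-loop at area {a!r}")
            i, j = index[a], index[b]
            seen.add((min(i, j), max(i, j)))
        return cls(area_ids, tuple(sorted(seen)))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_i(self) -> np.ndarray:
        """Neighbour count (degree) per area, in canonical order."""
        deg = np.zeros(self.n_areas, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def islands(self) -> tuple[str, ...]:
        """Areas with no neighbours (the intrinsic CAR conditional is undefined there)."""
        deg = self.n_i
        return tuple(a for a, d in zip(self.area_ids, deg) if d == 0)

    def neighbors(self, area_id: str) -> tuple[str, ...]:
        i = self._index[area_id]
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(self.area_ids[b])
            elif b == i:
                out.append(self.area_ids[a])
        return tuple(sorted(out))

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two integer index arrays (one row per unordered edge)."""
        if not self.edges:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        e = np.asarray(self.edges, dtype=int)
        return e[:, 0], e[:, 1]

    def adjacency_lists(self) -> list[np.ndarray]:
        """Neighbour index arrays per area."""
        nb: list[list[int]] = [[] for _ in range(self.n_areas)]
        for a, b in self.edges:
            nb[a].append(b)
            nb[b].append(a)
        return [np.asarray(sorted(x), dtype=int) for x in nb]

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian D - W, the ICAR precision structure."""
        lap = np.zeros((self.n_areas, self.n_areas))
        for a, b in self.edges:
            lap[a, b] -= 1.0
            lap[b, a] -= 1.0
            lap[a, a] += 1.0
            lap[b, b] += 1.0
        return lap

    def n_components(self) -> int:
        """Connected components, counting islands (= ICAR precision rank deficiency)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return nx.number_connected_components(g)

    def to_gal(self, path) -> None:
        lists = self.adjacency_lists()
        with open(path, "w") as fh:
            fh.write(f"{self.n_areas}\n")
            for i, area in enumerate(self.area_ids):
                fh.write(f"{area} {len(lists[i])}\n")
                fh.write(" ".join(self.area_ids[j] for j in lists[i]) + "\n")


def read_adjacency(path, dialect: str = "auto") -> AreaGraph:
    """Read an area adjacency structure from an edge-list CSV or a GAL file.

    The edge-list dialect expects a header with two columns (any names) whose
    rows are area-id pairs; edges are symmetrized.  GAL is the standard
    spatial-weights text format (count header, then per area a header line
    ``id n_neighbors`` followed by the neighbour ids).

    Parameters
    ----------
    dialect
        ``"edgelist"``, ``"gal"`` or ``"auto"`` (by file extension).
    """
    path = str(path)
    if dialect == "auto":
        dialect = "gal" if path.lower().endswith(".gal") else "edgelist"
    if dialect == "gal":
        return _read_gal(path)
    if dialect == "edgelist":
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("edge-list CSV needs at least two columns")
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        ids = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        return AreaGraph.from_id_pairs(ids, pairs)
    raise ValueError(f"unknown adjacency dialect: {dialect!r}")


def _read_gal(path: str) -> AreaGraph:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    # GAL headers are either "n" or "0 n shapefile key"
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    area_ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        ident, k = lines[i].split()[:2]
        k = int(k)
        if ident in nbrs:
            raise ValueError(f"duplicate area ids: {ident!r}")
        area_ids.append(ident)
        if k > 0:
            neigh = lines[i + 1].split()
            if len(neigh) != k:
                raise ValueError(f"area {ident!r}: expected {k} neighbours, found {len(neigh)}")
            nbrs[ident] = neigh
            i += 2
        else:
            nbrs[ident] = []
            i += 1
    if len(area_ids) != n:
        raise ValueError(f"GAL header announces {n} areas, file lists {len(area_ids)}")
    pairs = []
    known = set(area_ids)
    asym = []
    for a, neigh in nbrs.items():
        for b in neigh:
            if b not in known:
                raise ValueError(f"unknown area id in edge: {b!r}")
            if a == b:
                raise ValueError(f"self-loop at area {a!r}")
            pairs.append((a, b))
            if a not in nbrs.get(b, []):
                asym.append((a, b))
    graph = AreaGraph.from_id_pairs(area_ids, pairs)
    if asym:
        import warnings

        warnings.warn(f"GAL file not symmetric; symmetrized {len(asym)} edge(s)", stacklevel=2)
    return graph


# ---------------------------------------------------------------------------
# Stratified counts and internal indirect standardization
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ["area_id", "disease", "age_class", "year", "deaths", "population"]


def read_counts(path) -> pd.DataFrame:
    """Read the stratified counts CSV (area_id, disease, age_class, year, deaths, population)."""
    df = pd.read_csv(path, dtype={"area_id": str, "disease": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts CSV missing columns: {missing}")
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["area_id"] = df["area_id"].astype(str)
    if (df["deaths"] < 0).any():
        raise ValueError("negative deaths")
    if (df["population"] < 0).any():
        raise ValueError("negative person-years")
    bad = df[(df["population"] == 0) & (df["deaths"] > 0)]
    if not bad.empty:
        raise ValueError(
            f"{len(bad)} records with deaths > 0 but zero person-years "
            f"(first: area {bad.iloc[0]['area_id']})"
        )
    unknown = set(df["disease"]) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown disease codes: {sorted(unknown)} (expected {DISEASES})")
    return df


@dataclass
class BivariateAreaData:
    """Observed and expected deaths per area for the two diseases.

    ``observed[k]`` and ``expected[k]`` are arrays over areas in the order of
    ``area_ids``, for disease ``k`` in ``("P", "O")``.  Internal indirect
    standardization guarantees ``expected[k].sum() == observed[k].sum()``.
    """

    area_ids: tuple[str, ...]
    observed: dict[str, np.ndarray]
    expected: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        for k in DISEASES:
            if k not in self.observed or k not in self.expected:
                raise ValueError(f"missing disease {k!r}")
            o, e = np.asarray(self.observed[k]), np.asarray(self.expected[k])
            if o.shape != (n,) or e.shape != (n,):
                raise ValueError("observed/expected length mismatch with area_ids")
            if (o < 0).any() or (e < 0).any():
                raise ValueError("negative observed or expected counts")
            self.observed[k] = o.astype(float)
            self.expected[k] = e.astype(float)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in DISEASES:
            rows.append(
                pd.DataFrame(
                    {
                        "area_id": self.area_ids,
                        "disease": k,
                        "observed": self.observed[k],
                        "expected": self.expected[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BivariateAreaData":
        area_ids = tuple(dict.fromkeys(df["area_id"].astype(str)))
        obs, exp_ = {}, {}
        for k in DISEASES:
            sub = df[df["disease"] == k].set_index(df[df["disease"] == k]["area_id"].astype(str))
            obs[k] = sub["observed"].reindex(area_ids).to_numpy(dtype=float)
            exp_[k] = sub["expected"].reindex(area_ids).to_numpy(dtype=float)
            if np.isnan(obs[k]).any() or np.isnan(exp_[k]).any():
                raise ValueError(f"disease {k!r}: missing areas in data frame")
        return cls(area_ids, obs, exp_)


def compute_expected(counts: pd.DataFrame, strata: tuple[str, ...] = ("age_class", "year")) -> BivariateAreaData:
    """Expected deaths per area and disease under internal indirect standardization.

    For each disease the regional rate of each stratum ``s`` (age class x year
    by default, age class only if ``strata=("age_class",)``) is
    ``r_ks = sum_j O_jks / sum_j PY_js`` and the area's expected count is
    ``E_ik = sum_s PY_is * r_ks``.  Summing over areas, observed and expected
    totals coincide per disease.
    """
    counts = validate_counts(counts)
    area_ids = tuple(dict.fromkeys(counts["area_id"]))
    observed, expected = {}, {}
    for k in DISEASES:
        sub = counts[counts["disease"] == k]
        if sub.empty:
            raise ValueError(f"no records for disease {k!r}")
        g = sub.groupby(list(strata), observed=True)
        totals = g.agg(deaths=("deaths", "sum"), py=("population", "sum"))
        bad = totals[(totals["deaths"] > 0) & (totals["py"] <= 0)]
        if not bad.empty:
            raise ValueError(f"disease {k!r}: stratum with deaths but zero person-years: {bad.index[0]}")
        rate = (totals["deaths"] / totals["py"].where(totals["py"] > 0)).fillna(0.0).rename("rate")
        merged = sub.merge(rate.reset_index(), on=list(strata), how="left")
        merged["e"] = merged["population"] * merged["rate"]
        per_area = merged.groupby("area_id", observed=True).agg(o=("deaths", "sum"), e=("e", "sum"))
        observed[k] = per_area["o"].reindex(area_ids).fillna(0.0).to_numpy(dtype=float)
        expected[k] = per_area["e"].reindex(area_ids).fillna(0.0).to_numpy(dtype=float)
    return BivariateAreaData(area_ids, observed, expected)


# ---------------------------------------------------------------------------
# SMRs and funnel plots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SMRRecord:
    area_id: str
    disease: str
    observed: float
    expected: float
    smr: float  # NaN where expected == 0 (undefined)
    one_sided_p: float


def funnel_pvalue(observed: int, expected: float) -> float:
    """Exact one-sided Poisson upper-tail probability P(X >= O | mean E).

    This is the funnel-plot exceedance p-value: the chance of observing at
    least as many deaths as seen if the area had the regional rate.
    """
    if expected <= 0:
        raise ValueError("expected must be positive")
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if observed == 0:
        return 1.0
    # P(X >= O) = sf(O - 1)
    return float(stats.poisson.sf(observed - 1, expected))


def compute_smr(data: BivariateAreaData) -> list[SMRRecord]:
    """SMR = O/E with the exact one-sided Poisson p-value per area and disease.

    Areas with E = 0 (zero person-years) are flagged with NaN SMR and p-value
    rather than divided.
    """
    records = []
    for k in DISEASES:
        for area, o, e in zip(data.area_ids, data.observed[k], data.expected[k]):
            if e > 0:
                records.append(SMRRecord(area, k, float(o), float(e), float(o) / e, funnel_pvalue(int(round(o)), e)))
            else:
                records.append(SMRRecord(area, k, float(o), float(e), math.nan, math.nan))
    return records


def smr_table(records: list[SMRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area_id": [r.area_id for r in records],
            "disease": [r.disease for r in records],
            "observed": [r.observed for r in records],
            "expected": [r.expected for r in records],
            "smr": [r.smr for r in records],
            "p_one_sided": [r.one_sided_p for r in records],
        }
    )


FUNNEL_LEVELS = (0.99, 0.999, 0.9999)


def funnel_band(e_grid, level: float) -> np.ndarray:
    """Upper funnel-plot control limit on the SMR scale at each expected count.

    For expected count ``E`` the band is ``q/E`` with ``q`` the smallest
    integer count such that ``P(X >= q | E) <= 1 - level`` — the exact Poisson
    quantile without continuity correction, so an SMR strictly below the band
    cannot be significant at the one-sided ``1 - level`` level.
    """
    if level not in FUNNEL_LEVELS:
        raise ValueError(f"level must be one of {FUNNEL_LEVELS}")
    e_grid = np.atleast_1d(np.asarray(e_grid, dtype=float))
    if (e_grid <= 0).any():
        raise ValueError("expected counts must be positive")
    # smallest q with sf(q-1) <= 1-level  <=>  cdf(q-1) >= level  <=>  q = ppf(level) + 1
    q = stats.poisson.ppf(level, e_grid) + 1.0
    return q / e_grid


def select_signal_areas(
    records: list[SMRRecord], p_threshold: float = 0.001, smr_threshold: float = 1.0
) -> list[SMRRecord]:
    """Areas exceeding the funnel criterion: one-sided p < threshold and SMR > threshold."""
    out = [
        r
        for r in records
        if not math.isnan(r.smr) and r.one_sided_p < p_threshold and r.smr > smr_threshold
    ]
    return sorted(out, key=lambda r: (r.area_id, r.disease))
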