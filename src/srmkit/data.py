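"""Data model and I/O for directed dyadic interaction networks.

A study population is described by a :class:`Roster` (one row per
individual, with social-group membership and optional individual-level
covariates), a :class:`DirectedDyadIndex` enumerating every ordered
within-group pair, and a :class:`DyadicDataset` bundling the observed
directed counts ``y[a, b]`` with dyad-level covariates (binary
relatedness, sampling effort).

Conventions
-----------
* Individual ids are 1-based integer labels, unique and contiguous.
* Dyads exist only within social groups; groups are closed.
* Directed dyads are ordered deterministically by (group, giver,
  receiver), and both directions of every unordered pair are present.
* Symmetric dyad-level covariates are stored once per directed row with
  equal values in the two directions.
* An edge-list row that is absent for one direction is an observed zero
  count, not missing data.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("srmkit")

ROSTER_COLUMNS = ["id", "group", "kin_group", "x", "rank", "effort"]


def standardize(values, name: str = "covariate") -> np.ndarray:
    """Z-transform a vector to mean 0 and sample SD 1 (ddof=1).

    Parameters
    ----------
    values : array-like, length >= 2
    name : label used in error messages.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"cannot standardize {name!r}: need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"cannot standardize {name!r}: zero variance")
    return (v - v.mean()) / sd


@dataclass
class Roster:
    """Individual-level table: id, group, kin_group, x, rank, effort.

    ``x`` is a unitless continuous covariate, ``rank`` lies in (0, 1]
    with lower values for more dominant individuals, and ``effort`` is
    the individual sampling effort in time units (> 0). Unused columns
    may hold NaN.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.copy().reset_index(drop=True)
        missing = [c for c in ("id", "group") if c not in t.columns]
        if missing:
            raise ValueError(f"roster is missing required columns {missing}")
        for c in ROSTER_COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        t = t[ROSTER_COLUMNS]
        ids = t["id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("roster is empty")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate individual ids in roster")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("individual ids must be contiguous 1..N")
        t = t.sort_values("id").reset_index(drop=True)
        rank = t["rank"].to_numpy(dtype=float)
        if np.any((rank <= 0) & ~np.isnan(rank)) or np.any(rank > 1):
            raise ValueError("ranks must lie in (0, 1]")
        eff = t["effort"].to_numpy(dtype=float)
        if np.any(eff[~np.isnan(eff)] <= 0):
            raise ValueError("sampling effort must be positive")
        self.table = t

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=int)

    @property
    def group(self) -> np.ndarray:
        return self.table["group"].to_numpy(dtype=int)

    @property
    def kin_group(self) -> np.ndarray:
        return self.table["kin_group"].to_numpy()

    @property
    def x(self) -> np.ndarray:
        return self.table["x"].to_numpy(dtype=float)

    @property
    def rank(self) -> np.ndarray:
        return self.table["rank"].to_numpy(dtype=float)

    @property
    def effort(self) -> np.ndarray:
        return self.table["effort"].to_numpy(dtype=float)


@dataclass
class DirectedDyadIndex:
    """Every ordered within-group pair (a, b), a != b, in canonical order.

    ``reverse[i]`` is the row of (b, a) for row i of (a, b);
    ``unordered[i]`` indexes the unordered dyad |a, b|; ``is_first[i]``
    marks the a < b direction, so rows ``np.where(is_first)`` enumerate
    each unordered dyad exactly once.
    """

    giver: np.ndarray
    receiver: np.ndarray
    reverse: np.ndarray
    unordered: np.ndarray
    is_first: np.ndarray
    _row_of: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self._row_of:
            self._row_of = {
                (int(a), int(b)): i
                for i, (a, b) in enumerate(zip(self.giver, self.receiver))
            }

    @property
    def n_directed(self) -> int:
        return len(self.giver)

    @property
    def n_unordered(self) -> int:
        return self.n_directed // 2

    def row(self, a: int, b: int) -> int:
        """Row index of directed dyad (a, b)."""
        return self._row_of[(int(a), int(b))]

    @property
    def first_rows(self) -> np.ndarray:
        """Directed rows of the a < b direction, one per unordered dyad."""
        return np.flatnonzero(self.is_first)

    @property
    def second_rows(self) -> np.ndarray:
        """Directed rows of the b > a direction, aligned with first_rows."""
        return self.reverse[self.first_rows]


def build_dyad_index(roster: Roster) -> DirectedDyadIndex:
    """Enumerate both directions of every within-group pair.

    Rows are sorted by (group, giver, receiver); the count equals
    sum over groups of n_g * (n_g - 1).
    """
    ids, groups = roster.ids, roster.group
    givers, receivers = [], []
    for g in np.unique(groups):
        members = np.sort(ids[groups == g])
        for a in members:
            for b in members:
                if a != b:
                    givers.append(int(a))
                    receivers.append(int(b))
    giver = np.asarray(givers, dtype=int)
    receiver = np.asarray(receivers, dtype=int)
    row_of = {(int(a), int(b)): i for i, (a, b) in enumerate(zip(giver, receiver))}
    reverse = np.asarray(
        [row_of[(int(b), int(a))] for a, b in zip(giver, receiver)], dtype=int
    )
    lo = np.minimum(giver, receiver)
    hi = np.maximum(giver, receiver)
    pairs = {}
    unordered = np.empty(len(giver), dtype=int)
    for i, key in enumerate(zip(lo, hi)):
        unordered[i] = pairs.setdefault((int(key[0]), int(key[1])), len(pairs))
    is_first = giver < receiver
    return DirectedDyadIndex(giver, receiver, reverse, unordered, is_first, row_of)


@dataclass
class DyadicDataset:
    """Observed directed counts plus individual- and dyad-level covariates.

    ``counts`` are nonnegative integers per directed dyad; ``relatedness``
    (binary) and ``dyadic_effort`` (positive; S[a] + S[b] when derived
    from the roster) are symmetric and stored per directed row.
    """

    roster: Roster
    dyads: DirectedDyadIndex
    counts: np.ndarray
    relatedness: np.ndarray | None = None
    dyadic_effort: np.ndarray | None = None

    def __post_init__(self):
        n = self.dyads.n_directed
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (n,):
            raise ValueError("counts must have one entry per directed dyad")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(int)
        rev = self.dyads.reverse
        for name in ("relatedness", "dyadic_effort"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} must have one entry per directed dyad")
                if not np.allclose(v, v[rev]):
                    raise ValueError(f"{name} must be symmetric in (a, b) <-> (b, a)")
                setattr(self, name, v)
        if self.dyadic_effort is not None and np.any(self.dyadic_effort <= 0):
            raise ValueError("dyadic_effort must be positive")

    @property
    def n_dyads(self) -> int:
        return self.dyads.n_directed

    def giver_pos(self) -> np.ndarray:
        """0-based roster positions of givers (ids are contiguous 1..N)."""
        return self.dyads.giver - 1

    def receiver_pos(self) -> np.ndarray:
        return self.dyads.receiver - 1

    def unordered_values(self, values: np.ndarray) -> np.ndarray:
        """Collapse a symmetric per-directed-row vector to one value per unordered dyad."""
        return np.asarray(values)[self.dyads.first_rows]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.counts.tobytes())
        h.update(self.dyads.giver.tobytes())
        h.update(self.dyads.receiver.tobytes())
        for v in (self.relatedness, self.dyadic_effort):
            if v is not None:
                h.update(np.asarray(v, dtype=float).tobytes())
        return h.hexdigest()[:16]


def derive_dyadic_effort(roster: Roster, dyads: DirectedDyadIndex) -> np.ndarray:
    """Dyad-level sampling effort S|a,b| = S[a] + S[b]."""
    eff = roster.effort
    if np.any(np.isnan(eff)):
        raise ValueError("roster effort is required to derive dyadic effort")
    return eff[dyads.giver - 1] + eff[dyads.receiver - 1]


def derive_relatedness(roster: Roster, dyads: DirectedDyadIndex) -> np.ndarray:
    """Binary relatedness: 1 iff the two individuals share a kin group."""
    k = roster.kin_group
    if pd.isna(k).any():
        raise ValueError("roster kin_group is required to derive relatedness")
    k = np.asarray(k)
    return (k[dyads.giver - 1] == k[dyads.receiver - 1]).astype(float)


# ---------------------------------------------------------------------------
# I/O: comma-delimited, header row mandatory, UTF-8.
# ---------------------------------------------------------------------------

def read_dataset(
    edge_list_path, roster_path, dyadic_path=None
) -> DyadicDataset:
    """Read a dataset from edge-list + roster (+ optional dyadic covariate) CSVs.

    Edge list columns: giver, receiver, count. Roster columns:
    id, group, kin_group, x, rank, effort (unused may be blank). Dyadic
    CSV columns: a, b, relatedness, effort_ab — one row per unordered
    dyad. Edge rows missing for one direction are filled with count 0
    (with a warning); unknown ids are rejected.
    """
    roster = Roster(pd.read_csv(roster_path))
    dyads = build_dyad_index(roster)
    edges = pd.read_csv(edge_list_path)
    for c in ("giver", "receiver", "count"):
        if c not in edges.columns:
            raise ValueError(f"edge list is missing column {c!r}")
    known = set(int(i) for i in roster.ids)
    counts = np.zeros(dyads.n_directed, dtype=int)
    seen = np.zeros(dyads.n_directed, dtype=bool)
    for a, b, y in zip(edges["giver"], edges["receiver"], edges["count"]):
        a, b = int(a), int(b)
        if a not in known or b not in known:
            raise ValueError(f"edge list references unknown individual ({a}, {b})")
        try:
            i = dyads.row(a, b)
        except KeyError:
            raise ValueError(
                f"edge ({a}, {b}) pairs individuals from different social groups"
            ) from None
        counts[i] = int(y)
        seen[i] = True
    n_missing = int((~seen).sum())
    if n_missing:
        missing = [
            (int(dyads.giver[i]), int(dyads.receiver[i]))
            for i in np.flatnonzero(~seen)[:5]
        ]
        warnings.warn(
            f"{n_missing} directed dyad(s) absent from edge list, e.g. {missing}; "
            "filled with count 0",
            stacklevel=2,
        )
    relatedness = dyadic_effort = None
    if dyadic_path is not None:
        dy = pd.read_csv(dyadic_path)
        relatedness = np.full(dyads.n_directed, np.nan)
        dyadic_effort = np.full(dyads.n_directed, np.nan)
        for _, r in dy.iterrows():
            i = dyads.row(int(r["a"]), int(r["b"]))
            j = dyads.reverse[i]
            for arr, col in ((relatedness, "relatedness"), (dyadic_effort, "effort_ab")):
                if col in dy.columns and not pd.isna(r[col]):
                    arr[i] = arr[j] = float(r[col])
        if np.isnan(relatedness).all():
            relatedness = None
        if np.isnan(dyadic_effort).all():
            dyadic_effort = None
    return DyadicDataset(roster, dyads, counts, relatedness, dyadic_effort)


def write_dataset(dataset: DyadicDataset, out_dir) -> dict[str, Path]:
    """Write canonical edge-list, roster, and dyadic-covariate CSVs.

    Returns the paths written. Round-trips with :func:`read_dataset`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.csv",
        "roster": out / "roster.csv",
        "dyadic": out / "dyadic.csv",
    }
    d = dataset.dyads
    pd.DataFrame(
        {"giver": d.giver, "receiver": d.receiver, "count": dataset.counts}
    ).to_csv(paths["edges"], index=False)
    dataset.roster.table.to_csv(paths["roster"], index=False)
    first = d.first_rows
    dyadic = pd.DataFrame(
        {
            "a": d.giver[first],
            "b": d.receiver[first],
            "relatedness": (
                dataset.relatedness[first] if dataset.relatedness is not None else np.nan
            ),
            "effort_ab": (
                dataset.dyadic_effort[first]
                if dataset.dyadic_effort is not None
                else np.nan
            ),
        }
    )
    dyadic.to_csv(paths["dyadic"], index=False)
    return paths


@dataclass
class SimulatedNetwork:
    """A simulated dataset bundled with its generative ground truth.

    ``gamma``/``rho`` are per-individual giving/receiving latents,
    ``tau`` the per-directed-dyad tie latent, ``rate_m`` the true
    Poisson rate; ``truth`` maps generative parameter names to values.
    """

    dataset: DyadicDataset
    gamma: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    rate_m: np.ndarray
    truth: dict
    seed: int

    def __post_init__(self):
        if np.any(self.rate_m <= 0):
            raise ValueError("all simulated rates must be strictly positive")

    def linear_predictor(self) -> np.ndarray:
        """log rate_m = intercept + gamma[a] + rho[b] + tau[a,b], exactly."""
        ds = self.dataset
        return (
            self.truth["intercept"]
            + self.gamma[ds.giver_pos()]
            + self.rho[ds.receiver_pos()]
            + self.tau
        )
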