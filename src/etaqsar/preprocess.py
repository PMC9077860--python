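"""Descriptor-matrix pretreatment and k-medoids train/test division.

Pretreatment drops uninformative columns (missing values, near-zero
variance, near-duplicate information) before feature selection.  The
train/test division clusters compounds in autoscaled descriptor space
with a PAM-style k-medoids and then takes ~34% of each cluster — spread
across the activity range — as the external test set, so both sets cover
the same region of chemical space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SD_CUT = 0.0001
DEFAULT_CORR_CUT = 0.95
DEFAULT_TEST_FRACTION = 0.34
DEFAULT_K = 5
MAX_KMEDOIDS_ITER = 300


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix joined with the pLC50 response."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.X.index.has_duplicates:
            raise ValueError("duplicate compound ids")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.X.index]

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    def subset_rows(self, ids: list[str]) -> "DescriptorTable":
        return DescriptorTable(self.X.loc[ids].copy(), self.y.loc[ids].copy())

    def subset_columns(self, cols: list[str]) -> "DescriptorTable":
        return DescriptorTable(self.X[list(cols)].copy(), self.y.copy())

    @classmethod
    def from_frames(cls, descriptors: pd.DataFrame, activity: dict[str, float]) -> "DescriptorTable":
        ids = [i for i in descriptors.index.astype(str) if i in activity]
        missing = set(descriptors.index.astype(str)) - set(ids)
        if missing:
            raise ValueError(f"no activity for ids: {sorted(missing)}")
        X = descriptors.loc[ids]
        y = pd.Series({i: activity[i] for i in ids}, name="pLC50").loc[ids]
        return cls(X, y)


@dataclass
class SplitResult:
    """Cluster assignment and train/test division of a compound set."""

    clusters: dict[str, int]
    medoid_ids: list[str]
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": self.train_ids,
            "test": self.test_ids,
            "clusters": self.clusters,
            "medoids": self.medoid_ids,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            clusters={k: int(v) for k, v in d["clusters"].items()},
            medoid_ids=d["medoids"],
            train_ids=d["train"],
            test_ids=d["test"],
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Pretreatment
# ---------------------------------------------------------------------------

def pretreat(
    table: DescriptorTable,
    sd_cut: float = DEFAULT_SD_CUT,
    corr_cut: float = DEFAULT_CORR_CUT,
) -> tuple[DescriptorTable, dict[str, str]]:
    """Column pretreatment; returns the reduced table and a removal log.

    Removal order: all-missing columns, any-missing columns, columns with
    SD < ``sd_cut``, then one member of every pair with |Pearson r| >=
    ``corr_cut`` (the lower-variance member goes; ties keep the earlier
    column).
    """
    X = table.X.copy()
    log: dict[str, str] = {}

    all_missing = [c for c in X.columns if X[c].isna().all()]
    X = X.drop(columns=all_missing)
    log.update({c: "all values missing" for c in all_missing})

    any_missing = [c for c in X.columns if X[c].isna().any()]
    X = X.drop(columns=any_missing)
    log.update({c: "missing value(s)" for c in any_missing})

    sds = X.std(ddof=1)
    near_constant = [c for c in X.columns if sds[c] < sd_cut or not math.isfinite(sds[c])]
    X = X.drop(columns=near_constant)
    log.update({c: f"near-constant (SD < {sd_cut})" for c in near_constant})

    # Correlation pruning: scan pairs in column order, greedily dropping the
    # lower-variance member of each offending pair.
    cols = list(X.columns)
    variances = X.var(ddof=1)
    corr = X.corr().abs()
    dropped: set[str] = set()
    for a_pos, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[a_pos + 1:]:
            if b in dropped:
                continue
            if corr.loc[a, b] >= corr_cut:
                victim, kept = (a, b) if variances[a] < variances[b] else (b, a)
                dropped.add(victim)
                log[victim] = f"|r| >= {corr_cut} with {kept}"
                if victim == a:
                    break
    X = X.drop(columns=sorted(dropped, key=cols.index))

    if X.shape[1] == 0:
        raise ValueError("pretreatment removed every descriptor column")
    return DescriptorTable(X, table.y.copy()), log


# ---------------------------------------------------------------------------
# k-medoids clustering and activity-ranked division
# ---------------------------------------------------------------------------

def autoscale(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def kmedoids(table: DescriptorTable, k: int = DEFAULT_K, seed: int = 0) -> SplitResult:
    """PAM-style k-medoids on autoscaled descriptors (Euclidean distance).

    Initialization is a seeded farthest-point sweep: the first medoid is
    drawn at random, each further medoid is the point farthest from the
    chosen set.  Assignment and medoid-update steps alternate until the
    assignment stabilizes (at most 300 iterations); an emptied cluster is
    re-seeded from the globally farthest point.
    """
    ids = table.ids
    n = len(ids)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = autoscale(table.X).to_numpy(dtype=float)
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))

    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        mind = D[:, medoids].min(axis=1)
        mind[medoids] = -1.0
        medoids.append(int(mind.argmax()))

    assign = D[:, medoids].argmin(axis=1)
    for _ in range(MAX_KMEDOIDS_ITER):
        # medoid update: cost-minimizing member of each cluster
        new_medoids = list(medoids)
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                # re-seed from the farthest point overall (logged via seed determinism)
                mind = D[:, new_medoids].min(axis=1)
                new_medoids[c] = int(mind.argmax())
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[costs.argmin()])
        new_assign = D[:, new_medoids].argmin(axis=1)
        if new_medoids == medoids and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign

    return SplitResult(
        clusters={ids[i]: int(assign[i]) for i in range(n)},
        medoid_ids=[ids[m] for m in medoids],
        seed=seed,
    )


def kmedoids_cost(table: DescriptorTable, result: SplitResult) -> float:
    """Total distance of points to their assigned medoid (autoscaled space)."""
    Z = autoscale(table.X)
    total = 0.0
    for cid, cluster in result.clusters.items():
        med = result.medoid_ids[cluster]
        total += float(np.linalg.norm(Z.loc[cid] - Z.loc[med]))
    return total


def split(
    clusters: SplitResult,
    y: pd.Series,
    test_fraction: float = DEFAULT_TEST_FRACTION,
) -> SplitResult:
    """Activity-ranked per-cluster division into train and test sets.

    Within each cluster, members are sorted by response (ties fall back to
    input order); every third member (ranks 2, 5, 8, ...) goes to the test
    set until the per-cluster quota round(test_fraction * size) is met,
    topping up with the next unpicked members if the stride runs out.
    """
    test_ids: list[str] = []
    train_ids: list[str] = []
    by_cluster: dict[int, list[str]] = {}
    order = {cid: pos for pos, cid in enumerate(y.index.astype(str))}
    for cid, c in clusters.clusters.items():
        by_cluster.setdefault(c, []).append(cid)
    for c in sorted(by_cluster):
        members = sorted(by_cluster[c], key=lambda i: (y.loc[i], order[i]))
        quota = math.floor(test_fraction * len(members) + 0.5)
        picks = list(range(1, len(members), 3))[:quota]
        if len(picks) < quota:
            remaining = [i for i in range(len(members)) if i not in picks]
            picks += remaining[: quota - len(picks)]
        pickset = set(picks)
        for pos, cid in enumerate(members):
            (test_ids if pos in pickset else train_ids).append(cid)
    in_order = [str(i) for i in y.index]
    return SplitResult(
        clusters=dict(clusters.clusters),
        medoid_ids=list(clusters.medoid_ids),
        train_ids=[i for i in in_order if i in set(train_ids)],
        test_ids=[i for i in in_order if i in set(test_ids)],
        seed=clusters.seed,
    )


def divide(
    table: DescriptorTable,
    k: int = DEFAULT_K,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> SplitResult:
    """Cluster then split: the standard one-call train/test division."""
    return split(kmedoids(table, k=k, seed=seed), table.y, test_fraction=test_fraction)
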