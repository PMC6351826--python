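"""Longitudinal clustering of marker-gene expression trajectories.

Marker panels (pluripotency genes switching on, fibroblast-identity genes
switching off) are followed over the reprogramming time course. Per gene,
replicate-averaged linear expression is log2-transformed and affinely
rescaled to "arbitrary units": the first day anchors to 0 and the last day
to 1 for ascending panels (1 -> 0 for descending panels). Because the
rescale is affine in log space, any per-gene constant reference or scale
cancels, so no explicit reference sample is required.

Trajectories are then clustered with longitudinal k-means: plain k-means on
the per-gene day vectors (Euclidean distance over the shared day grid,
best-of-``n_restarts`` initializations), with the number of clusters chosen
by the Calinski-Harabasz criterion over a candidate range. Genes are
processed in a canonical (probe-ID-sorted) order internally, which makes the
result invariant to input gene order and deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .clocks import validate_sample_sheet

__all__ = [
    "GenePanel",
    "TrajectorySet",
    "ClusterResult",
    "read_panel",
    "normalize_panel",
    "cluster_trajectories",
    "composite_report",
]

DIRECTIONS = ("ascending", "descending")


@dataclass
class GenePanel:
    """A marker-gene panel: gene symbols, platform probe accessions, the
    shared trend direction, and optional prior cluster hints.

    ``table`` columns: ``marker``, ``probe``, ``cluster_hint`` (nullable,
    genes published without a cluster label keep a missing hint and are
    flagged, not dropped), ``direction``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"marker", "probe", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        df = self.table.copy()
        if "cluster_hint" not in df.columns:
            df["cluster_hint"] = pd.NA
        if df["probe"].duplicated().any():
            raise ValueError("panel has duplicate probe IDs")
        directions = set(df["direction"])
        if len(directions) != 1 or not directions <= set(DIRECTIONS):
            raise ValueError(
                f"panel direction must be uniform and one of {DIRECTIONS}, got {directions}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def probes(self) -> list[str]:
        return list(self.table["probe"])

    @property
    def direction(self) -> str:
        return self.table["direction"].iloc[0]

    @property
    def unhinted(self) -> list[str]:
        """Markers published without a cluster membership label."""
        mask = self.table["cluster_hint"].isna()
        return list(self.table.loc[mask, "marker"])


def read_panel(path) -> GenePanel:
    """Read a comma-separated panel file (marker, probe, cluster_hint, direction)."""
    df = pd.read_csv(path, dtype={"cluster_hint": "string"})
    if "cluster_hint" in df.columns:
        df["cluster_hint"] = df["cluster_hint"].replace({"-": pd.NA, "": pd.NA})
    return GenePanel(df)


@dataclass
class TrajectorySet:
    """[0, 1]-anchored per-gene trajectories on a shared day grid.

    ``values`` is genes x days; endpoint anchoring is exact by construction:
    column 0 is identically 0 (ascending) or 1 (descending), the last column
    the opposite.
    """

    genes: list[str]            # probe IDs
    markers: list[str]          # gene symbols, aligned with genes
    days: np.ndarray
    values: np.ndarray
    direction: str

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if self.values.shape != (len(self.genes), self.days.size):
            raise ValueError("values must be genes x days")
        first, last = (0.0, 1.0) if self.direction == "ascending" else (1.0, 0.0)
        if not (np.all(self.values[:, 0] == first) and np.all(self.values[:, -1] == last)):
            raise ValueError("trajectories are not endpoint-anchored")


def normalize_panel(
    expr: pd.DataFrame, panel: GenePanel, sheet: pd.DataFrame
) -> TrajectorySet:
    """Turn linear-scale expression into endpoint-anchored log2 trajectories.

    Per gene: average replicates within each day, log2-transform, then
    affinely rescale so the first-day value maps to the direction-appropriate
    endpoint (0 for ascending, 1 for descending) and the last-day value to
    the other. Intermediate days may fall outside [0, 1] if the trajectory
    is non-monotone; that is allowed.

    Raises if any panel probe is absent from ``expr``, if any expression
    value is not strictly positive, or if a gene's first- and last-day log2
    values coincide (the rescale is then undefined).
    """
    sheet = validate_sample_sheet(sheet)
    absent = [p for p in panel.probes if p not in expr.index]
    if absent:
        raise KeyError(f"panel probes missing from expression matrix: {absent}")
    sub = expr.loc[panel.probes, sheet["sample"]]
    vals = sub.to_numpy(dtype=float)
    if not np.all(vals > 0):
        raise ValueError("expression values must be strictly positive (linear scale)")

    days = np.unique(sheet["day"].to_numpy(dtype=float))
    if days.size < 2:
        raise ValueError("need >= 2 distinct days")
    day_of = sheet.set_index("sample")["day"]
    # replicate mean per day on the linear scale, then log2
    per_day = np.column_stack(
        [vals[:, (day_of[sub.columns] == d).to_numpy()].mean(axis=1) for d in days]
    )
    log2 = np.log2(per_day)

    v0, vL = log2[:, 0], log2[:, -1]
    flat = v0 == vL
    if flat.any():
        names = [panel.table["marker"].iloc[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"degenerate gene(s), equal first/last log2 expression: {names}")
    if panel.direction == "ascending":
        scaled = (log2 - v0[:, None]) / (vL - v0)[:, None]
    else:
        scaled = (log2 - vL[:, None]) / (v0 - vL)[:, None]
    return TrajectorySet(
        genes=panel.probes,
        markers=list(panel.table["marker"]),
        days=days,
        values=scaled,
        direction=panel.direction,
    )


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series          # probe ID -> cluster label (1-based)
    criterion: dict[int, float]    # candidate k -> Calinski-Harabasz score (NaN for k=1)
    seed: int
    composite: pd.DataFrame = field(default=None)  # cluster, day, mean, sd, n_genes


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[lab] for lab in raw])


def cluster_trajectories(
    ts: TrajectorySet,
    k_range=range(1, 7),
    n_restarts: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """Longitudinal k-means over the per-gene day vectors.

    Each candidate k is fitted with ``n_restarts`` initializations (best by
    within-cluster sum of squares); the k maximizing the Calinski-Harabasz
    criterion is selected. k = 1 has no defined criterion (recorded as NaN)
    and is selected only when it is the sole candidate. Genes are clustered
    in probe-ID-sorted order so the result does not depend on input order.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n_genes = len(ts.genes)
    if not k_range:
        raise ValueError("k_range is empty")
    if k_range[0] < 1 or k_range[-1] > n_genes:
        raise ValueError(f"k_range must lie within [1, {n_genes}], got {k_range}")

    order = np.argsort(np.asarray(ts.genes, dtype=object))
    X = ts.values[order]
    sorted_genes = [ts.genes[i] for i in order]

    criterion: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k == 1:
            labels_by_k[k] = np.ones(n_genes, dtype=int)
            criterion[k] = float("nan")
            continue
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=(seed * 1009 + k) % (2**31),
        ).fit(X)
        labels_by_k[k] = _canonical_labels(km.labels_)
        if k < n_genes:
            criterion[k] = float(calinski_harabasz_score(X, km.labels_))
        else:  # every gene its own cluster: criterion degenerates
            criterion[k] = float("inf")

    finite = {k: c for k, c in criterion.items() if not np.isnan(c)}
    best_k = max(finite, key=finite.get) if finite else k_range[0]

    assignment = pd.Series(
        labels_by_k[best_k], index=pd.Index(sorted_genes, name="probe"), name="cluster"
    ).reindex(ts.genes)
    result = ClusterResult(
        k=best_k, assignment=assignment, criterion=criterion, seed=seed
    )
    result.composite = composite_report(result, ts)
    return result


def composite_report(cr: ClusterResult, ts: TrajectorySet) -> pd.DataFrame:
    """Per-cluster composite trajectories: mean +/- SD over member genes.

    Returns rows (cluster, day, mean, sd, n_genes); SD is the sample
    standard deviation over member genes (0 for singleton clusters).
    """
    labels = cr.assignment.reindex(ts.genes).to_numpy()
    rows = []
    for cluster in sorted(set(labels)):
        member = ts.values[labels == cluster]
        sd = member.std(axis=0, ddof=1) if member.shape[0] > 1 else np.zeros(ts.days.size)
        for j, day in enumerate(ts.days):
            rows.append(
                {
                    "cluster": int(cluster),
                    "day": float(day),
                    "mean": float(member[:, j].mean()),
                    "sd": float(sd[j]),
                    "n_genes": int(member.shape[0]),
                }
            )
    return pd.DataFrame(rows)
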