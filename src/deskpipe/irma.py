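"""Rank-aggregation meta-algorithm for image registration selection.

Many candidate alignments of a reference volume (produced by different
registration families) are scored with a battery of similarity-cost metrics
(lower = better), rank-transformed within each metric, and the candidate
with the best consensus (median) rank wins.  Rank aggregation makes the
selection invariant to any strictly monotone rescaling of individual
metrics, which is the point: the metrics live on incomparable scales.

The battery defaults to 11 metrics and always includes

* **EDI** — Shannon entropy of the histogram of voxelwise intensity
  differences (64 bins over the observed difference range).  Zero when the
  difference image is constant (identical or offset candidates).
* **Woods' coefficient** — the reference intensity range is split into 16
  equal-width classes; the cost is the mean over nonempty classes of
  std/mean of the candidate intensities falling in each class.  Zero when
  the candidate is constant within every reference class (e.g. identical
  candidates over a piecewise-constant reference).

The remaining slots are standard voxelwise costs (MSE, MAE, RMSE, median
absolute difference, Chebyshev, normalized SSD, 1-|NCC|, gradient-magnitude
MSE, joint-entropy-normalized mutual-information cost).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Metric",
    "MetricBattery",
    "CostMatrix",
    "RankMatrix",
    "default_battery",
    "evaluate_battery",
    "rank_transform",
    "select_best",
    "export_parallel_coordinates",
    "import_parallel_coordinates",
    "edi",
    "woods",
    "EDI_BINS",
    "WOODS_CLASSES",
    "FAMILIES",
]

FAMILIES = ("air-linear", "air-warp", "flirt", "minc-tracc")

EDI_BINS = 64
WOODS_CLASSES = 16


# ---------------------------------------------------------------------------
# metrics (all deterministic functions of two same-shape volumes; lower =
# better; documented optimum on identical inputs is 0 for every default
# metric, for Woods under a piecewise-constant reference)
# ---------------------------------------------------------------------------


def edi(reference: np.ndarray, candidate: np.ndarray, bins: int = EDI_BINS) -> float:
    """Entropy of the difference-intensity histogram.

    A constant difference image (identical candidate, or candidate =
    reference + offset) occupies a single bin, so the entropy is 0.
    """
    diff = (candidate.astype(np.float64) - reference.astype(np.float64)).ravel()
    lo, hi = float(diff.min()), float(diff.max())
    if hi == lo:
        return 0.0
    hist, _ = np.histogram(diff, bins=bins, range=(lo, hi))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def woods(reference: np.ndarray, candidate: np.ndarray, classes: int = WOODS_CLASSES) -> float:
    """Woods' criterion: mean over reference-intensity classes of the
    coefficient of variation (std/mean) of candidate intensities."""
    ref = reference.astype(np.float64).ravel()
    cand = candidate.astype(np.float64).ravel()
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        idx = np.zeros(ref.shape, dtype=np.int64)
    else:
        idx = np.minimum(((ref - lo) / (hi - lo) * classes).astype(np.int64), classes - 1)
    cvs = []
    for k in range(classes):
        members = cand[idx == k]
        if members.size == 0:
            continue
        mean = members.mean()
        if mean == 0:
            continue
        cvs.append(members.std() / abs(mean))
    return float(np.mean(cvs)) if cvs else 0.0


def _mse(r: np.ndarray, c: np.ndarray) -> float:
    return float(np.mean((c.astype(np.float64) - r.astype(np.float64)) ** 2))


def _mae(r: np.ndarray, c: np.ndarray) -> float:
    return float(np.mean(np.abs(c.astype(np.float64) - r.astype(np.float64))))


def _rmse(r: np.ndarray, c: np.ndarray) -> float:
    return float(np.sqrt(_mse(r, c)))


def _median_abs(r: np.ndarray, c: np.ndarray) -> float:
    return float(np.median(np.abs(c.astype(np.float64) - r.astype(np.float64))))


def _chebyshev(r: np.ndarray, c: np.ndarray) -> float:
    return float(np.max(np.abs(c.astype(np.float64) - r.astype(np.float64))))


def _nssd(r: np.ndarray, c: np.ndarray) -> float:
    """SSD normalized by the reference variance (scale-free MSE)."""
    var = float(np.var(r.astype(np.float64)))
    return _mse(r, c) / var if var > 0 else _mse(r, c)


def _ncc_cost(r: np.ndarray, c: np.ndarray) -> float:
    """1 - |normalized cross-correlation|; 0 on identical inputs."""
    a = r.astype(np.float64).ravel()
    b = c.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0 if np.allclose(r, c) else 1.0
    return float(1.0 - abs((a @ b) / denom))


def _gradient_mse(r: np.ndarray, c: np.ndarray) -> float:
    """MSE of gradient magnitudes (edge-alignment sensitivity)."""
    def gmag(x: np.ndarray) -> np.ndarray:
        grads = np.gradient(x.astype(np.float64))
        return np.sqrt(sum(g ** 2 for g in grads))

    return _mse(gmag(r), gmag(c))


def _nmi_cost(r: np.ndarray, c: np.ndarray, bins: int = 32) -> float:
    """2 - NMI where NMI = (H(a) + H(b)) / H(a, b); 0 on identical inputs."""
    a = r.astype(np.float64).ravel()
    b = c.astype(np.float64).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    hj = entropy(pj.ravel())
    if hj == 0:
        return 0.0
    return float(2.0 - (entropy(pa) + entropy(pb)) / hj)


@dataclass(frozen=True)
class Metric:
    metric_id: str
    fn: Callable[[np.ndarray, np.ndarray], float]
    optimum: float = 0.0  # documented value on identical inputs


@dataclass(frozen=True)
class MetricBattery:
    metrics: tuple[Metric, ...]

    def __len__(self) -> int:
        return len(self.metrics)

    def ids(self) -> list[str]:
        return [m.metric_id for m in self.metrics]


def default_battery(size: int = 11) -> MetricBattery:
    """The default battery; EDI and Woods always lead, the rest fill the
    configured size in documented order."""
    pool = [
        Metric("edi", edi),
        Metric("woods", woods),
        Metric("mse", _mse),
        Metric("mae", _mae),
        Metric("rmse", _rmse),
        Metric("median_abs", _median_abs),
        Metric("chebyshev", _chebyshev),
        Metric("nssd", _nssd),
        Metric("ncc_cost", _ncc_cost),
        Metric("gradient_mse", _gradient_mse),
        Metric("nmi_cost", _nmi_cost),
    ]
    if not 2 <= size <= len(pool):
        raise ValueError(f"battery size must be in [2, {len(pool)}]")
    return MetricBattery(metrics=tuple(pool[:size]))


# ---------------------------------------------------------------------------
# cost and rank matrices
# ---------------------------------------------------------------------------


@dataclass
class CostMatrix:
    """Rows: alignment instances; columns: metrics; entries: costs."""

    instance_ids: list[str]
    families: list[str]
    metric_ids: list[str]
    values: np.ndarray  # (instances, metrics)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.instance_ids) != n or len(self.families) != n:
            raise ValueError("row labels do not match value matrix")
        if len(self.metric_ids) != m:
            raise ValueError("column labels do not match value matrix")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.metric_ids)
        df.insert(0, "instance", self.instance_ids)
        df.insert(1, "family", self.families)
        return df


@dataclass
class RankMatrix:
    """Within-column ranks of a CostMatrix: 1 = best, average-rank ties.
    Every column is a permutation of 1..n up to tie-averaging."""

    instance_ids: list[str]
    families: list[str]
    metric_ids: list[str]
    ranks: np.ndarray  # (instances, metrics)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranks, columns=self.metric_ids)
        df.insert(0, "instance", self.instance_ids)
        df.insert(1, "family", self.families)
        return df


def evaluate_battery(
    reference: np.ndarray,
    candidates: Mapping[str, np.ndarray] | Sequence[tuple[str, str, np.ndarray]],
    battery: MetricBattery | None = None,
    families: Mapping[str, str] | None = None,
) -> CostMatrix:
    """One cost per (candidate, metric).

    ``candidates`` is either a mapping id -> volume (with ``families``
    mapping id -> family tag) or a sequence of (id, family, volume).
    All volumes must share the reference's shape.
    """
    battery = battery or default_battery()
    if isinstance(candidates, Mapping):
        triples = [(cid, (families or {}).get(cid, "unknown"), vol)
                   for cid, vol in candidates.items()]
    else:
        triples = list(candidates)
    ids = [t[0] for t in triples]
    fams = [t[1] for t in triples]
    rows = []
    for cid, _, vol in triples:
        if vol.shape != reference.shape:
            raise ValueError(
                f"candidate {cid!r} shape {vol.shape} != reference {reference.shape}"
            )
        rows.append([m.fn(reference, vol) for m in battery.metrics])
    return CostMatrix(
        instance_ids=ids,
        families=fams,
        metric_ids=battery.ids(),
        values=np.asarray(rows, dtype=float),
    )


def rank_transform(costs: CostMatrix) -> RankMatrix:
    """Per-column ranks ascending in cost (1 = best); ties get the average
    rank."""
    if len(costs.instance_ids) < 2:
        raise ValueError("rank transform needs at least 2 instances")
    ranks = np.column_stack(
        [stats.rankdata(costs.values[:, j], method="average")
         for j in range(costs.values.shape[1])]
    )
    return RankMatrix(
        instance_ids=list(costs.instance_ids),
        families=list(costs.families),
        metric_ids=list(costs.metric_ids),
        ranks=ranks,
    )


@dataclass
class Selection:
    instance_id: str
    family: str
    median_rank: float
    mean_rank: float
    family_order: list[tuple[str, float]]  # (family, best member's median rank)


def select_best(ranks: RankMatrix) -> Selection:
    """Consensus selection: minimal median rank across metrics; ties broken
    by mean rank, then by row order.  Families are ordered by their best
    member's (median, mean) key."""
    if len(ranks.instance_ids) == 0:
        raise ValueError("empty rank matrix")
    medians = np.median(ranks.ranks, axis=1)
    means = ranks.ranks.mean(axis=1)
    order = sorted(range(len(medians)), key=lambda i: (medians[i], means[i], i))
    best = order[0]
    fam_best: dict[str, tuple[float, float]] = {}
    for i in order:
        fam = ranks.families[i]
        if fam not in fam_best:
            fam_best[fam] = (float(medians[i]), float(means[i]))
    family_order = sorted(fam_best.items(), key=lambda kv: kv[1])
    return Selection(
        instance_id=ranks.instance_ids[best],
        family=ranks.families[best],
        median_rank=float(medians[best]),
        mean_rank=float(means[best]),
        family_order=[(fam, key[0]) for fam, key in family_order],
    )


# ---------------------------------------------------------------------------
# parallel-coordinates export
# ---------------------------------------------------------------------------


def export_parallel_coordinates(ranks: RankMatrix, path: str) -> str:
    """CSV: one row per instance, identity columns (instance, family) then
    one rank column per metric.  Round-trips through
    :func:`import_parallel_coordinates`."""
    if not ranks.metric_ids:
        raise ValueError("empty battery: nothing to export")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["instance", "family"] + list(ranks.metric_ids))
        for i, iid in enumerate(ranks.instance_ids):
            writer.writerow(
                [iid, ranks.families[i]] + [f"{v:g}" for v in ranks.ranks[i]]
            )
    return path


def import_parallel_coordinates(path: str) -> RankMatrix:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    metric_ids = header[2:]
    instance_ids = [r[0] for r in rows[1:]]
    families = [r[1] for r in rows[1:]]
    values = np.asarray([[float(v) for v in r[2:]] for r in rows[1:]], dtype=float)
    return RankMatrix(instance_ids, families, metric_ids, values)
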