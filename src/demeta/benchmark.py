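"""Dataset accreditation: seven metrics, group distributions, stars.

Bulk transcriptomic datasets are heterogeneous in depth, platform
behaviour and effect-size spread.  Rather than modelling that
variability, each dataset/comparison is scored on seven descriptive
metrics, the metrics are pooled within groups of comparable datasets
(same species and technology; exclusively non-coding datasets form
their own groups), and a dataset earns one star per metric whose value
falls inside the group's central band (the closed interquartile range
by default).  Seven stars is the maximum; stars encode within-group
similarity, not biological quality.

The seven metrics:

1. number of detected features;
2. number of differentially expressed (DE) features;
3. number of known pro-fibrotic panel genes among the DE features;
4. counts of DE features with low (1.2 < |FC| < 2), intermediate
   (2 <= |FC| < 5) and high (|FC| >= 5) absolute linear fold change —
   a triple that earns a single star, granted only when all three
   counts sit inside their bands;
5. ratio of up- to down-regulated features, with +1 pseudocounts so a
   dataset with zero down-calls remains scoreable;
6. area under the empirical CDF of nominal p-values on [0, 1]
   (0.5 under uniform p-values; larger means more small p-values);
7. the same area for FDR-adjusted p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import (
    DEFAULT_GENE_THRESHOLDS,
    DEATable,
    DatasetMeta,
    DEThresholds,
    DOWN,
    UP,
)

logger = logging.getLogger(__name__)

#: The seven star-bearing metrics, in reporting order.
METRIC_NAMES = (
    "n_detected",
    "n_de",
    "n_profibrotic_de",
    "fc_bins",
    "updown_ratio",
    "auc_p_nominal",
    "auc_p_adjusted",
)

#: Scalar components per metric (the fc-bin triple expands to three).
METRIC_COMPONENTS: dict[str, tuple[str, ...]] = {
    "n_detected": ("n_detected",),
    "n_de": ("n_de",),
    "n_profibrotic_de": ("n_profibrotic_de",),
    "fc_bins": ("fc_low", "fc_mid", "fc_high"),
    "updown_ratio": ("updown_ratio",),
    "auc_p_nominal": ("auc_p_nominal",),
    "auc_p_adjusted": ("auc_p_adjusted",),
}

ALL_COMPONENTS = tuple(c for m in METRIC_NAMES for c in METRIC_COMPONENTS[m])


@dataclass(frozen=True)
class ProFibroticPanel:
    """Curated genes implicated in pulmonary fibrosis, per species."""

    species: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("pro-fibrotic panel must be non-empty")


def load_panel(path: str | Path, species: str) -> ProFibroticPanel:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return ProFibroticPanel(species=species, genes=frozenset(genes))


@dataclass(frozen=True)
class BenchmarkMetrics:
    """The seven metric values for one dataset/comparison."""

    n_detected: int
    n_de: int
    n_profibrotic_de: int
    fc_bins: tuple[int, int, int]
    updown_ratio: float
    auc_p_nominal: float
    auc_p_adjusted: float

    def components(self) -> dict[str, float]:
        """Flatten to the nine scalar components used for banding."""
        low, mid, high = self.fc_bins
        return {
            "n_detected": float(self.n_detected),
            "n_de": float(self.n_de),
            "n_profibrotic_de": float(self.n_profibrotic_de),
            "fc_low": float(low),
            "fc_mid": float(mid),
            "fc_high": float(high),
            "updown_ratio": float(self.updown_ratio),
            "auc_p_nominal": float(self.auc_p_nominal),
            "auc_p_adjusted": float(self.auc_p_adjusted),
        }


def ecdf_auc(pvals: np.ndarray) -> float:
    """Area under the empirical CDF of p-values over [0, 1].

    The ECDF is linearly interpolated through (0, 0), the sorted sample
    points at heights i/n, and (1, 1); the trapezoidal area of that
    polyline is returned.  Uniform p-values give ~0.5.  NaN entries are
    dropped; an all-missing vector yields NaN (metric ineligible).
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    n = p.size
    x = np.concatenate(([0.0], np.sort(p), [1.0]))
    y = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    return float(np.trapezoid(y, x))


def compute_metrics(
    table: DEATable,
    panel: ProFibroticPanel,
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
) -> BenchmarkMetrics:
    """Compute the seven benchmarking metrics for one table."""
    if panel.species != table.meta.species:
        raise ValueError(
            f"panel species {panel.species!r} does not match table species "
            f"{table.meta.species!r} ({table.meta.dataset_id})"
        )
    calls = table.classify(thresholds)
    de_mask = calls != "non_de"
    de_ids = set(table.data.index[de_mask])
    n_up = int((calls == UP).sum())
    n_down = int((calls == DOWN).sum())

    # bin on the log2 scale with log2-converted boundaries so that a fold
    # change stored as log2(x) lands in the bin of linear x exactly
    abs_lfc = np.abs(table.data.loc[de_mask, "log2fc"].to_numpy())
    lo_cut, mid_cut, high_cut = thresholds.log2_min_fc, 1.0, math.log2(5.0)
    n_low = int(np.sum((abs_lfc > lo_cut) & (abs_lfc < mid_cut)))
    n_mid = int(np.sum((abs_lfc >= mid_cut) & (abs_lfc < high_cut)))
    n_high = int(np.sum(abs_lfc >= high_cut))

    return BenchmarkMetrics(
        n_detected=len(table),
        n_de=n_up + n_down,
        n_profibrotic_de=len(panel.genes & de_ids),
        fc_bins=(n_low, n_mid, n_high),
        updown_ratio=(n_up + 1) / (n_down + 1),
        auc_p_nominal=ecdf_auc(table.data["p_nominal"].to_numpy()),
        auc_p_adjusted=ecdf_auc(table.data["p_adjusted"].to_numpy()),
    )


# ---------------------------------------------------------------------------
# grouping, distributions, star assignment
# ---------------------------------------------------------------------------

DEFAULT_GROUPING = ("species", "technology")
DEFAULT_BAND = (0.25, 0.75)
DEFAULT_MIN_GROUP_SIZE = 3


def group_key(meta: DatasetMeta, grouping: Sequence[str] = DEFAULT_GROUPING) -> tuple:
    """Grouping key for a dataset; exclusively non-coding datasets are
    always kept apart from coding/mixed ones."""
    key = [
        meta.comparison.raw if g == "comparison" else getattr(meta, g)
        for g in grouping
    ]
    scope = "noncoding" if meta.biotype_scope == "noncoding" else "coding"
    return (*key, scope)


@dataclass(frozen=True)
class GroupDistribution:
    """Per-metric star intervals for one dataset group.

    ``intervals`` maps each scalar component to its closed band
    ``[lo, hi]`` — the group's (q_lo, q_hi) quantiles computed with
    linear interpolation between order statistics.
    """

    key: tuple
    n_members: int
    band: tuple[float, float]
    intervals: dict[str, tuple[float, float]]


def build_group_distributions(
    items: Iterable[tuple[DatasetMeta, BenchmarkMetrics]],
    grouping: Sequence[str] = DEFAULT_GROUPING,
    band: tuple[float, float] = DEFAULT_BAND,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> dict[tuple, GroupDistribution]:
    """Pool metric values within groups and form quantile bands.

    Groups with fewer than ``min_group_size`` members yield no
    distribution (their members later receive an NA star report).
    """
    items = list(items)
    if not items:
        raise ValueError("no benchmark results to group")
    q_lo, q_hi = band
    if not (0.0 <= q_lo < q_hi <= 1.0):
        raise ValueError(f"band must satisfy 0 <= q_lo < q_hi <= 1, got {band}")

    groups: dict[tuple, list[BenchmarkMetrics]] = {}
    for meta, metrics in items:
        groups.setdefault(group_key(meta, grouping), []).append(metrics)

    out: dict[tuple, GroupDistribution] = {}
    for key, members in groups.items():
        if len(members) < min_group_size:
            logger.info("group %s has %d member(s) < %d; no distribution",
                        key, len(members), min_group_size)
            continue
        intervals: dict[str, tuple[float, float]] = {}
        for comp in ALL_COMPONENTS:
            values = np.array([m.components()[comp] for m in members], dtype=float)
            values = values[~np.isnan(values)]
            if values.size == 0:
                intervals[comp] = (float("nan"), float("nan"))
            else:
                lo = float(np.quantile(values, q_lo, method="linear"))
                hi = float(np.quantile(values, q_hi, method="linear"))
                intervals[comp] = (lo, hi)
        out[key] = GroupDistribution(key=key, n_members=len(members), band=(q_lo, q_hi),
                                     intervals=intervals)
    return out


@dataclass(frozen=True)
class StarReport:
    """Accreditation outcome for one dataset/comparison.

    ``stars`` maps each of the seven metrics to a boolean, or to None
    for the NA case (group too small to form distributions), in which
    case ``total_stars`` is None as well.
    """

    dataset_id: str
    comparison: str
    stars: dict[str, bool | None]
    total_stars: int | None

    @property
    def eligible(self) -> bool:
        return self.total_stars is not None


def _na_report(meta: DatasetMeta) -> StarReport:
    return StarReport(
        dataset_id=meta.dataset_id,
        comparison=meta.comparison.raw,
        stars={m: None for m in METRIC_NAMES},
        total_stars=None,
    )


def _inside(value: float, interval: tuple[float, float]) -> bool:
    lo, hi = interval
    if math.isnan(value) or math.isnan(lo) or math.isnan(hi):
        return False
    return lo <= value <= hi


def assign_stars(
    meta: DatasetMeta,
    metrics: BenchmarkMetrics,
    dist: GroupDistribution,
) -> StarReport:
    """One star per metric whose value lies within the closed group band.

    The fold-change-bin triple earns its single star only when all three
    bin counts sit inside their respective bands; a missing metric value
    never earns a star.
    """
    comps = metrics.components()
    stars: dict[str, bool | None] = {}
    for metric in METRIC_NAMES:
        stars[metric] = all(
            _inside(comps[c], dist.intervals[c]) for c in METRIC_COMPONENTS[metric]
        )
    return StarReport(
        dataset_id=meta.dataset_id,
        comparison=meta.comparison.raw,
        stars=stars,
        total_stars=sum(bool(s) for s in stars.values()),
    )


def benchmark_collection(
    tables: Sequence[DEATable],
    panels: Mapping[str, ProFibroticPanel],
    thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS,
    grouping: Sequence[str] = DEFAULT_GROUPING,
    band: tuple[float, float] = DEFAULT_BAND,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    comparison: str | None = None,
) -> list[StarReport]:
    """End-to-end accreditation: compute, group, band, assign.

    ``panels`` maps species to its pro-fibrotic panel.  ``comparison``,
    when given, restricts benchmarking to tables with that exact
    comparison label (e.g. re-running on ``IPF_vs_Ctrl`` only).
    Datasets in groups below ``min_group_size`` receive NA reports.
    """
    selected = [t for t in tables
                if comparison is None or t.meta.comparison.raw == comparison]
    if not selected:
        raise ValueError("no tables to benchmark")
    scored = [(t.meta, compute_metrics(t, panels[t.meta.species], thresholds))
              for t in selected]
    dists = build_group_distributions(scored, grouping, band, min_group_size)
    reports = []
    for meta, metrics in scored:
        key = group_key(meta, grouping)
        if key in dists:
            reports.append(assign_stars(meta, metrics, dists[key]))
        else:
            reports.append(_na_report(meta))
    return reports
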