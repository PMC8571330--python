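"""Core domain types for differential-expression meta-integration.

A *DEA table* is one dataset's differential expression analysis result:
per feature (gene, miRNA, or protein) a log2 fold change, a nominal
p-value and an FDR-adjusted p-value, together with dataset metadata
(species, technology, platform, tissue, comparison label, sample count).
Everything downstream — benchmarking, consensus calling, network
annotation — consumes these tables through the types defined here.

Fold changes are stored on the log2 scale; the linear cutoffs used
throughout the field (1.2, 2, 5) are applied after ``2**|log2fc|``
conversion.  Both differential-expression inequalities are strict: a
feature at exactly ``|FC| = 1.2`` or ``p = 0.05`` is not called.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")
TECHNOLOGIES = ("microarray", "rnaseq")
BIOTYPE_SCOPES = ("coding", "noncoding", "mixed")

#: Differential-expression call values.
UP, DOWN, NON_DE = "up", "down", "non_de"

#: Default column-name mapping for tab-delimited DEA tables.
DEFAULT_COLUMNS: dict[str, str] = {
    "feature": "feature",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


class ComparisonParseError(ValueError):
    """A comparison label does not follow the A_vs_B controlled vocabulary."""


class TableFormatError(ValueError):
    """A tab-delimited input file violates the expected schema."""


# ---------------------------------------------------------------------------
# comparison-label controlled vocabulary
# ---------------------------------------------------------------------------

_DAY_RE = re.compile(r"D(\d+)$")


@dataclass(frozen=True)
class ComparisonLabel:
    """A three-part comparison phrase ``A_vs_B``.

    ``condition_a`` and ``condition_b`` are the two experimental
    conditions; ``day``, when present, was parsed from a trailing
    ``D<digits>`` token of either condition (sampling day relative to
    treatment start, e.g. ``BleomD14_vs_Ctrl`` -> day 14).  ``raw``
    preserves the label exactly as parsed.
    """

    condition_a: str
    condition_b: str
    day: int | None
    raw: str


def parse_comparison_label(raw: str) -> ComparisonLabel:
    """Parse a comparison label of the controlled vocabulary.

    Splits on the literal token ``_vs_`` (a ``" vs "`` separator is also
    accepted).  Raises :class:`ComparisonParseError` when the separator
    is missing or appears more than once.
    """
    if not raw:
        raise ComparisonParseError("empty comparison label")
    for sep in ("_vs_", " vs "):
        parts = raw.split(sep)
        if len(parts) == 2:
            a, b = parts
            if not a or not b:
                raise ComparisonParseError(f"malformed comparison label: {raw!r}")
            day = None
            for side in (a, b):
                m = _DAY_RE.search(side)
                if m:
                    day = int(m.group(1))
                    break
            return ComparisonLabel(condition_a=a, condition_b=b, day=day, raw=raw)
        if len(parts) > 2:
            raise ComparisonParseError(
                f"comparison label contains more than one {sep.strip()!r} token: {raw!r}"
            )
    raise ComparisonParseError(f"comparison label lacks a '_vs_' token: {raw!r}")


# ---------------------------------------------------------------------------
# per-feature statistics and thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureStat:
    """One feature's DEA statistics.  Missing values are NaN."""

    feature_id: str
    log2fc: float
    p_nominal: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        for name in ("p_nominal", "p_adjusted"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v} ({self.feature_id})")


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression cutoffs.

    ``min_abs_fc`` is a *linear* fold-change floor (default 1.2) applied
    to ``2**|log2fc|``; ``max_p`` the p-value ceiling (default 0.05).
    ``use_adjusted`` selects the FDR-adjusted p-value instead of the
    nominal one — the convention for miRNA integration, while gene
    integration uses nominal p-values to keep borderline features that
    recur across datasets.
    """

    min_abs_fc: float = 1.2
    max_p: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.min_abs_fc > 1.0:
            raise ValueError(f"min_abs_fc must exceed 1 (linear scale): {self.min_abs_fc}")
        if not 0.0 < self.max_p < 1.0:
            raise ValueError(f"max_p must lie in (0, 1): {self.max_p}")

    @property
    def log2_min_fc(self) -> float:
        return math.log2(self.min_abs_fc)


DEFAULT_GENE_THRESHOLDS = DEThresholds()
DEFAULT_MIRNA_THRESHOLDS = DEThresholds(use_adjusted=True)


def classify_de(stat: FeatureStat, thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS) -> str:
    """Classify one feature as ``up``, ``down`` or ``non_de``.

    Up iff ``2**log2fc > min_abs_fc`` and ``p < max_p`` (both strict);
    down symmetrically for the reciprocal fold change.  Missing
    statistics never produce a call.
    """
    p = stat.p_adjusted if thresholds.use_adjusted else stat.p_nominal
    if math.isnan(stat.log2fc) or math.isnan(p):
        logger.warning("missing statistics for %s; classified non_de", stat.feature_id)
        return NON_DE
    if p < thresholds.max_p:
        cut = thresholds.log2_min_fc
        if stat.log2fc > cut:
            return UP
        if -stat.log2fc > cut:
            return DOWN
    return NON_DE


# ---------------------------------------------------------------------------
# dataset metadata and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetMeta:
    """Metadata describing one dataset/DEA comparison."""

    dataset_id: str
    species: str
    technology: str
    platform: str
    tissue: str
    comparison: ComparisonLabel
    n_samples: int
    biotype_scope: str = "coding"

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.technology not in TECHNOLOGIES:
            raise ValueError(
                f"unknown technology {self.technology!r}; expected one of {TECHNOLOGIES}"
            )
        if self.biotype_scope not in BIOTYPE_SCOPES:
            raise ValueError(
                f"unknown biotype_scope {self.biotype_scope!r}; expected one of {BIOTYPE_SCOPES}"
            )
        # datasets with fewer than three biological replicates are excluded
        if self.n_samples < 3:
            raise ValueError(f"n_samples must be >= 3, got {self.n_samples}")

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "species": self.species,
            "technology": self.technology,
            "platform": self.platform,
            "tissue": self.tissue,
            "comparison": self.comparison.raw,
            "n_samples": self.n_samples,
            "biotype_scope": self.biotype_scope,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetMeta":
        return cls(
            dataset_id=str(d["dataset_id"]),
            species=str(d["species"]),
            technology=str(d["technology"]),
            platform=str(d.get("platform", "")),
            tissue=str(d.get("tissue", "")),
            comparison=parse_comparison_label(str(d["comparison"])),
            n_samples=int(d["n_samples"]),
            biotype_scope=str(d.get("biotype_scope", "coding")),
        )


_TABLE_COLUMNS = ("log2fc", "p_nominal", "p_adjusted")


@dataclass
class DEATable:
    """One dataset's DEA results: metadata plus a per-feature frame.

    ``data`` is indexed by feature id with float columns ``log2fc``,
    ``p_nominal`` and ``p_adjusted``; NaN marks a missing statistic.
    """

    meta: DatasetMeta
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"DEA table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError(f"DEA table {self.meta.dataset_id} is empty")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableFormatError(
                f"duplicate feature id {dup!r} in table {self.meta.dataset_id}"
            )
        self.data = self.data[list(_TABLE_COLUMNS)].astype(float)
        for col in ("p_nominal", "p_adjusted"):
            bad = self.data[col].dropna()
            bad = bad[(bad < 0) | (bad > 1)]
            if len(bad):
                raise ValueError(
                    f"{col} outside [0, 1] for {bad.index[0]!r} in {self.meta.dataset_id}"
                )

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    def get(self, feature_id: str) -> FeatureStat | None:
        if feature_id not in self.data.index:
            return None
        row = self.data.loc[feature_id]
        return FeatureStat(feature_id, float(row.log2fc), float(row.p_nominal), float(row.p_adjusted))

    def classify(self, thresholds: DEThresholds = DEFAULT_GENE_THRESHOLDS) -> pd.Series:
        """Vectorised DE call per feature (``up``/``down``/``non_de``)."""
        p = self.data["p_adjusted" if thresholds.use_adjusted else "p_nominal"]
        lfc = self.data["log2fc"]
        cut = thresholds.log2_min_fc
        sig = p < thresholds.max_p  # NaN compares False: missing stats never call
        calls = pd.Series(NON_DE, index=self.data.index, name="call")
        calls[sig & (lfc > cut)] = UP
        calls[sig & (-lfc > cut)] = DOWN
        return calls

    @classmethod
    def from_records(
        cls,
        meta: DatasetMeta,
        records: Iterable[tuple[str, float, float, float]],
    ) -> "DEATable":
        """Build a table from ``(feature_id, log2fc, p_nominal, p_adjusted)`` rows."""
        rows = list(records)
        df = pd.DataFrame(rows, columns=["feature", *_TABLE_COLUMNS]).set_index("feature")
        return cls(meta=meta, data=df)


# ---------------------------------------------------------------------------
# tab-delimited I/O
# ---------------------------------------------------------------------------


def load_dea_table(
    path: str | Path,
    meta: DatasetMeta,
    columns: Mapping[str, str] | None = None,
) -> DEATable:
    """Read a tab-delimited DEA result file into a :class:`DEATable`.

    ``columns`` maps the logical names ``feature``, ``log2fc``,
    ``pvalue``, ``padj`` to the header names actually present; rows with
    unparseable numerics are retained with the statistic flagged missing.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; header found: {list(raw.columns)}"
        )
    feats = raw[colmap["feature"]]
    if feats.duplicated().any():
        dup = feats[feats.duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicated feature id {dup!r}")
    df = pd.DataFrame(index=pd.Index(feats, name="feature"))
    for logical, col in (("log2fc", "log2fc"), ("pvalue", "p_nominal"), ("padj", "p_adjusted")):
        values = pd.to_numeric(raw[colmap[logical]], errors="coerce")
        n_flagged = int((values.isna() & raw[colmap[logical]].notna()).sum())
        if n_flagged:
            logger.warning(
                "%s: %d unparseable value(s) in column %r flagged missing",
                path, n_flagged, colmap[logical],
            )
        df[col] = values.to_numpy()
    return DEATable(meta=meta, data=df)


def write_dea_table(
    table: DEATable,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a table in the tab-delimited interchange layout (default headers)."""
    out = table.data.reset_index()
    out.columns = ["feature", "log2fc", "pvalue", "padj"]
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def write_meta(meta: DatasetMeta, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta.to_dict(), indent=1) + "\n", encoding="utf-8")


def load_meta(path: str | Path) -> DatasetMeta:
    return DatasetMeta.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# multiple-testing plumbing
# ---------------------------------------------------------------------------


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, clipped to [0, 1]."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return np.clip(adjusted, 0.0, 1.0)
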