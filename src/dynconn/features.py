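"""Feature-matrix assembly under the three scheme axes.

A long-format metric table (one row per condition, subject, connectivity
method, band, window, metric) is pivoted into a ``samples x features`` matrix
according to a :class:`SchemeConfig`:

* ``method``: ``"pli"``, ``"wpli"``, or ``"fusion"`` — under fusion every
  subject contributes *two* rows with the same class label, one derived from
  the PLI network and one from the WPLI network (sample doubling);
* ``windows``: a single 1-based window number, or ``"fusion"`` (all windows
  concatenated feature-wise);
* ``bands``: a single band name, or ``"fusion"`` (all bands concatenated).

Row and column counts follow closed-form arithmetic: with S subjects per
class, rows = ``2 * S * (2 if fusion else 1)`` and columns =
``9 * n_windows * n_bands``. With S = 25 and 63 windows this reproduces the
canonical shapes 50 x 567 (single method, one band), 100 x 2835 (method and
band fusion), 50 x 45 (one window, five bands), etc.

Feature ordering is fixed and band-major: band, then window, then metric in
the canonical metric order — documented for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graphmetrics import METRIC_ORDER
from .preprocess import BAND_ORDER

logger = logging.getLogger(__name__)

__all__ = ["SchemeConfig", "FeatureMatrix", "assemble_features", "scale_features", "metric_table"]

TABLE_COLUMNS = ("condition", "subject", "method", "band", "window", "metric", "value")


@dataclass(frozen=True)
class SchemeConfig:
    """One point on the scheme grid: connectivity method x windows x bands,
    for one ordered binary task (positive class first)."""

    method: str = "fusion"  # 'pli' | 'wpli' | 'fusion'
    windows: str | int = "fusion"  # 'fusion' | 1-based window number
    bands: str = "full"  # band name | 'fusion'
    task: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.method not in ("pli", "wpli", "fusion"):
            raise ValueError(f"unknown method {self.method!r}")
        if isinstance(self.windows, str) and self.windows != "fusion":
            raise ValueError("windows must be 'fusion' or a window number")
        if self.task[0] == self.task[1]:
            raise ValueError("task classes must be distinct")

    @property
    def methods(self) -> tuple[str, ...]:
        return ("pli", "wpli") if self.method == "fusion" else (self.method,)


@dataclass
class FeatureMatrix:
    """``samples x features`` values with labels, per-sample provenance
    (condition, subject, source method) and band/window/metric feature names."""

    values: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame  # columns: condition, subject, method
    feature_names: list[str]
    task: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_method(self, method: str) -> "FeatureMatrix":
        """Rows whose features came from one connectivity method."""
        mask = (self.provenance["method"] == method).to_numpy()
        return FeatureMatrix(
            values=self.values[mask],
            labels=self.labels[mask],
            provenance=self.provenance.loc[mask].reset_index(drop=True),
            feature_names=list(self.feature_names),
            task=self.task,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        for i, col in enumerate(("condition", "subject", "method")):
            df.insert(1 + i, col, self.provenance[col].to_numpy())
        return df


def metric_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Normalize an iterable of per-matrix metric records into the canonical
    long-format table."""
    df = pd.DataFrame(list(rows))
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    return df[list(TABLE_COLUMNS)]


def _select_bands(table: pd.DataFrame, scheme: SchemeConfig) -> list[str]:
    present = set(table["band"].unique())
    if scheme.bands == "fusion":
        bands = [b for b in BAND_ORDER if b in present]
        extra = sorted(present - set(BAND_ORDER))
        return bands + extra
    if scheme.bands not in present:
        raise ValueError(f"band {scheme.bands!r} absent from metric table")
    return [scheme.bands]


def assemble_features(table: pd.DataFrame, scheme: SchemeConfig) -> FeatureMatrix:
    """Pivot a long metric table into the scheme's feature matrix.

    Rows are ordered (class, subject, method); columns band-major then window
    then metric. Missing (condition, subject, method, band, window) cells
    raise with a listing of the gaps.
    """
    df = table[table["condition"].isin(scheme.task)].copy()
    df = df[df["method"].isin(scheme.methods)]
    expected_rows = {
        (c, s, m)
        for c in scheme.task
        for s in df.loc[df["condition"] == c, "subject"].unique()
        for m in scheme.methods
    }
    bands = _select_bands(df, scheme)
    df = df[df["band"].isin(bands)]
    if scheme.windows != "fusion":
        df = df[df["window"] == int(scheme.windows)]
        if df.empty:
            raise ValueError(f"window {scheme.windows} absent from metric table")
    windows = sorted(df["window"].unique())

    wide = df.pivot_table(
        index=["condition", "subject", "method"],
        columns=["band", "window", "metric"],
        values="value",
        aggfunc="first",
    )
    col_order = [
        (b, w, m) for b in bands for w in windows for m in METRIC_ORDER
    ]
    missing_cols = [c for c in col_order if c not in wide.columns]
    missing_rows = sorted(expected_rows - set(wide.index))
    if missing_cols or missing_rows or wide.isna().any().any():
        gaps = [str(c) for c in missing_cols][:5] + [str(r) for r in missing_rows][:5]
        if not gaps:
            gaps = [str(i) for i in wide.index[wide.isna().any(axis=1)][:10]]
        raise ValueError(f"metric table has gaps, e.g. {gaps}")
    wide = wide[col_order]

    # row order: class (task order), subject, method
    idx = wide.index.to_frame(index=False)
    idx["condition"] = pd.Categorical(idx["condition"], categories=list(scheme.task))
    order = idx.sort_values(["condition", "subject", "method"]).index
    wide = wide.iloc[order]
    idx = wide.index.to_frame(index=False).reset_index(drop=True)

    names = [f"{b}:w{w}:{m}" for (b, w, m) in col_order]
    return FeatureMatrix(
        values=wide.to_numpy(dtype=float),
        labels=idx["condition"].astype(str).to_numpy(),
        provenance=idx[["condition", "subject", "method"]].astype(
            {"condition": str, "subject": int, "method": str}
        ),
        feature_names=names,
        task=scheme.task,
    )


def scale_features(fm: FeatureMatrix, fit_rows: np.ndarray | Sequence[int]) -> FeatureMatrix:
    """Standardize each feature using statistics from ``fit_rows`` only
    (train fold), applied to all rows. Zero-variance features are left
    unscaled with a log message."""
    fit_rows = np.asarray(fit_rows)
    if fit_rows.dtype == bool:
        fit_rows = np.flatnonzero(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    x = fm.values
    mu = x[fit_rows].mean(axis=0)
    sd = x[fit_rows].std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning("scale_features: %d zero-variance feature(s) left unscaled", flat.sum())
    mu = np.where(flat, 0.0, mu)
    sd = np.where(flat, 1.0, sd)
    return replace(fm, values=(x - mu) / sd, provenance=fm.provenance.copy())
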