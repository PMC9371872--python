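"""Dataset schema, covariate encoding, and CSV readers/writers.

A survival dataset is one row per subject with columns ``time`` (years,
positive), ``event`` (1 = event observed, 0 = right-censored), ``cluster``
(categorical group label, here a region) plus one column per categorical
covariate.  Covariates are encoded against a :class:`CovariateCodebook` that
fixes each covariate's category order; the first category is the reference and
emits no design column (dummy / one-hot-minus-reference coding).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CodebookError",
    "DataValidationError",
    "CovariateCodebook",
    "SurvivalDataset",
    "read_dataset",
    "write_dataset",
    "summarize_dataset",
]

REQUIRED_COLUMNS = ("time", "event", "cluster")


class SchemaError(ValueError):
    """The CSV is missing a required column."""


class CodebookError(ValueError):
    """A data value does not appear in the codebook."""


class DataValidationError(ValueError):
    """A row violates the schema invariants (time > 0, event in {0,1}, ...)."""


@dataclass(frozen=True)
class CovariateCodebook:
    """Ordered category lists per covariate; first category = reference.

    The design matrix has one 0/1 column per non-reference category, so a
    covariate with L levels contributes L-1 columns.
    """

    categories: dict[str, list[str]]

    def __post_init__(self) -> None:
        for cov, cats in self.categories.items():
            if len(cats) < 2:
                raise CodebookError(f"covariate {cov!r} needs >= 2 categories")
            if len(set(cats)) != len(cats):
                raise CodebookError(f"covariate {cov!r} has duplicate categories")

    @property
    def covariates(self) -> list[str]:
        return list(self.categories)

    def reference(self, covariate: str) -> str:
        return self.categories[covariate][0]

    @property
    def design_columns(self) -> list[str]:
        """Design column names, ``covariate[category]`` for non-reference levels."""
        return [
            f"{cov}[{cat}]"
            for cov, cats in self.categories.items()
            for cat in cats[1:]
        ]

    def design_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Dummy-encode ``frame``'s covariate columns (reference level dropped)."""
        cols = []
        for cov, cats in self.categories.items():
            values = frame[cov].astype(str)
            unknown = set(values.unique()) - set(cats)
            if unknown:
                raise CodebookError(
                    f"covariate {cov!r} has categories {sorted(unknown)} "
                    "not present in the codebook"
                )
            for cat in cats[1:]:
                cols.append((values == cat).to_numpy(dtype=float))
        if not cols:
            return np.empty((len(frame), 0))
        return np.column_stack(cols)

    @classmethod
    def from_yaml(cls, path) -> "CovariateCodebook":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({str(k): [str(c) for c in v] for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) for k, v in self.categories.items()}, fh, sort_keys=False
            )


@dataclass
class SurvivalDataset:
    """A validated clustered survival dataset plus its covariate codebook.

    ``frame`` holds one row per subject with the columns described in the
    module docstring.  Clusters are indexed in order of first appearance.
    """

    frame: pd.DataFrame
    codebook: CovariateCodebook
    _design: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        _validate_frame(self.frame, self.codebook)

    # -- basic shape ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def cluster_labels(self) -> list[str]:
        """Distinct cluster labels in order of first appearance."""
        return list(pd.unique(self.frame["cluster"].astype(str)))

    @property
    def r(self) -> int:
        """Number of clusters."""
        return len(self.cluster_labels)

    @property
    def cluster_index(self) -> np.ndarray:
        """Integer cluster index (0..r-1) per subject."""
        labels = self.cluster_labels
        lookup = {lab: i for i, lab in enumerate(labels)}
        return self.frame["cluster"].astype(str).map(lookup).to_numpy(dtype=int)

    @property
    def cluster_sizes(self) -> np.ndarray:
        """n_i per cluster; sums to n."""
        return np.bincount(self.cluster_index, minlength=self.r)

    @property
    def cluster_events(self) -> np.ndarray:
        """d_i = number of observed events per cluster."""
        return np.bincount(self.cluster_index, weights=self.event, minlength=self.r).astype(int)

    # -- design matrix -------------------------------------------------------
    @property
    def design_columns(self) -> list[str]:
        return self.codebook.design_columns

    @property
    def design(self) -> np.ndarray:
        """Dummy-coded design matrix X (n x p), cached."""
        if self._design is None:
            self._design = self.codebook.design_matrix(self.frame)
        return self._design

    def data_key(self) -> str:
        """A fingerprint of (time, event, cluster) used to detect mixed-dataset comparisons."""
        import hashlib

        h = hashlib.sha1()
        h.update(self.time.tobytes())
        h.update(self.event.tobytes())
        h.update(",".join(self.frame["cluster"].astype(str)).encode())
        return h.hexdigest()


def _validate_frame(frame: pd.DataFrame, codebook: CovariateCodebook) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    for cov in codebook.covariates:
        if cov not in frame.columns:
            raise SchemaError(f"missing covariate column {cov!r}")
    def _parse(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    # Python's float() is correctly rounded, so write/read round-trips exactly
    time = frame["time"].map(_parse).astype(float)
    bad = frame.index[time.isna() | (time <= 0) | ~np.isfinite(time)]
    if len(bad):
        raise DataValidationError(
            f"rows {list(bad[:10])}: time must be a positive number"
        )
    event = pd.to_numeric(frame["event"], errors="coerce")
    bad = frame.index[~event.isin([0, 1])]
    if len(bad):
        raise DataValidationError(f"rows {list(bad[:10])}: event must be 0 or 1")
    cluster = frame["cluster"].astype(str)
    bad = frame.index[(cluster.str.len() == 0) | frame["cluster"].isna()]
    if len(bad):
        raise DataValidationError(f"rows {list(bad[:10])}: cluster label is empty")
    for cov in codebook.covariates:
        missing = frame.index[frame[cov].isna()]
        if len(missing):
            raise DataValidationError(
                f"rows {list(missing[:10])}: missing value for covariate {cov!r}"
            )
        values = frame[cov].astype(str)
        unknown_mask = ~values.isin(codebook.categories[cov])
        if unknown_mask.any():
            row = int(frame.index[unknown_mask][0])
            raise CodebookError(
                f"row {row}: covariate {cov!r} value {values[row]!r} "
                "not in the codebook"
            )
    frame["time"] = time.astype(float)
    frame["event"] = event.astype(int)
    frame["cluster"] = cluster


def read_dataset(path, codebook: CovariateCodebook) -> SurvivalDataset:
    """Read a CSV (comma-separated, UTF-8, header row) into a validated dataset.

    Invalid rows raise — nothing is silently dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    return SurvivalDataset(frame, codebook)


def write_dataset(ds: SurvivalDataset, path) -> None:
    """Write the dataset as CSV; ``read_dataset`` round-trips it exactly."""
    cols = list(REQUIRED_COLUMNS) + ds.codebook.covariates
    out = ds.frame[cols].copy()
    out["time"] = out["time"].map(lambda v: repr(float(v)))
    out.to_csv(path, index=False)


def dataset_to_csv_bytes(ds: SurvivalDataset) -> bytes:
    """Serialize to CSV in memory (used for byte-identity checks)."""
    buf = io.StringIO()
    write_dataset(ds, buf)
    return buf.getvalue().encode()


def summarize_dataset(ds: SurvivalDataset) -> pd.DataFrame:
    """Descriptive table: event/censored counts and percentages per level.

    One block per variable (``cluster`` first, then each covariate, then an
    overall row).  Percentages are 100 * count / column-total, rounded to one
    decimal for display; raw counts are also kept so that event + censored
    always reconstructs the level total exactly.
    """
    if ds.n == 0:
        raise DataValidationError("cannot summarize an empty dataset")
    event = ds.event
    total_events = int(event.sum())
    total_censored = int(ds.n - total_events)
    rows = []

    def block(variable: str, values: pd.Series) -> None:
        for level in pd.unique(values):
            mask = (values == level).to_numpy()
            ev = int(event[mask].sum())
            ce = int(mask.sum() - ev)
            rows.append(
                {
                    "variable": variable,
                    "category": level,
                    "censored_n": ce,
                    "censored_pct": round(100.0 * ce / total_censored, 1)
                    if total_censored
                    else 0.0,
                    "event_n": ev,
                    "event_pct": round(100.0 * ev / total_events, 1)
                    if total_events
                    else 0.0,
                    "total_n": ce + ev,
                }
            )

    block("cluster", ds.frame["cluster"].astype(str))
    for cov in ds.codebook.covariates:
        block(cov, ds.frame[cov].astype(str))
    rows.append(
        {
            "variable": "overall",
            "category": "all",
            "censored_n": total_censored,
            "censored_pct": round(100.0 * total_censored / ds.n, 1),
            "event_n": total_events,
            "event_pct": round(100.0 * total_events / ds.n, 1),
            "total_n": ds.n,
        }
    )
    return pd.DataFrame(rows)
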