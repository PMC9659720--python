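"""Per-site cohort tables and the data-preparation steps.

A cohort is one hospital's patient-by-feature numeric table. Preparation
follows the convention for multi-site ICU feature tables: per-parameter
medians over the first day of stay, removal of features missing in more
than a configurable fraction of patients, restriction to the feature set
shared by all sites, and imputation of the remaining gaps with the
site-wide median of each feature.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "TimeSeriesRecord",
    "load_cohort",
    "load_timeseries",
    "aggregate_first_day",
    "filter_sparse_features",
    "intersect_features",
    "impute_site_median",
]

TS_COLUMNS = ("patient_id", "parameter", "time_h", "value")


@dataclasses.dataclass(frozen=True)
class TimeSeriesRecord:
    """One charted measurement: a parameter value at hours from ICU admission."""

    patient_id: str
    parameter: str
    time_h: float
    value: float

    def __post_init__(self) -> None:
        if not self.parameter:
            raise ValueError("parameter name must be non-empty")
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError(
                f"time_h must be finite and non-negative, got {self.time_h!r}"
            )


class CohortTable:
    """One site's patient-by-feature table.

    Parameters
    ----------
    site_id : str
        Label of the originating site.
    data : pandas.DataFrame
        Numeric matrix, index = patient ids, columns = feature names.
        Missing entries (NaN) are permitted before imputation.
    endpoint : pandas.Series, optional
        Binary label per patient (values in {0, 1}), aligned with ``data``.
    codes : mapping, optional
        Patient id -> set of diagnosis-code strings.
    """

    def __init__(
        self,
        site_id: str,
        data: pd.DataFrame,
        endpoint: pd.Series | None = None,
        codes: Mapping[str, frozenset[str]] | None = None,
    ) -> None:
        if data.index.has_duplicates:
            dups = sorted(map(str, data.index[data.index.duplicated()].unique()))
            raise ValueError(f"duplicate patient ids in site {site_id!r}: {dups}")
        if data.columns.has_duplicates:
            dups = sorted(map(str, data.columns[data.columns.duplicated()].unique()))
            raise ValueError(f"duplicate feature names in site {site_id!r}: {dups}")
        for col in data.columns:
            if not pd.api.types.is_numeric_dtype(data[col]):
                raise ValueError(
                    f"feature {col!r} in site {site_id!r} is not numeric; "
                    "only numeric features enter the pipeline"
                )
        if endpoint is not None:
            endpoint = pd.Series(endpoint)
            if not endpoint.index.equals(data.index):
                endpoint = endpoint.reindex(data.index)
            if endpoint.isna().any():
                missing = endpoint.index[endpoint.isna()].tolist()
                raise ValueError(f"endpoint missing for patients {missing}")
            bad = set(endpoint.unique()) - {0, 1}
            if bad:
                raise ValueError(f"endpoint values must be in {{0,1}}, got {bad}")
            endpoint = endpoint.astype(int)
        self.site_id = str(site_id)
        self.data = data.astype(float)
        self.endpoint = endpoint
        self.codes = dict(codes) if codes is not None else None

    # -- basic views -------------------------------------------------------
    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def replace(self, data: pd.DataFrame | None = None, **kwargs) -> "CohortTable":
        """Return a copy with some parts replaced, keeping alignment."""
        new_data = self.data if data is None else data
        endpoint = kwargs.get("endpoint", self.endpoint)
        if endpoint is not None:
            endpoint = endpoint.reindex(new_data.index)
        codes = kwargs.get("codes", self.codes)
        return CohortTable(kwargs.get("site_id", self.site_id), new_data, endpoint, codes)

    def select_features(self, features: Sequence[str]) -> "CohortTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features {missing} not present in site {self.site_id!r}")
        return self.replace(data=self.data.loc[:, list(features)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ep = "with endpoint" if self.endpoint is not None else "no endpoint"
        return (
            f"<CohortTable site={self.site_id!r} patients={self.n_patients} "
            f"features={len(self.features)} {ep}>"
        )

    # -- IO ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Canonical flat frame: site_id, patient_id, features, optional endpoint/codes."""
        out = self.data.copy()
        out.insert(0, "site_id", self.site_id)
        if self.endpoint is not None:
            out["endpoint"] = self.endpoint
        if self.codes is not None:
            out["codes"] = [
                ";".join(sorted(self.codes.get(pid, frozenset())))
                for pid in self.data.index
            ]
        out.index.name = "patient_id"
        return out.reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_SCHEMA: dict = {
    "patient_id": "patient_id",
    "site": "site_id",
    "endpoint": "endpoint",
    "codes": "codes",
    "features": None,  # None: every remaining column
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    return pd.read_csv(path)


def load_cohort(path: str | Path, schema: Mapping | None = None) -> CohortTable:
    """Read one site's feature table from CSV or Parquet.

    ``schema`` maps column roles: ``patient_id`` (column name), ``site``
    (column name) or ``site_id`` (literal label), optional ``endpoint`` and
    ``codes`` column names, and ``features`` (explicit list, or None to take
    every remaining column). Non-numeric cells in feature columns and
    duplicated patient ids are rejected with the offending location named.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = _read_table(path)

    pid_col = schema["patient_id"]
    if pid_col not in df.columns:
        raise ValueError(f"patient-id column {pid_col!r} not found in {path}")
    pids = df[pid_col].astype(str)
    if pids.duplicated().any():
        dups = sorted(pids[pids.duplicated()].unique())
        raise ValueError(f"duplicate patient ids in {path}: {dups}")

    if "site_id" in schema and schema.get("site_id") is not None:
        site_id = str(schema["site_id"])
    else:
        site_col = schema["site"]
        if site_col in df.columns:
            uniq = df[site_col].dropna().unique()
            if len(uniq) != 1:
                raise ValueError(
                    f"{path}: site column {site_col!r} must carry a single value, got {list(uniq)}"
                )
            site_id = str(uniq[0])
        else:
            site_id = Path(path).stem

    reserved = {pid_col, schema.get("site"), schema.get("endpoint"), schema.get("codes")}
    if schema["features"] is None:
        feat_cols = [c for c in df.columns if c not in reserved]
    else:
        feat_cols = list(schema["features"])
        absent = [c for c in feat_cols if c not in df.columns]
        if absent:
            raise ValueError(f"{path}: feature columns {absent} not found")

    values = {}
    for col in feat_cols:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in feature column "
                f"{col!r}, row {row}"
            )
        values[col] = num.to_numpy(dtype=float)
    data = pd.DataFrame(values, index=pd.Index(pids, name="patient_id"))

    endpoint = None
    ep_col = schema.get("endpoint")
    if ep_col and ep_col in df.columns:
        endpoint = pd.Series(df[ep_col].to_numpy(), index=data.index)

    codes = None
    codes_col = schema.get("codes")
    if codes_col and codes_col in df.columns:
        codes = {
            pid: frozenset(str(c).split(";")) - {"", "nan"}
            for pid, c in zip(data.index, df[codes_col].fillna(""))
        }

    return CohortTable(site_id, data, endpoint, codes)


def load_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a long-format time-series table (patient_id, parameter, time_h, value)."""
    df = _read_table(path)
    missing = [c for c in TS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: time-series table lacks columns {missing}")
    df = df.loc[:, list(TS_COLUMNS)].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["value"] = pd.to_numeric(df["value"])
    if (df["time_h"] < 0).any() or not np.isfinite(df["time_h"]).all():
        raise ValueError(f"{path}: time_h must be finite and non-negative")
    return df


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in TS_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"time-series frame lacks columns {missing}")
        return records.loc[:, list(TS_COLUMNS)]
    rows = [
        (r.patient_id, r.parameter, r.time_h, r.value)
        if isinstance(r, TimeSeriesRecord)
        else tuple(r)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(TS_COLUMNS))


def aggregate_first_day(
    records: Iterable[TimeSeriesRecord] | pd.DataFrame,
    window_h: float = 24.0,
    site_id: str = "cohort",
) -> CohortTable:
    """Per-patient medians of each charted parameter over the first day.

    The window is half-open: measurements with ``time_h < window_h`` count,
    a tie at exactly ``window_h`` does not. A patient with no in-window
    value for a parameter gets a missing entry; patients with no in-window
    values at all keep an all-missing row.
    """
    if window_h <= 0:
        raise ValueError(f"window_h must be positive, got {window_h}")
    df = _records_to_frame(records)
    if df.empty:
        return CohortTable(site_id, pd.DataFrame(index=pd.Index([], name="patient_id")))
    all_pids = pd.unique(df["patient_id"].astype(str))
    all_params = pd.unique(df["parameter"].astype(str))
    inwin = df[df["time_h"] < window_h]
    if inwin.empty:
        data = pd.DataFrame(
            np.nan, index=pd.Index(all_pids, name="patient_id"), columns=all_params
        )
        return CohortTable(site_id, data)
    med = (
        inwin.astype({"patient_id": str, "parameter": str})
        .groupby(["patient_id", "parameter"], sort=False)["value"]
        .median()
        .unstack()
    )
    med = med.reindex(index=all_pids, columns=all_params)
    med.index.name = "patient_id"
    return CohortTable(site_id, med)


def filter_sparse_features(
    cohort: CohortTable, max_missing_frac: float = 0.3
) -> CohortTable:
    """Drop features missing in *more than* ``max_missing_frac`` of patients.

    The boundary is kept: a feature missing in exactly the threshold
    fraction is retained (strict inequality for dropping).
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError(f"max_missing_frac must be in [0,1], got {max_missing_frac}")
    if cohort.n_patients == 0:
        return cohort.replace()
    frac = cohort.data.isna().mean()
    keep = [f for f in cohort.features if frac[f] <= max_missing_frac]
    return cohort.replace(data=cohort.data.loc[:, keep])


def intersect_features(cohorts: Sequence[CohortTable]) -> list[CohortTable]:
    """Restrict every cohort to the feature set present at all sites.

    The shared order is the first cohort's column order.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to intersect features")
    shared = [
        f
        for f in cohorts[0].features
        if all(f in c.features for c in cohorts[1:])
    ]
    if not shared:
        sets = {c.site_id: sorted(c.features) for c in cohorts}
        raise ValueError(f"no features shared by all cohorts; per-site sets: {sets}")
    return [c.select_features(shared) for c in cohorts]


def impute_site_median(cohort: CohortTable) -> CohortTable:
    """Fill each missing entry with this site's median of the feature.

    Imputation is strictly per site (no pooling across cohorts) and
    univariate; observed entries are never altered.
    """
    fully_missing = [f for f in cohort.features if cohort.data[f].isna().all()]
    if fully_missing:
        raise ValueError(
            f"features fully missing in site {cohort.site_id!r}: {fully_missing}; "
            "cannot impute a site median"
        )
    medians = cohort.data.median()
    return cohort.replace(data=cohort.data.fillna(medians))


def prepare_cohorts(
    cohorts: Sequence[CohortTable],
    max_missing_frac: float = 0.3,
    sparse_filter_first: bool = True,
) -> list[CohortTable]:
    """Standard preparation: sparse-feature filter, intersection, imputation.

    ``sparse_filter_first`` controls whether the missingness filter runs
    per site before the cross-site intersection (default) or after it.
    """
    if sparse_filter_first:
        cohorts = [filter_sparse_features(c, max_missing_frac) for c in cohorts]
        cohorts = intersect_features(cohorts)
    else:
        cohorts = intersect_features(cohorts)
        cohorts = [filter_sparse_features(c, max_missing_frac) for c in cohorts]
        cohorts = intersect_features(cohorts)
    return [impute_site_median(c) for c in cohorts]
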