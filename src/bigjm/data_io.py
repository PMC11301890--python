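"""Data model, CSV readers/writers and id-consistency validation.

Two plain tables drive every fit: a long-format longitudinal table (one row
per biomarker measurement) and a one-row-per-subject survival table holding
the observed follow-up time, the event indicator and baseline covariates.
Validation enforces that the two tables describe the same subjects and that
no longitudinal record postdates a subject's observed time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "SchemaError",
    "ParseError",
    "ConsistencyError",
    "LongitudinalData",
    "SurvivalData",
    "ValidatedDataset",
    "read_long_table",
    "read_surv_table",
    "validate_join",
    "write_long_table",
    "write_surv_table",
]

#: tokens treated as missing and rejected in required columns
MISSING_TOKENS = ("", "NA")


class DataError(ValueError):
    """Base class for data-layer failures."""


class SchemaError(DataError):
    """A required/mapped column is absent."""


class ParseError(DataError):
    """A cell failed to parse; message carries the 1-based data row number."""


class ConsistencyError(DataError):
    """Cross-table or cross-row invariant violated."""


@dataclass(frozen=True)
class LongitudinalData:
    """Long-format biomarker records, sorted by (subject_id, time).

    ``records`` holds columns ``subject_id``, ``time``, ``outcome`` plus one
    column per entry of ``covariates`` (the fixed-effect design covariates
    beyond intercept and time). ``random_design`` names the columns of the
    subject-level random design z_i(t); the default random intercept + slope.
    """

    records: pd.DataFrame
    covariates: tuple[str, ...] = ()
    random_design: tuple[str, ...] = ("intercept", "time")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["subject_id"].unique()

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SurvivalData:
    """One row per subject: observed time T_i, event indicator and w_i.

    ``event`` is 1 when the true event time was observed (T_i <= C_i) and 0
    under censoring. ``admin_horizon`` is the administrative maximum
    follow-up tau, when known.
    """

    records: pd.DataFrame
    covariates: tuple[str, ...] = ()
    admin_horizon: float | None = None

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ValidatedDataset:
    """A joinable (longitudinal, survival) pair that passed validation."""

    longitudinal: LongitudinalData
    survival: SurvivalData
    n_subjects: int
    dropped_records: int = 0


def _require_columns(df: pd.DataFrame, wanted: dict[str, str], path: str) -> None:
    for canonical, col in wanted.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing column {col!r} (mapped to {canonical!r})"
            )


def _parse_numeric(df: pd.DataFrame, col: str, path: str) -> np.ndarray:
    raw = df[col].astype(str).str.strip()
    bad = raw.isin(MISSING_TOKENS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(
            f"{path}: cannot parse {raw.iloc[row - 1]!r} in column {col!r} "
            f"at data row {row}"
        )
    return values.to_numpy(dtype=float)


def read_long_table(
    path,
    column_map: dict[str, str] | None = None,
    covariates: tuple[str, ...] = (),
) -> LongitudinalData:
    """Read a long-format longitudinal CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps canonical names ``subject_id``, ``time``, ``outcome`` to the
        file's column names. Defaults to the identity mapping.
    covariates
        File column names to carry along as fixed-design covariates.
    """
    cmap = {"subject_id": "subject_id", "time": "time", "outcome": "outcome"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, cmap, str(path))
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"{path}: missing covariate column {cov!r}")

    out = pd.DataFrame(
        {
            "subject_id": df[cmap["subject_id"]].astype(str),
            "time": _parse_numeric(df, cmap["time"], str(path)),
            "outcome": _parse_numeric(df, cmap["outcome"], str(path)),
        }
    )
    for cov in covariates:
        out[cov] = _parse_numeric(df, cov, str(path))
    if (out["time"] < 0).any():
        row = int(np.flatnonzero((out["time"] < 0).to_numpy())[0]) + 1
        raise ParseError(f"{path}: negative time at data row {row}")
    out = out.sort_values(["subject_id", "time"], kind="stable").reset_index(drop=True)
    return LongitudinalData(records=out, covariates=tuple(covariates))


def read_surv_table(
    path,
    column_map: dict[str, str] | None = None,
    covariates: tuple[str, ...] = (),
    admin_horizon: float | None = None,
) -> SurvivalData:
    """Read a one-row-per-subject survival CSV.

    ``event`` values must coerce to {0, 1}; observed times must be positive
    and subject ids unique.
    """
    cmap = {
        "subject_id": "subject_id",
        "observed_time": "observed_time",
        "event": "event",
    }
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, cmap, str(path))
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"{path}: missing covariate column {cov!r}")

    ids = df[cmap["subject_id"]].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ConsistencyError(
            f"{path}: duplicated subject_id values: {sorted(dup)}"
        )
    times = _parse_numeric(df, cmap["observed_time"], str(path))
    if (times <= 0).any():
        row = int(np.flatnonzero(times <= 0)[0]) + 1
        raise DataError(f"{path}: observed_time must be > 0 at data row {row}")
    event = _parse_numeric(df, cmap["event"], str(path))
    ok = np.isin(event, (0.0, 1.0))
    if not ok.all():
        row = int(np.flatnonzero(~ok)[0]) + 1
        raise DataError(
            f"{path}: event value {event[row - 1]!r} outside {{0,1}} at data row {row}"
        )
    if admin_horizon is not None and (times > admin_horizon).any():
        raise DataError(f"{path}: observed_time exceeds admin_horizon {admin_horizon}")

    out = pd.DataFrame(
        {
            "subject_id": ids,
            "observed_time": times,
            "event": event.astype(int),
        }
    )
    for cov in covariates:
        out[cov] = _parse_numeric(df, cov, str(path))
    out = out.reset_index(drop=True)
    return SurvivalData(
        records=out, covariates=tuple(covariates), admin_horizon=admin_horizon
    )


def validate_join(
    long: LongitudinalData,
    surv: SurvivalData,
    drop_post_event: bool = True,
) -> ValidatedDataset:
    """Check id consistency and time ordering between the two tables.

    The id sets must match exactly. Longitudinal rows timed after a
    subject's observed time are dropped and counted when
    ``drop_post_event`` is set (the default pipeline behaviour, since EHR
    extracts routinely contain post-censoring rows), otherwise they raise a
    :class:`ConsistencyError`. Idempotent: validating an already-validated
    pair is the identity.
    """
    long_ids = set(long.records["subject_id"])
    surv_ids = set(surv.records["subject_id"])
    if long_ids != surv_ids:
        only_long = sorted(long_ids - surv_ids)
        only_surv = sorted(surv_ids - long_ids)
        raise ConsistencyError(
            "subject id mismatch between tables: "
            f"only in longitudinal {only_long}; only in survival {only_surv}"
        )

    obs_time = surv.records.set_index("subject_id")["observed_time"]
    t_limit = long.records["subject_id"].map(obs_time).to_numpy()
    late = long.records["time"].to_numpy() > t_limit
    dropped = int(late.sum())
    if dropped and not drop_post_event:
        offenders = sorted(long.records.loc[late, "subject_id"].unique())
        raise ConsistencyError(
            f"{dropped} longitudinal record(s) timed after the observed time "
            f"for subjects {offenders}; pass drop_post_event=True to drop them"
        )
    records = long.records.loc[~late].reset_index(drop=True)
    if records["subject_id"].nunique() != len(surv_ids):
        lost = sorted(surv_ids - set(records["subject_id"]))
        raise ConsistencyError(
            f"dropping post-event records left subjects {lost} without any "
            "longitudinal record"
        )
    clean = replace(long, records=records)
    return ValidatedDataset(
        longitudinal=clean,
        survival=surv,
        n_subjects=len(surv_ids),
        dropped_records=dropped,
    )


def write_long_table(long: LongitudinalData, path) -> None:
    long.records.to_csv(path, index=False)


def write_surv_table(surv: SurvivalData, path) -> None:
    surv.records.to_csv(path, index=False)
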