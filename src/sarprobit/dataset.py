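"""Owner-level survey tables: loading, validation, splitting, summaries.

A :class:`SurveyTable` holds one row per forest owner with a binary
willingness-to-harvest outcome ``wth``, the model covariates, an
``absentee`` indicator, and parcel coordinates in decimal degrees.
Rows that violate the coding invariants (non-binary dummies, mutually
exclusive income indicators both set, negative distances, mismatched
squared market access, duplicate ids, missing fields) are rejected at
load time and reported rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MODEL_COVARIATES

logger = logging.getLogger(__name__)

#: Binary covariates (coded 0/1).
DUMMY_COVARIATES: tuple[str, ...] = (
    "beauty",
    "privacy",
    "sawlog",
    "past_harvest",
    "age55",
    "male",
    "college",
    "income_ge_50k",
    "income_unknown",
    "absentee",
    "ge_500ac",
)

#: Non-negative distance covariates, stored in miles.
DISTANCE_COVARIATES: tuple[str, ...] = (
    "dist_service_center",
    "dist_mtnf",
    "market_access",
    "market_access_sq",
)

#: All covariates carried by a table (model covariates plus absentee).
COVARIATES: tuple[str, ...] = (
    "beauty",
    "privacy",
    "sawlog",
    "past_harvest",
    "dist_service_center",
    "age55",
    "male",
    "college",
    "income_ge_50k",
    "income_unknown",
    "absentee",
    "ge_500ac",
    "sawtimber_volume",
    "dist_mtnf",
    "market_access",
    "market_access_sq",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("id", "wth", *COVARIATES, "lon", "lat")

KM_PER_MILE = 1.609344


@dataclass
class SurveyTable:
    """Validated owner-level records with canonical column names."""

    df: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def wth(self) -> np.ndarray:
        return self.df["wth"].to_numpy(dtype=np.int64)

    @property
    def coords(self) -> np.ndarray:
        """Longitude/latitude pairs, shape (n, 2)."""
        return self.df[["lon", "lat"]].to_numpy(dtype=float)

    def design_matrix(
        self, covariates: tuple[str, ...] | list[str] | None = None, intercept: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Return (X, names) for a model specification.

        The default specification uses the 15 model covariates (the
        absentee flag is a sample-splitting variable, not a regressor).
        """
        covariates = list(covariates if covariates is not None else MODEL_COVARIATES)
        X = self.df[covariates].to_numpy(dtype=float)
        names = list(covariates)
        if intercept:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["intercept"] + names
        return X, names

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise invariant checks; returns (valid, rejects)."""
    reasons: dict[int, list[str]] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask.fillna(True)]:
            reasons.setdefault(idx, []).append(reason)

    missing = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    flag(missing, "missing required field")

    flag(~df["wth"].isin([0, 1]), "wth not in {0,1}")
    for c in DUMMY_COVARIATES:
        flag(~df[c].isin([0, 1]), f"{c} not in {{0,1}}")
    flag(
        (df["income_ge_50k"] == 1) & (df["income_unknown"] == 1),
        "income_ge_50k and income_unknown both set",
    )
    for c in DISTANCE_COVARIATES:
        flag(df[c] < 0, f"{c} negative")
    sq_ok = np.isclose(
        df["market_access_sq"], df["market_access"] ** 2, rtol=1e-6, atol=1e-9
    )
    flag(pd.Series(~sq_ok, index=df.index), "market_access_sq != market_access^2")
    finite = np.isfinite(df[["lon", "lat"]].to_numpy(dtype=float)).all(axis=1)
    flag(pd.Series(~finite, index=df.index), "non-finite coordinates")
    dup = df["id"].duplicated(keep="first")
    flag(dup, "duplicate id")

    bad = sorted(reasons)
    rejects = pd.DataFrame(
        {
            "id": [df.loc[i, "id"] for i in bad],
            "reason": ["; ".join(reasons[i]) for i in bad],
        }
    )
    valid = df.drop(index=bad).reset_index(drop=True)
    return valid, rejects


def load_table(
    path: str | Path,
    fmt: str | None = None,
    column_map: dict[str, str] | None = None,
    distance_unit: str = "miles",
) -> SurveyTable:
    """Load and validate an owner table from CSV or XLSX.

    Parameters
    ----------
    path
        Input file.  ``fmt`` is inferred from the suffix when omitted.
    column_map
        Mapping from canonical names to the file's headers (matched
        case-insensitively); canonical headers are assumed by default.
    distance_unit
        ``"miles"`` (storage unit) or ``"km"``; kilometre inputs are
        converted, with the squared access term converted by km².
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv")
    if fmt == "xlsx":
        raw = pd.read_excel(path)
    elif fmt == "csv":
        raw = pd.read_csv(path, float_precision="round_trip")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    column_map = column_map or {}
    lower_to_actual = {str(c).strip().lower(): c for c in raw.columns}
    rename: dict[str, str] = {}
    missing_cols: list[str] = []
    for canon in REQUIRED_COLUMNS:
        source = column_map.get(canon, canon).strip().lower()
        if source in lower_to_actual:
            rename[lower_to_actual[source]] = canon
        else:
            missing_cols.append(canon)
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    df = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()
    df["id"] = df["id"].astype(str)

    if distance_unit == "km":
        for c in ("dist_service_center", "dist_mtnf", "market_access"):
            df[c] = df[c] / KM_PER_MILE
        df["market_access_sq"] = df["market_access_sq"] / KM_PER_MILE**2
    elif distance_unit != "miles":
        raise ValueError(f"unknown distance unit {distance_unit!r}")

    if len(df) == 0:
        raise ValueError("no valid rows: file contains headers only")
    valid, rejects = _validate_rows(df)
    if len(rejects):
        logger.warning("rejected %d invalid rows", len(rejects))
    if len(valid) == 0:
        raise ValueError("no valid rows after validation")
    logger.info("loaded %d records (%d rejected)", len(valid), len(rejects))
    return SurveyTable(valid, rejects)


def split_residential(table: SurveyTable) -> tuple[SurveyTable, SurveyTable]:
    """Partition a table into (residential, absentee) owners."""
    absentee = table.df["absentee"].to_numpy() == 1
    res = SurveyTable(table.df.loc[~absentee].reset_index(drop=True))
    abs_ = SurveyTable(table.df.loc[absentee].reset_index(drop=True))
    assert res.n + abs_.n == table.n
    return res, abs_


def summarize(table: SurveyTable, by_absentee: bool = False) -> pd.DataFrame:
    """Per-variable mean and SD, optionally split by residency.

    With ``by_absentee=True`` the summary adds residential and absentee
    group means/SDs, the residential-minus-absentee mean difference, and
    a Welch two-sample mean-difference flag at the 1% level.
    """
    if table.n == 0:
        raise ValueError("empty table")
    variables = ["wth", *COVARIATES]
    out = pd.DataFrame(
        {
            "mean": table.df[variables].mean(),
            "sd": table.df[variables].std(ddof=1),
        }
    )
    if not by_absentee:
        return out
    res, abs_ = split_residential(table)
    if res.n == 0 or abs_.n == 0:
        raise ValueError("both residency groups required for a grouped summary")
    group_vars = [v for v in variables if v != "absentee"]
    out = out.loc[variables]
    out["mean_residential"] = res.df[variables].mean()
    out["sd_residential"] = res.df[variables].std(ddof=1)
    out["mean_absentee"] = abs_.df[variables].mean()
    out["sd_absentee"] = abs_.df[variables].std(ddof=1)
    out["difference"] = out["mean_residential"] - out["mean_absentee"]
    pvals = {}
    for v in group_vars:
        a = res.df[v].to_numpy(dtype=float)
        b = abs_.df[v].to_numpy(dtype=float)
        if np.std(a) == 0 and np.std(b) == 0:
            pvals[v] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            pvals[v] = stats.ttest_ind(a, b, equal_var=False).pvalue
    out["p_value"] = pd.Series(pvals)
    out["significant_1pct"] = out["p_value"] < 0.01
    out.loc["absentee", ["mean_residential", "sd_residential", "mean_absentee",
                         "sd_absentee", "difference", "p_value"]] = np.nan
    out.loc["absentee", "significant_1pct"] = False
    return out
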