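"""Conversion between the long PopPK dataset and the wide per-patient
feature table used by the generative model.

The feature table has one row per patient and a fixed column order: one-hot
sex, the continuous covariates, the dose, and the concentration at each of
the eight nominal sampling times.  Scaling to [-1, 1] is invertible
(constant columns map to 0 and are restored exactly); sex is decoded back to
a single column by one-cold (argmax) decoding.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .popsim import NOMINAL_TIMES, to_nonmem

__all__ = [
    "FEATURE_COLUMNS",
    "CONCENTRATION_COLUMNS",
    "to_feature_table",
    "FeatureScaler",
    "fit_scaler",
    "scale",
    "unscale",
    "one_cold_decode",
    "postprocess_artificial",
]

CONCENTRATION_COLUMNS = [f"C_{t:g}" for t in NOMINAL_TIMES]
FEATURE_COLUMNS = ["SEX_F", "SEX_M", "AGE", "WT", "HT", "DOSE"] + CONCENTRATION_COLUMNS

#: bump when the column layout changes; serialized with the ScalingSpec
FEATURE_SCHEMA_VERSION = 1


def to_feature_table(
    covariates: pd.DataFrame,
    observations: pd.DataFrame,
    dose: float,
    lloq: float = 0.5,
    blq_impute: float | None = None,
) -> pd.DataFrame:
    """Build the wide per-patient feature table.

    Every patient must have an entry at each nominal time; observations below
    the LLOQ are imputed at ``blq_impute`` (default ``lloq / 2``) so that the
    table has no missing entries.  Index = patient id.
    """
    if blq_impute is None:
        blq_impute = lloq / 2.0
    wide = observations.pivot_table(index="id", columns="time", values="conc", aggfunc="first")
    missing = [t for t in NOMINAL_TIMES if t not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError("every patient needs an observation (or BLQ flag) at each nominal time")
    wide = wide[list(NOMINAL_TIMES)]
    conc = wide.to_numpy(dtype=float)
    conc = np.where(conc < lloq, blq_impute, conc)
    cov = covariates.set_index("id").loc[wide.index]
    table = pd.DataFrame(index=wide.index)
    table["SEX_F"] = (cov["sex"] == "female").astype(float)
    table["SEX_M"] = (cov["sex"] == "male").astype(float)
    table["AGE"] = cov["age"].astype(float)
    table["WT"] = cov["weight"].astype(float)
    table["HT"] = cov["height"].astype(float)
    table["DOSE"] = float(dose)
    for j, col in enumerate(CONCENTRATION_COLUMNS):
        table[col] = conc[:, j]
    return table


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Invertible per-column min-max scaling onto [-1, 1].

    Non-constant columns are mapped by x -> 2 (x - min) / (max - min) - 1;
    constant columns map to 0 and the constant is restored exactly on
    inverse transform.  Values outside the training range are extrapolated
    linearly in both directions, so generator outputs outside [-1, 1] remain
    decodable.
    """

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 1:
            raise ValueError("cannot fit scaler on an empty table")
        self.columns_ = list(X.columns)
        self.data_min_ = X.to_numpy(dtype=float).min(axis=0)
        self.data_max_ = X.to_numpy(dtype=float).max(axis=0)
        self.constant_ = self.data_min_ == self.data_max_
        return self

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "columns_")
        if list(X.columns) != self.columns_:
            raise ValueError("column set/order does not match the fitted scaler")
        return X.to_numpy(dtype=float)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        x = self._check(X)
        span = np.where(self.constant_, 1.0, self.data_max_ - self.data_min_)
        z = 2.0 * (x - self.data_min_) / span - 1.0
        z[:, self.constant_] = 0.0
        return pd.DataFrame(z, index=X.index, columns=self.columns_)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        z = self._check(X)
        span = np.where(self.constant_, 1.0, self.data_max_ - self.data_min_)
        x = (z + 1.0) / 2.0 * span + self.data_min_
        x[:, self.constant_] = np.broadcast_to(
            self.data_min_[self.constant_], x[:, self.constant_].shape
        )
        return pd.DataFrame(x, index=X.index, columns=self.columns_)

    def to_json(self) -> str:
        check_is_fitted(self, "columns_")
        doc = {
            "schema_version": FEATURE_SCHEMA_VERSION,
            "columns": [
                {
                    "name": c,
                    "min": float(lo),
                    "max": float(hi),
                    "constant": bool(k),
                }
                for c, lo, hi, k in zip(self.columns_, self.data_min_, self.data_max_, self.constant_)
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        doc = json.loads(text)
        self = cls()
        self.columns_ = [c["name"] for c in doc["columns"]]
        self.data_min_ = np.array([c["min"] for c in doc["columns"]])
        self.data_max_ = np.array([c["max"] for c in doc["columns"]])
        self.constant_ = np.array([c["constant"] for c in doc["columns"]])
        return self


def fit_scaler(table: pd.DataFrame) -> FeatureScaler:
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit the scaler")
    return FeatureScaler().fit(table)


def scale(table: pd.DataFrame, scaler: FeatureScaler) -> pd.DataFrame:
    return scaler.transform(table)


def unscale(table: pd.DataFrame, scaler: FeatureScaler) -> pd.DataFrame:
    return scaler.inverse_transform(table)


def one_cold_decode(table: pd.DataFrame) -> pd.Series:
    """Merge the one-hot sex columns back into a single label.

    sex = argmax(SEX_F, SEX_M); exact ties resolve to female with a warning.
    """
    f = table["SEX_F"].to_numpy(dtype=float)
    m = table["SEX_M"].to_numpy(dtype=float)
    if np.any(f == m):
        warnings.warn("one-cold decoding tie(s) resolved to female", stacklevel=2)
    return pd.Series(np.where(m > f, "male", "female"), index=table.index, name="sex")


def postprocess_artificial(
    scaled: pd.DataFrame,
    scaler: FeatureScaler,
    lloq: float = 0.5,
    dose: float | None = None,
    start_id: int = 1001,
    src: str = "artificial",
):
    """Decode generator output into patient records and a long PopPK dataset.

    Unscales, one-cold decodes sex, rejects physically invalid rows
    (non-positive weight/height or age), censors concentrations below the
    LLOQ on export (a row losing all its concentrations is rejected), and
    assigns fresh ids starting at ``start_id``.

    Returns ``(wide, long_df, report)`` where ``wide`` holds the accepted
    decoded rows (patient ids as index) and ``report`` counts rejections.
    """
    raw = scaler.inverse_transform(scaled)
    sex = one_cold_decode(raw)
    report = {"n_input": len(raw), "rejected_invalid": 0, "rejected_all_blq": 0}
    cov_rows, obs_rows, wide_rows, wide_index = [], [], [], []
    pid = start_id
    for i in range(len(raw)):
        r = raw.iloc[i]
        if r["WT"] <= 0 or r["HT"] <= 0 or r["AGE"] <= 0:
            report["rejected_invalid"] += 1
            warnings.warn(f"artificial row {i}: non-physical covariates, rejected", stacklevel=2)
            continue
        conc = np.asarray([r[c] for c in CONCENTRATION_COLUMNS], dtype=float)
        keep = conc >= lloq
        if not keep.any():
            report["rejected_all_blq"] += 1
            warnings.warn(f"artificial row {i}: all concentrations below LLOQ, rejected", stacklevel=2)
            continue
        cov_rows.append((pid, sex.iloc[i], r["AGE"], r["WT"], r["HT"]))
        for t, c, k in zip(NOMINAL_TIMES, conc, keep):
            if k:
                obs_rows.append((pid, t, c))
        row = r.copy()
        row["SEX_F"] = 1.0 if sex.iloc[i] == "female" else 0.0
        row["SEX_M"] = 1.0 - row["SEX_F"]
        wide_rows.append(row)
        wide_index.append(pid)
        pid += 1
    covariates = pd.DataFrame(cov_rows, columns=["id", "sex", "age", "weight", "height"])
    observations = pd.DataFrame(obs_rows, columns=["id", "time", "conc"])
    if dose is None:
        dose = float(raw["DOSE"].iloc[0]) if len(raw) else 0.0
    long_df = to_nonmem(covariates, observations, dose, src=src)
    wide = pd.DataFrame(wide_rows, index=wide_index) if wide_rows else pd.DataFrame(columns=scaled.columns)
    report["n_accepted"] = len(wide)
    return wide, long_df, report
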