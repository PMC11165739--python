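"""Predictive mean matching (type-1 PMM) for systematically missing gait speed.

A linear predictor is fitted on donors (records with the target
observed); each recipient is filled with the *observed* value of one of
the ``k`` donors whose predicted means are closest to the recipient's,
drawn uniformly with a seeded generator.  Imputed values are therefore
always a subset of observed donor values.

Matching covariates default to age, sex, education, a 5-year mortality
flag, and the other four health indicators.  Single imputation only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PMMModel", "fit_pmm", "impute", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ["age", "sex", "education", "mort_5y", "mmse", "n_chronic", "iadl", "padl"]
_MORTALITY_HORIZON_YEARS = 5.0


def _design_matrix(table: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, complete_mask); categorical covariates are dummy-coded."""
    cols = [np.ones(len(table))]
    complete = np.ones(len(table), dtype=bool)
    for cov in covariates:
        if cov == "sex":
            complete &= table["sex"].notna().to_numpy()
            cols.append((table["sex"] == "female").to_numpy(dtype=float))
        elif cov == "education":
            complete &= table["education"].notna().to_numpy()
            cols.append((table["education"] == "high_school").to_numpy(dtype=float))
            cols.append((table["education"] == "university").to_numpy(dtype=float))
        elif cov == "mort_5y":
            ok = table["death_time"].notna().to_numpy()
            complete &= ok
            flag = ((table["death_event"].fillna(0) == 1)
                    & (table["death_time"] <= _MORTALITY_HORIZON_YEARS))
            cols.append(flag.to_numpy(dtype=float))
        else:
            vals = pd.to_numeric(table[cov], errors="coerce")
            complete &= vals.notna().to_numpy()
            cols.append(vals.fillna(0.0).to_numpy(dtype=float))
    return np.column_stack(cols), complete


@dataclass
class PMMModel:
    target: str
    covariates: list[str]
    coef: list[float]
    k: int
    n_donors: int
    donor_values: list[float] = field(default_factory=list)
    donor_preds: list[float] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PMMModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_pmm(table: pd.DataFrame, target: str = "gait_speed",
            covariates: list[str] | None = None, k: int = 5) -> PMMModel:
    """Fit the donor regression for PMM.

    Donors are rows with the target observed and complete covariates.
    Least-squares via ``lstsq`` (least-norm on rank deficiency, with a
    warning), so collinear covariate sets do not abort the pipeline.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    X, complete = _design_matrix(table, covariates)
    observed = pd.to_numeric(table[target], errors="coerce").notna().to_numpy()
    donors = observed & complete
    if donors.sum() < k:
        raise ValueError(f"only {int(donors.sum())} eligible donors for k={k}")
    Xd = X[donors]
    yd = table.loc[donors, target].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(Xd, yd, rcond=None)
    if rank < Xd.shape[1]:
        warnings.warn("collinear covariates in PMM regression; least-norm solution used")
    preds = Xd @ coef
    return PMMModel(target=target, covariates=covariates, coef=coef.tolist(), k=k,
                    n_donors=int(donors.sum()), donor_values=yd.tolist(),
                    donor_preds=preds.tolist())


def impute(model: PMMModel, table: pd.DataFrame, seed: int = 0,
           return_report: bool = False):
    """Fill missing target values by donor draws; flags provenance.

    Recipients with incomplete covariates are left missing and counted in
    the report.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    table = table.copy()
    X, complete = _design_matrix(table, model.covariates)
    target_missing = pd.to_numeric(table[model.target], errors="coerce").isna().to_numpy()
    recipients = target_missing & complete
    skipped = target_missing & ~complete

    coef = np.asarray(model.coef)
    donor_preds = np.asarray(model.donor_preds)
    donor_values = np.asarray(model.donor_values)
    k = min(model.k, len(donor_values))

    flag = np.zeros(len(table), dtype=int)
    filled = table[model.target].to_numpy(dtype=float).copy()
    idx = np.flatnonzero(recipients)
    if idx.size:
        preds_r = X[idx] @ coef
        dist = np.abs(donor_preds[None, :] - preds_r[:, None])
        nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
        pick = nearest[np.arange(idx.size), rng.integers(0, k, size=idx.size)]
        filled[idx] = donor_values[pick]
        flag[idx] = 1
    table[model.target] = filled
    table["gait_imputed" if model.target == "gait_speed" else f"{model.target}_imputed"] = flag

    if return_report:
        report = {"n_imputed": int(recipients.sum()),
                  "n_left_missing": int(skipped.sum()), "k_used": int(k)}
        return table, report
    return table
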