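"""Score-based geriatric percentile charts.

Percentile curves of the 0-10 health score versus age, per sex, fitted
by logistic quantile regression: the bounded score is mapped through a
bounded logit, quantile regressions (check-loss) are fitted on a
restricted cubic spline basis of age with four knots, predictions are
back-transformed, and crossing is prevented by monotone rearrangement
across percentiles at each age.  Outcome-risk contours come from a
logistic model of the outcome on the age spline plus the score, and the
chart renderer overlays both, exporting tidy CSVs of everything it
plots so the figure is a pure view of the exported data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChartModel",
    "RiskSurface",
    "bounded_logit",
    "bounded_logit_inv",
    "rcs_basis",
    "default_knots",
    "fit_quantile_curves",
    "fit_risk_surface",
    "render_chart",
]

DEFAULT_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
DEFAULT_EPS = 0.01


def bounded_logit(y, L: float = 0.0, U: float = 10.0, eps: float = DEFAULT_EPS) -> np.ndarray:
    """h(y) = log((y - L + eps) / (U - y + eps)); strictly increasing on [L, U]."""
    y = np.asarray(y, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if ((y < L) | (y > U)).any():
        raise ValueError(f"values outside [{L}, {U}]")
    return np.log((y - L + eps) / (U - y + eps))


def bounded_logit_inv(h, L: float = 0.0, U: float = 10.0, eps: float = DEFAULT_EPS) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    e = np.exp(h)
    return (L - eps + (U + eps) * e) / (1.0 + e)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond boundary knots.

    For ``m`` knots returns ``m - 1`` columns (the first is the identity),
    so 4 knots give 3 columns; the intercept is left to the regression.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.size < 3 or np.any(np.diff(k) <= 0):
        raise ValueError("need >= 3 strictly increasing knots")
    km, k1 = k[-1], k[-2]
    cols = [x]
    denom = km - k[0]
    for j in range(k.size - 2):
        term = (np.maximum(x - k[j], 0.0) ** 3
                - np.maximum(x - k1, 0.0) ** 3 * (km - k[j]) / (km - k1)
                + np.maximum(x - km, 0.0) ** 3 * (k1 - k[j]) / (km - k1))
        cols.append(term / denom ** 2)
    return np.column_stack(cols)


def default_knots(age: np.ndarray) -> np.ndarray:
    """Knots at the 5th/35th/65th/95th age quantiles."""
    return np.quantile(np.asarray(age, dtype=float), [0.05, 0.35, 0.65, 0.95])


@dataclass
class ChartModel:
    sex: str
    percentiles: tuple[int, ...]
    knots: np.ndarray
    coefs: np.ndarray          # (n_percentiles, n_basis + 1) incl. intercept
    L: float = 0.0
    U: float = 10.0
    eps: float = DEFAULT_EPS
    check_loss: list[float] = field(default_factory=list)
    age_range: tuple[float, float] = (60.0, 100.0)

    def predict(self, ages) -> pd.DataFrame:
        """Back-transformed, non-crossing percentile predictions."""
        ages = np.asarray(ages, dtype=float)
        X = np.column_stack([np.ones(ages.size), rcs_basis(ages, self.knots)])
        preds = bounded_logit_inv(self.coefs @ X.T, self.L, self.U, self.eps)
        # the eps-padded inverse can leak past the bounds for extreme fitted
        # values; clamp strictly inside (L, U)
        tol = 1e-6
        preds = np.clip(preds, self.L + tol, self.U - tol)
        preds = np.sort(preds, axis=0)  # monotone rearrangement across percentiles
        out = pd.DataFrame(preds.T, columns=[f"p{p}" for p in self.percentiles])
        out.insert(0, "age", ages)
        return out

    def to_json(self, path=None) -> str:
        payload = {"sex": self.sex, "percentiles": list(self.percentiles),
                   "knots": self.knots.tolist(), "coefs": self.coefs.tolist(),
                   "L": self.L, "U": self.U, "eps": self.eps,
                   "check_loss": self.check_loss, "age_range": list(self.age_range)}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_quantile_curves(table: pd.DataFrame, sex: str = "all",
                        percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
                        knots: np.ndarray | None = None,
                        score_col: str = "hat") -> ChartModel:
    """Logistic quantile regression of the score on an age spline.

    Check loss is minimized by ``statsmodels`` ``QuantReg`` (IRLS) on the
    bounded-logit transformed score.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    if sex != "all":
        table = table[table["sex"] == sex]
    if len(table) < 200:
        warnings.warn(f"stratum {sex!r} has only {len(table)} records; curves unstable")
    hat = table[score_col].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    if np.ptp(hat) == 0:
        raise ValueError("degenerate score distribution (all values equal)")
    if knots is None:
        knots = default_knots(age)
    z = bounded_logit(hat)
    X = np.column_stack([np.ones(age.size), rcs_basis(age, knots)])
    coefs = np.empty((len(percentiles), X.shape[1]))
    losses = []
    for i, p in enumerate(percentiles):
        q = p / 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = QuantReg(z, X).fit(q=q, max_iter=5000)
        coefs[i] = res.params
        resid = z - X @ res.params
        losses.append(float(np.mean(resid * (q - (resid < 0)))))
    return ChartModel(sex=sex, percentiles=tuple(percentiles), knots=np.asarray(knots),
                      coefs=coefs, check_loss=losses,
                      age_range=(float(age.min()), float(age.max())))


@dataclass
class RiskSurface:
    outcome: str
    age_grid: np.ndarray
    hat_grid: np.ndarray
    prob: np.ndarray            # (n_age, n_hat)
    coefs: np.ndarray
    knots: np.ndarray
    penalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        aa, hh = np.meshgrid(self.age_grid, self.hat_grid, indexing="ij")
        return pd.DataFrame({"age": aa.ravel(), "hat": hh.ravel(),
                             "predicted_prob": self.prob.ravel()})

    def predict(self, age, hat) -> np.ndarray:
        from scipy.special import expit
        age = np.asarray(age, dtype=float)
        hat = np.asarray(hat, dtype=float)
        X = np.column_stack([np.ones(age.size), rcs_basis(age, self.knots), hat])
        return expit(X @ self.coefs)


def fit_risk_surface(table: pd.DataFrame, outcome: np.ndarray | str,
                     score_col: str = "hat", knots: np.ndarray | None = None,
                     age_grid: np.ndarray | None = None,
                     hat_grid: np.ndarray | None = None,
                     outcome_label: str = "outcome") -> RiskSurface:
    """Logistic model of a binary outcome on age spline + score, on a grid.

    Falls back to an L2-penalized fit (with a warning) if the unpenalized
    GLM fails to converge, e.g. under separation.
    """
    import statsmodels.api as sm

    if isinstance(outcome, str):
        outcome_label = outcome
        y = table[outcome].to_numpy(dtype=float)
    else:
        y = np.asarray(outcome, dtype=float)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError("outcome must have both classes")
    age = table["age"].to_numpy(dtype=float)
    hat = table[score_col].to_numpy(dtype=float)
    if knots is None:
        knots = default_knots(age)
    X = np.column_stack([np.ones(age.size), rcs_basis(age, knots), hat])
    penalized = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        coefs = np.asarray(fit.params)
        if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 1e3:
            raise RuntimeError("unstable coefficients")
    except Exception:
        warnings.warn("logistic fit unstable; refitting with L2 penalty")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=5000)
        lr.fit(X[:, 1:], y.astype(int))
        coefs = np.concatenate([[lr.intercept_[0]], lr.coef_[0]])
        penalized = True

    if age_grid is None:
        age_grid = np.linspace(age.min(), age.max(), 41)
    if hat_grid is None:
        hat_grid = np.linspace(0.0, 10.0, 41)
    aa, hh = np.meshgrid(age_grid, hat_grid, indexing="ij")
    from scipy.special import expit
    Xg = np.column_stack([np.ones(aa.size), rcs_basis(aa.ravel(), knots), hh.ravel()])
    prob = expit(Xg @ coefs).reshape(aa.shape)
    return RiskSurface(outcome=outcome_label, age_grid=np.asarray(age_grid),
                       hat_grid=np.asarray(hat_grid), prob=prob, coefs=coefs,
                       knots=np.asarray(knots), penalized=penalized)


def render_chart(chart: ChartModel, surface: RiskSurface | None, out_path,
                 n_ages: int = 81) -> dict[str, str]:
    """Write the chart image plus tidy CSVs of every plotted value.

    Returns a mapping of artifact kind -> file path.  Deterministic given
    the fitted inputs; the CSVs alone are sufficient to regenerate the
    figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = str(out_path)
    stem = out_path.rsplit(".", 1)[0]
    ages = np.linspace(chart.age_range[0], chart.age_range[1], n_ages)
    curves = chart.predict(ages)
    curves_csv = f"{stem}_percentiles.csv"
    curves.to_csv(curves_csv, index=False)

    fig, ax = plt.subplots(figsize=(7, 5))
    artifacts = {"image": out_path, "percentiles_csv": curves_csv}
    if surface is not None:
        sf = surface.to_frame()
        surface_csv = f"{stem}_risk.csv"
        sf.to_csv(surface_csv, index=False)
        artifacts["risk_csv"] = surface_csv
        cs = ax.contourf(surface.age_grid, surface.hat_grid, surface.prob.T,
                         levels=10, cmap="RdYlGn_r", alpha=0.6)
        fig.colorbar(cs, ax=ax, label=f"P({surface.outcome})")
    for p in chart.percentiles:
        ax.plot(curves["age"], curves[f"p{p}"], color="black",
                lw=1.5 if p == 50 else 0.8)
        ax.annotate(f"{p}", (curves["age"].iloc[-1], curves[f"p{p}"].iloc[-1]),
                    fontsize=7)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("health score (0-10)")
    ax.set_ylim(0, 10)
    ax.set_title(f"Percentile chart ({chart.sex})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120, metadata={"Software": None} if out_path.endswith(".png") else {})
    plt.close(fig)
    return artifacts
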