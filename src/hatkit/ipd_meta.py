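"""Two-stage fixed-effect individual-participant-data meta-analysis.

Stage-1 estimates (per-cohort AUC or concordance) are pooled by
inverse-variance weighting on a transform scale — the logit by default,
which keeps back-transformed CIs inside (0, 1).  Standard errors passed
in are interpreted on the transform scale (for validation results they
come from the CI half-width divided by 1.96 after transforming the CI
bounds).  Leave-cohort-out reruns keep full and reduced results side by
side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = ["MetaResult", "pool_fixed", "leave_cohort_out", "meta_input_from_result"]


@dataclass
class MetaResult:
    outcome: str
    metric: str
    estimates: list[float]
    ses: list[float]                     # on the transform scale
    weights: list[float]                 # normalized inverse-variance weights
    pooled: float                        # back-transformed pooled estimate
    ci_lo: float
    ci_hi: float
    pooled_se_transformed: float
    transform: str
    cohorts: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_TRANSFORMS = {
    "logit": (lambda x: logit(x), lambda z: expit(z)),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda z: z),
}


def pool_fixed(estimates, ses, transform: str = "logit",
               outcome: str = "", metric: str = "",
               cohorts: list[str] | None = None) -> MetaResult:
    """Inverse-variance fixed-effect pooling on the transform scale.

    ``ses`` are standard errors *on the transform scale* (raw scale for
    the identity transform).  Estimates must lie strictly inside (0, 1)
    for the logit transform.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and ses must be aligned non-empty 1-d arrays")
    if (se <= 0).any():
        raise ValueError("all standard errors must be > 0")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "logit" and ((est <= 0) | (est >= 1)).any():
        raise ValueError("estimates at 0 or 1 are not logit-poolable; "
                         "use transform='identity'")
    fwd, inv = _TRANSFORMS[transform]
    z = fwd(est)
    w = 1.0 / se ** 2
    w_norm = w / w.sum()
    pooled_z = float((w_norm * z).sum())
    pooled_se = float(np.sqrt(1.0 / w.sum()))
    half = norm.ppf(0.975) * pooled_se
    return MetaResult(
        outcome=outcome, metric=metric,
        estimates=est.tolist(), ses=se.tolist(), weights=w_norm.tolist(),
        pooled=float(inv(pooled_z)),
        ci_lo=float(inv(pooled_z - half)), ci_hi=float(inv(pooled_z + half)),
        pooled_se_transformed=pooled_se, transform=transform,
        cohorts=list(cohorts) if cohorts is not None else [],
    )


def leave_cohort_out(results_by_cohort: dict[str, tuple[float, float]], drop: str,
                     transform: str = "logit", outcome: str = "",
                     metric: str = "") -> MetaResult:
    """Pool excluding one named cohort; >= 2 cohorts must remain."""
    if drop not in results_by_cohort:
        raise KeyError(f"unknown cohort label {drop!r}")
    remaining = {k: v for k, v in results_by_cohort.items() if k != drop}
    if len(remaining) < 2:
        raise ValueError("leave-one-out requires >= 2 remaining cohorts")
    labels = sorted(remaining)
    est = [remaining[k][0] for k in labels]
    se = [remaining[k][1] for k in labels]
    return pool_fixed(est, se, transform=transform, outcome=outcome,
                      metric=metric, cohorts=labels)


def meta_input_from_result(result, transform: str = "logit") -> tuple[float, float]:
    """(estimate, transform-scale SE) from a :class:`ValidationResult`.

    SE = transform-scale CI half-width / 1.96.
    """
    fwd, _ = _TRANSFORMS[transform]
    lo, hi = result.ci_lo, result.ci_hi
    if transform == "logit":
        lo = min(max(lo, 1e-6), 1 - 1e-6)
        hi = min(max(hi, 1e-6), 1 - 1e-6)
    half = (float(fwd(hi)) - float(fwd(lo))) / 2.0
    se = max(half / norm.ppf(0.975), 1e-8)
    return float(result.estimate), se
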