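"""Nominal response model (NRm) engine.

Implements Bock's nominal categories model from scratch:

* category probabilities ``P_k(theta) = softmax_k(a_k * theta + c_k)``
  with sum-to-zero identification over categories within each item;
* marginal maximum likelihood fitting by EM with Gauss-Hermite
  quadrature over a standard-normal latent prior (posterior over nodes
  in the E-step, per-item weighted multinomial-logit Newton updates in
  the M-step, with step-halving so the expected complete-data objective
  never decreases — hence a monotone marginal log-likelihood);
* test characteristic curves (TCC), test information functions (TIF),
  and EAP latent scores with posterior SDs.

Respondent response patterns are collapsed to unique rows before the EM
loop, which makes fits on tens of thousands of respondents with a
handful of polytomous items essentially instantaneous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import roots_hermitenorm

__all__ = [
    "IndicatorCutoffs",
    "NRMItemParams",
    "NRMFit",
    "CurveTable",
    "categorize",
    "fit_nrm",
    "category_prob",
    "tcc",
    "tif",
    "eap_score",
]

from .synthetic_cohorts import INDICATORS

#: default direction per indicator: does a larger raw value mean better health?
HIGHER_IS_HEALTHIER = {
    "gait_speed": True, "mmse": True, "n_chronic": False, "iadl": False, "padl": False,
}


@dataclass(frozen=True)
class IndicatorCutoffs:
    """Ordered thresholds per indicator plus direction flags.

    ``thresholds[name]`` is a strictly increasing tuple defining
    ``len + 1`` categories.  Categories are always coded health-ordered:
    0 = least healthy.  The boundary convention is half-open with values
    *at* a threshold belonging to the upper raw bin.
    """

    thresholds: dict[str, tuple[float, ...]]
    higher_is_healthier: dict[str, bool] = field(default_factory=lambda: dict(HIGHER_IS_HEALTHIER))

    def __post_init__(self):
        for name, thr in self.thresholds.items():
            thr = tuple(thr)
            if len(thr) < 1:
                raise ValueError(f"{name}: at least one threshold required")
            if any(b <= a for a, b in zip(thr, thr[1:])):
                raise ValueError(f"{name}: thresholds must be strictly increasing: {thr}")

    def n_categories(self, name: str) -> int:
        return len(self.thresholds[name]) + 1

    def to_dict(self) -> dict:
        return {"thresholds": {k: list(v) for k, v in self.thresholds.items()},
                "higher_is_healthier": dict(self.higher_is_healthier)}

    @classmethod
    def from_dict(cls, d: dict) -> "IndicatorCutoffs":
        return cls(thresholds={k: tuple(v) for k, v in d["thresholds"].items()},
                   higher_is_healthier=dict(d["higher_is_healthier"]))


def categorize(table: pd.DataFrame, cutoffs: IndicatorCutoffs,
               items: tuple[str, ...] = INDICATORS) -> np.ndarray:
    """Map indicator values to health-ordered category codes (n x n_items).

    Raises on missing or out-of-range values — callers are expected to
    have applied complete-case exclusion already.
    """
    out = np.empty((len(table), len(items)), dtype=np.int64)
    for j, name in enumerate(items):
        vals = table[name].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"{name}: missing values; complete-case input required")
        thr = np.asarray(cutoffs.thresholds[name], dtype=float)
        raw = np.searchsorted(thr, vals, side="right")  # values >= threshold go up
        if cutoffs.higher_is_healthier.get(name, True):
            out[:, j] = raw
        else:
            out[:, j] = len(thr) - raw
    return out


# ---------------------------------------------------------------------------
# model pieces
# ---------------------------------------------------------------------------

@dataclass
class NRMItemParams:
    """Slopes and intercepts per category, sum-to-zero identified."""

    a: np.ndarray  # (K,)
    c: np.ndarray  # (K,)
    name: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        # size 1 = degenerate constant item (all respondents in one
        # category after collapsing); it contributes nothing to the fit
        if self.a.shape != self.c.shape or self.a.ndim != 1 or self.a.size < 1:
            raise ValueError("a and c must be 1-d arrays of equal length >= 1")

    @property
    def n_categories(self) -> int:
        return self.a.size


def category_prob(params: NRMItemParams, theta) -> np.ndarray:
    """Category probabilities at theta; overflow-safe (max subtraction).

    Returns shape ``(..., K)`` broadcasting over theta.
    """
    th = np.asarray(theta, dtype=float)
    eta = th[..., None] * params.a + params.c
    eta -= eta.max(axis=-1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=-1, keepdims=True)


@dataclass
class NRMFit:
    items: list[NRMItemParams]
    nodes: np.ndarray
    weights: np.ndarray
    loglik: float
    trace: list[float]
    converged: bool
    n_respondents: int
    n_patterns: int
    category_maps: list[dict[int, int]]  # observed code -> fitted code (collapsing)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_json(self, path=None) -> str:
        payload = {
            "items": [{"name": it.name, "a": it.a.tolist(), "c": it.c.tolist()}
                      for it in self.items],
            "nodes": self.nodes.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "trace": list(self.trace),
            "converged": self.converged,
            "n_respondents": self.n_respondents,
            "n_patterns": self.n_patterns,
            "category_maps": [{str(k): v for k, v in m.items()} for m in self.category_maps],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "NRMFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            items=[NRMItemParams(np.array(it["a"]), np.array(it["c"]), it["name"])
                   for it in d["items"]],
            nodes=np.array(d["nodes"]), weights=np.array(d["weights"]),
            loglik=d["loglik"], trace=d["trace"], converged=d["converged"],
            n_respondents=d["n_respondents"], n_patterns=d["n_patterns"],
            category_maps=[{int(k): v for k, v in m.items()} for m in d["category_maps"]],
        )


def _quadrature(n: int) -> tuple[np.ndarray, np.ndarray]:
    # Gauss-Hermite for weight exp(-x^2/2): nodes are N(0,1) abscissae
    nodes, w = roots_hermitenorm(n)
    return nodes, w / w.sum()


def _apply_category_maps(responses: np.ndarray, maps: list[dict[int, int]]) -> np.ndarray:
    out = np.empty_like(responses)
    for j, m in enumerate(maps):
        col = responses[:, j]
        try:
            out[:, j] = np.vectorize(m.__getitem__, otypes=[np.int64])(col)
        except KeyError as exc:
            raise ValueError(f"item {j}: unseen category code {exc.args[0]}") from None
    return out


def _item_objective(a0: np.ndarray, c0: np.ndarray, nodes: np.ndarray,
                    r: np.ndarray) -> float:
    eta = nodes[:, None] * a0 + c0
    eta -= eta.max(axis=1, keepdims=True)
    logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
    return float((r * logp).sum())


def _mstep_item(a: np.ndarray, c: np.ndarray, nodes: np.ndarray, r: np.ndarray,
                ridge: float = 1e-8, max_newton: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Maximize sum_q sum_k r[q,k] log P_k(theta_q) over item parameters.

    Works in baseline parameterization (category 0 fixed at 0), Newton
    with step-halving, then recenters to sum-to-zero.
    """
    K = a.size
    # shift to baseline-0 parameterization
    a0 = a - a[0]
    c0 = c - c[0]
    x = np.column_stack([nodes, np.ones_like(nodes)])  # (Q, 2)
    nq = r.sum(axis=1)  # (Q,)
    obj = _item_objective(a0, c0, nodes, r)
    for _ in range(max_newton):
        eta = nodes[:, None] * a0 + c0
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        # gradient for categories 1..K-1 over (a_k, c_k)
        resid = r[:, 1:] - nq[:, None] * p[:, 1:]  # (Q, K-1)
        grad = np.concatenate([(resid * nodes[:, None]).sum(axis=0)[:, None],
                               resid.sum(axis=0)[:, None]], axis=1).ravel()  # (2(K-1),)
        if np.max(np.abs(grad)) < 1e-9 * max(1.0, nq.sum()):
            break
        # Hessian: block structure over category pairs
        dim = 2 * (K - 1)
        H = np.zeros((dim, dim))
        xx = np.einsum("qi,qj->qij", x, x)  # (Q,2,2)
        for k in range(1, K):
            for l in range(1, K):
                w = nq * (p[:, k] * ((k == l) - p[:, l]))
                H[2 * (k - 1):2 * k, 2 * (l - 1):2 * l] = -np.einsum("q,qij->ij", w, xx)
        H -= ridge * np.eye(dim)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Newton direction (H is negative definite): delta = -H^{-1} g
        delta = -step
        scale = 1.0
        for _ in range(30):
            a_try = a0.copy()
            c_try = c0.copy()
            a_try[1:] += scale * delta[0::2]
            c_try[1:] += scale * delta[1::2]
            new_obj = _item_objective(a_try, c_try, nodes, r)
            if new_obj >= obj - 1e-12:
                a0, c0, obj = a_try, c_try, new_obj
                break
            scale *= 0.5
        else:
            break  # no improving step; give up on this M-step
        if scale * np.max(np.abs(delta)) < 1e-10:
            break
    return a0 - a0.mean(), c0 - c0.mean()


def fit_nrm(responses: np.ndarray, n_quadrature: int = 41, tol: float = 1e-6,
            max_iter: int = 500, seed: int | None = None,
            item_names: list[str] | None = None) -> NRMFit:
    """Fit the nominal response model by marginal maximum likelihood.

    Parameters
    ----------
    responses
        Integer category codes, shape (n_respondents, n_items); codes
        need not be contiguous — unobserved categories are collapsed
        away with a warning and recorded in ``category_maps``.
    tol
        Relative marginal log-likelihood change declaring convergence.
    seed
        Unused for the deterministic EM itself; accepted for interface
        stability.
    """
    responses = np.asarray(responses, dtype=np.int64)
    if responses.ndim != 2:
        raise ValueError("responses must be 2-d")
    n, J = responses.shape
    if n < 50:
        warnings.warn(f"only {n} respondents; NRm estimates will be unstable")

    # collapse unobserved categories per item; codes become 0..K-1
    category_maps: list[dict[int, int]] = []
    coded = np.empty_like(responses)
    for j in range(J):
        observed = np.unique(responses[:, j])
        if observed.size < 2:
            warnings.warn(f"item {j}: constant responses; collapsed to a null item")
        full = np.arange(responses[:, j].min(), responses[:, j].max() + 1)
        if observed.size < full.size:
            warnings.warn(f"item {j}: collapsing {full.size - observed.size} empty categories")
        m = {int(code): i for i, code in enumerate(observed)}
        category_maps.append(m)
        coded[:, j] = np.vectorize(m.__getitem__, otypes=[np.int64])(responses[:, j])
    Ks = [len(m) for m in category_maps]

    # collapse to unique patterns
    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    P = patterns.shape[0]

    nodes, wq = _quadrature(n_quadrature)
    Q = nodes.size

    names = item_names if item_names is not None else [f"item_{j}" for j in range(J)]
    items = [NRMItemParams(np.linspace(-0.5, 0.5, K), np.zeros(K), names[j])
             for j, K in enumerate(Ks)]
    for it in items:
        it.a -= it.a.mean()

    trace: list[float] = []
    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step: pattern x node likelihood
        logL = np.zeros((P, Q))
        probs = [category_prob(it, nodes) for it in items]  # each (Q, K_j)
        for j in range(J):
            logL += np.log(np.maximum(probs[j][:, patterns[:, j]].T, 1e-300))
        logpost = logL + np.log(wq)[None, :]
        mx = logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost - mx)
        norm = post.sum(axis=1, keepdims=True)
        ll = float((counts * (np.log(norm[:, 0]) + mx[:, 0])).sum())
        post /= norm
        trace.append(ll)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-10):
            converged = True
            break
        prev_ll = ll

        # expected counts per item: r_j[q, k]
        wpost = post * counts[:, None]  # (P, Q)
        for j in range(J):
            K = Ks[j]
            if K == 1:   # constant item: nothing to estimate
                continue
            r = np.zeros((Q, K))
            for k in range(K):
                sel = patterns[:, j] == k
                if sel.any():
                    r[:, k] = wpost[sel].sum(axis=0)
            a_new, c_new = _mstep_item(items[j].a, items[j].c, nodes, r)
            items[j] = NRMItemParams(a_new, c_new, items[j].name)

    if not converged:
        warnings.warn("EM did not converge within max_iter; fit flagged")
    return NRMFit(items=items, nodes=nodes, weights=wq, loglik=trace[-1],
                  trace=trace, converged=converged, n_respondents=n,
                  n_patterns=P, category_maps=category_maps)


# ---------------------------------------------------------------------------
# curves and scoring
# ---------------------------------------------------------------------------

@dataclass
class CurveTable:
    theta: np.ndarray
    per_item: np.ndarray   # (n_items, n_theta)
    total: np.ndarray      # (n_theta,)
    kind: str              # "tcc" | "tif"
    item_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = {"theta": self.theta, "total": self.total}
        for j, name in enumerate(self.item_names):
            rows[name] = self.per_item[j]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tcc(fit: NRMFit, theta_grid: np.ndarray) -> CurveTable:
    """Expected category score per item and in total: sum_k k * P_k(theta)."""
    grid = np.asarray(theta_grid, dtype=float)
    per_item = np.empty((fit.n_items, grid.size))
    for j, it in enumerate(fit.items):
        p = category_prob(it, grid)
        per_item[j] = p @ np.arange(it.n_categories)
    return CurveTable(grid, per_item, per_item.sum(axis=0), "tcc",
                      [it.name for it in fit.items])


def tif(fit: NRMFit, theta_grid: np.ndarray) -> CurveTable:
    """Fisher information per item: sum_k P_k a_k^2 - (sum_k P_k a_k)^2."""
    grid = np.asarray(theta_grid, dtype=float)
    per_item = np.empty((fit.n_items, grid.size))
    for j, it in enumerate(fit.items):
        p = category_prob(it, grid)
        m1 = p @ it.a
        m2 = p @ (it.a ** 2)
        per_item[j] = m2 - m1 ** 2
    return CurveTable(grid, per_item, per_item.sum(axis=0), "tif",
                      [it.name for it in fit.items])


def eap_score(fit: NRMFit, responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EAP theta and posterior SD per respondent (standard-normal prior)."""
    responses = np.asarray(responses, dtype=np.int64)
    coded = _apply_category_maps(responses, fit.category_maps)
    patterns, inverse = np.unique(coded, axis=0, return_inverse=True)
    P = patterns.shape[0]
    Q = fit.nodes.size
    logL = np.zeros((P, Q))
    for j, it in enumerate(fit.items):
        probs = category_prob(it, fit.nodes)
        logL += np.log(np.maximum(probs[:, patterns[:, j]].T, 1e-300))
    logpost = logL + np.log(fit.weights)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ fit.nodes
    var = post @ (fit.nodes ** 2) - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean[inverse], sd[inverse]
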