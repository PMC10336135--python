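"""Cox partial-likelihood modelling and survival evaluation.

The training loss is the negative log partial likelihood (Breslow convention
for tied event times):

    L = - sum_{i: event_i} [ s_i - log sum_{j: Y_j >= Y_i} exp(s_j) ]

with s the risk score (X.beta for the linear model, f_theta(X) for the small
network, whose mini-batch variant takes risk sets within each batch).
Evaluation uses Harrell's concordance index, the IPCW (Graf) integrated Brier
score with a Breslow baseline hazard, and the composite score

    CS = (C-index + (1 - IBS)) / 2.

Kaplan-Meier curves and the log-rank test delegate to lifelines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

log = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cox loss


def _order_desc(time: np.ndarray) -> np.ndarray:
    return np.argsort(-time, kind="stable")


def cox_loss(scores, time, event) -> float:
    """Negative log Cox partial likelihood (Breslow ties).

    With zero events the sum is empty: returns 0.0 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if np.isnan(s).any():
        raise ValueError("NaN scores")
    if d.sum() == 0:
        warnings.warn("cox_loss: no events; loss is 0")
        return 0.0
    loss, _ = _cox_loss_grad(s, t, d)
    return float(loss)


def _cox_loss_grad(s: np.ndarray, t: np.ndarray, d: np.ndarray):
    """Loss and gradient wrt scores, numerically stabilized.

    Sorting time descending, the risk set of an event at time y is the prefix
    of subjects with time >= y (ties included).
    """
    order = _order_desc(t)
    ts, ss, ds = t[order], s[order], d[order]
    m = ss.max()
    e = np.exp(ss - m)
    cum = np.cumsum(e)
    # risk-set end per position: last index with time == ts[pos]
    ends = np.searchsorted(-ts, -ts, side="right") - 1
    ev = np.flatnonzero(ds == 1)
    s0 = cum[ends[ev]]
    loss = -np.sum(ss[ev] - (np.log(s0) + m))
    # gradient: dL/ds_j = -d_j + e_j * sum_{events i with Y_i <= Y_j} 1/S0_i
    inv = np.zeros(len(ts))
    inv[ev] = 1.0 / s0
    # subject j (position pj) is in the risk set of event i iff pos_i >= first
    # position with time == ts[pj]
    starts = np.searchsorted(-ts, -ts, side="left")
    suffix = np.concatenate([np.cumsum(inv[::-1])[::-1], [0.0]])
    grad_sorted = -ds + e * suffix[starts]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad


# ---------------------------------------------------------------------------
# Linear Cox fit (Newton-Raphson on the Breslow partial likelihood)


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    converged: bool
    loglik: float
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def _cox_derivatives(X: np.ndarray, beta: np.ndarray, t: np.ndarray, d: np.ndarray):
    """Breslow log-likelihood, gradient and observed information."""
    n, p = X.shape
    order = _order_desc(t)
    Xs, ts, ds = X[order], t[order], d[order]
    eta = Xs @ beta
    m = eta.max()
    w = np.exp(eta - m)
    s0 = np.cumsum(w)
    s1 = np.cumsum(Xs * w[:, None], axis=0)
    xw = Xs[:, :, None] * Xs[:, None, :] * w[:, None, None]
    s2 = np.cumsum(xw, axis=0)
    ends = np.searchsorted(-ts, -ts, side="right") - 1
    ev = np.flatnonzero(ds == 1)
    k = ends[ev]
    s0e = s0[k]
    s1e = s1[k] / s0e[:, None]
    ll = float(np.sum(eta[ev] - (np.log(s0e) + m)))
    grad = Xs[ev].sum(axis=0) - s1e.sum(axis=0)
    info = np.einsum("kij->ij", s2[k] / s0e[:, None, None]) - np.einsum(
        "ki,kj->ij", s1e, s1e
    )
    return ll, grad, info


def fit_linear_cox(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    time_col: str = "time",
    event_col: str = "event",
    l2: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a linear Cox proportional-hazards model by Newton-Raphson.

    Maximizes the Breslow partial likelihood minus ``l2 * ||beta||^2``.
    Standard errors come from the inverse observed information; HRs, 95% CIs
    and p-values are Wald. Constant covariate columns raise; an apparently
    monotone likelihood (diverging beta) clears the convergence flag with
    advice to set ``l2 > 0``.
    """
    if covariates is None:
        covariates = [c for c in table.columns if c not in (time_col, event_col, "patient_id")]
    t = table[time_col].to_numpy(float)
    d = table[event_col].to_numpy(int)
    if not (np.isfinite(t).all() and (t > 0).all()):
        raise ValueError("times must be finite and positive")
    if d.sum() < 1:
        raise ValueError("need >= 1 event")
    X = table[covariates].to_numpy(float)
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        bad = [covariates[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
        raise ValueError(f"constant covariate columns: {bad}")
    p = X.shape[1]
    beta = np.zeros(p)
    ll_pen = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, info = _cox_derivatives(X, beta, t, d)
        ll_new = ll - l2 * beta @ beta
        g = grad - 2.0 * l2 * beta
        H = info + 2.0 * l2 * np.eye(p)
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(H, g)[0]
        # step-halving
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_c, _, _ = _cox_derivatives(X, cand, t, d)
            if ll_c - l2 * cand @ cand >= ll_new - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if abs(ll_new - ll_pen) < tol and np.abs(alpha * step).max() < 1e-8:
            converged = True
            break
        ll_pen = ll_new
    if np.abs(beta).max() > 50:
        converged = False
        log.warning(
            "fit_linear_cox: likelihood appears monotone (|beta| > 50); "
            "consider l2 > 0"
        )
    ll, _, info = _cox_derivatives(X, beta, t, d)
    H = info + 2.0 * l2 * np.eye(p)
    try:
        cov = linalg.inv(H)
    except linalg.LinAlgError:
        cov = linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    idx = pd.Index(covariates)
    return CoxFit(
        beta=pd.Series(beta, idx),
        se=pd.Series(se, idx),
        hr=pd.Series(np.exp(beta), idx),
        ci_low=pd.Series(np.exp(beta - 1.959963984540054 * se), idx),
        ci_high=pd.Series(np.exp(beta + 1.959963984540054 * se), idx),
        p=pd.Series(pvals, idx),
        converged=converged,
        loglik=float(ll),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Small risk network trained on the batch-wise Cox loss


@dataclass
class RiskModel:
    """Feed-forward risk scorer f_theta (tanh hidden layers, linear output)."""

    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ W + b
            if i < len(self.weights) - 1:
                a = np.tanh(a)
        return a.ravel()

    def to_json(self, path) -> None:
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": "tanh",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=[np.asarray(w) for w in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
        )


def init_risk_model(
    n_features: int, hidden_sizes: tuple = (), seed: int = 0, scale: float = 0.5
) -> RiskModel:
    """Random (untrained) model; also the baseline comparator."""
    rng = np.random.default_rng(seed)
    sizes = [n_features, *hidden_sizes, 1]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, scale / np.sqrt(a), size=(a, b)))
        biases.append(np.zeros(b))
    return RiskModel(weights=weights, biases=biases)


def fit_risk_network(
    table: pd.DataFrame,
    feature_cols: list[str],
    hidden_sizes: tuple = (),
    batch_size: int = 128,
    lr: float = 0.05,
    epochs: int = 200,
    seed: int = 0,
    l2: float = 0.0,
    time_col: str = "time",
    event_col: str = "event",
) -> RiskModel:
    """Train f_theta on the mini-batch Cox loss with within-batch risk sets.

    Batches are a fresh seeded permutation each epoch; a batch with zero
    events contributes no loss (skipped, counted). ``hidden_sizes=()`` gives a
    linear model whose full-batch optimum matches :func:`fit_linear_cox`.
    Optimized with Adam; deterministic per seed.
    """
    X = table[feature_cols].to_numpy(float)
    t = table[time_col].to_numpy(float)
    d = table[event_col].to_numpy(int)
    n = len(t)
    model = init_risk_model(len(feature_cols), hidden_sizes, seed=seed, scale=0.1)
    rng = np.random.default_rng(seed + 1)
    mw = [np.zeros_like(w) for w in model.weights]
    vw = [np.zeros_like(w) for w in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    skipped = 0
    for _ in range(epochs):
        perm = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = perm[lo : lo + batch_size]
            if d[idx].sum() == 0:
                skipped += 1
                continue
            xb, tb, db = X[idx], t[idx], d[idx]
            # forward with cached activations
            acts = [xb]
            a = xb
            for i, (W, bia) in enumerate(zip(model.weights, model.biases)):
                z = a @ W + bia
                a = np.tanh(z) if i < len(model.weights) - 1 else z
                acts.append(a)
            scores = a.ravel()
            _, gs = _cox_loss_grad(scores, tb, db)
            gs = gs / max(int(db.sum()), 1)
            delta = gs[:, None]
            gw = [None] * len(model.weights)
            gb = [None] * len(model.biases)
            for i in range(len(model.weights) - 1, -1, -1):
                gw[i] = acts[i].T @ delta + 2.0 * l2 * model.weights[i]
                gb[i] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ model.weights[i].T) * (1.0 - acts[i] ** 2)
            step += 1
            for i in range(len(model.weights)):
                mw[i] = b1 * mw[i] + (1 - b1) * gw[i]
                vw[i] = b2 * vw[i] + (1 - b2) * gw[i] ** 2
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                mhw = mw[i] / (1 - b1**step)
                vhw = vw[i] / (1 - b2**step)
                mhb = mb[i] / (1 - b1**step)
                vhb = vb[i] / (1 - b2**step)
                model.weights[i] -= lr * mhw / (np.sqrt(vhw) + eps)
                model.biases[i] -= lr * mhb / (np.sqrt(vhb) + eps)
    if skipped:
        log.info("fit_risk_network: %d zero-event batches skipped", skipped)
    return model


# ---------------------------------------------------------------------------
# Evaluation


def concordance_index(scores, time, event) -> float:
    """Harrell's C with the admissible-pair rule.

    A pair is admissible if neither subject is censored, or the earlier time is
    uncensored; pairs with exactly tied times are excluded (no ordering
    exists). Higher score = higher risk = earlier failure counts concordant;
    tied scores count 0.5. Raises when no pair is admissible.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    ti = t[:, None]
    tj = t[None, :]
    earlier = ti < tj  # i fails strictly earlier than j
    admissible = earlier & (d[:, None] == 1)
    n_adm = int(admissible.sum())
    if n_adm == 0:
        raise ValueError("no admissible pairs")
    si = s[:, None]
    sj = s[None, :]
    conc = (admissible & (si > sj)).sum() + 0.5 * (admissible & (si == sj)).sum()
    return float(conc / n_adm)


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard and the induced survival function."""

    times: np.ndarray
    cumhaz: np.ndarray

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
        return out

    def survival(self, scores, t) -> np.ndarray:
        """S(t | x) = exp(-Lambda0(t) * exp(score)); shape (n_subjects, n_times)."""
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        lam = self.cumulative_hazard(t)
        return np.exp(-np.outer(np.exp(s), lam))


def breslow_baseline(scores, time, event) -> BaselineHazard:
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    ts, ss, ds = t[order], s[order], d[order]
    e = np.exp(ss - ss.max())
    # sum over risk set {j: Y_j >= y} = suffix sums in ascending order
    suffix = np.concatenate([np.cumsum(e[::-1])[::-1], [0.0]])
    ev_times = np.unique(ts[ds == 1])
    cum = []
    acc = 0.0
    for y in ev_times:
        k = np.searchsorted(ts, y, side="left")
        dk = int(((ts == y) & (ds == 1)).sum())
        acc += dk / (suffix[k] * np.exp(ss.max()))
        cum.append(acc)
    return BaselineHazard(times=ev_times, cumhaz=np.asarray(cum))


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) = P(C > t).

    Returns a function ``G(t, left=False)``; ``left=True`` gives the left
    limit G(t-). Implemented directly because left limits are needed for the
    IPCW weights.
    """
    t = np.asarray(time, dtype=float)
    c = 1 - np.asarray(event, dtype=int)  # censorings are the "events" of G
    order = np.argsort(t, kind="stable")
    ts, cs = t[order], c[order]
    uniq = np.unique(ts)
    n = len(ts)
    surv = []
    g = 1.0
    for y in uniq:
        at_risk = n - np.searchsorted(ts, y, side="left")
        d_cens = int(((ts == y) & (cs == 1)).sum())
        if at_risk > 0:
            g *= 1.0 - d_cens / at_risk
        surv.append(g)
    surv = np.asarray(surv)

    def G(t_query, left: bool = False) -> np.ndarray:
        tq = np.atleast_1d(np.asarray(t_query, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(uniq, tq, side=side) - 1
        return np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)

    return G


def brier_curve(
    surv_probs: np.ndarray, time, event, time_grid
) -> tuple[np.ndarray, np.ndarray]:
    """IPCW (Graf) Brier score at each grid time.

    ``surv_probs[i, k]`` is the predicted S(t_k | x_i). The grid is truncated
    (with a log message) where the censoring KM reaches 0.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    grid = np.asarray(time_grid, dtype=float)
    S = np.asarray(surv_probs, dtype=float)
    if S.shape != (len(t), len(grid)):
        raise ValueError("surv_probs must be (n_subjects, n_times)")
    G = _censoring_survival(t, d)
    g_at_grid = G(grid)
    ok = g_at_grid > 0
    if not ok.all():
        log.warning(
            "brier_curve: censoring KM hit 0; truncating grid %d -> %d points",
            len(grid), int(ok.sum()),
        )
        grid, S, g_at_grid = grid[ok], S[:, ok], g_at_grid[ok]
    g_at_ti = G(t, left=True)
    bs = np.empty(len(grid))
    for k, tk in enumerate(grid):
        died = (t <= tk) & (d == 1)
        alive = t > tk
        term = np.zeros(len(t))
        w_died = np.where(g_at_ti[died] > 0, 1.0 / np.maximum(g_at_ti[died], 1e-12), 0.0)
        term[died] = (S[died, k] ** 2) * w_died
        term[alive] = ((1.0 - S[alive, k]) ** 2) / g_at_grid[k]
        bs[k] = term.mean()
    return grid, bs


def brier_ibs(surv_probs: np.ndarray, time, event, time_grid=None) -> float:
    """Integrated Brier score: trapezoidal integral over the grid, normalized
    by the grid span. Default grid is all unique event times."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if time_grid is None:
        time_grid = np.unique(t[d == 1])
    grid, bs = brier_curve(surv_probs, t, d, time_grid)
    if len(grid) == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


def composite_score(cindex: float, ibs: float) -> float:
    """CS = (C-index + (1 - IBS)) / 2."""
    if not (0.0 <= cindex <= 1.0 and 0.0 <= ibs <= 1.0):
        raise ValueError("C-index and IBS must lie in [0, 1]")
    return (cindex + (1.0 - ibs)) / 2.0


def evaluate_risk_scores(scores, time, event, time_grid=None) -> dict:
    """C-index, IBS (Breslow baseline survival) and CS for a score vector."""
    c = concordance_index(scores, time, event)
    base = breslow_baseline(scores, time, event)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if time_grid is None:
        time_grid = np.unique(t[d == 1])
    S = base.survival(scores, time_grid)
    ibs = brier_ibs(S, t, d, time_grid)
    return {"cindex": c, "ibs": ibs, "cs": composite_score(c, ibs)}


def kaplan_meier(table: pd.DataFrame, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Product-limit survival curve with Greenwood confidence bands."""
    from lifelines import KaplanMeierFitter

    if len(table) < 1:
        raise ValueError("need >= 1 subject")
    kmf = KaplanMeierFitter()
    kmf.fit(table[time_col], table[event_col])
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
            "ci_low": ci.iloc[:, 0].to_numpy(float),
            "ci_high": ci.iloc[:, 1].to_numpy(float),
        }
    ).reset_index(drop=True)
    return out


def logrank(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    from lifelines.statistics import logrank_test

    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(table_a[event_col].sum() + table_b[event_col].sum()) == 0:
        raise ValueError("need >= 1 event in total")
    res = logrank_test(
        table_a[time_col], table_b[time_col],
        event_observed_A=table_a[event_col], event_observed_B=table_b[event_col],
    )
    return float(res.test_statistic), float(res.p_value)


def median_split(patient_scores: pd.Series) -> pd.Series:
    """Split patients into high/low risk at the median predicted score.

    Scores strictly above the median are "high", the rest (including ties at
    the median) "low". All-identical scores raise DegenerateSplitError.
    """
    s = patient_scores.astype(float)
    if len(s) < 2:
        raise ValueError("need >= 2 patients")
    if s.nunique() == 1:
        raise DegenerateSplitError("all scores identical; no split possible")
    med = float(s.median())
    n_ties = int((s == med).sum())
    if n_ties:
        log.info("median_split: %d scores tied at the median -> low group", n_ties)
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="risk_group")
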