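"""Censored-data feature selection.

Four methods operating on a design matrix and a right-censored outcome,
plus a passthrough arm:

* ``univariate_cox`` — one-covariate Cox fits, keep Wald p < 0.001;
* ``rfe_cox`` — recursive elimination of the smallest-|z| covariate from a
  multivariable Cox fit until 10 remain;
* ``mrmr_cindex`` — greedy minimum-redundancy / maximum-relevance where
  relevance is |C-index - 0.5| of the single feature against the censored
  outcome and redundancy is the mean absolute Pearson correlation with the
  already-selected set (difference combination rule);
* ``coxnet`` — elastic-net-penalized Cox over a regularization path, with
  the (l1_ratio, alpha) pair chosen by internal cross-validated C-index;
  nonzero coefficients are the selection.

All Cox partial-likelihood fits here use Newton–Raphson with Breslow tie
handling (month-resolution follow-up produces many ties), written out below
because it also has to expose Wald standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eval_metrics import c_index
from .preprocess import DesignMatrix

__all__ = ["SelectionConfig", "SelectionResult", "CoxConvergenceError",
           "cox_newton", "univariate_cox_select", "rfe_cox_select",
           "mrmr_cindex_select", "coxnet_select", "passthrough_select",
           "select_features"]

log = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    method: str = "coxnet"     # univariate_cox | rfe_cox | mrmr_cindex | coxnet | none
    alpha: float = 0.001       # Wald threshold for univariate_cox
    n_keep: int = 10
    l1_ratio_grid: tuple = (0.1, 0.5, 0.9)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")


@dataclass
class SelectionResult:
    """Retained feature names with a per-feature statistic.

    ``stat`` holds the method's native figure of merit for each kept column
    (Wald p, final |z|, mRMR score, or signed elastic-net coefficient);
    ``extra`` carries method-specific bookkeeping such as elimination ranks.
    """

    kept: list[str]
    stat: dict[str, float]
    method: str
    extra: dict = field(default_factory=dict)

    def to_frame(self, metadata=None) -> pd.DataFrame:
        """Tabular export: feature, statistic, actionable flag if resolvable."""
        rows = []
        meta = {m.name: m for m in (metadata or [])}
        for name in self.kept:
            src = name.split("=")[0]
            rows.append({
                "feature": name,
                "statistic": self.stat.get(name, np.nan),
                "type": (("Actionable" if meta[src].actionable else "Intrinsic")
                         if src in meta else ""),
            })
        return pd.DataFrame(rows)


class CoxConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Breslow-tie Cox partial likelihood by Newton-Raphson

def cox_newton(X, time, event, ridge=0.0, max_iter=60, tol=1e-8):
    """Fit a Cox proportional-hazards model (Breslow ties).

    Returns (beta, se, loglik).  ``ridge`` adds an L2 penalty used to
    stabilize near-singular multivariable fits.  Raises
    :class:`CoxConvergenceError` on non-convergence or a singular
    information matrix.
    """
    X = np.asarray(X, float)
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    n, p = X.shape
    if d.sum() < 1:
        raise CoxConvergenceError("no events")

    order = np.argsort(t, kind="stable")
    X, t, d = X[order], t[order], d[order]
    # tie groups: first/last index of each subject's tie group
    uniq, first_idx, inv = np.unique(t, return_index=True, return_inverse=True)
    group_first = first_idx[inv]
    last_idx = np.concatenate([first_idx[1:], [n]]) - 1
    group_last = last_idx[inv]
    ev = d == 1

    beta = np.zeros(p)
    ll_prev = -np.inf
    for it in range(max_iter):
        eta = X @ beta
        eta -= eta.max()                       # guard overflow; cancels in ratios
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]          # suffix sums
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        S0 = s0[group_first]                   # risk-set sums at each subject's time
        mu_all = s1[group_first] / S0[:, None]

        ll = _cox_loglik(X, t, d, group_first, ev, beta, ridge)
        grad = (X[ev] - mu_all[ev]).sum(axis=0) - ridge * beta
        # a_j = sum over event times <= t_j of 1/S0 (events tied with j count)
        inc = np.where(ev, 1.0 / S0, 0.0)
        a = np.cumsum(inc)[group_last]
        H = (X * (w * a)[:, None]).T @ X
        M = mu_all[ev]
        H -= M.T @ M
        H[np.diag_indices_from(H)] += ridge

        if np.abs(grad).max() < tol * max(1.0, abs(ll)):
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        if not np.all(np.isfinite(step)):
            raise CoxConvergenceError("non-finite Newton step")
        # step-halving on the penalized partial log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _cox_loglik(X, t, d, group_first, ev, cand, ridge) >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise CoxConvergenceError("step-halving failed")
        new_beta = beta + scale * step
        if np.abs(new_beta - beta).max() < 1e-10:
            beta = new_beta
            break
        beta = new_beta
        ll_prev = ll
    else:
        raise CoxConvergenceError(f"no convergence in {max_iter} iterations")

    # final information matrix for Wald standard errors
    eta = X @ beta
    w = np.exp(eta - eta.max())
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S0 = s0[group_first]
    mu_all = s1[group_first] / S0[:, None]
    inc = np.where(ev, 1.0 / S0, 0.0)
    a = np.cumsum(inc)[group_last]
    H = (X * (w * a)[:, None]).T @ X - mu_all[ev].T @ mu_all[ev]
    H[np.diag_indices_from(H)] += ridge
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if (se == 0).any():
        raise CoxConvergenceError("zero-variance covariate")
    ll = _cox_loglik(X, t, d, group_first, ev, beta, ridge)
    return beta, se, ll


def _cox_loglik(X, t, d, group_first, ev, beta, ridge):
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    S0 = s0[group_first]
    return (float(eta[ev].sum()) - float((np.log(S0[ev]) + shift).sum())
            - 0.5 * ridge * float(beta @ beta))


# ---------------------------------------------------------------------------
# the four selectors + passthrough

def _as_xy(dm, time, event):
    X = dm.X if isinstance(dm, DesignMatrix) else np.asarray(dm, float)
    cols = dm.columns if isinstance(dm, DesignMatrix) else [f"x{i}" for i in range(X.shape[1])]
    return X, list(cols), np.asarray(time, float), np.asarray(event, int)


def univariate_cox_select(dm, time, event, alpha=0.001) -> SelectionResult:
    """Keep columns whose single-covariate Cox Wald p-value is below alpha."""
    X, cols, t, d = _as_xy(dm, time, event)
    if d.sum() < 2:
        raise ValueError("need at least 2 events")
    kept, stat, dropped = [], {}, []
    for j, name in enumerate(cols):
        try:
            beta, se, _ = cox_newton(X[:, [j]], t, d)
        except CoxConvergenceError as exc:
            log.warning("univariate Cox: %s dropped (%s)", name, exc)
            dropped.append(name)
            continue
        z = beta[0] / se[0]
        pval = float(2.0 * stats.norm.sf(abs(z)))
        if pval < alpha:
            kept.append(name)
            stat[name] = pval
    return SelectionResult(kept, stat, "univariate_cox",
                           extra={"dropped_nonconvergent": dropped})


def rfe_cox_select(dm, time, event, n_keep=10) -> SelectionResult:
    """Recursive feature elimination on multivariable Cox Wald |z|.

    Repeatedly fits the joint model and removes the covariate with the
    smallest |coef| / se until ``n_keep`` remain.  Singular fits are retried
    with a small L2 stabilizer.  Elimination order is recorded (1 = first
    removed).
    """
    X, cols, t, d = _as_xy(dm, time, event)
    if n_keep > len(cols):
        raise ValueError("n_keep exceeds number of features")
    if d.sum() < 2:
        raise ValueError("need at least 2 events")
    current = list(range(len(cols)))
    eliminated: dict[str, int] = {}
    rank = 0
    zfinal = {}
    while True:
        idx = np.array(current)
        try:
            beta, se, _ = cox_newton(X[:, idx], t, d)
        except CoxConvergenceError:
            log.warning("RFE: singular fit with %d features; ridge-stabilized refit",
                        len(current))
            beta, se, _ = cox_newton(X[:, idx], t, d, ridge=1e-6 * d.sum())
        z = np.abs(beta / se)
        if len(current) <= n_keep:
            zfinal = {cols[i]: float(zv) for i, zv in zip(current, z)}
            break
        j = int(np.argmin(z))            # ties: first (column order)
        rank += 1
        eliminated[cols[current[j]]] = rank
        del current[j]
    kept = [cols[i] for i in current]
    return SelectionResult(kept, zfinal, "rfe_cox", extra={"eliminated": eliminated})


def mrmr_cindex_select(dm, time, event, n_keep=10) -> SelectionResult:
    """Greedy mRMR with concordance-based relevance.

    relevance(f) = |C(f) - 0.5| where C(f) ranks subjects by the feature
    value alone against the censored outcome, so protective and deleterious
    features score symmetrically; redundancy(f, S) = mean |Pearson r| with
    the selected set; greedy argmax of relevance - redundancy (difference
    rule).  Constant features have relevance 0.  Ties break by column order.
    """
    X, cols, t, d = _as_xy(dm, time, event)
    if n_keep > len(cols):
        raise ValueError("n_keep exceeds number of features")
    p = X.shape[1]
    relevance = np.zeros(p)
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            continue
        relevance[j] = abs(c_index(X[:, j], t, d) - 0.5)
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    corr_cache = {}
    selected: list[int] = [int(np.argmax(relevance))]
    score = {cols[selected[0]]: float(relevance[selected[0]])}
    while len(selected) < n_keep:
        best_j, best_val = None, -np.inf
        sel_set = set(selected)
        for j in range(p):
            if j in sel_set:
                continue
            red = np.mean([abs(_pearson(Xc, j, s, corr_cache, sd)) for s in selected])
            val = relevance[j] - red
            if val > best_val + 1e-15:
                best_val, best_j = val, j
        selected.append(best_j)
        score[cols[best_j]] = float(best_val)
    kept = [cols[j] for j in selected]
    return SelectionResult(kept, score, "mrmr_cindex")


def _pearson(Xc, i, j, cache, sd):
    key = (min(i, j), max(i, j))
    if key not in cache:
        if sd[i] == 0 or sd[j] == 0:
            cache[key] = 0.0
        else:
            cache[key] = float(Xc[:, i] @ Xc[:, j] / len(Xc))
    return cache[key]


def coxnet_select(dm, time, event, l1_ratio_grid=(0.1, 0.5, 0.9), cv_folds=5,
                  seed=0, n_alphas=50) -> SelectionResult:
    """Elastic-net Cox selection with internal-CV choice of (l1_ratio, λ).

    For each mix in ``l1_ratio_grid`` a regularization path is fitted on the
    full fitting set; each (mix, λ) point is then scored by the mean
    concordance of its linear risk score over ``cv_folds`` internal folds,
    and the maximizer is refitted on all data.  Columns with nonzero
    coefficients at that point are kept, reported with their signed
    coefficients sorted by decreasing magnitude.
    """
    from sklearn.model_selection import StratifiedKFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X, cols, t, d = _as_xy(dm, time, event)
    if d.sum() < cv_folds:
        raise ValueError(f"need at least {cv_folds} events for {cv_folds}-fold CV")
    y = Surv.from_arrays(event=d.astype(bool), time=t)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best = None    # (mean_ci, ratio, alpha_index); ties keep the first entry
    paths = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ratio in l1_ratio_grid:
            path = CoxnetSurvivalAnalysis(l1_ratio=ratio, n_alphas=n_alphas,
                                          alpha_min_ratio=0.01)
            try:
                path.fit(X, y)
            except Exception as exc:
                log.warning("coxnet path failed for l1_ratio=%s: %s", ratio, exc)
                continue
            paths[ratio] = path
            alphas = path.alphas_
            scores = np.zeros((cv_folds, len(alphas)))
            valid = np.ones(len(alphas), bool)
            for fi, (tr, va) in enumerate(skf.split(X, d)):
                m = CoxnetSurvivalAnalysis(l1_ratio=ratio, alphas=alphas)
                try:
                    m.fit(X[tr], y[tr])
                except Exception:
                    valid[:] = False
                    break
                for ai, a in enumerate(alphas):
                    try:
                        risk = m.predict(X[va], alpha=a)
                        # higher risk should mean earlier onset
                        scores[fi, ai] = c_index(-risk, t[va], d[va])
                    except Exception:
                        valid[ai] = False
            mean_ci = scores.mean(axis=0)
            for ai, a in enumerate(alphas):
                if not valid[ai]:
                    continue
                key = mean_ci[ai]
                if best is None or key > best[0] + 1e-12:
                    best = (key, ratio, ai, float(a))
        if best is None:
            raise RuntimeError("all elastic-net fits failed")
        _, ratio, ai, alpha = best
    # coefficients at the chosen point come from the warm-started path fit
    # on the full fitting set (a cold single-alpha refit can diverge)
    coefs = paths[ratio].coef_[:, ai]
    nz = np.nonzero(coefs)[0]
    order = nz[np.argsort(-np.abs(coefs[nz]), kind="stable")]
    kept = [cols[j] for j in order]
    if not kept:
        log.warning("coxnet selection: all coefficients zero at the CV optimum")
    stat = {cols[j]: float(coefs[j]) for j in order}
    return SelectionResult(kept, stat, "coxnet",
                           extra={"l1_ratio": ratio, "alpha": alpha,
                                  "cv_c_index": float(best[0])})


def passthrough_select(dm, time, event) -> SelectionResult:
    """No selection: every column kept."""
    _, cols, _, _ = _as_xy(dm, time, event)
    return SelectionResult(list(cols), {c: np.nan for c in cols}, "none")


def select_features(dm, time, event, config: SelectionConfig) -> SelectionResult:
    """Dispatch on ``config.method``."""
    if config.method == "univariate_cox":
        return univariate_cox_select(dm, time, event, alpha=config.alpha)
    if config.method == "rfe_cox":
        return rfe_cox_select(dm, time, event, n_keep=config.n_keep)
    if config.method == "mrmr_cindex":
        return mrmr_cindex_select(dm, time, event, n_keep=config.n_keep)
    if config.method == "coxnet":
        return coxnet_select(dm, time, event, l1_ratio_grid=config.l1_ratio_grid,
                             cv_folds=config.cv_folds, seed=config.seed)
    if config.method == "none":
        return passthrough_select(dm, time, event)
    raise ValueError(f"unknown selection method {config.method!r}")
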