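"""Item response theory engine: Rasch and 2PL marginal maximum likelihood.

Models
------
The probability that person ``p`` with latent ability ``theta`` solves item
``j`` is a logistic function of ability and item difficulty ``b_j``:

    Rasch:  P = logistic(theta - b_j)
    2PL:    P = logistic(a_j * (theta - b_j))

Abilities are nuisance parameters integrated out against a normal latent
prior (marginal maximum likelihood) via an EM algorithm over a fixed
equally spaced quadrature grid.  Identification follows the conventional
practice: the Rasch fit fixes the common discrimination at 1 and estimates
the latent SD; the 2PL fit fixes the latent prior to standard normal and
frees per-item discriminations.  The two are nested (Rasch with latent SD
``s`` equals a 2PL with all discriminations equal to ``s``), so the
likelihood-ratio test between them has ``J - 1`` degrees of freedom for
``J`` items.

Missing responses (e.g. omission errors) are excluded from the likelihood
person-wise item-wise, never imputed or scored incorrect.

Ability estimates are expected a posteriori (EAP) means with posterior SDs
reported as standard errors; empirical marginal reliability is
``var(theta_hat) / (var(theta_hat) + mean(SE^2))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

__all__ = [
    "ResponseMatrix",
    "FitResult",
    "AbilityEstimate",
    "LRTestResult",
    "DIFResult",
    "rasch_icc",
    "fit_rasch",
    "fit_2pl",
    "lr_test",
    "eap_abilities",
    "empirical_reliability",
    "test_information",
    "item_fit",
    "empirical_icc",
    "dif_test",
]

DEFAULT_N_QUAD = 61
DEFAULT_QUAD_RANGE = 6.0
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 500
DEFAULT_A_BOUNDS = (0.05, 5.0)


# ---------------------------------------------------------------------------
# data container


@dataclass
class ResponseMatrix:
    """Persons x items correctness in {0, 1, missing} with optional RTs/groups.

    ``correct`` is a float array with ``nan`` marking missing (omitted)
    responses; missing entries are excluded from likelihoods.
    """

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    correct: np.ndarray
    rt_ms: np.ndarray | None = None
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.correct = np.asarray(self.correct, dtype=float)
        if self.correct.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("correct must be (n_persons, n_items)")
        finite = self.correct[np.isfinite(self.correct)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("correctness entries must be 0, 1, or missing")
        if self.rt_ms is not None:
            self.rt_ms = np.asarray(self.rt_ms, dtype=float)
            if self.rt_ms.shape != self.correct.shape:
                raise ValueError("rt_ms must match correct in shape")
        for name, labels in self.groups.items():
            if len(labels) != len(self.person_ids):
                raise ValueError(f"group column {name!r} must have one label per person")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def scored_mask(self) -> np.ndarray:
        return np.isfinite(self.correct)

    def mean_accuracy(self) -> np.ndarray:
        """Per-item observed proportion correct over scored responses."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.correct, axis=0)

    def with_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            self.person_ids,
            tuple(item_ids),
            self.correct[:, idx],
            None if self.rt_ms is None else self.rt_ms[:, idx],
            dict(self.groups),
        )

    def with_omissions_excluded(self, rt_cutoff_ms: float = 4000.0) -> "ResponseMatrix":
        """Mark responses with RT >= cutoff (inclusive) as missing."""
        if self.rt_ms is None:
            return self
        correct = self.correct.copy()
        correct[self.rt_ms >= rt_cutoff_ms] = np.nan
        return ResponseMatrix(self.person_ids, self.item_ids, correct, self.rt_ms, dict(self.groups))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_wide(cls, df: pd.DataFrame, group_cols: tuple[str, ...] = ()) -> "ResponseMatrix":
        """Wide layout: one row per person, one column per item (+ group cols)."""
        df = df.set_index(df.columns[0]) if df.columns[0].lower() in ("person", "person_id") else df
        groups = {c: df[c].to_numpy(dtype=str) for c in group_cols}
        items = [c for c in df.columns if c not in group_cols]
        return cls(
            tuple(str(i) for i in df.index),
            tuple(items),
            df[items].to_numpy(dtype=float),
            groups=groups,
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, group_cols: tuple[str, ...] = ()) -> "ResponseMatrix":
        """Long layout: columns person_id, item_id, correct, optional rt_ms."""
        persons = tuple(pd.unique(df["person_id"].astype(str)))
        items = tuple(pd.unique(df["item_id"].astype(str)))
        p_idx = {p: i for i, p in enumerate(persons)}
        i_idx = {i: j for j, i in enumerate(items)}
        correct = np.full((len(persons), len(items)), np.nan)
        rt = np.full_like(correct, np.nan) if "rt_ms" in df.columns else None
        for row in df.itertuples(index=False):
            pi, ij = p_idx[str(row.person_id)], i_idx[str(row.item_id)]
            correct[pi, ij] = row.correct
            if rt is not None:
                rt[pi, ij] = row.rt_ms
        groups = {}
        for c in group_cols:
            per_person = df.groupby(df["person_id"].astype(str))[c].first()
            groups[c] = per_person.loc[list(persons)].to_numpy(dtype=str)
        return cls(persons, items, correct, rt, groups)

    def to_long(self) -> pd.DataFrame:
        rows = []
        mask = self.scored_mask()
        for p in range(self.n_persons):
            for j in range(self.n_items):
                if mask[p, j] or (self.rt_ms is not None and np.isfinite(self.rt_ms[p, j])):
                    row = {
                        "person_id": self.person_ids[p],
                        "item_id": self.item_ids[j],
                        "correct": self.correct[p, j],
                    }
                    if self.rt_ms is not None:
                        row["rt_ms"] = self.rt_ms[p, j]
                    for name, labels in self.groups.items():
                        row[name] = labels[p]
                    rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """One fitted IRT model with parameters, uncertainty, and fit indices."""

    model: str  # "rasch" | "2pl"
    item_ids: tuple[str, ...]
    difficulty: np.ndarray
    discrimination: np.ndarray
    latent_mean: np.ndarray  # per group; single 0.0 for one group
    latent_sd: float
    loglik: float
    n_free_params: int
    n_persons: int
    converged: bool
    n_iter: int
    se_difficulty: np.ndarray | None = None
    se_discrimination: np.ndarray | None = None
    se_latent_sd: float | None = None
    inestimable_items: tuple[str, ...] = ()
    quad_nodes: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_free_params * np.log(self.n_persons)

    def item_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "difficulty": self.difficulty,
                "discrimination": self.discrimination,
                "se_difficulty": self.se_difficulty
                if self.se_difficulty is not None
                else np.nan,
            }
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "item_ids": list(self.item_ids),
            "difficulty": np.asarray(self.difficulty).tolist(),
            "discrimination": np.asarray(self.discrimination).tolist(),
            "latent_mean": np.asarray(self.latent_mean).tolist(),
            "latent_sd": self.latent_sd,
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "aic": self.aic,
            "bic": self.bic,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "inestimable_items": list(self.inestimable_items),
        }


@dataclass
class AbilityEstimate:
    person_ids: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"person_id": self.person_ids, "theta": self.theta, "se": self.se})


@dataclass
class LRTestResult:
    chi2: float
    df: int
    p: float


@dataclass
class DIFResult:
    grouping: str
    chi2: float
    df: int
    p: float
    item_table: pd.DataFrame  # item_id, delta_b, se, z, p, flagged


# ---------------------------------------------------------------------------
# response function


def rasch_icc(theta, b, a=1.0):
    """Item characteristic curve: ``logistic(a * (theta - b))``.

    With ``a = 1`` this is the Rasch curve; a person whose ability equals
    the item difficulty has probability exactly 0.5 of solving the item.
    """
    theta, b, a = np.asarray(theta, float), np.asarray(b, float), np.asarray(a, float)
    out = expit(a * (theta - b))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# EM machinery


def _quad_grid(n_quad: int, quad_range: float) -> np.ndarray:
    return np.linspace(-quad_range, quad_range, n_quad)


def _prior_log_weights(nodes: np.ndarray, mu: float, sd: float) -> np.ndarray:
    logw = stats.norm.logpdf(nodes, loc=mu, scale=sd)
    return logw - logsumexp(logw)


def _item_logP(a: np.ndarray, b: np.ndarray, nodes: np.ndarray):
    z = a[:, None] * (nodes[None, :] - b[:, None])
    # log expit computed stably
    logP = -np.logaddexp(0.0, -z)
    log1mP = -np.logaddexp(0.0, z)
    return logP, log1mP


def _person_node_loglik(X01, M, logP, log1mP):
    return (X01 * M) @ logP + ((1.0 - X01) * M) @ log1mP


def _newton_item(r, n, nodes, a, b, a_free, a_bounds):
    """Maximize sum_k r log P + (n - r) log(1-P) over (a, b) for one item.

    Parameterized as ``logit = a * theta + c`` (a plain weighted logistic
    regression), with ``b = -c / a`` recovered at the end.  Safeguarded
    Newton with step halving.
    """
    c = -a * b

    def q(a_, c_):
        z = a_ * nodes + c_
        return float(r @ (-np.logaddexp(0.0, -z)) + (n - r) @ (-np.logaddexp(0.0, z)))

    q_cur = q(a, c)
    for _ in range(50):
        P = expit(a * nodes + c)
        resid = r - n * P
        w = n * P * (1.0 - P)
        if a_free:
            g = np.array([resid @ nodes, resid.sum()])
            H = np.array(
                [[w @ (nodes**2), w @ nodes], [w @ nodes, w.sum()]]
            )
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(2), g)
            except np.linalg.LinAlgError:
                break
        else:
            g = np.array([resid.sum()])
            step = g / max(w.sum(), 1e-12)
        if np.max(np.abs(step)) < 1e-10:
            break
        scale = 1.0
        for _ in range(30):
            if a_free:
                a_new = float(np.clip(a + scale * step[0], *a_bounds))
                c_new = c + scale * step[1]
            else:
                a_new, c_new = a, c + scale * step[0]
            q_new = q(a_new, c_new)
            if q_new >= q_cur - 1e-12:
                break
            scale *= 0.5
        a, c, q_cur = a_new, c_new, q_new
    return a, -c / a


def _marginal_loglik(X01, M, group_idx, a, b_by_group, mus, sd, nodes):
    """Exact marginal log-likelihood on the quadrature grid."""
    total = 0.0
    for g in range(len(mus)):
        sel = group_idx == g
        if not np.any(sel):
            continue
        logw = _prior_log_weights(nodes, mus[g], sd)
        logP, log1mP = _item_logP(a, b_by_group[g], nodes)
        L = _person_node_loglik(X01[sel], M[sel], logP, log1mP)
        total += float(logsumexp(L + logw[None, :], axis=1).sum())
    return total


def _em(
    X: np.ndarray,
    a_free: bool,
    sigma_free: bool,
    group_idx: np.ndarray | None = None,
    group_b: bool = False,
    free_group_means: bool = False,
    n_quad: int = DEFAULT_N_QUAD,
    quad_range: float = DEFAULT_QUAD_RANGE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    a_bounds: tuple[float, float] = DEFAULT_A_BOUNDS,
):
    """Core EM loop shared by all model variants.

    Groups: persons carry group indices; difficulties may be group-specific
    (``group_b``) and non-reference group means may be freed.  The marginal
    log-likelihood is checked to be non-decreasing every iteration.
    """
    N, J = X.shape
    M = np.isfinite(X)
    X01 = np.nan_to_num(X, nan=0.0)
    nodes = _quad_grid(n_quad, quad_range)
    if group_idx is None:
        group_idx = np.zeros(N, dtype=int)
    G = int(group_idx.max()) + 1

    # starting values: logit of observed accuracy, latent standard normal
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(X01.sum(0) / np.maximum(M.sum(0), 1), 0.02, 0.98)
    b0 = -np.log(p / (1 - p))
    b = np.tile(b0, (G, 1)) if group_b else b0[None, :].repeat(1, axis=0)
    if not group_b:
        b = b0.copy()[None, :]  # stored (1, J), broadcast per group
    a = np.ones(J)
    sd = 1.0
    mus = np.zeros(G)

    def b_of(g):
        return b[g] if group_b else b[0]

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b_groups = [b_of(g) for g in range(G)]
        ll = _marginal_loglik(X01, M, group_idx, a, b_groups, mus, sd, nodes)
        if ll < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        ll_prev = ll

        # E-step: posterior node weights and expected counts per group
        T = np.zeros((G, n_quad))  # posterior mass per group/node
        n_exp = np.zeros((G, J, n_quad)) if group_b else np.zeros((1, J, n_quad))
        r_exp = np.zeros_like(n_exp)
        for g in range(G):
            sel = group_idx == g
            if not np.any(sel):
                continue
            logw = _prior_log_weights(nodes, mus[g], sd)
            logP, log1mP = _item_logP(a, b_of(g), nodes)
            L = _person_node_loglik(X01[sel], M[sel], logP, log1mP) + logw[None, :]
            post = np.exp(L - logsumexp(L, axis=1, keepdims=True))
            T[g] = post.sum(0)
            gi = g if group_b else 0
            n_exp[gi] += M[sel].T @ post
            r_exp[gi] += (X01[sel] * M[sel]).T @ post

        # M-step: item parameters (independent weighted logistic fits)
        params_old = np.concatenate([b.ravel(), a, [sd], mus])
        for gi in range(n_exp.shape[0]):
            for j in range(J):
                if n_exp[gi, j].sum() <= 0:
                    continue
                a_j, b_j = _newton_item(
                    r_exp[gi, j], n_exp[gi, j], nodes, a[j], b[gi, j], a_free, a_bounds
                )
                b[gi, j] = b_j
                if a_free:
                    a[j] = a_j

        # M-step: latent distribution (maximizes the discretized prior term)
        if sigma_free or free_group_means:
            free_mu_idx = list(range(1, G)) if free_group_means else []

            def neg_q(v):
                sd_ = float(np.exp(v[0])) if sigma_free else sd
                mus_ = mus.copy()
                for i, g in enumerate(free_mu_idx):
                    mus_[g] = v[(1 if sigma_free else 0) + i]
                total = 0.0
                for g in range(G):
                    total += float(T[g] @ _prior_log_weights(nodes, mus_[g], sd_))
                return -total

            x0 = ([np.log(sd)] if sigma_free else []) + [mus[g] for g in free_mu_idx]
            if x0:
                res = optimize.minimize(neg_q, np.array(x0), method="Nelder-Mead",
                                        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400})
                v = res.x
                if sigma_free:
                    sd = float(np.exp(v[0]))
                for i, g in enumerate(free_mu_idx):
                    mus[g] = v[(1 if sigma_free else 0) + i]

        params_new = np.concatenate([b.ravel(), a, [sd], mus])
        if np.max(np.abs(params_new - params_old)) < tol:
            converged = True
            break

    b_groups = [b_of(g) for g in range(G)]
    ll = _marginal_loglik(X01, M, group_idx, a, b_groups, mus, sd, nodes)
    return {
        "b": b if group_b else b[0],
        "a": a,
        "sd": sd,
        "mus": mus,
        "loglik": ll,
        "n_iter": it,
        "converged": converged,
        "nodes": nodes,
        "group_b": group_b,
    }


def _screen_items(responses: ResponseMatrix):
    """Flag items without both a correct and an incorrect scored response."""
    M = responses.scored_mask()
    X01 = np.nan_to_num(responses.correct, nan=0.0)
    n_scored = M.sum(0)
    n_correct = (X01 * M).sum(0)
    bad = (n_correct == 0) | (n_correct == n_scored) | (n_scored == 0)
    return [responses.item_ids[j] for j in np.where(bad)[0]]


def _numeric_hessian(f, x0, rel_step=1e-4):
    x0 = np.asarray(x0, float)
    h = rel_step * (1.0 + np.abs(x0))
    d = len(x0)
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _fit(
    responses: ResponseMatrix,
    model: str,
    n_quad: int,
    quad_range: float,
    tol: float,
    max_iter: int,
    a_bounds,
    compute_se: bool,
) -> FitResult:
    if responses.n_items < 2 or responses.n_persons < 2:
        raise ValueError("need at least 2 items and 2 persons")
    bad = _screen_items(responses)
    keep = [i for i in responses.item_ids if i not in bad]
    if bad:
        warnings.warn(
            f"{len(bad)} item(s) inestimable (no response variation): {bad}",
            stacklevel=3,
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 estimable items")
    sub = responses.with_items(keep)

    a_free = model == "2pl"
    res = _em(
        sub.correct,
        a_free=a_free,
        sigma_free=not a_free,
        n_quad=n_quad,
        quad_range=quad_range,
        tol=tol,
        max_iter=max_iter,
        a_bounds=a_bounds,
    )
    if not res["converged"]:
        warnings.warn(
            f"{model} EM did not converge in {max_iter} iterations; results provisional",
            stacklevel=3,
        )

    J = len(keep)
    n_free = 2 * J if a_free else J + 1

    se_b = se_a = None
    se_sd = None
    if compute_se:
        X01 = np.nan_to_num(sub.correct, nan=0.0)
        M = sub.scored_mask()
        gidx = np.zeros(sub.n_persons, dtype=int)
        nodes = res["nodes"]

        if a_free:
            def negll(v):
                return -_marginal_loglik(
                    X01, M, gidx, v[:J], [v[J:]], np.zeros(1), 1.0, nodes
                )
            x0 = np.concatenate([res["a"], res["b"]])
        else:
            def negll(v):
                return -_marginal_loglik(
                    X01, M, gidx, np.ones(J), [v[:J]], np.zeros(1), np.exp(v[J]), nodes
                )
            x0 = np.concatenate([res["b"], [np.log(res["sd"])]])
        H = _numeric_hessian(negll, x0)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError
            se = np.sqrt(diag)
            if a_free:
                se_a, se_b = se[:J], se[J:]
            else:
                se_b = se[:J]
                se_sd = float(se[J] * res["sd"])  # delta method from log sd
        except np.linalg.LinAlgError:
            warnings.warn("observed information not invertible; SEs unavailable", stacklevel=3)

    # expand to the full item list with NaN for inestimable items
    def expand(vec, fill=np.nan):
        if vec is None:
            return None
        out = np.full(responses.n_items, fill)
        for k, item in enumerate(keep):
            out[responses.item_ids.index(item)] = vec[k]
        return out

    return FitResult(
        model=model,
        item_ids=responses.item_ids,
        difficulty=expand(res["b"]),
        discrimination=expand(res["a"] if a_free else np.full(J, 1.0)),
        latent_mean=np.zeros(1),
        latent_sd=res["sd"],
        loglik=res["loglik"],
        n_free_params=n_free,
        n_persons=responses.n_persons,
        converged=res["converged"],
        n_iter=res["n_iter"],
        se_difficulty=expand(se_b),
        se_discrimination=expand(se_a),
        se_latent_sd=se_sd,
        inestimable_items=tuple(bad),
        quad_nodes=res["nodes"],
    )


def fit_rasch(
    responses: ResponseMatrix,
    n_quad: int = DEFAULT_N_QUAD,
    quad_range: float = DEFAULT_QUAD_RANGE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    compute_se: bool = True,
) -> FitResult:
    """Marginal ML Rasch fit (common discrimination 1, latent SD estimated).

    Deterministic: starting values come from observed accuracies, no random
    initialization.  Items answered all-correct or all-incorrect are flagged
    inestimable and excluded with a warning.
    """
    return _fit(responses, "rasch", n_quad, quad_range, tol, max_iter, DEFAULT_A_BOUNDS, compute_se)


def fit_2pl(
    responses: ResponseMatrix,
    n_quad: int = DEFAULT_N_QUAD,
    quad_range: float = DEFAULT_QUAD_RANGE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    a_bounds: tuple[float, float] = DEFAULT_A_BOUNDS,
    compute_se: bool = True,
) -> FitResult:
    """Marginal ML 2PL fit (standard-normal latent prior, free discriminations).

    Discriminations are constrained to ``a_bounds`` to prevent divergence on
    quasi-separated items.
    """
    return _fit(responses, "2pl", n_quad, quad_range, tol, max_iter, a_bounds, compute_se)


def lr_test(fit_nested: FitResult, fit_full: FitResult, tol: float = 1e-6) -> LRTestResult:
    """Likelihood-ratio test of two nested fits on the same data."""
    if fit_full.n_free_params <= fit_nested.n_free_params:
        raise ValueError("full model must have more free parameters than nested")
    if fit_nested.n_persons != fit_full.n_persons:
        raise ValueError("fits must be on the same data")
    chi2 = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if chi2 < -tol * (1.0 + abs(fit_full.loglik)):
        raise ValueError(
            f"full-model log-likelihood {fit_full.loglik} below nested {fit_nested.loglik}"
        )
    chi2 = max(chi2, 0.0)
    df = fit_full.n_free_params - fit_nested.n_free_params
    return LRTestResult(chi2, df, float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# abilities, reliability, information


def _posterior(fit: FitResult, responses: ResponseMatrix):
    keep = [j for j, i in enumerate(fit.item_ids) if np.isfinite(fit.difficulty[j])]
    a = fit.discrimination[keep]
    b = fit.difficulty[keep]
    nodes = fit.quad_nodes if fit.quad_nodes is not None else _quad_grid(DEFAULT_N_QUAD, DEFAULT_QUAD_RANGE)
    logw = _prior_log_weights(nodes, float(fit.latent_mean[0]), fit.latent_sd)
    X = responses.correct[:, keep]
    M = np.isfinite(X)
    X01 = np.nan_to_num(X, nan=0.0)
    logP, log1mP = _item_logP(a, b, nodes)
    L = _person_node_loglik(X01, M, logP, log1mP) + logw[None, :]
    post = np.exp(L - logsumexp(L, axis=1, keepdims=True))
    return nodes, post


def eap_abilities(fit: FitResult, responses: ResponseMatrix) -> AbilityEstimate:
    """Expected a posteriori abilities with posterior SDs as standard errors.

    Persons with no scored responses fall back to the prior mean and SD.
    """
    nodes, post = _posterior(fit, responses)
    theta = post @ nodes
    second = post @ (nodes**2)
    se = np.sqrt(np.maximum(second - theta**2, 0.0))
    return AbilityEstimate(responses.person_ids, theta, se)


def empirical_reliability(abilities: AbilityEstimate) -> float:
    """Empirical marginal reliability: var(theta_hat) / (var + mean SE^2).

    True-score variance is estimated by the variance of the EAP estimates,
    error variance by the mean squared posterior SD.
    """
    if len(abilities.theta) < 2:
        raise ValueError("need >= 2 persons")
    v = float(np.var(abilities.theta, ddof=1))
    err = float(np.mean(abilities.se**2))
    if v + err <= 0:
        raise ValueError("total variance is zero; reliability undefined")
    if v == 0:
        raise ValueError("no true-score variance; reliability undefined")
    return v / (v + err)


def test_information(fit: FitResult, theta=None):
    """Test information curve I(theta) = sum_j a_j^2 P(1-P) and SE = 1/sqrt(I)."""
    if theta is None:
        theta = np.linspace(-4.0, 4.0, 161)
    theta = np.asarray(theta, float)
    keep = np.isfinite(fit.difficulty)
    a = fit.discrimination[keep]
    b = fit.difficulty[keep]
    P = expit(a[:, None] * (theta[None, :] - b[:, None]))
    info = (a[:, None] ** 2 * P * (1 - P)).sum(0)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(info)
    return theta, info, se


# ---------------------------------------------------------------------------
# item fit and empirical ICCs


def _ability_bins(theta, mask_counts, n_bins, min_per_bin):
    """Equal-count ability bin edges; merging is handled by the caller."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(theta, qs)
    edges[0], edges[-1] = -np.inf, np.inf
    return np.unique(edges)


def item_fit(
    fit: FitResult,
    responses: ResponseMatrix,
    n_bins: int = 6,
    min_per_bin: int = 5,
    bounds: tuple[float, float] = (0.7, 1.3),
    abilities: AbilityEstimate | None = None,
) -> pd.DataFrame:
    """Per-item infit/outfit mean squares and a binned observed-expected chi2.

    Residuals are taken against EAP abilities.  Infit is the
    information-weighted mean square, outfit the unweighted mean square of
    standardized residuals; items outside ``bounds`` on either are flagged.
    The chi-square bins persons by ability (equal-count bins, merged below
    ``min_per_bin``) and compares observed to model-implied proportions.
    """
    if abilities is None:
        abilities = eap_abilities(fit, responses)
    theta = abilities.theta
    rows = []
    for j, item in enumerate(fit.item_ids):
        if not np.isfinite(fit.difficulty[j]):
            rows.append({"item_id": item, "infit": np.nan, "outfit": np.nan,
                         "chi2": np.nan, "chi2_df": 0, "chi2_p": np.nan, "flagged": True})
            continue
        m = np.isfinite(responses.correct[:, j])
        x = responses.correct[m, j]
        th = theta[m]
        E = rasch_icc(th, fit.difficulty[j], fit.discrimination[j])
        W = np.clip(E * (1 - E), 1e-9, None)
        z2 = (x - E) ** 2 / W
        outfit = float(np.mean(z2))
        infit = float(np.sum((x - E) ** 2) / np.sum(W))

        # binned chi-square
        edges = _ability_bins(th, None, n_bins, min_per_bin)
        idx = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, len(edges) - 2)
        chi2 = 0.0
        used = 0
        # merge sparse bins left-to-right
        obs_list, exp_list, cnt_list = [], [], []
        for bcode in range(len(edges) - 1):
            sel = idx == bcode
            if not np.any(sel):
                continue
            obs_list.append(float(x[sel].sum()))
            exp_list.append(float(E[sel].sum()))
            cnt_list.append(int(sel.sum()))
        merged = []
        acc = [0.0, 0.0, 0]
        for o, e, c in zip(obs_list, exp_list, cnt_list):
            acc = [acc[0] + o, acc[1] + e, acc[2] + c]
            if acc[2] >= min_per_bin:
                merged.append(acc)
                acc = [0.0, 0.0, 0]
        if acc[2] > 0:
            if merged:
                merged[-1] = [merged[-1][0] + acc[0], merged[-1][1] + acc[1], merged[-1][2] + acc[2]]
            else:
                merged.append(acc)
        for o, e, c in merged:
            p_exp = np.clip(e / c, 1e-9, 1 - 1e-9)
            chi2 += (o - e) ** 2 / (c * p_exp * (1 - p_exp))
            used += 1
        df = max(used - 1, 1)
        flagged = not (bounds[0] <= infit <= bounds[1]) or not (bounds[0] <= outfit <= bounds[1])
        rows.append(
            {
                "item_id": item,
                "infit": infit,
                "outfit": outfit,
                "chi2": chi2,
                "chi2_df": df,
                "chi2_p": float(stats.chi2.sf(chi2, df)),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def empirical_icc(
    responses: ResponseMatrix,
    abilities: AbilityEstimate,
    n_bins: int = 6,
    min_per_bin: int = 5,
    fit: FitResult | None = None,
) -> pd.DataFrame:
    """Observed proportion correct per ability bin for every item.

    Returns one row per (item, bin) with bin midpoints, counts, observed
    proportions, and (when a fit is given) the model-implied probability at
    the bin's mean ability — the plotting data for empirical ICC inspection.
    """
    theta = abilities.theta
    rows = []
    for j, item in enumerate(responses.item_ids):
        m = np.isfinite(responses.correct[:, j])
        x = responses.correct[m, j]
        th = theta[m]
        if th.size == 0:
            continue
        edges = _ability_bins(th, None, n_bins, min_per_bin)
        idx = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, len(edges) - 2)
        bins = []
        for bcode in range(len(edges) - 1):
            sel = idx == bcode
            if np.any(sel):
                bins.append([float(th[sel].mean() * sel.sum()), float(x[sel].sum()), int(sel.sum())])
        merged: list[list[float]] = []
        acc = [0.0, 0.0, 0]
        for t_sum, o, c in bins:
            acc = [acc[0] + t_sum, acc[1] + o, acc[2] + c]
            if acc[2] >= min_per_bin:
                merged.append(acc)
                acc = [0.0, 0.0, 0]
        if acc[2] > 0:
            if merged:
                merged[-1] = [merged[-1][0] + acc[0], merged[-1][1] + acc[1], merged[-1][2] + acc[2]]
            else:
                merged.append(acc)
        for t_sum, o, c in merged:
            mean_theta = t_sum / c
            row = {
                "item_id": item,
                "bin_mean_theta": mean_theta,
                "n": c,
                "observed": o / c,
            }
            if fit is not None and np.isfinite(fit.difficulty[j]):
                row["expected"] = float(
                    rasch_icc(mean_theta, fit.difficulty[j], fit.discrimination[j])
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential item functioning


def dif_test(
    responses: ResponseMatrix,
    grouping: str,
    min_group_size: int = 20,
    alpha: float = 0.05,
    per_item: bool = True,
    n_quad: int = DEFAULT_N_QUAD,
    quad_range: float = DEFAULT_QUAD_RANGE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DIFResult:
    """Rasch DIF test between two groups.

    Omnibus: likelihood-ratio comparison of a model with group-equal item
    difficulties (the non-reference group's latent mean freed, shared latent
    SD) against group-specific difficulties (group means fixed at 0, shared
    SD); df = J - 1.

    Per item: Wald tests of the difficulty difference from separate
    per-group Rasch fits linked by the all-items anchor (equal mean
    difficulty across groups).  ``flagged`` marks items with unadjusted
    p < ``alpha``; multiplicity adjustment is the caller's concern.
    ``per_item=False`` skips the Wald fits and returns an empty item table
    (omnibus only).
    """
    if grouping not in responses.groups:
        raise ValueError(f"no group column {grouping!r} on the response matrix")
    labels = responses.groups[grouping]
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"DIF test requires exactly 2 groups, got {levels}")
    gidx = np.array([levels.index(l) for l in labels])
    sizes = np.bincount(gidx, minlength=2)
    if sizes.min() < min_group_size:
        raise ValueError(f"group sizes {dict(zip(levels, sizes))} below minimum {min_group_size}")

    bad = _screen_items(responses)
    keep = [i for i in responses.item_ids if i not in bad]
    sub = responses.with_items(keep)
    J = len(keep)

    null = _em(sub.correct, a_free=False, sigma_free=True, group_idx=gidx,
               group_b=False, free_group_means=True,
               n_quad=n_quad, quad_range=quad_range, tol=tol, max_iter=max_iter)
    alt = _em(sub.correct, a_free=False, sigma_free=True, group_idx=gidx,
              group_b=True, free_group_means=False,
              n_quad=n_quad, quad_range=quad_range, tol=tol, max_iter=max_iter)
    chi2 = max(2.0 * (alt["loglik"] - null["loglik"]), 0.0)
    df = J - 1
    p = float(stats.chi2.sf(chi2, df))

    if not per_item:
        empty = pd.DataFrame(
            columns=["item_id", "delta_b", "se", "z", "p", "flagged"]
        )
        return DIFResult(grouping=grouping, chi2=chi2, df=df, p=p, item_table=empty)

    # per-item Wald from separate per-group fits, all-items anchoring
    fits = []
    for g in range(2):
        sel = gidx == g
        rm = ResponseMatrix(
            tuple(np.array(responses.person_ids)[sel]),
            tuple(keep),
            sub.correct[sel],
        )
        fits.append(fit_rasch(rm, n_quad=n_quad, quad_range=quad_range, tol=tol,
                              max_iter=max_iter, compute_se=True))
    bA, bB = fits[0].difficulty, fits[1].difficulty
    seA = fits[0].se_difficulty if fits[0].se_difficulty is not None else np.full(J, np.nan)
    seB = fits[1].se_difficulty if fits[1].se_difficulty is not None else np.full(J, np.nan)
    delta = (bB - np.nanmean(bB)) - (bA - np.nanmean(bA))
    se = np.sqrt(seA**2 + seB**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = delta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "item_id": keep,
            "delta_b": delta,
            "se": se,
            "z": z,
            "p": pvals,
            "flagged": pvals < alpha,
        }
    )
    return DIFResult(grouping=grouping, chi2=chi2, df=df, p=p, item_table=table)
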