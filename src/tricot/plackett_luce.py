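"""Plackett-Luce worth estimation from tricot rankings.

The Plackett-Luce model assigns each item i a positive *worth* w_i = exp(theta_i)
and builds the probability of a complete ranking as a sequence of Luce
choices without replacement: the probability that item i is ranked first
among a set S is w_i / sum_{l in S} w_l, then the same rule is applied to
the remainder.  Log-worths theta are identified only up to an additive
constant; this package constrains mean(theta) = 0 so per-item uncertainty
summaries (quasi-variances) are symmetric in the items.

The model object follows the statsmodels convention::

    model = PlackettLuce(rankings)
    res = model.fit()
    res.summary()
    res.prob_outperform("V03", check="CHECK")
    draws = res.bayesian_bootstrap(n_draws=200, seed=42)
    table = risk_assessment(draws, check="CHECK")

Estimation uses Hunter-style Minorize-Maximize updates (monotone in the
log-likelihood), tol 1e-8 on the log-likelihood change, max 500 iterations.
Items involved in separation (never beaten, or never winning) are flagged;
an optional pseudo-item regulariser keeps their estimates finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import logsumexp

from .exceptions import (
    ConvergenceError,
    DisconnectedError,
    ModelError,
    ValidationError,
)
from .rankings import PairwiseComparison, Ranking, connectivity_check

__all__ = [
    "PlackettLuce",
    "PlackettLuceResults",
    "QuasiVariances",
    "BootstrapDraws",
    "ItemCovariateResults",
    "loglik_ranking",
    "fit_plackett_luce",
    "fit_bradley_terry",
    "fit_pl_item_covariates",
    "prob_outperform",
    "quasi_variances",
    "bayesian_bootstrap",
    "risk_assessment",
    "win_rate",
]

_THETA_CLAMP = 30.0  # |theta| bound during MM updates; guards separated items


def _as_ranking(r) -> Ranking:
    return r if isinstance(r, Ranking) else Ranking(tuple(r))


class PlackettLuce:
    """Plackett-Luce model for a collection of (possibly weighted) rankings.

    Parameters
    ----------
    rankings : sequence of Ranking (or item sequences)
        Strict orderings, most preferred first.  Triads from tricot trials
        are the typical case but any lengths >= 2 are accepted.
    items : sequence of str, optional
        Item universe; defaults to the sorted set of ranked items.  Items
        never appearing in any ranking are rejected (not identifiable).
    """

    def __init__(self, rankings, items=None):
        self.rankings = [_as_ranking(r) for r in rankings]
        if not self.rankings:
            raise ValidationError("need at least one ranking")
        seen = {it for r in self.rankings for it in r.ordered_items}
        if items is None:
            items = sorted(seen)
        self.items = list(items)
        missing = seen - set(self.items)
        if missing:
            raise ValidationError(f"rankings mention unknown items: {sorted(missing)}")
        unranked = set(self.items) - seen
        if unranked:
            raise ValidationError(
                f"items never ranked (not identifiable): {sorted(unranked)}"
            )
        self._index = {it: i for i, it in enumerate(self.items)}
        self.n_items = len(self.items)
        self.n_rankings = len(self.rankings)
        self.base_weights = np.array([r.weight for r in self.rankings])
        self._build_stages()

    # ---- internal representation -------------------------------------

    def _build_stages(self):
        """Flatten rankings into choice stages.

        A ranking of m items contributes m-1 stages; stage j has choice set
        = items ranked j..m-1 and winner = the item at rank j.
        """
        sets, winners, rank_ids = [], [], []
        kmax = max(len(r) for r in self.rankings)
        for rid, r in enumerate(self.rankings):
            idx = [self._index[it] for it in r.ordered_items]
            for j in range(len(idx) - 1):
                sets.append(idx[j:])
                winners.append(idx[j])
                rank_ids.append(rid)
        S = len(sets)
        self._sets = np.zeros((S, kmax), dtype=np.int64)
        self._mask = np.zeros((S, kmax), dtype=bool)
        for s, members in enumerate(sets):
            self._sets[s, : len(members)] = members
            self._mask[s, : len(members)] = True
        self._winners = np.array(winners, dtype=np.int64)
        self._rank_ids = np.array(rank_ids, dtype=np.int64)
        # win/appearance counts for separation diagnostics (unweighted)
        wins = np.bincount(self._winners, minlength=self.n_items)
        appear = np.bincount(self._sets[self._mask], minlength=self.n_items)
        self._wins = wins
        self._losses = appear - wins

    def separated_items(self) -> list[str]:
        """Items whose MLE worth is infinite (never beaten) or zero (never
        winning a choice stage)."""
        return [
            it
            for i, it in enumerate(self.items)
            if self._wins[i] == 0 or self._losses[i] == 0
        ]

    def check_connected(self) -> None:
        comps = connectivity_check(self.rankings)
        if len(comps) > 1:
            raise DisconnectedError(comps)

    # ---- likelihood machinery ----------------------------------------

    def _stage_weights(self, weights):
        w = self.base_weights if weights is None else np.asarray(weights, dtype=float)
        if w.shape != (self.n_rankings,):
            raise ValidationError("weights must have one entry per ranking")
        return w[self._rank_ids]

    def loglik_per_ranking(self, theta) -> np.ndarray:
        """Unweighted log-likelihood contribution of each ranking."""
        theta = np.asarray(theta, dtype=float)
        vals = np.where(self._mask, theta[self._sets], -np.inf)
        lse = logsumexp(vals, axis=1)
        stage_ll = theta[self._winners] - lse
        return np.bincount(self._rank_ids, weights=stage_ll, minlength=self.n_rankings)

    def loglik(self, theta, weights=None) -> float:
        w = self.base_weights if weights is None else np.asarray(weights, dtype=float)
        return float(w @ self.loglik_per_ranking(theta))

    def _stage_probs(self, theta) -> np.ndarray:
        vals = np.where(self._mask, theta[self._sets], -np.inf)
        lse = logsumexp(vals, axis=1, keepdims=True)
        return np.where(self._mask, np.exp(vals - lse), 0.0)

    def score_per_ranking(self, theta) -> np.ndarray:
        """Per-ranking gradient of the log-likelihood at theta (n x t)."""
        theta = np.asarray(theta, dtype=float)
        P = self._stage_probs(theta)
        n, t = self.n_rankings, self.n_items
        out = np.zeros((n, t))
        np.add.at(out, (self._rank_ids, self._winners), 1.0)
        for c in range(self._sets.shape[1]):
            np.add.at(out, (self._rank_ids, self._sets[:, c]), -P[:, c])
        return out

    def score(self, theta, weights=None) -> np.ndarray:
        w = self.base_weights if weights is None else np.asarray(weights, dtype=float)
        return w @ self.score_per_ranking(theta)

    def hessian(self, theta, weights=None) -> np.ndarray:
        """Hessian of the weighted log-likelihood (t x t, singular along 1)."""
        theta = np.asarray(theta, dtype=float)
        P = self._stage_probs(theta)
        sw = self._stage_weights(weights)
        t = self.n_items
        H = np.zeros((t, t))
        kmax = self._sets.shape[1]
        for a in range(kmax):
            np.add.at(H, (self._sets[:, a], self._sets[:, a]), -sw * P[:, a])
            for bcol in range(kmax):
                np.add.at(
                    H, (self._sets[:, a], self._sets[:, bcol]), sw * P[:, a] * P[:, bcol]
                )
        return H

    # ---- fitting ------------------------------------------------------

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        weights=None,
        start=None,
        regularize: bool = False,
        pseudo_weight: float = 0.1,
        check_connectivity: bool = True,
        compute_vcov: bool = True,
    ) -> "PlackettLuceResults":
        """Maximum-likelihood fit by Minorize-Maximize updates.

        ``regularize=True`` augments the data with a pseudo-item that beats
        and loses to every real item with weight ``pseudo_weight``, which
        keeps separated items finite (off by default).
        """
        if check_connectivity:
            self.check_connected()
        if regularize:
            return self._fit_regularized(tol, max_iter, weights, pseudo_weight,
                                         compute_vcov)
        w = self.base_weights if weights is None else np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValidationError("ranking weights must be non-negative")
        theta = np.zeros(self.n_items) if start is None else np.asarray(start, float).copy()
        theta -= theta.mean()
        sw = w[self._rank_ids]
        wins = np.zeros(self.n_items)
        np.add.at(wins, self._winners, sw)
        ll = self.loglik(theta, w)
        converged = False
        n_iter = 0
        # phase 1: monotone MM updates (globally stable)
        for n_iter in range(1, max_iter + 1):
            wv = np.exp(theta)
            denom = np.where(self._mask, wv[self._sets], 0.0).sum(axis=1)
            contrib = sw / denom
            A = np.zeros(self.n_items)
            for c in range(self._sets.shape[1]):
                np.add.at(A, self._sets[:, c], np.where(self._mask[:, c], contrib, 0.0))
            with np.errstate(divide="ignore"):
                theta_new = np.log(wins) - np.log(A)
            theta_new = np.clip(theta_new, -_THETA_CLAMP, _THETA_CLAMP)
            theta_new -= theta_new.mean()
            ll_new = self.loglik(theta_new, w)
            theta = theta_new
            delta = abs(ll_new - ll)
            ll = ll_new
            if delta < tol:
                converged = True
                break
            if delta < 1e-4 or n_iter >= 100:
                break  # switch to Newton polishing
        # phase 2: projected Newton with step halving (fast near the
        # optimum; MM alone crawls when one worth dominates)
        if not converged:
            t = self.n_items
            B = np.linalg.svd(np.eye(t) - np.ones((t, t)) / t)[0][:, : t - 1]
            for _ in range(50):
                n_iter += 1
                g = B.T @ self.score(theta, w)
                info = B.T @ (-self.hessian(theta, w)) @ B
                try:
                    step = np.linalg.solve(info, g)
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(info, g, rcond=None)[0]
                alpha_ls = 1.0
                for _ in range(30):
                    cand = np.clip(theta + alpha_ls * (B @ step),
                                   -_THETA_CLAMP, _THETA_CLAMP)
                    cand -= cand.mean()
                    ll_new = self.loglik(cand, w)
                    if ll_new >= ll - 1e-12:
                        break
                    alpha_ls /= 2.0
                delta = abs(ll_new - ll)
                if ll_new >= ll:
                    theta, ll = cand, ll_new
                if delta < tol:
                    converged = True
                    break
        grad = self.score(theta, w)
        vcov = self._constrained_vcov(theta, w) if compute_vcov else None
        return PlackettLuceResults(
            model=self,
            params=theta,
            llf=ll,
            vcov=vcov,
            converged=converged,
            n_iter=n_iter,
            grad_norm=float(np.max(np.abs(grad))),
            weights=None if weights is None else w,
        )

    def _constrained_vcov(self, theta, w) -> np.ndarray:
        """Covariance of theta under the mean-zero constraint, from the
        observed information projected onto the contrast space."""
        H = self.hessian(theta, w)
        t = self.n_items
        # orthonormal basis of the mean-zero subspace
        B = np.linalg.svd(np.eye(t) - np.ones((t, t)) / t)[0][:, : t - 1]
        info = B.T @ (-H) @ B
        cov_b = np.linalg.pinv(info)
        return B @ cov_b @ B.T

    def _fit_regularized(self, tol, max_iter, weights, pseudo_weight, compute_vcov=True):
        ghost = "__pseudo__"
        cache_key = float(pseudo_weight)
        if getattr(self, "_aug_cache", None) is None or self._aug_cache[0] != cache_key:
            aug = list(self.rankings)
            for it in self.items:
                aug.append(Ranking((it, ghost), weight=pseudo_weight))
                aug.append(Ranking((ghost, it), weight=pseudo_weight))
            self._aug_cache = (cache_key, PlackettLuce(aug, items=self.items + [ghost]))
        aug_model = self._aug_cache[1]
        w_aug = None
        if weights is not None:
            w_aug = np.concatenate(
                [np.asarray(weights, float), np.full(2 * self.n_items, pseudo_weight)]
            )
            # pseudo rankings carry their weight via base_weights; when the
            # caller supplies weights they replace base weights entirely
        res_aug = aug_model.fit(
            tol=tol, max_iter=max_iter, weights=w_aug, check_connectivity=False,
            compute_vcov=compute_vcov,
        )
        theta = res_aug.params[: self.n_items].copy()
        theta -= theta.mean()
        vcov = None
        if compute_vcov:
            vcov = res_aug.vcov[: self.n_items, : self.n_items]
            t = self.n_items
            P = np.eye(t) - np.ones((t, t)) / t
            vcov = P @ vcov @ P
        return PlackettLuceResults(
            model=self,
            params=theta,
            llf=self.loglik(theta, self.base_weights if weights is None else weights),
            vcov=vcov,
            converged=res_aug.converged,
            n_iter=res_aug.n_iter,
            grad_norm=res_aug.grad_norm,
            weights=None if weights is None else np.asarray(weights, float),
            regularized=True,
        )


@dataclass
class QuasiVariances:
    """Per-item quasi-variances q_i with q_i + q_j ~ Var(theta_i - theta_j)."""

    items: list
    q: np.ndarray
    max_relative_error: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.q, index=self.items, name="quasi_var")


@dataclass
class BootstrapDraws:
    """Bayesian-bootstrap draws of the log-worth vector (n_draws x n_items)."""

    items: list
    theta: np.ndarray
    seed: int
    n_draws: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, columns=self.items)


class PlackettLuceResults:
    """Fitted Plackett-Luce model: mean-zero log-worths with uncertainty."""

    def __init__(
        self,
        model: PlackettLuce,
        params: np.ndarray,
        llf: float,
        vcov: np.ndarray | None,
        converged: bool,
        n_iter: int,
        grad_norm: float,
        weights=None,
        regularized: bool = False,
    ):
        self.model = model
        self.items = model.items
        self.params = params
        self.llf = llf
        self.vcov = vcov
        self.converged = converged
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.weights = weights
        self.regularized = regularized
        self.separated = model.separated_items()
        self.n_rankings = model.n_rankings

    @property
    def theta(self) -> pd.Series:
        return pd.Series(self.params, index=self.items, name="log_worth")

    @property
    def worth(self) -> pd.Series:
        w = np.exp(self.params)
        return pd.Series(w / w.sum(), index=self.items, name="worth")

    @property
    def bse(self) -> pd.Series:
        if self.vcov is None:
            raise ModelError("vcov not computed")
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.items, name="se")

    def contrast_variance(self, item: str, other: str) -> float:
        i, j = self.items.index(item), self.items.index(other)
        return float(self.vcov[i, i] + self.vcov[j, j] - 2 * self.vcov[i, j])

    def prob_outperform(self, item: str, check: str) -> float:
        """Luce pairwise probability that ``item`` beats ``check``:
        w_item / (w_item + w_check).  Invariant to worth rescaling."""
        if item == check:
            raise ValidationError("item and check must differ")
        w = self.worth
        for it in (item, check):
            if it not in w.index:
                raise ValidationError(f"unknown item {it!r}")
        return float(w[item] / (w[item] + w[check]))

    def quasi_variances(self) -> QuasiVariances:
        """Firth/De Menezes quasi-variances: q minimising the summed squared
        error between log(q_i + q_j) and log Var(theta_i - theta_j) over all
        item pairs.  The 2-item case is underdetermined; the symmetric
        minimum-norm solution q_1 = q_2 = v_12 / 2 is used."""
        if self.vcov is None:
            raise ModelError("vcov not computed")
        t = len(self.items)
        d = np.diag(self.vcov)
        V = d[:, None] + d[None, :] - 2 * self.vcov
        iu = np.triu_indices(t, k=1)
        v_pairs = V[iu]
        if np.any(v_pairs <= 0):
            raise ModelError("degenerate vcov: non-positive contrast variance")
        if t == 2:
            q = np.full(2, v_pairs[0] / 2)
            return QuasiVariances(list(self.items), q, 0.0)
        log_v = np.log(v_pairs)
        i_idx, j_idx = iu

        def resid(s):
            q = np.exp(s)
            return np.log(q[i_idx] + q[j_idx]) - log_v

        s0 = np.log(np.full(t, v_pairs.mean() / 2))
        sol = least_squares(resid, s0, method="lm", xtol=1e-12, ftol=1e-12)
        q = np.exp(sol.x)
        rel_err = np.abs((q[i_idx] + q[j_idx]) / v_pairs - 1.0)
        return QuasiVariances(list(self.items), q, float(rel_err.max()))

    def bayesian_bootstrap(self, n_draws: int = 200, seed: int = 0) -> BootstrapDraws:
        """Rubin's Bayesian bootstrap: ranking weights drawn from a flat
        Dirichlet (scaled to sum n), weighted refit per draw.  Deterministic
        given seed; non-convergent draws are excluded with a count."""
        rng = np.random.default_rng(seed)
        n = self.model.n_rankings
        draws = []
        n_excluded = 0
        for _ in range(n_draws):
            g = rng.gamma(1.0, 1.0, size=n)
            w = g / g.sum() * n * self.model.base_weights
            res = self.model.fit(
                weights=w,
                start=self.params,
                check_connectivity=False,
                compute_vcov=False,
                regularize=self.regularized,
            )
            if res.converged:
                draws.append(res.params)
            else:
                n_excluded += 1
        if not draws:
            raise ConvergenceError("no bootstrap draw converged")
        return BootstrapDraws(
            list(self.items), np.vstack(draws), seed, n_draws, n_excluded
        )

    def summary(self) -> str:
        lines = [
            "Plackett-Luce model results",
            "=" * 55,
            f"n_rankings: {self.n_rankings:>6}    log-likelihood: {self.llf:.4f}",
            f"converged:  {str(self.converged):>6}    iterations: {self.n_iter}"
            f"    max|grad|: {self.grad_norm:.2e}",
        ]
        if self.separated:
            lines.append(f"separated items (infinite MLE direction): {self.separated}")
        tab = pd.DataFrame(
            {
                "log_worth": np.round(self.params, 4),
                "worth": np.round(self.worth.to_numpy(), 4),
                "se": np.round(self.bse.to_numpy(), 4)
                if self.vcov is not None
                else np.nan,
            },
            index=self.items,
        )
        lines.append(tab.to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "items": list(self.items),
            "theta": [round(float(x), 6) for x in self.params],
            "worth": [round(float(x), 6) for x in self.worth],
            "loglik": float(self.llf),
            "n": self.n_rankings,
            "converged": bool(self.converged),
        }
        if self.vcov is not None:
            d["se"] = [round(float(x), 6) for x in self.bse]
            d["quasi_q"] = [round(float(x), 6) for x in self.quasi_variances().q]
        return d


# ---- module-level operations ------------------------------------------


def loglik_ranking(theta, ranking, items) -> float:
    """Log-likelihood of a single ranking under log-worths theta, times its
    weight: sum over choice stages of theta_winner - log sum exp(theta) over
    the not-yet-chosen set."""
    theta = np.asarray(theta, dtype=float)
    index = {it: i for i, it in enumerate(items)}
    r = _as_ranking(ranking)
    for it in r.ordered_items:
        if it not in index:
            raise ValidationError(f"unknown item {it!r}")
    idx = [index[it] for it in r.ordered_items]
    ll = 0.0
    for j in range(len(idx) - 1):
        ll += theta[idx[j]] - logsumexp(theta[idx[j:]])
    return float(ll * r.weight)


def fit_plackett_luce(rankings, items=None, tol=1e-8, max_iter=500, **kw) -> PlackettLuceResults:
    """Convenience wrapper: build a :class:`PlackettLuce` model and fit it."""
    return PlackettLuce(rankings, items=items).fit(tol=tol, max_iter=max_iter, **kw)


def fit_bradley_terry(pairs, items=None, **kw) -> PlackettLuceResults:
    """Bradley-Terry fit: the Plackett-Luce model restricted to pairwise
    comparisons (e.g. obtained by rank-breaking)."""
    rankings = [
        Ranking((p.winner, p.loser), p.weight)
        if isinstance(p, PairwiseComparison)
        else Ranking(tuple(p))
        for p in pairs
    ]
    return fit_plackett_luce(rankings, items=items, **kw)


def prob_outperform(results: PlackettLuceResults, item: str, check: str) -> float:
    return results.prob_outperform(item, check)


def quasi_variances(results: PlackettLuceResults) -> QuasiVariances:
    return results.quasi_variances()


def bayesian_bootstrap(rankings, n_draws=200, seed=0, **fit_kw) -> BootstrapDraws:
    return fit_plackett_luce(rankings, **fit_kw).bayesian_bootstrap(n_draws, seed)


def risk_assessment(draws: BootstrapDraws, check: str) -> pd.DataFrame:
    """Per-item reliability versus a check variety.

    reliability = fraction of bootstrap draws where the item's log-worth
    exceeds the check's; the table also reports the central 90% interval of
    theta_item - theta_check.  The check against itself has reliability 0 by
    convention.
    """
    if check not in draws.items:
        raise ValidationError(f"check {check!r} not among items")
    c = draws.items.index(check)
    diff = draws.theta - draws.theta[:, [c]]
    rows = []
    for i, it in enumerate(draws.items):
        if it == check:
            rows.append({"item": it, "reliability": 0.0, "lower90": 0.0, "upper90": 0.0})
            continue
        d = diff[:, i]
        rows.append(
            {
                "item": it,
                "reliability": float(np.mean(d > 0)),
                "lower90": float(np.quantile(d, 0.05)),
                "upper90": float(np.quantile(d, 0.95)),
            }
        )
    return pd.DataFrame(rows).set_index("item")


def win_rate(rankings, item: str, check: str) -> float:
    """Observed fraction of rankings containing both items where ``item`` is
    ranked above ``check``.  This is an interpretation of the informal
    "win rate" notion (number of times/locations the entry outperforms the
    check); the model-based counterpart is :func:`prob_outperform`."""
    if item == check:
        raise ValidationError("item and check must differ")
    wins = total = 0
    for r in rankings:
        r = _as_ranking(r)
        if item in r.ordered_items and check in r.ordered_items:
            total += 1
            if r.ordered_items.index(item) < r.ordered_items.index(check):
                wins += 1
    if total == 0:
        raise ValidationError(f"no ranking compares {item!r} with {check!r}")
    return wins / total


# ---- item covariates ---------------------------------------------------


class ItemCovariateResults:
    """Plackett-Luce fit with worths restricted to theta = X beta."""

    def __init__(self, features, beta, beta_vcov, implied: PlackettLuceResults):
        self.features = list(features)
        self.beta = pd.Series(beta, index=self.features, name="beta")
        self.beta_vcov = beta_vcov
        self.beta_se = pd.Series(
            np.sqrt(np.diag(beta_vcov)), index=self.features, name="se"
        )
        self.implied = implied

    def summary(self) -> str:
        tab = pd.DataFrame({"beta": self.beta.round(4), "se": self.beta_se.round(4)})
        return "Plackett-Luce item-covariate regression\n" + tab.to_string()


def fit_pl_item_covariates(rankings, item_features: pd.DataFrame, items=None, tol=1e-9):
    """Fit log-worths as a linear combination of item features.

    ``item_features`` is an item x feature DataFrame (full column rank
    required).  With saturated one-hot features the implied log-worths equal
    the unconstrained Plackett-Luce fit.
    """
    model = PlackettLuce(rankings, items=items)
    model.check_connected()
    X = item_features.reindex(model.items)
    if X.isna().any().any():
        raise ValidationError("item_features must cover every ranked item")
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValidationError("feature matrix is rank deficient")

    def negll(beta):
        return -model.loglik(Xm @ beta)

    def grad(beta):
        return -(Xm.T @ model.score(Xm @ beta))

    res = minimize(negll, np.zeros(Xm.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": tol, "maxiter": 1000})
    beta = res.x
    theta = Xm @ beta
    H_beta = Xm.T @ model.hessian(theta) @ Xm
    beta_vcov = np.linalg.pinv(-H_beta)
    theta_c = theta - theta.mean()
    implied = PlackettLuceResults(
        model=model,
        params=theta_c,
        llf=model.loglik(theta_c),
        vcov=None,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
    )
    return ItemCovariateResults(item_features.columns, beta, beta_vcov, implied)
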