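"""Plackett-Luce trees: recursive partitioning of rankings on covariates.

Farm-level covariates (typically seasonal agroclimatic indices and
coordinates) may shift which varieties perform well.  A Plackett-Luce tree
recursively splits the trial on the covariate with the strongest evidence of
parameter instability, refits the worth model in each child, and stops when
no instability test is significant, a child would fall below ``minsize``
rankings, or ``maxdepth`` is reached.  Leaves carry full Plackett-Luce fits;
new locations are routed down the tree to obtain local worths and top-k
variety recommendations.

Instability is assessed with maximally-selected two-sample statistics on the
per-ranking score contributions (the gradient of each ranking's
log-likelihood at the node estimate), calibrated by permutation and
Bonferroni-corrected across covariates.  This is a permutation-exact variant
of model-based recursive partitioning: same intent, simpler null
calibration at small n.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .plackett_luce import PlackettLuce, PlackettLuceResults
from .rankings import Ranking

__all__ = ["SplitRule", "PLTreeNode", "PlackettLuceTree", "PLTreeResults", "fit_pl_tree"]

logger = logging.getLogger(__name__)

MAX_SPLIT_CANDIDATES = 50


@dataclass(frozen=True)
class SplitRule:
    """Binary split: rows with covariate <= threshold go left."""

    covariate: str
    threshold: float
    p_value: float


@dataclass
class PLTreeNode:
    n_rankings: int
    results: PlackettLuceResults
    split: SplitRule | None = None
    left: "PLTreeNode | None" = None
    right: "PLTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def route(self, row: pd.Series) -> "PLTreeNode":
        if self.is_leaf:
            return self
        val = row.get(self.split.covariate)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ValidationError(f"missing split covariate {self.split.covariate!r}")
        child = self.left if val <= self.split.threshold else self.right
        return child.route(row)

    def leaves(self) -> list["PLTreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": {
                    "items": list(self.results.items),
                    "theta": [round(float(x), 6) for x in self.results.params],
                    "n": self.n_rankings,
                }
            }
        return {
            "split": {
                "var": self.split.covariate,
                "thr": float(self.split.threshold),
                "p": float(self.split.p_value),
            },
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


class PlackettLuceTree:
    """Model-based partitioning of rankings on numeric covariates.

    Parameters
    ----------
    rankings : sequence of Ranking
    covariates : DataFrame
        One row per ranking, aligned by position, numeric columns only
        (a ``participant_id`` column, if present, is used only for
        alignment checks and dropped).  Rows with missing values are
        dropped with a logged count.
    alpha : float
        Significance level for the Bonferroni-corrected permutation test.
    minsize : int
        Minimum rankings per leaf.
    maxdepth : int
        Maximum tree depth (0 = root only).
    n_perm : int
        Permutation draws for the instability test.
    """

    def __init__(
        self,
        rankings,
        covariates: pd.DataFrame,
        alpha: float = 0.05,
        minsize: int = 30,
        maxdepth: int = 3,
        n_perm: int = 199,
        seed: int = 0,
    ):
        if not 0 <= alpha < 1:
            raise ValidationError("alpha must be in [0, 1)")
        rankings = [r if isinstance(r, Ranking) else Ranking(tuple(r)) for r in rankings]
        if len(rankings) != len(covariates):
            raise ValidationError(
                f"{len(rankings)} rankings but {len(covariates)} covariate rows"
            )
        cov = covariates.reset_index(drop=True)
        if "participant_id" in cov.columns:
            cov = cov.drop(columns=["participant_id"])
        cov = cov.apply(pd.to_numeric)
        keep = ~cov.isna().any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d rankings with missing covariates", n_dropped)
        self.rankings = [r for r, k in zip(rankings, keep) if k]
        self.covariates = cov.loc[keep].reset_index(drop=True)
        self.n_dropped = n_dropped
        self.alpha = alpha
        self.minsize = minsize
        self.maxdepth = maxdepth
        self.n_perm = n_perm
        self.seed = seed
        self.items = sorted({it for r in self.rankings for it in r.ordered_items})

    def fit(self) -> "PLTreeResults":
        rng = np.random.default_rng(self.seed)
        idx = np.arange(len(self.rankings))
        root = self._grow(idx, depth=0, rng=rng)
        return PLTreeResults(root, self)

    # ---- recursion ----------------------------------------------------

    def _fit_node(self, idx) -> PlackettLuceResults:
        model = PlackettLuce([self.rankings[i] for i in idx], items=self.items)
        return model.fit(check_connectivity=False, compute_vcov=False)

    def _grow(self, idx, depth, rng) -> PLTreeNode:
        res = self._fit_node(idx)
        node = PLTreeNode(n_rankings=len(idx), results=res)
        if (
            self.alpha <= 0
            or depth >= self.maxdepth
            or len(idx) < 2 * self.minsize
        ):
            return node
        best = self._instability_test(idx, res, rng)
        if best is None or best[1] > self.alpha:
            return node
        covariate, p_adj = best
        thr = self._best_threshold(idx, covariate)
        if thr is None:
            return node
        vals = self.covariates[covariate].to_numpy()[idx]
        left_idx = idx[vals <= thr]
        right_idx = idx[vals > thr]
        node.split = SplitRule(covariate, float(thr), float(p_adj))
        node.left = self._grow(left_idx, depth + 1, rng)
        node.right = self._grow(right_idx, depth + 1, rng)
        return node

    def _candidate_thresholds(self, vals) -> np.ndarray:
        """Midpoints of sorted unique values, capped at quantile-spaced
        candidates, restricted so both children satisfy minsize."""
        uniq = np.unique(vals)
        if len(uniq) < 2:
            return np.array([])
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        if len(mids) > MAX_SPLIT_CANDIDATES:
            qs = np.quantile(mids, np.linspace(0, 1, MAX_SPLIT_CANDIDATES))
            mids = np.unique(qs)
        ok = [
            c
            for c in mids
            if (vals <= c).sum() >= self.minsize and (vals > c).sum() >= self.minsize
        ]
        return np.asarray(ok)

    @staticmethod
    def _max_stat(scores_sorted: np.ndarray, n_left: np.ndarray) -> float:
        """Max over cut points of the normalised CUSUM norm of score sums."""
        csum = np.cumsum(scores_sorted, axis=0)
        n = scores_sorted.shape[0]
        S_L = csum[n_left - 1]  # (n_cuts, t)
        scale = n_left * (1.0 - n_left / n)
        return float(np.max(np.sum(S_L**2, axis=1) / scale))

    def _instability_test(self, idx, res: PlackettLuceResults, rng):
        """Permutation-calibrated maximally-selected score statistic per
        covariate; returns (best covariate, Bonferroni-adjusted p) or None."""
        sub_model = res.model
        scores = sub_model.score_per_ranking(res.params)  # (n, t)
        n = len(idx)
        tested = []
        for covariate in self.covariates.columns:
            vals = self.covariates[covariate].to_numpy()[idx]
            cands = self._candidate_thresholds(vals)
            if len(cands) == 0:
                continue
            order = np.argsort(vals, kind="stable")
            n_left = np.searchsorted(vals[order], cands, side="right")
            obs = self._max_stat(scores[order], n_left)
            exceed = 0
            for _ in range(self.n_perm):
                perm = rng.permutation(n)
                if self._max_stat(scores[perm], n_left) >= obs:
                    exceed += 1
            p = (1 + exceed) / (1 + self.n_perm)
            tested.append((covariate, p))
        if not tested:
            return None
        m = len(tested)
        covariate, p = min(tested, key=lambda cp: cp[1])
        return covariate, min(1.0, p * m)

    def _best_threshold(self, idx, covariate):
        """Split point maximising the summed child log-likelihood."""
        vals = self.covariates[covariate].to_numpy()[idx]
        cands = self._candidate_thresholds(vals)
        best_thr, best_ll = None, -np.inf
        for c in cands:
            left = idx[vals <= c]
            right = idx[vals > c]
            try:
                ll = self._fit_node(left).llf + self._fit_node(right).llf
            except ValidationError:
                continue  # e.g. an item absent on one side
            if ll > best_ll:
                best_thr, best_ll = c, ll
        return best_thr


class PLTreeResults:
    """Fitted Plackett-Luce tree."""

    def __init__(self, root: PLTreeNode, model: PlackettLuceTree):
        self.root = root
        self.model = model
        self.items = model.items

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def predict_worth(self, new_covariates: pd.DataFrame) -> pd.DataFrame:
        """Route each row to its leaf; return that leaf's normalised worths."""
        rows = []
        for _, row in new_covariates.iterrows():
            leaf = self.root.route(row)
            rows.append(leaf.results.worth)
        return pd.DataFrame(rows, index=new_covariates.index)

    def top_k(self, new_covariates: pd.DataFrame, k: int = 3) -> pd.DataFrame:
        """Top-k items per row by leaf worth; ties broken alphabetically and
        flagged in the ``tied`` column."""
        if not 1 <= k <= len(self.items):
            raise ValidationError(f"k must be in 1..{len(self.items)}")
        worths = self.predict_worth(new_covariates)
        out = []
        for _, w in worths.iterrows():
            ordered = sorted(w.index, key=lambda it: (-w[it], it))
            vals = np.sort(w.to_numpy())[::-1]
            tied = bool(np.any(np.isclose(vals[:-1], vals[1:], rtol=0, atol=1e-12)))
            out.append({f"top{j + 1}": ordered[j] for j in range(k)} | {"tied": tied})
        return pd.DataFrame(out, index=new_covariates.index)

    def summary(self) -> str:
        lines = [f"Plackett-Luce tree: {self.n_leaves} leaf/leaves"]

        def walk(node, depth, label):
            pad = "  " * depth
            if node.is_leaf:
                top = node.results.worth.idxmax()
                lines.append(
                    f"{pad}{label} leaf: n={node.n_rankings}, best={top}"
                )
            else:
                s = node.split
                lines.append(
                    f"{pad}{label} split {s.covariate} <= {s.threshold:.4g} "
                    f"(p={s.p_value:.4f})"
                )
                walk(node.left, depth + 1, "L")
                walk(node.right, depth + 1, "R")

        walk(self.root, 0, "root")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.root.to_dict()

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_pl_tree(
    rankings,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    minsize: int = 30,
    maxdepth: int = 3,
    n_perm: int = 199,
    seed: int = 0,
) -> PLTreeResults:
    """Convenience wrapper around :class:`PlackettLuceTree`."""
    return PlackettLuceTree(
        rankings, covariates, alpha=alpha, minsize=minsize,
        maxdepth=maxdepth, n_perm=n_perm, seed=seed,
    ).fit()
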