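"""Simulated tricot trials with known ground truth.

Rankings are sampled exactly from the Plackett-Luce model via the Gumbel
latent-utility construction: each item's utility is its log-worth plus
independent standard Gumbel noise, and sorting utilities descending yields a
PL-distributed ranking.  Trials bundle a balanced triadic design, farm
covariates, best/worst responses and the rankings they imply, so every
analysis module can be exercised end-to-end without external data.

Covariates are drawn from simple stated distributions: coordinates uniform
on [-1, 1], named numeric covariates standard normal.  A two-regime truth
flips the worth vector across a covariate threshold, emulating
genotype-by-environment crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design, random_balanced_design
from .exceptions import ValidationError
from .rankings import POSITION_LABELS, Ranking, TriadAssignment, TricotResponse

__all__ = [
    "TrialTruth",
    "SimulatedTrial",
    "sample_ranking_from_worths",
    "simulate_trial",
    "power_simulation",
]

GUMBEL_SD = np.pi / np.sqrt(6.0)  # sd of the latent noise, maps Cohen's d


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth for a simulated trial.

    ``theta`` is the global log-worth vector; an optional second regime
    (``theta_alt``) applies to farms whose ``regime_covariate`` exceeds
    ``regime_threshold``.
    """

    items: tuple[str, ...]
    theta: tuple[float, ...]
    theta_alt: tuple[float, ...] | None = None
    regime_covariate: str | None = None
    regime_threshold: float = 0.0

    def __post_init__(self):
        if len(self.items) != len(self.theta):
            raise ValidationError("items and theta lengths differ")
        if self.theta_alt is not None:
            if len(self.theta_alt) != len(self.items):
                raise ValidationError("theta_alt length differs")
            if self.regime_covariate is None:
                raise ValidationError("two-regime truth needs a regime covariate")

    def theta_for(self, covariate_row: pd.Series) -> np.ndarray:
        if self.theta_alt is None or self.regime_covariate is None:
            return np.asarray(self.theta)
        if covariate_row[self.regime_covariate] <= self.regime_threshold:
            return np.asarray(self.theta)
        return np.asarray(self.theta_alt)


def sample_ranking_from_worths(theta, items_in_block, rng) -> Ranking:
    """Draw one exactly-PL-distributed ranking of a block.

    ``theta`` maps every item to its log-worth (dict or Series); latent
    utility = theta + Gumbel(0, 1); items are ranked by descending utility.
    """
    block = list(items_in_block)
    if len(block) < 2:
        raise ValidationError("need at least 2 items to rank")
    th = np.array([theta[it] for it in block], dtype=float)
    utility = th + rng.gumbel(0.0, 1.0, size=len(block))
    order = np.argsort(-utility, kind="stable")
    return Ranking(tuple(block[i] for i in order))


def _ranking_to_response(pid, block, ranking: Ranking, trait="overall") -> TricotResponse:
    """Invert response_to_ranking: recover best/worst slot labels."""
    slots = {it: POSITION_LABELS[i] for i, it in enumerate(block)}
    return TricotResponse(
        pid, trait, slots[ranking.ordered_items[0]], slots[ranking.ordered_items[-1]]
    )


@dataclass
class SimulatedTrial:
    truth: TrialTruth
    design: Design
    covariates: pd.DataFrame
    assignments: list[TriadAssignment]
    responses: list[TricotResponse]
    rankings: list[Ranking]


def simulate_trial(
    truth: TrialTruth,
    n_farms: int,
    seed: int = 0,
    covariate_names: tuple[str, ...] = ("cov1", "cov2", "cov3"),
    trait: str = "overall",
) -> SimulatedTrial:
    """Simulate a complete trial: balanced triadic design, farm covariates,
    PL rankings under the (possibly regime-dependent) truth, and the
    best/worst responses that reproduce those rankings exactly."""
    if n_farms < 1:
        raise ValidationError("n_farms must be >= 1")
    t = len(truth.items)
    if t < 3:
        raise ValidationError("need at least 3 items for triads")
    rng = np.random.default_rng(seed)
    design = random_balanced_design(
        t, n_farms, 3, seed=int(rng.integers(2**31)), items=list(truth.items)
    )
    names = list(covariate_names)
    if truth.regime_covariate is not None and truth.regime_covariate not in names:
        names.append(truth.regime_covariate)
    cov = pd.DataFrame(
        {
            "participant_id": [str(i + 1) for i in range(n_farms)],
            "lon": rng.uniform(-1, 1, n_farms),
            "lat": rng.uniform(-1, 1, n_farms),
        }
    )
    for name in names:
        cov[name] = rng.normal(0.0, 1.0, n_farms)

    theta_map_cache = {}
    assignments, responses, rankings = [], [], []
    for farm in range(n_farms):
        pid = str(farm + 1)
        block = design.blocks[farm]
        th = truth.theta_for(cov.iloc[farm])
        key = th.tobytes()
        if key not in theta_map_cache:
            theta_map_cache[key] = dict(zip(truth.items, th))
        ranking = sample_ranking_from_worths(theta_map_cache[key], block, rng)
        assignments.append(TriadAssignment(pid, farm + 1, tuple(block)))
        responses.append(_ranking_to_response(pid, block, ranking, trait))
        rankings.append(ranking)
    return SimulatedTrial(truth, design, cov, assignments, responses, rankings)


def power_simulation(
    n_farms: int,
    n_items: int = 12,
    effect_d: float = 0.8,
    n_sims: int = 25,
    alpha: float = 0.05,
    seed: int = 0,
    n_draws: int = 100,
) -> float:
    """Detection probability for one superior entry of effect size d.

    One item's latent location exceeds the others by ``effect_d`` latent
    noise standard deviations (Gumbel sd = pi/sqrt(6)).  A trial is a
    "detection" when the Bayesian-bootstrap reliability of that item against
    the best other item (by estimated worth) reaches 1 - alpha.  Returns the
    detected fraction over ``n_sims`` simulated trials.
    """
    from .plackett_luce import PlackettLuce

    if effect_d < 0:
        raise ValidationError("effect_d must be >= 0")
    rng = np.random.default_rng(seed)
    items = tuple(f"V{i + 1:02d}" for i in range(n_items))
    theta = np.zeros(n_items)
    theta[0] = effect_d * GUMBEL_SD
    theta -= theta.mean()
    truth = TrialTruth(items, tuple(theta))
    target = items[0]
    detections = 0
    for _ in range(n_sims):
        trial = simulate_trial(truth, n_farms, seed=int(rng.integers(2**31)))
        model = PlackettLuce(trial.rankings, items=list(items))
        # pseudo-item regularisation keeps separated trials (an entry never
        # beaten at large d) estimable so every bootstrap draw converges
        res = model.fit(check_connectivity=False, regularize=True)
        others = res.theta.drop(target)
        rival = others.idxmax()
        draws = res.bayesian_bootstrap(n_draws=n_draws, seed=int(rng.integers(2**31)))
        i, j = draws.items.index(target), draws.items.index(rival)
        reliability = float(np.mean(draws.theta[:, i] > draws.theta[:, j]))
        if reliability >= 1 - alpha:
            detections += 1
    return detections / n_sims
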