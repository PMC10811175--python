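"""A-optimal triadic incomplete block designs and trial cost-effectiveness.

A tricot trial assigns each participant (block) a subset of k = 3 entries out
of t.  Relative to a randomized complete block design (RCBD), such an
incomplete block design has relative statistical efficiency

    E = t/(t-1) * (k-1)/k

assuming plot heterogeneity plays no role.  Plot counts discounted by E give
"equivalent experimental units" (EEU), the basis for fair cost comparison
between trial designs: cost per EEU = total cost / EEU.

Designs are scored by the A-criterion: the average variance of elementary
treatment contrasts, computed from the information matrix
C = diag(r) - N N^T / k, where N is the item-by-block incidence matrix and
r the replication counts.  The canonical efficiency factor (harmonic mean of
the t-1 nonzero eigenvalues of C divided by the average replication) equals
the closed form E exactly when the design is balanced (a BIBD).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DisconnectedError, ValidationError

__all__ = [
    "DesignSpec",
    "Design",
    "CostSheet",
    "EfficiencyReport",
    "relative_efficiency",
    "equivalent_units",
    "cost_effectiveness",
    "cost_saving_percent",
    "readings_per_entry",
    "random_balanced_design",
    "generate_design",
    "a_score",
    "canonical_efficiency",
    "order_blocks_sequentially",
]


def relative_efficiency(t: int, k: int) -> float:
    """Closed-form relative efficiency of an incomplete block design with
    t treatments and block size k, versus a complete block design."""
    if t < 2:
        raise ValidationError(f"need at least 2 treatments, got t={t}")
    if not 2 <= k <= t:
        raise ValidationError(f"block size k={k} must satisfy 2 <= k <= t={t}")
    return (t / (t - 1)) * ((k - 1) / k)


def equivalent_units(n_units: int, t: int, k: int) -> float:
    """Equivalent experimental units: plot count discounted by the relative
    efficiency.  Full precision; round to the nearest integer for reporting."""
    if n_units < 1:
        raise ValidationError("n_units must be >= 1")
    return n_units * relative_efficiency(t, k)


def cost_effectiveness(total_cost: float, eeu: float) -> float:
    """Cost per equivalent experimental unit, rounded to 2 decimals."""
    if eeu <= 0:
        raise ValidationError("EEU must be positive")
    return round(total_cost / eeu, 2)


def cost_saving_percent(cost_a: float, cost_b: float) -> int:
    """Percent saving of option a over option b, rounded to integer percent."""
    if cost_b <= 0:
        raise ValidationError("reference cost must be positive")
    return round(100.0 * (1.0 - cost_a / cost_b))


def readings_per_entry(n_farms: int, n_items: int, k: int = 3) -> int:
    """Guaranteed minimum replication per entry in a balanced design:
    floor(n_farms * k / n_items)."""
    if n_farms < 1 or n_items < 1 or k < 1:
        raise ValidationError("all arguments must be positive")
    if n_items < k:
        raise ValidationError(f"n_items={n_items} must be >= block size k={k}")
    return (n_farms * k) // n_items


@dataclass(frozen=True)
class DesignSpec:
    """Specification for generating a triadic incomplete block design."""

    t: int
    b: int
    k: int = 3
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self):
        if self.t < self.k:
            raise ValidationError(f"t={self.t} must be >= block size k={self.k}")
        if self.b < 1:
            raise ValidationError("b must be >= 1")
        if self.k < 2:
            raise ValidationError("k must be >= 2")


class Design:
    """An ordered list of k-item blocks over a fixed item set."""

    def __init__(self, blocks, items=None):
        blocks = [tuple(bl) for bl in blocks]
        if not blocks:
            raise ValidationError("a design needs at least one block")
        k = len(blocks[0])
        for bl in blocks:
            if len(bl) != k or len(set(bl)) != k:
                raise ValidationError(f"block {bl!r} must hold {k} distinct items")
        self.blocks = blocks
        if items is None:
            items = sorted({i for bl in blocks for i in bl})
        self.items = list(items)
        self.k = k
        self._index = {it: i for i, it in enumerate(self.items)}
        unknown = {i for bl in blocks for i in bl} - set(self.items)
        if unknown:
            raise ValidationError(f"blocks mention unknown items: {sorted(unknown)}")

    @property
    def t(self) -> int:
        return len(self.items)

    @property
    def b(self) -> int:
        return len(self.blocks)

    def incidence(self) -> np.ndarray:
        """Item-by-block 0/1 incidence matrix N (t x b)."""
        N = np.zeros((self.t, self.b), dtype=float)
        for j, bl in enumerate(self.blocks):
            for it in bl:
                N[self._index[it], j] = 1.0
        return N

    def replication(self) -> pd.Series:
        N = self.incidence()
        return pd.Series(N.sum(axis=1).astype(int), index=self.items, name="r")

    def concurrence(self) -> pd.DataFrame:
        """lambda_ij = number of blocks where items i and j co-occur."""
        N = self.incidence()
        lam = N @ N.T
        np.fill_diagonal(lam, 0.0)
        return pd.DataFrame(lam.astype(int), index=self.items, columns=self.items)

    def information_matrix(self) -> np.ndarray:
        N = self.incidence()
        return np.diag(N.sum(axis=1)) - (N @ N.T) / self.k

    def connected_components(self) -> list[set[str]]:
        lam = self.concurrence().to_numpy()
        g = nx.from_numpy_array(lam)
        return [
            {self.items[i] for i in comp} for comp in nx.connected_components(g)
        ]

    def is_bibd(self) -> bool:
        """Equal replication and constant pairwise concurrence."""
        r = self.replication().to_numpy()
        lam = self.concurrence().to_numpy()
        off = lam[~np.eye(self.t, dtype=bool)]
        return np.ptp(r) == 0 and np.ptp(off) == 0

    def to_dict(self) -> dict:
        return {
            "spec": {"t": self.t, "b": self.b, "k": self.k},
            "items": self.items,
            "blocks": [list(bl) for bl in self.blocks],
            "order": list(range(1, self.b + 1)),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Design":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["blocks"], items=d.get("items"))

    def __eq__(self, other):
        return isinstance(other, Design) and self.blocks == other.blocks

    def __repr__(self):
        return f"Design(t={self.t}, b={self.b}, k={self.k})"


def _eigvals_c(design: Design) -> np.ndarray:
    return np.linalg.eigvalsh(design.information_matrix())


def _check_connected(design: Design) -> None:
    comps = design.connected_components()
    if len(comps) > 1:
        raise DisconnectedError(comps)


def a_score(design: Design) -> float:
    """Average variance of elementary contrasts, up to the error variance:
    the mean of reciprocals of the t-1 nonzero eigenvalues of C."""
    _check_connected(design)
    ev = _eigvals_c(design)[1:]  # drop the structural zero eigenvalue
    return float(np.mean(1.0 / ev))


def canonical_efficiency(design: Design) -> float:
    """Canonical efficiency factor: harmonic mean of the nonzero eigenvalues
    of C divided by the average replication.  Equals relative_efficiency(t,k)
    exactly for a BIBD."""
    _check_connected(design)
    ev = _eigvals_c(design)[1:]
    harmonic = (design.t - 1) / np.sum(1.0 / ev)
    r_bar = design.b * design.k / design.t
    return float(harmonic / r_bar)


def random_balanced_design(t: int, b: int, k: int = 3, seed: int = 0, items=None) -> Design:
    """Deal items round-robin into b blocks of k, in a random repetition
    order, so replication counts differ by at most one.  Within-block
    duplicates (possible at the seams of the deal) are repaired by swapping
    with later positions."""
    rng = np.random.default_rng(seed)
    if items is None:
        width = len(str(t))
        items = [f"V{str(i + 1).zfill(width)}" for i in range(t)]
    items = list(items)
    if len(items) != t:
        raise ValidationError("items list length must equal t")
    seq = []
    while len(seq) < b * k:
        seq.extend(rng.permutation(t))
    seq = seq[: b * k]
    # repair within-block duplicates by count-preserving swaps
    def block_of(pos):
        return pos // k

    for j in range(b):
        lo = j * k
        for pos in range(lo + 1, lo + k):
            if seq[pos] not in seq[lo:pos]:
                continue
            cur_block = set(seq[lo:pos])
            fixed = False
            # scan other positions for a swap keeping both blocks duplicate-free
            order = list(range(b * k))
            rng.shuffle(order)
            for swap in order:
                if block_of(swap) == j:
                    continue
                other_lo = block_of(swap) * k
                other = [seq[p] for p in range(other_lo, other_lo + k) if p != swap]
                if seq[swap] not in cur_block and seq[pos] not in other:
                    seq[pos], seq[swap] = seq[swap], seq[pos]
                    fixed = True
                    break
            if not fixed:  # degenerate tiny designs: replace, accepting imbalance
                choices = [i for i in range(t) if i not in cur_block]
                seq[pos] = int(rng.choice(choices))
    blocks = [tuple(items[seq[j * k + c]] for c in range(k)) for j in range(b)]
    return Design(blocks, items=items)


def _concurrence_spread(design: Design) -> int:
    lam = design.concurrence().to_numpy()
    off = lam[~np.eye(design.t, dtype=bool)]
    return int(off.max() - off.min())


def generate_design(spec: DesignSpec, items=None) -> Design:
    """Generate a near-A-optimal triadic incomplete block design.

    Random balanced initialisation (round-robin deal), then hill climbing on
    the A-score using pairwise swaps of items between blocks (which preserve
    replication balance), tie-broken on concurrence spread; best design over
    ``n_restarts`` restarts.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    best = None
    best_key = None
    for _ in range(max(1, spec.n_restarts)):
        d = random_balanced_design(
            spec.t, spec.b, spec.k, seed=int(rng.integers(2**31)), items=items
        )
        d = _hill_climb(d, rng)
        key = (a_score_safe(d), _concurrence_spread(d))
        if best_key is None or key < best_key:
            best, best_key = d, key
    return best


def a_score_safe(design: Design) -> float:
    """A-score, +inf for a disconnected design (used during optimisation)."""
    ev = _eigvals_c(design)[1:]
    if ev[0] < 1e-9:
        return math.inf
    return float(np.mean(1.0 / ev))


def _hill_climb(design: Design, rng, max_sweeps: int = 60) -> Design:
    """First-improvement local search over single-item swaps between blocks."""
    blocks = [list(bl) for bl in design.blocks]
    items = design.items
    cur = Design([tuple(bl) for bl in blocks], items=items)
    cur_key = (a_score_safe(cur), _concurrence_spread(cur))
    b, k = len(blocks), design.k
    positions = [(i, p) for i in range(b) for p in range(k)]
    for _ in range(max_sweeps):
        improved = False
        order = rng.permutation(len(positions))
        for oi in order:
            i, p = positions[oi]
            for j in range(b):
                if j == i:
                    continue
                for q in range(k):
                    x, y = blocks[i][p], blocks[j][q]
                    if x == y or y in blocks[i] or x in blocks[j]:
                        continue
                    blocks[i][p], blocks[j][q] = y, x
                    cand = Design([tuple(bl) for bl in blocks], items=items)
                    key = (a_score_safe(cand), _concurrence_spread(cand))
                    if key < cur_key:
                        cur, cur_key = cand, key
                        improved = True
                    else:
                        blocks[i][p], blocks[j][q] = x, y
            if improved:
                break
        if not improved:
            break
    return cur


def order_blocks_sequentially(design: Design) -> Design:
    """Reorder blocks so every prefix keeps per-item replication as even as
    possible: greedily append the block minimising the running replication
    spread (ties broken by original block index).  Block contents unchanged."""
    remaining = list(enumerate(design.blocks))
    counts = {it: 0 for it in design.items}
    ordered = []
    while remaining:
        best_idx = None
        best_key = None
        for pos, (orig_idx, bl) in enumerate(remaining):
            trial = dict(counts)
            for it in bl:
                trial[it] += 1
            vals = list(trial.values())
            key = (max(vals) - min(vals), max(vals), orig_idx)
            if best_key is None or key < best_key:
                best_key, best_idx = key, pos
        orig_idx, bl = remaining.pop(best_idx)
        for it in bl:
            counts[it] += 1
        ordered.append(bl)
    return Design(ordered, items=design.items)


@dataclass
class CostSheet:
    """Itemised trial cost ledger (category -> amount, in one currency)."""

    lines: dict[str, float]

    def __post_init__(self):
        for cat, amt in self.lines.items():
            if amt < 0:
                raise ValidationError(f"negative cost for {cat!r}")

    @property
    def total(self) -> float:
        return round(sum(self.lines.values()), 2)

    @classmethod
    def from_csv(cls, path) -> "CostSheet":
        df = pd.read_csv(path)
        for col in ("category", "amount"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing required column {col!r}")
        return cls(dict(zip(df["category"].astype(str), df["amount"].astype(float))))


@dataclass
class EfficiencyReport:
    """Efficiency and cost summary for one trial arm."""

    t: int
    k: int
    n_units: int
    total_cost: float | None = None
    E: float = field(init=False)
    eeu: float = field(init=False)
    cost_per_eeu: float | None = field(init=False, default=None)

    def __post_init__(self):
        self.E = relative_efficiency(self.t, self.k)
        self.eeu = equivalent_units(self.n_units, self.t, self.k)
        if self.total_cost is not None:
            self.cost_per_eeu = cost_effectiveness(self.total_cost, round(self.eeu))

    def to_dict(self) -> dict:
        d = {
            "t": self.t,
            "k": self.k,
            "n_units": self.n_units,
            "E": round(self.E, 2),
            "EEU": round(self.eeu),
        }
        if self.total_cost is not None:
            d["total_cost"] = round(self.total_cost, 2)
            d["cost_per_EEU"] = self.cost_per_eeu
        return d
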