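"""Simulated-annealing wrapper feature selection with a neural-network cost.

The selector searches over feature subsets of fixed cardinality ``nf``.
Each candidate subset is scored by a small 3-layer feedforward network
(one hidden layer) trained on a stratified split of the feature table;
the cost is the held-out misclassification rate, averaged over a few
restarts to damp initialization and split noise.  Classic simulated
annealing drives the search: a neighbor swaps one selected feature for
one unselected feature, downhill moves are always accepted, uphill moves
with probability exp(-dcost / T), and T decays geometrically.

The temperature scale must match the cost scale.  The classical settings
temp0 = 10, alpha = 0.99 correspond to a cost counted in misclassified
*samples*; with the cost expressed as a rate in [0, 1] the equivalent
temperature is temp0 / n_heldout.  :func:`rate_equivalent_temp0` applies
that conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import train_test_split

from .features import FEATURE_CODES

__all__ = [
    "AnnealingConfig",
    "SubsetState",
    "ann_cost",
    "neighbor",
    "anneal",
    "rate_equivalent_temp0",
]


@dataclass(frozen=True)
class AnnealingConfig:
    max_it: int = 50
    temp0: float = 10.0
    alpha: float = 0.99
    nf: int = 20
    hidden_units: int = 10
    seed: int = 0
    n_cost_repeats: int = 3
    moves_per_temp: int = 1  # neighbor proposals evaluated per temperature step
    test_fraction: float = 0.25
    ann_max_iter: int = 150  # quasi-Newton (L-BFGS) iterations per network fit

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if not 1 <= self.nf <= len(FEATURE_CODES):
            raise ValueError(f"nf must lie in [1, {len(FEATURE_CODES)}]")
        if self.max_it < 1 or self.moves_per_temp < 1 or self.n_cost_repeats < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass(frozen=True)
class SubsetState:
    """A fixed-cardinality feature subset with its wrapper cost."""

    selected: frozenset[str]
    cost: float = math.nan

    def codes(self) -> list[str]:
        return sorted(self.selected, key=lambda c: int(c[1:]))


@dataclass
class AnnealResult:
    best: SubsetState
    trace: pd.DataFrame = field(repr=False)


def rate_equivalent_temp0(temp0_counts: float, n_heldout: int) -> float:
    """Map a count-scale initial temperature to the rate-scale equivalent."""
    return temp0_counts / max(n_heldout, 1)


def _split_xy(table: pd.DataFrame, codes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    y = (table["label"].to_numpy() == "malignant").astype(int)
    if y.all() or not y.any():
        raise ValueError("feature table must contain both classes")
    return table[codes].to_numpy(dtype=float), y


def _fit_net(
    xtr: np.ndarray,
    ytr: np.ndarray,
    hidden: int,
    max_iter: int,
    rng: np.random.Generator,
    l2: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Train a 3-layer net (tanh hidden, logistic output) by L-BFGS.

    Returns the trained weights (W1, b1, w2, b2).  Cross-entropy loss
    with a small ridge penalty for conditioning; analytic gradients.
    """
    n, d = xtr.shape
    sizes = (d * hidden, hidden, hidden, 1)
    w0 = rng.normal(0.0, 1.0 / np.sqrt(d), size=sum(sizes))

    def unpack(w):
        i = 0
        out = []
        for s, shape in zip(sizes, ((d, hidden), (hidden,), (hidden,), ())):
            out.append(w[i : i + s].reshape(shape))
            i += s
        return out

    yt = ytr.astype(float)

    def loss_grad(w):
        w1, b1, w2, b2 = unpack(w)
        z = np.tanh(xtr @ w1 + b1)
        logit = z @ w2 + b2
        p = 1.0 / (1.0 + np.exp(-logit))
        eps = 1e-12
        loss = -np.mean(yt * np.log(p + eps) + (1 - yt) * np.log(1 - p + eps))
        loss += l2 * (np.sum(w1**2) + np.sum(w2**2))
        dlogit = (p - yt) / n
        gw2 = z.T @ dlogit + 2 * l2 * w2
        gb2 = dlogit.sum()
        dz = np.outer(dlogit, w2) * (1 - z**2)
        gw1 = xtr.T @ dz + 2 * l2 * w1
        gb1 = dz.sum(axis=0)
        return loss, np.concatenate([gw1.ravel(), gb1, gw2, [gb2]])

    res = minimize(loss_grad, w0, jac=True, method="L-BFGS-B", options=dict(maxiter=max_iter))
    return unpack(res.x)


def _net_predict(weights, x: np.ndarray) -> np.ndarray:
    w1, b1, w2, b2 = weights
    return (np.tanh(x @ w1 + b1) @ w2 + b2) > 0


class _CostEvaluator:
    """Wrapper cost on one fixed stratified split of the table.

    The train/test split and per-column standardization do not depend on
    the candidate subset, so they are computed once; each evaluation
    slices the subset's columns and trains ``n_cost_repeats`` networks
    from different seeded initializations on that common split.
    """

    def __init__(self, table: pd.DataFrame, cfg: AnnealingConfig, seed: int) -> None:
        x, y = _split_xy(table, FEATURE_CODES)
        self.cfg = cfg
        self.seed = seed % (2**31 - 1)
        self.splits = []
        self.n_heldout = 0
        for rep in range(cfg.n_cost_repeats):
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=cfg.test_fraction, stratify=y,
                random_state=(self.seed + 7919 * rep) % (2**31 - 1),
            )
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0)
            sd[sd == 0] = 1.0
            self.splits.append(((xtr - mu) / sd, (xte - mu) / sd, ytr, yte))
            self.n_heldout = len(yte)
        self.col = {c: k for k, c in enumerate(FEATURE_CODES)}

    def __call__(self, selected: frozenset[str]) -> float:
        cols = [self.col[c] for c in sorted(selected, key=lambda c: int(c[1:]))]
        errs = []
        for rep, (xtr, xte, ytr, yte) in enumerate(self.splits):
            rng = np.random.default_rng(self.seed * 1009 + rep)
            weights = _fit_net(xtr[:, cols], ytr, self.cfg.hidden_units, self.cfg.ann_max_iter, rng)
            errs.append(float(np.mean(_net_predict(weights, xte[:, cols]) != yte)))
        return float(np.mean(errs))


def ann_cost(
    subset: SubsetState | frozenset[str],
    table: pd.DataFrame,
    cfg: AnnealingConfig = AnnealingConfig(),
    seed: int | None = None,
) -> float:
    """Held-out misclassification rate of a 3-layer network on the subset.

    The network (nf inputs, ``cfg.hidden_units`` tanh hidden neurons, one
    logistic output) is trained by the L-BFGS quasi-Newton solver on a
    standardized stratified split; the rate is averaged over
    ``cfg.n_cost_repeats`` weight-initialization restarts on that split.
    Deterministic under a fixed seed.
    """
    selected = subset.selected if isinstance(subset, SubsetState) else subset
    evaluator = _CostEvaluator(table, cfg, cfg.seed if seed is None else seed)
    return evaluator(frozenset(selected))


def neighbor(subset: SubsetState | frozenset[str], rng: np.random.Generator) -> frozenset[str]:
    """Swap one uniformly chosen selected code for one unselected code."""
    selected = subset.selected if isinstance(subset, SubsetState) else subset
    pool = sorted(set(FEATURE_CODES) - selected, key=lambda c: int(c[1:]))
    if not pool:
        raise ValueError("subset already contains every feature; no neighbor exists")
    out_code = sorted(selected, key=lambda c: int(c[1:]))[rng.integers(len(selected))]
    in_code = pool[rng.integers(len(pool))]
    return (selected - {out_code}) | {in_code}


def anneal(table: pd.DataFrame, cfg: AnnealingConfig = AnnealingConfig()) -> AnnealResult:
    """Simulated-annealing search for the best nf-feature subset.

    Returns the best-so-far state (S_best) and a per-evaluation trace
    (iteration, temperature, candidate cost, current cost, best cost).
    The best-so-far cost is non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    cost = _CostEvaluator(table, cfg, seed=int(rng.integers(2**31 - 1)))

    current = frozenset(rng.choice(FEATURE_CODES, size=cfg.nf, replace=False).tolist())
    current_cost = cost(current)
    best = SubsetState(current, current_cost)

    temp = cfg.temp0
    rows = []
    for it in range(cfg.max_it):
        for _ in range(cfg.moves_per_temp):
            cand = neighbor(current, rng)
            cand_cost = cost(cand)
            delta = cand_cost - current_cost
            if delta <= 0 or (temp > 0 and rng.random() < math.exp(-delta / temp)):
                current, current_cost = cand, cand_cost
            if current_cost < best.cost:
                best = SubsetState(current, current_cost)
            rows.append(
                dict(iteration=it, temperature=temp, candidate_cost=cand_cost,
                     current_cost=current_cost, best_cost=best.cost)
            )
        temp *= cfg.alpha
    return AnnealResult(best=best, trace=pd.DataFrame(rows))
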