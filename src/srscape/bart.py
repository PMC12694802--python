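"""Bayesian Additive Regression Trees: sum-of-trees MCMC in logit space.

The response z (a bounded-logit transformed 87Sr/86Sr ratio) is modelled
as a sum of m regression trees plus Gaussian noise:

    z_i = sum_j g(x_i; T_j, M_j) + eps_i,    eps_i ~ N(0, sigma^2)

with a regularization prior that keeps each tree a weak learner:

* tree shape — a node at depth d splits with probability
  alpha * (1 + d)^(-beta); split variables are uniform over variables
  with at least one admissible cutpoint at the node, cutpoints uniform
  over the admissible grid values (both children must receive data);
* leaf values — mu ~ N(0, sigma_mu^2) with
  sigma_mu = (max z - min z) / (2 k sqrt(m)) after centring the response;
* noise — sigma^2 ~ nu * lambda / chi^2_nu, lambda calibrated so the
  prior puts mass q below a rough residual-sd estimate.

Sampling is Metropolis-within-Gibbs backfitting: each sweep visits
every tree, proposes one structural move (grow / prune / change / swap)
against the tree's partial residuals, accepts via the leaf-marginalized
likelihood, redraws leaf values from their conjugate normals, and
finally redraws sigma^2 from its scaled inverse-chi-square full
conditional.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import gzip
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .predictors import ColumnInfo, DesignMatrix
from .samples import BoundedLogitTransform

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class BartConfig:
    m: int = 200
    alpha: float = 0.95
    beta: float = 2.0
    k: float = 2.0
    nu: float = 3.0
    q: float = 0.90
    n_burn: int = 1000
    n_draw: int = 1000
    thin: int = 1
    move_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.40, 0.10)
    n_cutpoints: int = 100
    include_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.nu <= 0 or not 0.0 < self.q < 1.0:
            raise ValueError("nu must be > 0 and q in (0, 1)")
        if abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move_probs must sum to 1")


# ---------------------------------------------------------------------------
# Trees

class Node:
    __slots__ = ("var", "cut", "left", "right", "parent", "value", "idx")

    def __init__(self, idx: np.ndarray, parent: "Node | None" = None):
        self.var: int | None = None
        self.cut: float = 0.0
        self.left: Node | None = None
        self.right: Node | None = None
        self.parent = parent
        self.value: float = 0.0
        self.idx = idx  # training rows reaching this node (leaves only, kept fresh)

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d


class Tree:
    """One regression tree with training-row bookkeeping."""

    def __init__(self, n: int):
        self.root = Node(np.arange(n))

    def leaves(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.append(nd.right)
                stack.append(nd.left)
        return out

    def internals(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                out.append(nd)
                stack.append(nd.right)
                stack.append(nd.left)
        return out

    def prunable(self) -> list[Node]:
        """Internal nodes whose both children are leaves."""
        return [nd for nd in self.internals()
                if nd.left.is_leaf and nd.right.is_leaf]

    def fit_vector(self, n: int) -> np.ndarray:
        fit = np.empty(n)
        for leaf in self.leaves():
            fit[leaf.idx] = leaf.value
        return fit

    def subtree_idx(self, node: Node) -> np.ndarray:
        parts, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                parts.append(nd.idx)
            else:
                stack.append(nd.right)
                stack.append(nd.left)
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)

    def reassign(self, node: Node, X: np.ndarray, idx: np.ndarray) -> bool:
        """Re-partition ``idx`` below ``node``; False if any leaf empties."""
        if node.is_leaf:
            node.idx = idx
            return idx.size > 0
        mask = X[idx, node.var] <= node.cut
        ok_l = self.reassign(node.left, X, idx[mask])
        ok_r = self.reassign(node.right, X, idx[~mask])
        return ok_l and ok_r


# flattened snapshot: rows = nodes, cols = (var, cut, left, right, value)
def _flatten(tree: Tree) -> np.ndarray:
    rows: list[list[float]] = []

    def rec(node: Node) -> int:
        i = len(rows)
        rows.append([0.0] * 5)
        if node.is_leaf:
            rows[i] = [-1.0, 0.0, -1.0, -1.0, node.value]
        else:
            li = rec(node.left)
            ri = rec(node.right)
            rows[i] = [float(node.var), node.cut, float(li), float(ri), 0.0]
        return i

    rec(tree.root)
    return np.array(rows)


def _eval_flat(flat: np.ndarray, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        i, idx = stack.pop()
        var = int(flat[i, 0])
        if var < 0:
            out[idx] = flat[i, 4]
        else:
            mask = X[idx, var] <= flat[i, 1]
            stack.append((int(flat[i, 2]), idx[mask]))
            stack.append((int(flat[i, 3]), idx[~mask]))
    return out


# ---------------------------------------------------------------------------
# Conjugate pieces

def leaf_log_marginal(n: int, sum_r: float, sum_r2: float,
                      sigma: float, sigma_mu: float) -> float:
    """log integral of prod_i N(r_i | mu, sigma^2) N(mu | 0, sigma_mu^2) dmu.

    Closed form of the leaf-marginalized likelihood used by every MH
    step; n = 0 is the empty product (0).
    """
    if n == 0:
        return 0.0
    if not (np.isfinite(sum_r) and np.isfinite(sum_r2)):
        raise ValueError("non-finite leaf sums")
    v, vm = sigma * sigma, sigma_mu * sigma_mu
    denom = v + n * vm
    return (
        -0.5 * n * (_LOG2PI + math.log(v))
        + 0.5 * math.log(v / denom)
        - 0.5 * (sum_r2 - vm * sum_r * sum_r / denom) / v
    )


def leaf_posterior(n: int, sum_r: float, sigma: float, sigma_mu: float) -> tuple[float, float]:
    """Mean and sd of the leaf-value full conditional."""
    v, vm = sigma * sigma, sigma_mu * sigma_mu
    post_var = 1.0 / (1.0 / vm + n / v)
    return post_var * sum_r / v, math.sqrt(post_var)


def draw_sigma(residuals: np.ndarray, nu: float, lam: float,
               rng: np.random.Generator) -> float:
    """sigma^2 ~ (nu*lam + sum r^2) / chi^2_{nu+n} (scaled inverse-chi-square)."""
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    ssq = float(residuals @ residuals)
    return math.sqrt((nu * lam + ssq) / rng.chisquare(nu + n))


def calibrate_lambda(sigma_hat: float, nu: float, q: float) -> float:
    """lambda such that the sigma^2 prior puts mass q below sigma_hat^2."""
    return sigma_hat * sigma_hat * stats.chi2.ppf(1.0 - q, nu) / nu


# ---------------------------------------------------------------------------
# Moves and the MH kernel

@dataclass(frozen=True)
class GrowMove:
    leaf: Node
    var: int
    cut: float


@dataclass(frozen=True)
class PruneMove:
    node: Node


@dataclass(frozen=True)
class ChangeMove:
    node: Node
    var: int
    cut: float


@dataclass(frozen=True)
class SwapMove:
    parent: Node
    child: Node


class _Cutpoints:
    """Per-variable cutpoint grids (interior quantiles of training values)."""

    def __init__(self, X: np.ndarray, n_cutpoints: int):
        self.grids: list[np.ndarray] = []
        for j in range(X.shape[1]):
            uniq = np.unique(X[:, j])
            if uniq.size <= 1:
                self.grids.append(np.empty(0))
            elif uniq.size == 2 and set(np.round(uniq, 12)) <= {0.0, 1.0}:
                self.grids.append(np.array([0.5]))  # one-hot column
            else:
                k = min(n_cutpoints, uniq.size - 1)
                qs = np.quantile(X[:, j], np.arange(1, k + 1) / (k + 1))
                self.grids.append(np.unique(qs))

    def admissible(self, X: np.ndarray, idx: np.ndarray, var: int) -> np.ndarray:
        """Cutpoints splitting ``idx`` into two nonempty children on ``var``."""
        if idx.size < 2:
            return np.empty(0)
        x = X[idx, var]
        lo, hi = x.min(), x.max()
        g = self.grids[var]
        return g[(g >= lo) & (g < hi)]

    def admissible_vars(self, X: np.ndarray, idx: np.ndarray) -> list[int]:
        return [j for j in range(X.shape[1])
                if self.admissible(X, idx, j).size > 0]


def _log_p_split(depth: int, cfg: BartConfig) -> float:
    return math.log(cfg.alpha) - cfg.beta * math.log1p(depth)


def _log_1m_p_split(depth: int, cfg: BartConfig) -> float:
    return math.log1p(-cfg.alpha * (1.0 + depth) ** (-cfg.beta))


def _leaf_stats(r: np.ndarray, idx: np.ndarray) -> tuple[int, float, float]:
    ri = r[idx]
    return idx.size, float(ri.sum()), float(ri @ ri)


def _rule_log_prior(tree: Tree, X: np.ndarray, cuts: _Cutpoints, node: Node) -> float:
    """log prior of the (var, cut) rule at an internal node, given its data."""
    idx = tree.subtree_idx(node)
    adm = cuts.admissible_vars(X, idx)
    n_cuts = cuts.admissible(X, idx, node.var).size
    if node.var not in adm or n_cuts == 0:
        return -math.inf
    return -math.log(len(adm)) - math.log(n_cuts)


def mh_log_ratio(tree: Tree, move, X: np.ndarray, r: np.ndarray,
                 sigma: float, sigma_mu: float, cfg: BartConfig,
                 cuts: _Cutpoints) -> float:
    """Log MH acceptance ratio (prior x marginal-likelihood x proposal) for a move.

    Grow and its reversing prune yield ratios summing to zero by
    construction (detailed balance).
    """
    p_grow, p_prune, _, _ = cfg.move_probs

    if isinstance(move, GrowMove):
        leaf = move.leaf
        if not leaf.is_leaf:
            raise ValueError("grow target is not a leaf")
        idx = leaf.idx
        adm_vars = cuts.admissible_vars(X, idx)
        if not adm_vars:
            raise ValueError("grow proposed on a node with no admissible cutpoints")
        adm_cuts = cuts.admissible(X, idx, move.var)
        if adm_cuts.size == 0:
            raise ValueError("no admissible cutpoints on the proposed variable")
        d = leaf.depth
        mask = X[idx, move.var] <= move.cut
        idx_l, idx_r = idx[mask], idx[~mask]

        log_prior = (
            _log_p_split(d, cfg)
            + _log_1m_p_split(d + 1, cfg) * 2
            - _log_1m_p_split(d, cfg)
            - math.log(len(adm_vars)) - math.log(adm_cuts.size)
        )
        ml_new = (leaf_log_marginal(*_leaf_stats(r, idx_l), sigma, sigma_mu)
                  + leaf_log_marginal(*_leaf_stats(r, idx_r), sigma, sigma_mu))
        ml_old = leaf_log_marginal(*_leaf_stats(r, idx), sigma, sigma_mu)

        n_leaves = len(tree.leaves())
        prunable_now = tree.prunable()
        n_prunable_after = len(prunable_now) + 1
        parent = leaf.parent
        if parent is not None:
            sib = parent.right if parent.left is leaf else parent.left
            if sib.is_leaf:
                n_prunable_after -= 1  # parent stops being prunable
        log_fwd = (math.log(p_grow) - math.log(n_leaves)
                   - math.log(len(adm_vars)) - math.log(adm_cuts.size))
        log_rev = math.log(p_prune) - math.log(n_prunable_after)
        return log_prior + (ml_new - ml_old) + (log_rev - log_fwd)

    if isinstance(move, PruneMove):
        node = move.node
        if node.is_leaf:
            raise ValueError("prune proposed on a leaf (root-only tree?)")
        if not (node.left.is_leaf and node.right.is_leaf):
            raise ValueError("prune target must have two leaf children")
        idx = np.concatenate([node.left.idx, node.right.idx])
        adm_vars = cuts.admissible_vars(X, idx)
        adm_cuts = cuts.admissible(X, idx, node.var)
        d = node.depth

        log_prior = -(
            _log_p_split(d, cfg)
            + _log_1m_p_split(d + 1, cfg) * 2
            - _log_1m_p_split(d, cfg)
            - math.log(len(adm_vars)) - math.log(adm_cuts.size)
        )
        ml_new = leaf_log_marginal(*_leaf_stats(r, idx), sigma, sigma_mu)
        ml_old = (leaf_log_marginal(*_leaf_stats(r, node.left.idx), sigma, sigma_mu)
                  + leaf_log_marginal(*_leaf_stats(r, node.right.idx), sigma, sigma_mu))

        n_prunable = len(tree.prunable())
        n_leaves_after = len(tree.leaves()) - 1
        log_fwd = math.log(p_prune) - math.log(n_prunable)
        log_rev = (math.log(p_grow) - math.log(n_leaves_after)
                   - math.log(len(adm_vars)) - math.log(adm_cuts.size))
        return log_prior + (ml_new - ml_old) + (log_rev - log_fwd)

    if isinstance(move, ChangeMove):
        node = move.node
        idx = np.concatenate([node.left.idx, node.right.idx])
        mask = X[idx, move.var] <= move.cut
        idx_l, idx_r = idx[mask], idx[~mask]
        if idx_l.size == 0 or idx_r.size == 0:
            return -math.inf
        ml_new = (leaf_log_marginal(*_leaf_stats(r, idx_l), sigma, sigma_mu)
                  + leaf_log_marginal(*_leaf_stats(r, idx_r), sigma, sigma_mu))
        ml_old = (leaf_log_marginal(*_leaf_stats(r, node.left.idx), sigma, sigma_mu)
                  + leaf_log_marginal(*_leaf_stats(r, node.right.idx), sigma, sigma_mu))
        # proposal and rule prior are symmetric: the admissible set at the
        # node depends only on its (unchanged) data
        return ml_new - ml_old

    if isinstance(move, SwapMove):
        parent, child = move.parent, move.child
        idx = tree.subtree_idx(parent)
        old_rules = [(nd, nd.var, nd.cut) for nd in _subtree_internals(parent)]
        prior_old = sum(_rule_log_prior(tree, X, cuts, nd)
                        for nd in _subtree_internals(parent))
        ml_old = sum(
            leaf_log_marginal(*_leaf_stats(r, lf.idx), sigma, sigma_mu)
            for lf in _subtree_leaves(parent)
        )
        # trial swap
        parent.var, parent.cut, child.var, child.cut = (
            child.var, child.cut, parent.var, parent.cut)
        ok = tree.reassign(parent, X, idx)
        if not ok:
            _restore_swap(parent, child, old_rules, tree, X, idx)
            return -math.inf
        prior_new = sum(_rule_log_prior(tree, X, cuts, nd)
                        for nd in _subtree_internals(parent))
        ml_new = sum(
            leaf_log_marginal(*_leaf_stats(r, lf.idx), sigma, sigma_mu)
            for lf in _subtree_leaves(parent)
        )
        _restore_swap(parent, child, old_rules, tree, X, idx)
        if not np.isfinite(prior_new):
            return -math.inf
        return (prior_new - prior_old) + (ml_new - ml_old)

    raise TypeError(f"unknown move {move!r}")


def _subtree_internals(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf:
            out.append(nd)
            stack.append(nd.right)
            stack.append(nd.left)
    return out


def _subtree_leaves(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.append(nd.right)
            stack.append(nd.left)
    return out


def _restore_swap(parent: Node, child: Node, old_rules, tree: Tree,
                  X: np.ndarray, idx: np.ndarray) -> None:
    for nd, var, cut in old_rules:
        nd.var, nd.cut = var, cut
    tree.reassign(parent, X, idx)


def _apply_grow(tree: Tree, move: GrowMove, X: np.ndarray) -> None:
    leaf = move.leaf
    mask = X[leaf.idx, move.var] <= move.cut
    leaf.var, leaf.cut = move.var, move.cut
    leaf.left = Node(leaf.idx[mask], parent=leaf)
    leaf.right = Node(leaf.idx[~mask], parent=leaf)
    leaf.idx = np.empty(0, dtype=int)


def _apply_prune(tree: Tree, move: PruneMove) -> None:
    node = move.node
    node.idx = np.concatenate([node.left.idx, node.right.idx])
    node.var, node.left, node.right = None, None, None


def _apply_change(tree: Tree, move: ChangeMove, X: np.ndarray) -> None:
    node = move.node
    idx = np.concatenate([node.left.idx, node.right.idx])
    node.var, node.cut = move.var, move.cut
    mask = X[idx, node.var] <= node.cut
    node.left.idx, node.right.idx = idx[mask], idx[~mask]


def _apply_swap(tree: Tree, move: SwapMove, X: np.ndarray) -> None:
    parent, child = move.parent, move.child
    idx = tree.subtree_idx(parent)
    parent.var, parent.cut, child.var, child.cut = (
        child.var, child.cut, parent.var, parent.cut)
    tree.reassign(parent, X, idx)


def propose_move(tree: Tree, X: np.ndarray, cuts: _Cutpoints, cfg: BartConfig,
                 rng: np.random.Generator):
    """Draw one move proposal, or None if the drawn move type is inadmissible."""
    kind = rng.choice(4, p=cfg.move_probs)
    if kind == 0:  # grow
        leaves = tree.leaves()
        leaf = leaves[rng.integers(len(leaves))]
        adm_vars = cuts.admissible_vars(X, leaf.idx)
        if not adm_vars:
            return None
        var = adm_vars[rng.integers(len(adm_vars))]
        adm_cuts = cuts.admissible(X, leaf.idx, var)
        return GrowMove(leaf, var, float(adm_cuts[rng.integers(adm_cuts.size)]))
    if kind == 1:  # prune
        cand = tree.prunable()
        if not cand:
            return None
        return PruneMove(cand[rng.integers(len(cand))])
    if kind == 2:  # change
        cand = tree.prunable()  # internal nodes with two leaf children
        if not cand:
            return None
        node = cand[rng.integers(len(cand))]
        idx = np.concatenate([node.left.idx, node.right.idx])
        adm_vars = cuts.admissible_vars(X, idx)
        if not adm_vars:
            return None
        var = adm_vars[rng.integers(len(adm_vars))]
        adm_cuts = cuts.admissible(X, idx, var)
        return ChangeMove(node, var, float(adm_cuts[rng.integers(adm_cuts.size)]))
    # swap
    pairs = [(p, c) for p in tree.internals()
             for c in (p.left, p.right) if not c.is_leaf]
    if not pairs:
        return None
    p, c = pairs[rng.integers(len(pairs))]
    return SwapMove(p, c)


def _apply(tree: Tree, move, X: np.ndarray) -> None:
    if isinstance(move, GrowMove):
        _apply_grow(tree, move, X)
    elif isinstance(move, PruneMove):
        _apply_prune(tree, move)
    elif isinstance(move, ChangeMove):
        _apply_change(tree, move, X)
    elif isinstance(move, SwapMove):
        _apply_swap(tree, move, X)


# ---------------------------------------------------------------------------
# Posterior container

@dataclass
class BartPosterior:
    """Retained draws of the sum-of-trees ensemble.

    ``tree_draws[d]`` is a list of m flattened trees (node arrays);
    ``sigma_draws[d]`` the residual sd of draw d (logit units).
    ``split_counts`` tallies splits per design column over all retained
    draws.  Training metadata lets predictions return to ratio units.
    """

    config: BartConfig
    column_names: list[str]
    transform: BoundedLogitTransform
    y_center: float
    sigma_mu: float
    lam: float
    tree_draws: list[list[np.ndarray]]
    sigma_draws: np.ndarray
    split_counts: np.ndarray
    type_levels: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return len(self.tree_draws)

    # -- serialization -----------------------------------------------------
    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Write the posterior as a versioned gzip-compressed JSON container."""
        payload = {
            "format": "srscape-bart-posterior",
            "version": self.FORMAT_VERSION,
            "config": asdict(self.config),
            "column_names": self.column_names,
            "transform": {"lower": self.transform.lower,
                          "upper": self.transform.upper,
                          "epsilon": self.transform.epsilon},
            "y_center": self.y_center,
            "sigma_mu": self.sigma_mu,
            "lam": self.lam,
            "type_levels": list(self.type_levels),
            "sigma_draws": self.sigma_draws.tolist(),
            "split_counts": self.split_counts.tolist(),
            "tree_draws": [[t.tolist() for t in draw] for draw in self.tree_draws],
        }
        # mtime=0 keeps the container byte-identical across runs
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(json.dumps(payload).encode("utf-8"))

    @classmethod
    def load(cls, path) -> "BartPosterior":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "srscape-bart-posterior":
            raise ValueError("not a srscape posterior file")
        if payload["version"] > cls.FORMAT_VERSION:
            raise ValueError("posterior file written by a newer version")
        cfgd = payload["config"]
        cfgd["move_probs"] = tuple(cfgd["move_probs"])
        return cls(
            config=BartConfig(**cfgd),
            column_names=payload["column_names"],
            transform=BoundedLogitTransform(**payload["transform"]),
            y_center=payload["y_center"],
            sigma_mu=payload["sigma_mu"],
            lam=payload["lam"],
            tree_draws=[[np.array(t) for t in draw] for draw in payload["tree_draws"]],
            sigma_draws=np.array(payload["sigma_draws"]),
            split_counts=np.array(payload["split_counts"]),
            type_levels=tuple(payload["type_levels"]),
        )


# ---------------------------------------------------------------------------
# Fitting

def fit_bart(X: DesignMatrix | np.ndarray, z: Sequence[float],
             cfg: BartConfig = BartConfig(),
             transform: BoundedLogitTransform | None = None) -> BartPosterior:
    """Fit the sum-of-trees model to logit responses by backfitting MCMC.

    Runs ``n_burn + n_draw * thin`` sweeps; each sweep proposes one
    structural move per tree (accepted by Metropolis-Hastings with the
    leaf-marginalized likelihood), redraws all leaf values from their
    normal full conditionals, then redraws sigma.  Retains ``n_draw``
    post-burn-in states.  Deterministic given ``cfg.seed``.
    """
    if isinstance(X, DesignMatrix):
        column_names = X.column_names
        type_levels = X.type_levels
        Xmat = X.X
    else:
        Xmat = np.asarray(X, dtype=float)
        column_names = [f"x{j}" for j in range(Xmat.shape[1])]
        type_levels = ()
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite response values")
    n, p = Xmat.shape
    if z.shape != (n,):
        raise ValueError("rows of X must match z")
    if n < 2:
        raise ValueError("need at least 2 observations")

    cuts = _Cutpoints(Xmat, cfg.n_cutpoints)
    if all(g.size == 0 for g in cuts.grids):
        raise ValueError("degenerate design: no admissible cutpoints on any variable")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    y_center = float(z.mean())
    y = z - y_center
    y_range = float(y.max() - y.min())
    sigma_mu = max(y_range / (2.0 * cfg.k * math.sqrt(cfg.m)), 1e-10)

    # lambda calibration from a saturated least-squares residual sd when p < n
    if p < n:
        A = np.column_stack([np.ones(n), Xmat])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        dof = max(n - A.shape[1], 1)
        sigma_hat = math.sqrt(float(resid @ resid) / dof)
    else:
        sigma_hat = float(np.std(y, ddof=1))
    sigma_hat = max(sigma_hat, 1e-8)
    lam = calibrate_lambda(sigma_hat, cfg.nu, cfg.q)

    trees = [Tree(n) for _ in range(cfg.m)]
    fits = np.zeros((cfg.m, n))
    total_fit = np.zeros(n)
    sigma = sigma_hat

    tree_draws: list[list[np.ndarray]] = []
    sigma_draws: list[float] = []
    split_counts = np.zeros(p, dtype=np.int64)

    n_sweeps = cfg.n_burn + cfg.n_draw * cfg.thin
    for sweep in range(n_sweeps):
        for j, tree in enumerate(trees):
            r = y - total_fit + fits[j]
            move = propose_move(tree, Xmat, cuts, cfg, rng)
            if move is not None:
                log_ratio = mh_log_ratio(tree, move, Xmat, r, sigma, sigma_mu, cfg, cuts)
                if math.log(rng.uniform()) < log_ratio:
                    _apply(tree, move, Xmat)
            # conjugate leaf draws, ordered by tree traversal
            new_fit = np.empty(n)
            for leaf in tree.leaves():
                mean, sd = leaf_posterior(leaf.idx.size, float(r[leaf.idx].sum()),
                                          sigma, sigma_mu)
                leaf.value = mean + sd * rng.standard_normal()
                new_fit[leaf.idx] = leaf.value
            total_fit += new_fit - fits[j]
            fits[j] = new_fit
        sigma = draw_sigma(y - total_fit, cfg.nu, lam, rng)

        if sweep >= cfg.n_burn and (sweep - cfg.n_burn) % cfg.thin == 0:
            snapshot = [_flatten(t) for t in trees]
            tree_draws.append(snapshot)
            sigma_draws.append(sigma)
            for flat in snapshot:
                internal = flat[:, 0] >= 0
                if internal.any():
                    cols, counts = np.unique(flat[internal, 0].astype(int),
                                             return_counts=True)
                    split_counts[cols] += counts

    return BartPosterior(
        config=cfg, column_names=list(column_names),
        transform=transform or BoundedLogitTransform(),
        y_center=y_center, sigma_mu=sigma_mu, lam=lam,
        tree_draws=tree_draws, sigma_draws=np.array(sigma_draws),
        split_counts=split_counts, type_levels=tuple(type_levels),
    )


# ---------------------------------------------------------------------------
# Prediction and importance

def predict_draws(post: BartPosterior, X_new: DesignMatrix | np.ndarray,
                  include_noise: bool = False,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Posterior draws of the regression function at new rows (logit units).

    Returns an array shaped (n_locations, n_draws).  With
    ``include_noise`` each draw adds N(0, sigma_draw^2) observation
    noise, turning mean-function draws into posterior-predictive draws.
    """
    if isinstance(X_new, DesignMatrix):
        if X_new.column_names != post.column_names:
            raise ValueError("design columns do not match the fitted posterior")
        Xmat = X_new.X
    else:
        Xmat = np.asarray(X_new, dtype=float)
        if Xmat.shape[1] != len(post.column_names):
            raise ValueError("design columns do not match the fitted posterior")
    if include_noise and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)

    n_new = Xmat.shape[0]
    out = np.empty((n_new, post.n_draws))
    for d, trees in enumerate(post.tree_draws):
        acc = np.full(n_new, post.y_center)
        for flat in trees:
            acc += _eval_flat(flat, Xmat)
        if include_noise:
            acc = acc + post.sigma_draws[d] * rng.standard_normal(n_new)
        out[:, d] = acc
    return out


def variable_importance(post: BartPosterior) -> dict[str, float]:
    """Split-frequency importance: splits per column / total splits."""
    total = int(post.split_counts.sum())
    if total == 0:
        warnings.warn("posterior contains no splits (all stumps); importance is zero")
        return {name: 0.0 for name in post.column_names}
    props = post.split_counts / total
    return {name: float(p) for name, p in zip(post.column_names, props)}
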