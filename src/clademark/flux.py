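"""Ancestral gene-content reconstruction on a fixed rooted species tree.

Two desk-scale reconstructions of presence/absence history are provided:
Fitch small parsimony (minimum gain+loss changes) and a two-state
continuous-time Markov model (gain rate g for 0->1, loss rate l for 1->0)
solved by Felsenstein pruning, giving marginal presence posteriors at every
node and expected gain/loss events per branch.

Neither method reconciles gene trees against the species tree: a horizontal
transfer into a clade is indistinguishable here from an independent gain on
the recipient branch.  Rates can be estimated from a profile collection by a
coarse grid followed by golden-section refinement of the pruning likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "BinaryProfile",
    "MkModel",
    "fitch_min_changes",
    "mk_ancestral",
    "branch_events",
    "fit_mk",
    "simulate_binary_profiles",
]


@dataclass
class BinaryProfile:
    """Presence (1) / absence (0) of one gene family across genomes."""

    id: str
    states: dict[str, int]

    def __post_init__(self):
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"profile {self.id}: non-binary states {bad}")

    @classmethod
    def from_counts(cls, fam_id: str, counts: dict[str, int]) -> "BinaryProfile":
        return cls(fam_id, {g: 1 if c >= 1 else 0 for g, c in counts.items()})


@dataclass
class MkModel:
    """Two-state gain/loss chain: rates per branch-length unit, root prior pi=P(present)."""

    gain: float = 1.0
    loss: float = 1.0
    root_prior: Optional[float] = None  # None -> stationary gain/(gain+loss)

    def __post_init__(self):
        if self.gain < 0 or self.loss < 0:
            raise ValueError("rates must be nonnegative")
        if self.gain + self.loss == 0 and self.root_prior is None:
            raise ValueError("zero total rate needs an explicit root prior")
        if self.root_prior is not None and not (0.0 <= self.root_prior <= 1.0):
            raise ValueError("root prior outside [0, 1]")

    @property
    def prior(self) -> np.ndarray:
        if self.root_prior is not None:
            return np.array([1.0 - self.root_prior, self.root_prior])
        r = self.gain + self.loss
        return np.array([self.loss / r, self.gain / r])

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[i, j] = P(state j at branch bottom | state i at top), branch length t."""
        r = self.gain + self.loss
        if r == 0 or t == 0:
            return np.eye(2)
        e = math.exp(-r * t)
        pi1 = self.gain / r
        pi0 = self.loss / r
        return np.array(
            [[pi0 + pi1 * e, pi1 * (1.0 - e)], [pi0 * (1.0 - e), pi1 + pi0 * e]]
        )


# ---------------------------------------------------------------------------
# tree plumbing
# ---------------------------------------------------------------------------


def _rooted_nodes(tree: PhyloTree):
    """Postorder nodes of a rooted binary tree with stable node ids."""
    dtree = tree.dendropy_tree
    root = dtree.seed_node
    if len(root.child_nodes()) != 2:
        raise ValueError("tree must be rooted (root with exactly two children)")
    ids = {}
    k = 0
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            ids[nd] = nd.taxon.label
        else:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be binary")
            ids[nd] = nd.label if nd.label else f"I{k}"
            k += 1
    return dtree, root, ids


def _leaf_states(tree: PhyloTree, profile: BinaryProfile) -> dict[str, int]:
    missing = sorted(tree.leaf_labels - set(profile.states))
    if missing:
        raise ValueError(f"profile {profile.id}: unlabeled leaves {missing}")
    return {lf: int(profile.states[lf]) for lf in tree.leaf_labels}


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def fitch_min_changes(
    tree: PhyloTree, profile: BinaryProfile
) -> tuple[int, dict[str, int]]:
    """Fitch small parsimony: minimum change count and one optimal labeling.

    Ambiguous internal nodes resolve to absence (state 0) — a deliberate,
    documented tie-break that never increases the change count.
    """
    dtree, root, ids = _rooted_nodes(tree)
    states = _leaf_states(tree, profile)
    sets: dict = {}
    changes = 0
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = {states[ids[nd]]}
        else:
            a, b = (sets[c] for c in nd.child_nodes())
            inter = a & b
            if inter:
                sets[nd] = inter
            else:
                sets[nd] = a | b
                changes += 1
    labeling: dict[str, int] = {}
    assigned: dict = {}
    for nd in dtree.preorder_node_iter():
        if nd is root:
            s = 0 if 0 in sets[nd] else 1
        else:
            p = assigned[nd.parent_node]
            if p in sets[nd]:
                s = p
            else:
                s = 0 if 0 in sets[nd] else 1
        assigned[nd] = s
        labeling[ids[nd]] = s
    return changes, labeling


# ---------------------------------------------------------------------------
# Mk pruning
# ---------------------------------------------------------------------------


class _MkEngine:
    """Pruning down/up passes for one profile under one model."""

    def __init__(self, tree: PhyloTree, profile: BinaryProfile, model: MkModel):
        self.dtree, self.root, self.ids = _rooted_nodes(tree)
        states = _leaf_states(tree, profile)
        self.model = model
        self.P = {}
        self.down = {}
        for nd in self.dtree.postorder_node_iter():
            if nd is not self.root:
                self.P[nd] = model.transition_matrix(nd.edge.length or 0.0)
            if nd.is_leaf():
                v = np.zeros(2)
                v[states[self.ids[nd]]] = 1.0
                self.down[nd] = v
            else:
                v = np.ones(2)
                for c in nd.child_nodes():
                    v = v * (self.P[c] @ self.down[c])
                self.down[nd] = v
        self.likelihood = float(model.prior @ self.down[self.root])
        if self.likelihood <= 0:
            raise ValueError("data has zero likelihood under the model")
        self.loglik = math.log(self.likelihood)
        self.up = {self.root: model.prior.copy()}
        for nd in self.dtree.preorder_node_iter():
            for c in nd.child_nodes():
                sib_msg = np.ones(2)
                for s in nd.child_nodes():
                    if s is not c:
                        sib_msg = sib_msg * (self.P[s] @ self.down[s])
                self.up[c] = (self.up[nd] * sib_msg) @ self.P[c]

    def posteriors(self) -> dict[str, float]:
        out = {}
        for nd in self.dtree.preorder_node_iter():
            w = self.up[nd] * self.down[nd]
            out[self.ids[nd]] = float(w[1] / w.sum())
        return out

    def branch_joint(self, child) -> np.ndarray:
        """J[i, j] = P(parent = i, child = j | data) for the branch above ``child``."""
        parent = child.parent_node
        sib_msg = np.ones(2)
        for s in parent.child_nodes():
            if s is not child:
                sib_msg = sib_msg * (self.P[s] @ self.down[s])
        J = (
            (self.up[parent] * sib_msg)[:, None]
            * self.P[child]
            * self.down[child][None, :]
        )
        return J / self.likelihood


def mk_ancestral(
    tree: PhyloTree, profile: BinaryProfile, model: MkModel
) -> tuple[pd.Series, float]:
    """Marginal P(present) at every node and the data log-likelihood."""
    eng = _MkEngine(tree, profile, model)
    post = pd.Series(eng.posteriors(), name=f"P_present[{profile.id}]")
    return post, eng.loglik


def branch_events(
    tree: PhyloTree,
    profile: BinaryProfile,
    model: Optional[MkModel] = None,
    mode: str = "parsimony",
) -> pd.DataFrame:
    """Per-branch gain (0->1) and loss (1->0) events for one profile.

    ``mode='parsimony'`` counts transitions along the Fitch-optimal labeling;
    ``mode='expected'`` sums posterior endpoint-transition probabilities under
    the Mk model.  Branches are named by their child node.
    """
    dtree, root, ids = _rooted_nodes(tree)
    rows = []
    if mode == "parsimony":
        _, labeling = fitch_min_changes(tree, profile)
        for nd in dtree.preorder_node_iter():
            if nd is root:
                continue
            p, c = labeling[ids[nd.parent_node]], labeling[ids[nd]]
            rows.append(
                {"branch": ids[nd], "gain": int(p == 0 and c == 1), "loss": int(p == 1 and c == 0)}
            )
    elif mode == "expected":
        if model is None:
            raise ValueError("expected mode requires an MkModel")
        eng = _MkEngine(tree, profile, model)
        for nd in dtree.preorder_node_iter():
            if nd is root:
                continue
            J = eng.branch_joint(nd)
            rows.append({"branch": ids[nd], "gain": float(J[0, 1]), "loss": float(J[1, 0])})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).set_index("branch")


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------


def _total_loglik(tree, profiles, gain, loss) -> float:
    """Summed pruning log-likelihood, vectorized across profiles."""
    model = MkModel(gain=gain, loss=loss)
    dtree, root, ids = _rooted_nodes(tree)
    F = len(profiles)
    down: dict = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            v = np.zeros((F, 2))
            lf = ids[nd]
            for k, p in enumerate(profiles):
                try:
                    v[k, int(p.states[lf])] = 1.0
                except KeyError:
                    raise ValueError(f"profile {p.id}: unlabeled leaves ['{lf}']") from None
            down[nd] = v
        else:
            v = np.ones((F, 2))
            for c in nd.child_nodes():
                P = model.transition_matrix(c.edge.length or 0.0)
                v = v * (down.pop(c) @ P.T)
            down[nd] = v
    lk = down[root] @ model.prior
    if (lk <= 0).any():
        raise ValueError("data has zero likelihood under the model")
    return float(np.log(lk).sum())


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section search for the maximum of a unimodal f on [lo, hi]."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_mk(
    tree: PhyloTree,
    profiles: Sequence[BinaryProfile],
    rate_grid: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
) -> tuple[MkModel, float]:
    """Estimate (gain, loss) by maximum likelihood over a profile collection.

    A log-spaced grid locates the basin; golden-section line searches on the
    log-rates then refine each rate in turn (coordinate ascent) to ``tol``.
    The root prior is the stationary distribution of the fitted rates.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if rate_grid is None:
        rate_grid = np.logspace(-2, 1.5, 8)
    best = None
    for g in rate_grid:
        for l in rate_grid:
            ll = _total_loglik(tree, profiles, g, l)
            if best is None or ll > best[0]:
                best = (ll, g, l)
    _, g, l = best
    span = 1.5  # search window around the grid optimum, in log-rate units
    for _ in range(6):
        lg = _golden_max(
            lambda x: _total_loglik(tree, profiles, math.exp(x), l),
            math.log(g) - span, math.log(g) + span, tol,
        )
        g = math.exp(lg)
        ll_ = _golden_max(
            lambda x: _total_loglik(tree, profiles, g, math.exp(x)),
            math.log(l) - span, math.log(l) + span, tol,
        )
        l = math.exp(ll_)
    model = MkModel(gain=g, loss=l)
    return model, _total_loglik(tree, profiles, g, l)


# ---------------------------------------------------------------------------
# forward simulation (planted truth for recovery tests)
# ---------------------------------------------------------------------------


def simulate_binary_profiles(
    tree: PhyloTree, model: MkModel, n_families: int, seed: int = 0
) -> tuple[list[BinaryProfile], pd.DataFrame]:
    """Simulate presence/absence profiles by drawing node states down the tree.

    States are drawn exactly from the endpoint transition matrices (no path
    detail), so the returned per-branch truth counts endpoint transitions —
    the quantity branch_events' expected mode estimates.  Returns the
    profiles and a branches x (gain, loss) truth table of total counts.
    """
    rng = np.random.default_rng(seed)
    dtree, root, ids = _rooted_nodes(tree)
    branch_ids = [ids[nd] for nd in dtree.preorder_node_iter() if nd is not root]
    truth = pd.DataFrame(0.0, index=branch_ids, columns=["gain", "loss"])
    prior = model.prior
    profiles = []
    for k in range(n_families):
        state = {root: int(rng.random() < prior[1])}
        leaf_states = {}
        for nd in dtree.preorder_node_iter():
            if nd is root:
                continue
            P = model.transition_matrix(nd.edge.length or 0.0)
            s = int(rng.random() < P[state[nd.parent_node], 1])
            state[nd] = s
            p = state[nd.parent_node]
            if p == 0 and s == 1:
                truth.at[ids[nd], "gain"] += 1
            elif p == 1 and s == 0:
                truth.at[ids[nd], "loss"] += 1
            if nd.is_leaf():
                leaf_states[ids[nd]] = s
        profiles.append(BinaryProfile(f"fam{k + 1}", leaf_states))
    return profiles, truth
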