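"""Two-state Equal-Rates Mk model on rooted trees.

Used to reconstruct the ancestral presence/absence of the canonical PAZ
domain over a Dicer phylogeny. The character evolves by a continuous-time
Markov chain with a single rate ``q`` for both the 0->1 and 1->0
transitions; over a branch of length ``t`` the transition probabilities
have the closed form

    P(stay)   = (1 + exp(-2 q t)) / 2
    P(switch) = (1 - exp(-2 q t)) / 2.

The likelihood is computed with Felsenstein's pruning algorithm with
per-node rescaling (safe on multi-thousand-tip trees), the rate is fit by
bounded 1-D maximization, and per-node marginal state probabilities come
from the standard inside/outside (up-down) pass. The root prior defaults
to the ER stationary distribution (1/2, 1/2); polytomies and zero-length
branches are handled without special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

Q_LOWER_BOUND = 1e-8


def er_transition(q: float, t: float) -> np.ndarray:
    """2x2 transition-probability matrix of the two-state ER chain."""
    if q < 0:
        raise ValueError("rate q must be non-negative")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    switch = 0.5 * (1.0 - np.exp(-2.0 * q * t))
    stay = 1.0 - switch
    return np.array([[stay, switch], [switch, stay]])


class _IndexedTree:
    """Flat postorder view of a rooted dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children: list[list[int]] = []
        self.lengths: list[float] = []
        self.labels: list[str] = []
        for i, node in enumerate(self.nodes):
            self.children.append([self.index[id(c)] for c in node.child_nodes()])
            bl = node.edge.length
            if bl is None:
                bl = 0.0
            if not np.isfinite(bl) or bl < 0:
                raise ValueError(f"invalid branch length {bl!r}")
            self.lengths.append(float(bl))
            if node.is_leaf():
                self.labels.append(node.taxon.label if node.taxon else f"tip_{i}")
            else:
                self.labels.append(node.label if node.label else f"node_{i}")
        self.root_index = len(self.nodes) - 1
        self.tip_indices = [i for i, n in enumerate(self.nodes) if n.is_leaf()]
        self.mean_branch_length = (
            float(np.mean([self.lengths[i] for i in range(len(self.nodes) - 1)]))
            if len(self.nodes) > 1 else 0.0
        )


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


@dataclass
class PhyloCharacter:
    """A rooted tree with binary tip states (0 = absent, 1 = present)."""

    tree: dendropy.Tree
    tip_states: dict[str, int]
    root_prior: tuple[float, float] = (0.5, 0.5)
    _indexed: _IndexedTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tree = _as_tree(self.tree)
        if abs(sum(self.root_prior) - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")
        self._indexed = _IndexedTree(self.tree)
        for i in self._indexed.tip_indices:
            label = self._indexed.labels[i]
            if label not in self.tip_states:
                raise ValueError(f"tip {label!r} has no state")
            if self.tip_states[label] not in (0, 1):
                raise ValueError(f"tip {label!r} state must be 0 or 1")

    @property
    def n_tips(self) -> int:
        return len(self._indexed.tip_indices)

    def both_states_present(self) -> bool:
        states = {self.tip_states[self._indexed.labels[i]]
                  for i in self._indexed.tip_indices}
        return states == {0, 1}


def _inside_pass(pc: PhyloCharacter, q: float):
    """Partial (inside) likelihoods with per-node rescaling.

    Returns (partials, log_scale_total) where ``partials[i]`` is the
    rescaled conditional likelihood of the data below node i given its
    state, and the sum of log scaling factors restores absolute scale
    at the root.
    """
    it = pc._indexed
    n = len(it.nodes)
    partials = np.zeros((n, 2))
    log_scale = 0.0
    for i in range(n):
        if not it.children[i]:
            partials[i, pc.tip_states[it.labels[i]]] = 1.0
            continue
        vals = np.ones(2)
        for c in it.children[i]:
            p = er_transition(q, it.lengths[c])
            vals *= p @ partials[c]
        top = vals.max()
        if top <= 0.0:
            raise ValueError("zero likelihood: contradictory data")
        partials[i] = vals / top
        log_scale += np.log(top)
    return partials, log_scale


def pruning_loglik(pc: PhyloCharacter, q: float) -> float:
    """Log-likelihood of the tip data under the ER model at rate ``q``."""
    partials, log_scale = _inside_pass(pc, q)
    prior = np.asarray(pc.root_prior)
    return float(np.log(prior @ partials[pc._indexed.root_index]) + log_scale)


@dataclass
class AceResult:
    """ER fit + marginal ancestral reconstruction."""

    q_hat: float
    log_likelihood: float
    node_marginals: dict[str, tuple[float, float]]
    at_lower_bound: bool = False


def fit_er(pc: PhyloCharacter,
           q_max: float | None = None) -> tuple[float, float, bool]:
    """Maximum-likelihood ER rate.

    Returns (q_hat, logL, at_lower_bound). When all tips share one state
    the likelihood is maximized at q -> 0; q_hat is pinned at the lower
    bound and flagged. The search interval is [1e-8, 100 / mean branch
    length] with convergence tolerance 1e-8 on q.
    """
    if pc.n_tips < 2:
        raise ValueError("need at least two tips to fit a rate")
    if q_max is None:
        mbl = pc._indexed.mean_branch_length
        q_max = 100.0 / mbl if mbl > 0 else 100.0
    if not pc.both_states_present():
        q = Q_LOWER_BOUND
        return q, pruning_loglik(pc, q), True
    res = minimize_scalar(
        lambda q: -pruning_loglik(pc, q),
        bounds=(Q_LOWER_BOUND, q_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    q_hat = float(res.x)
    at_bound = q_hat <= Q_LOWER_BOUND * 10
    return q_hat, float(-res.fun), at_bound


def marginal_ace(pc: PhyloCharacter, q: float) -> dict[str, tuple[float, float]]:
    """Marginal state probabilities at every node given the rate.

    The outside pass propagates root-to-tips: for child c of node v,
    out_c(s_c) = sum_{s_v} P(s_v -> s_c) out_v(s_v) prod_{siblings b}
    [P L_b](s_v). Each node's marginal is the normalized product of its
    inside and outside vectors; outside vectors are renormalized per
    node, which cancels in the marginal.
    """
    it = pc._indexed
    partials, _ = _inside_pass(pc, q)
    n = len(it.nodes)
    outside = np.zeros((n, 2))
    outside[it.root_index] = np.asarray(pc.root_prior)
    for i in range(n - 1, -1, -1):  # preorder = reversed postorder
        kids = it.children[i]
        if not kids:
            continue
        # messages from each child subtree up into node i
        messages = {c: er_transition(q, it.lengths[c]) @ partials[c] for c in kids}
        for c in kids:
            sib = np.ones(2)
            for b in kids:
                if b != c:
                    sib *= messages[b]
            out_c = er_transition(q, it.lengths[c]).T @ (outside[i] * sib)
            total = out_c.sum()
            if total <= 0:
                raise ValueError("zero outside likelihood")
            outside[c] = out_c / total
    marginals: dict[str, tuple[float, float]] = {}
    for i in range(n):
        if not it.children[i]:
            continue
        joint = outside[i] * partials[i]
        joint /= joint.sum()
        marginals[it.labels[i]] = (float(joint[0]), float(joint[1]))
    return marginals


def ancestral_reconstruction(pc: PhyloCharacter) -> AceResult:
    """Fit the ER rate and reconstruct marginal node states."""
    q_hat, logl, at_bound = fit_er(pc)
    return AceResult(
        q_hat=q_hat,
        log_likelihood=logl,
        node_marginals=marginal_ace(pc, q_hat),
        at_lower_bound=at_bound,
    )


def read_tip_states(stream) -> dict[str, int]:
    """Read a two-column (id, 0/1) TSV of tip states."""
    states: dict[str, int] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("protein_id"):
            continue
        name, value = line.split("\t")
        states[name] = int(value)
    return states


def marginals_to_tsv(marginals: Mapping[str, tuple[float, float]]) -> str:
    buf = StringIO()
    buf.write("node\tp_absent\tp_present\n")
    for node, (p0, p1) in marginals.items():
        buf.write(f"{node}\t{p0:.6f}\t{p1:.6f}\n")
    return buf.getvalue()
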