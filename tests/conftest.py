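"""Shared fixtures and independent brute-force oracles.

The oracles here recompute quantities by exhaustive enumeration or naive
algorithms, independent of the package's implementations, so tests can
compare two routes to the same answer.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from dicer_atlas import mk_ace
from dicer_atlas.domain_hits import DomainHit

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# Mk-model enumeration oracles (sum over all internal-node state assignments)


def enumeration_loglik(pc: mk_ace.PhyloCharacter, q: float) -> float:
    """Log-likelihood by brute-force sum over internal-node states."""
    it = pc._indexed
    internal = [i for i in range(len(it.nodes)) if it.children[i]]
    tips = {i: pc.tip_states[it.labels[i]] for i in it.tip_indices}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        states = dict(tips)
        states.update(zip(internal, assign))
        p = pc.root_prior[states[it.root_index]]
        for i in internal:
            for c in it.children[i]:
                table = mk_ace.er_transition(q, it.lengths[c])
                p *= table[states[i], states[c]]
        total += p
    return float(np.log(total))


def enumeration_marginals(pc: mk_ace.PhyloCharacter, q: float) -> dict:
    """Internal-node marginals by brute-force conditional probabilities."""
    it = pc._indexed
    internal = [i for i in range(len(it.nodes)) if it.children[i]]
    tips = {i: pc.tip_states[it.labels[i]] for i in it.tip_indices}
    mass = {i: np.zeros(2) for i in internal}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        states = dict(tips)
        states.update(zip(internal, assign))
        p = pc.root_prior[states[it.root_index]]
        for i in internal:
            for c in it.children[i]:
                table = mk_ace.er_transition(q, it.lengths[c])
                p *= table[states[i], states[c]]
        for i in internal:
            mass[i][states[i]] += p
    return {it.labels[i]: v / v.sum() for i, v in mass.items()}


# ---------------------------------------------------------------------------
# graph and hit-selection oracles


def components_oracle(nodes: list, edges: list[tuple]) -> list[frozenset]:
    """Connected components by iterated transitive closure of a boolean
    adjacency matrix (no graph library)."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for a, b in edges:
        reach[idx[a], idx[b]] = reach[idx[b], idx[a]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        members = frozenset(nodes[j] for j in np.flatnonzero(reach[i]))
        seen.update(np.flatnonzero(reach[i]).tolist())
        comps.append(members)
    return comps


def greedy_selection_oracle(hits: list[DomainHit]) -> set[DomainHit]:
    """Best maximal independent hit set by exhaustive subset enumeration.

    Among all maximal (non-extendable) sets of pairwise non-overlapping
    hits, picks the one whose priority keys (ascending E-value, then
    descending score, then start) read lexicographically smallest.
    """

    def independent(subset):
        return all(not a.overlaps(b)
                   for a, b in itertools.combinations(subset, 2))

    def maximal(subset):
        rest = [h for h in hits if h not in subset]
        return all(any(h.overlaps(s) for s in subset) for h in rest)

    def key(subset):
        return sorted((h.evalue, -h.score, h.start, h.end, h.domain_label)
                      for h in subset)

    candidates = [
        set(sub)
        for r in range(len(hits) + 1)
        for sub in itertools.combinations(hits, r)
        if independent(sub) and maximal(sub)
    ]
    return min(candidates, key=lambda s: key(s))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_proteome():
    """A 120-protein planted proteome shared across read-only tests."""
    from dicer_atlas import synthetic_data as sd

    config = sd.SimulationConfig(seed=11, n_proteins=120)
    hits, truth = sd.generate_hit_table(config)
    return config, hits, truth
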