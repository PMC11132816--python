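"""Ancestral sequence reconstruction: site likelihoods, marginal posteriors,
and exact ranked joint reconstructions.

The joint reconstruction of a site assigns one amino acid to every internal
node; its posterior is the prior-weighted probability of that full labeling
divided by the site likelihood. Classification downstream aggregates over
the ranked list, because the best (rank-1) labeling alone can carry modest
posterior mass and near-optimal labelings may imply a different substitution
history — ignoring them produces false negatives. Enumeration is exact:
a best-first search over internal labelings with an admissible max-product
bound yields reconstructions in strictly non-increasing posterior order
until a cumulative-mass target or a count cap is reached.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np

from convscan.phylo_io import AA_INDEX, Tree
from convscan.submodel import SubstitutionModel, transition_probabilities


@dataclass(frozen=True)
class SitePattern:
    """Observed amino-acid indices at every tip (gap-free columns only)."""

    states: dict[str, int]

    @staticmethod
    def from_column(column: dict[str, str]) -> "SitePattern":
        return SitePattern({sp: AA_INDEX[aa] for sp, aa in column.items()})


@dataclass(frozen=True)
class JointReconstruction:
    """One full internal-node labeling with its posterior probability."""

    assignment: dict[int, int]   # internal node id -> amino-acid index
    posterior: float

    def key(self) -> tuple[int, ...]:
        """Assignment vector in node-id order, the deterministic tie-break."""
        return tuple(self.assignment[k] for k in sorted(self.assignment))


@dataclass(frozen=True)
class ReconstructionSet:
    reconstructions: tuple[JointReconstruction, ...]
    cumulative_mass: float
    truncated: bool


def _edge_logP(tree: Tree, model: SubstitutionModel) -> dict[int, np.ndarray]:
    """log transition matrix for the branch above each non-root node."""
    with np.errstate(divide="ignore"):
        return {
            n.id: np.log(transition_probabilities(model, n.length))
            for n in tree.nodes
            if n.parent is not None
        }


def _logsumexp_rows(msgs: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp; rows that are entirely -inf stay -inf
    (zero-length branches make some transitions impossible)."""
    m = msgs.max(axis=1)
    out = np.full(m.shape, -np.inf)
    ok = m > -np.inf
    if np.any(ok):
        sub = msgs[ok] - m[ok, None]
        out[ok] = m[ok] + np.log(np.exp(sub).sum(axis=1))
    return out


def _tip_states(tree: Tree, pattern: SitePattern) -> dict[int, int]:
    states = {}
    for label, node_id in tree.tip_ids.items():
        if label not in pattern.states:
            raise ValueError(f"tip {label!r} missing from site pattern")
        states[node_id] = pattern.states[label]
    return states


def site_log_likelihood(tree: Tree, model: SubstitutionModel, pattern: SitePattern) -> float:
    """Felsenstein pruning in log space; returns log L of the site."""
    logP = _edge_logP(tree, model)
    tip_state = _tip_states(tree, pattern)
    # up[v][s]: log P(tip data below v | state of v = s), with edge of v folded
    # into the parent's combination step.
    k = len(model.pi)
    up: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.nodes[v].is_tip:
            vec = np.full(k, -np.inf)
            vec[tip_state[v]] = 0.0
            up[v] = vec
        else:
            total = np.zeros(k)
            for c in tree.children(v):
                msgs = logP[c] + up[c][None, :]       # (parent s, child s')
                total += _logsumexp_rows(msgs)
            up[v] = total
    root_vec = np.log(model.pi) + up[tree.root]
    m = root_vec.max()
    if m == -np.inf:
        return -np.inf
    return float(m + np.log(np.exp(root_vec - m).sum()))


def site_likelihood(tree: Tree, model: SubstitutionModel, pattern: SitePattern) -> float:
    return float(np.exp(site_log_likelihood(tree, model, pattern)))


def marginal_posteriors(
    tree: Tree, model: SubstitutionModel, pattern: SitePattern
) -> dict[int, np.ndarray]:
    """Per-internal-node posterior state distributions (inside-outside)."""
    P = {
        n.id: transition_probabilities(model, n.length)
        for n in tree.nodes
        if n.parent is not None
    }
    tip_state = _tip_states(tree, pattern)
    k = len(model.pi)
    up: dict[int, np.ndarray] = {}
    # child message seen from the parent: L_c[s_p] = sum_s' P_c[s_p,s'] up[c][s']
    msg: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.nodes[v].is_tip:
            vec = np.zeros(k)
            vec[tip_state[v]] = 1.0
            up[v] = vec
        else:
            total = np.ones(k)
            for c in tree.children(v):
                msg[c] = P[c] @ up[c]
                total = total * msg[c]
            scale = total.max()
            up[v] = total / scale if scale > 0 else total

    out: dict[int, np.ndarray] = {tree.root: model.pi.copy()}
    for v in tree.preorder():
        if tree.nodes[v].is_tip:
            continue
        for c in tree.children(v):
            if tree.nodes[c].is_tip:
                continue
            sib = np.ones(k)
            for b in tree.children(v):
                if b != c:
                    sib = sib * msg[b]
            vec = (out[v] * sib) @ P[c]
            scale = vec.max()
            out[c] = vec / scale if scale > 0 else vec

    result = {}
    for v in tree.internal_ids:
        post = out[v] * up[v]
        result[v] = post / post.sum()
    return result


def max_product_reconstruction(
    tree: Tree, model: SubstitutionModel, pattern: SitePattern
) -> dict[int, int]:
    """Single best joint labeling (Viterbi-style dynamic program)."""
    rec = joint_reconstructions(tree, model, pattern, mass_target=0.0, k_max=1)
    return rec.reconstructions[0].assignment


def joint_reconstructions(
    tree: Tree,
    model: SubstitutionModel,
    pattern: SitePattern,
    mass_target: float = 0.99,
    k_max: int = 100,
) -> ReconstructionSet:
    """Exact ranked enumeration of joint reconstructions.

    Best-first search assigns internal nodes in pre-order; the priority of a
    partial labeling is its exact log-probability prefix plus, for every
    unassigned subtree, the max-product bound given the assigned parent
    state. The bound is admissible, so completed labelings pop off the heap
    in exact descending posterior order. Enumeration stops when cumulative
    posterior mass reaches ``mass_target`` or ``k_max`` labelings have been
    produced (``truncated`` is set accordingly). Ties are broken by the
    lexicographic order of the assignment vector in node-id order.
    """
    if not (0.0 <= mass_target <= 1.0):
        raise ValueError("mass_target must be in [0, 1]")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    logL = site_log_likelihood(tree, model, pattern)
    logP = _edge_logP(tree, model)
    tip_state = _tip_states(tree, pattern)
    log_pi = np.log(model.pi)
    k_states = len(model.pi)

    internals_pre = [v for v in tree.preorder() if not tree.nodes[v].is_tip]
    pos_of = {v: i for i, v in enumerate(internals_pre)}
    n_int = len(internals_pre)
    id_order = sorted(internals_pre)  # tie-break coordinate order

    # D[v][s]: max over labelings of v's strict descendants of the log
    # product of all edge factors inside v's subtree, given state(v)=s.
    D: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.nodes[v].is_tip:
            continue
        total = np.zeros(k_states)
        for c in tree.children(v):
            if tree.nodes[c].is_tip:
                total += logP[c][:, tip_state[c]]
            else:
                total += (logP[c] + D[c][None, :]).max(axis=1)
        D[v] = total

    def tip_factor(v: int, s: int) -> float:
        return sum(
            logP[c][s, tip_state[c]]
            for c in tree.children(v)
            if tree.nodes[c].is_tip
        )

    def internal_children(v: int) -> list[int]:
        return [c for c in tree.children(v) if not tree.nodes[c].is_tip]

    def child_bound(v: int, s: int) -> float:
        return sum(
            float((logP[c][s] + D[c]).max()) for c in internal_children(v)
        )

    # heap items: (-bound, depth_assigned, tie_key, states_tuple)
    root = internals_pre[0]
    results: list[JointReconstruction] = []
    mass = 0.0
    heap: list[tuple[float, tuple[int, ...], tuple[int, ...]]] = []
    start_bound = float((log_pi + D[root]).max())
    heapq.heappush(heap, (-start_bound, (), ()))

    while heap:
        neg_bound, _tie, states = heapq.heappop(heap)
        i = len(states)
        if i == n_int:
            assignment = dict(zip(internals_pre, states))
            posterior = float(np.exp(-neg_bound - logL))
            rec = JointReconstruction(assignment=assignment, posterior=posterior)
            results.append(rec)
            mass += posterior
            if len(results) >= k_max or (mass_target > 0 and mass >= mass_target - 1e-12):
                break
            continue
        v = internals_pre[i]
        g_minus = -neg_bound
        # remove v's own slack term from the parent's bound
        if i == 0:
            slack = start_bound
            base = 0.0
        else:
            p = tree.nodes[v].parent
            sp = states[pos_of[p]]
            slack = float((logP[v][sp] + D[v]).max())
            base = g_minus - slack
        for s in range(k_states):
            if i == 0:
                edge = float(log_pi[s])
            else:
                edge = float(logP[v][sp, s])
            if edge == -np.inf:
                continue
            new_bound = base + edge + tip_factor(v, s) + child_bound(v, s)
            if new_bound == -np.inf:
                continue
            new_states = states + (s,)
            tie = tuple(
                new_states[pos_of[u]] if pos_of[u] < len(new_states) else -1
                for u in id_order
            )
            heapq.heappush(heap, (-new_bound, tie, new_states))

    truncated = mass < 1.0 - 1e-9
    results.sort(key=lambda r: (-r.posterior, r.key()))
    return ReconstructionSet(
        reconstructions=tuple(results),
        cumulative_mass=mass,
        truncated=bool(truncated),
    )


def enumerate_reconstructions_bruteforce(
    tree: Tree,
    model: SubstitutionModel,
    pattern: SitePattern,
    alphabet: tuple[int, ...] | None = None,
) -> list[JointReconstruction]:
    """Full enumeration over internal labelings — the independent oracle.

    Only feasible on tiny trees; ``alphabet`` can restrict states to speed
    up tests (posteriors are then renormalized over the restricted space).
    """
    logP = _edge_logP(tree, model)
    tip_state = _tip_states(tree, pattern)
    log_pi = np.log(model.pi)
    internals = sorted(v for v in tree.preorder() if not tree.nodes[v].is_tip)
    states = alphabet if alphabet is not None else tuple(range(len(model.pi)))

    entries = []
    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        full = dict(assign)
        full.update(tip_state)
        lp = log_pi[assign[tree.root]] if tree.root in assign else 0.0
        for n in tree.nodes:
            if n.parent is None:
                continue
            lp += logP[n.id][full[n.parent], full[n.id]]
        entries.append((assign, lp))
    m = max(lp for _, lp in entries)
    weights = [np.exp(lp - m) for _, lp in entries]
    total = sum(weights)
    recs = [
        JointReconstruction(assignment=a, posterior=w / total)
        for (a, _), w in zip(entries, weights)
    ]
    recs.sort(key=lambda r: (-r.posterior, r.key()))
    return recs
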