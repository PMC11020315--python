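"""Time calibration and ancestral-state reconstruction of replacement patterns.

The workflow mirrors standard practice for discrete morphological characters
on fossil phylogenies:

1. A supplied topology is time-calibrated from taxon first-appearance dates
   (FADs): each tip sits at its FAD, each internal node at the oldest FAD
   among its descendants, the root is pushed back by a chosen extension, and
   chains of zero-length branches share the time available from the nearest
   ancestral branch of positive length in equal parts (the 'equal' rule).
2. A k-state continuous-time Markov (Mk) model is fitted by maximum
   likelihood (Felsenstein pruning) under three parameterisations of the
   transition-rate matrix Q: equal rates (ER), symmetric (SYM) and
   all-rates-different (ARD).
3. Akaike weights over the three fits allocate a budget of stochastic
   character maps (SIMMAP-style full histories sampled conditional on the
   tips), and per-node state frequencies across the maps summarise the
   ancestral states; the root row is the ancestral-state estimate.

Polytomies are accepted and treated as hard. The root-state prior defaults to
flat over states and may be set to the stationary distribution of Q.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

from .errors import AllocationError, DegenerateDataError, ValidationError

__all__ = [
    "DEFAULT_STATES",
    "CharacterMatrix",
    "CalibratedTree",
    "RateModelFit",
    "StochasticMap",
    "calibrate_equal",
    "mk_loglik",
    "fit_mk",
    "akaike_weights",
    "simmap_sample",
    "model_averaged_maps",
    "node_state_summary",
]

#: Default coding of the tooth-replacement-pattern character.
DEFAULT_STATES = ("one_generation", "two_generations", "three_plus")

MODELS = ("ER", "SYM", "ARD")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# character matrix


@dataclass
class CharacterMatrix:
    """Tip states of one discrete character. ``None`` marks an explicitly
    missing observation (the tip contributes no information)."""

    data: dict
    states: tuple = DEFAULT_STATES

    def __post_init__(self):
        for taxon, state in self.data.items():
            if state is not None and state not in self.states:
                raise ValidationError(
                    f"taxon {taxon!r} has state {state!r} not in {self.states}"
                )

    @classmethod
    def from_csv(cls, path, states: Sequence[str] | None = None) -> "CharacterMatrix":
        df = pd.read_csv(path)
        if not {"taxon", "state"} <= set(df.columns):
            raise ValidationError("character table needs columns: taxon, state")
        data = {}
        for _, row in df.iterrows():
            raw = str(row["state"]).strip()
            data[str(row["taxon"])] = None if raw in ("", "?", "nan") else raw
        observed = sorted({s for s in data.values() if s is not None})
        return cls(data=data, states=tuple(states) if states else tuple(observed) or DEFAULT_STATES)

    def state_index(self, taxon: str) -> int | None:
        state = self.data[taxon]
        return None if state is None else self.states.index(state)

    @property
    def k(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# time calibration


@dataclass
class CalibratedTree:
    """A dendropy tree whose nodes carry absolute ages (Ma, root oldest) and
    whose edge lengths are age differences in Myr."""

    tree: dendropy.Tree

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def ages(self) -> dict:
        return {_node_label(n): n.age for n in self.tree.preorder_node_iter()}

    def age(self, label: str) -> float:
        for n in self.tree.preorder_node_iter():
            if _node_label(n) == label:
                return n.age
        raise KeyError(label)

    def tip_labels(self) -> list:
        return [t.taxon.label for t in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _as_tree(topology) -> dendropy.Tree:
    if isinstance(topology, CalibratedTree):
        return topology.tree
    if isinstance(topology, dendropy.Tree):
        return topology
    text = str(topology)
    if "(" not in text and Path(text).exists():
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def _normalize_ages(ages) -> dict:
    """Accepts a DataFrame (taxon, fad_ma[, lad_ma]) or a mapping taxon ->
    fad or (fad, lad). Returns taxon -> (fad, lad)."""
    table: dict = {}
    if isinstance(ages, pd.DataFrame):
        cols = {c.lower(): c for c in ages.columns}
        if "taxon" not in cols or "fad_ma" not in cols:
            raise ValidationError("age table needs columns: taxon, fad_ma[, lad_ma]")
        for _, row in ages.iterrows():
            fad = float(row[cols["fad_ma"]])
            lad = float(row[cols["lad_ma"]]) if "lad_ma" in cols else fad
            table[str(row[cols["taxon"]])] = (fad, lad)
    else:
        for taxon, val in ages.items():
            fad, lad = (val, val) if np.isscalar(val) else (val[0], val[1])
            table[str(taxon)] = (float(fad), float(lad))
    for taxon, (fad, lad) in table.items():
        if fad < lad:
            raise ValidationError(f"taxon {taxon!r}: FAD ({fad}) must be >= LAD ({lad})")
    return table


def calibrate_equal(topology, ages, root_extension: float = 0.0) -> CalibratedTree:
    """Time-calibrate a topology by the 'equal' method.

    Tip age = FAD; internal node age = oldest descendant FAD; the root is
    pushed back by ``root_extension`` Myr. Each chain of zero-length branches
    then shares, in equal parts, the time available from the nearest
    ancestral branch of positive length, by sliding the chain's internal
    nodes rootward (tip ages never move). With a positive root extension
    every branch ends up strictly positive.
    """
    tree = _as_tree(topology).clone(depth=1)
    age_table = _normalize_ages(ages)

    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in age_table:
            raise ValidationError(f"no age for taxon {name!r}")
        leaf.age = age_table[name][0]
    for node in tree.postorder_internal_node_iter():
        node.age = max(c.age for c in node.child_nodes())
    tree.seed_node.age += float(root_extension)

    # 'equal' redistribution of zero-length chains
    for q in tree.preorder_node_iter():
        if q.parent_node is None or q.is_leaf():
            continue
        avail = q.parent_node.age - q.age
        if avail <= _EPS:
            continue
        # zero-connected subtree hanging below q (original ages)
        depths: dict = {}
        frontier = [(q, 0)]
        while frontier:
            node, d = frontier.pop()
            for c in node.child_nodes():
                if node.age - c.age <= _EPS:
                    depths[id(c)] = (c, d + 1)
                    frontier.append((c, d + 1))
        if not depths:
            continue
        k = max(d for _, d in depths.values())
        unit = avail / (k + 1)
        q.age = q.parent_node.age - unit
        for c, d in depths.values():
            if not c.is_leaf():
                c.age = q.parent_node.age - (d + 1) * unit

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.parent_node.age - node.age
            assert length >= -1e-9, "negative branch after equal redistribution"
            node.edge.length = max(length, 0.0)

    i = 0
    for node in tree.postorder_internal_node_iter():
        if node.taxon is None and not node.label:
            i += 1
            node.label = f"n{i}"
    return CalibratedTree(tree=tree)


# ---------------------------------------------------------------------------
# Mk likelihood machinery


def _validate_generator(Q: np.ndarray, k: int) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (k, k):
        raise ValidationError(f"Q must be {k}x{k}, got {Q.shape}")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-10):
        raise ValidationError("Q has negative off-diagonal rates")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(Q).max())):
        raise ValidationError("rows of Q must sum to zero")
    return Q


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a batch of branch lengths, via eigendecomposition
    with an expm fallback for defective Q."""
    ts = np.asarray(ts, dtype=float)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(ts, w)), Vinv).real
        if not np.all(np.isfinite(P)) or np.any(P < -1e-6):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.array([scipy.linalg.expm(Q * t) for t in ts])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


class _TreeArrays:
    """Flat postorder representation of a (possibly multifurcating) tree."""

    def __init__(self, tree):
        dtree = tree.tree if isinstance(tree, CalibratedTree) else tree
        nodes = list(dtree.postorder_node_iter())
        self.n = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children: list = [[] for _ in nodes]
        self.parent = np.full(self.n, -1, dtype=int)
        self.edge_len = np.zeros(self.n)
        self.labels: list = []
        for i, n in enumerate(nodes):
            lbl = _node_label(n)
            self.labels.append(lbl if lbl else f"nd{i}")
            for c in n.child_nodes():
                j = index[id(c)]
                self.children[i].append(j)
                self.parent[j] = i
                self.edge_len[j] = c.edge.length if c.edge.length is not None else 0.0
        self.root = self.n - 1
        self.is_tip = np.array([len(ch) == 0 for ch in self.children])
        self.tip_label_to_index = {
            self.labels[i]: i for i in range(self.n) if self.is_tip[i]
        }
        self.total_length = float(self.edge_len.sum())


def _tip_partials(arr: _TreeArrays, chars: CharacterMatrix) -> np.ndarray:
    k = chars.k
    L = np.ones((arr.n, k))
    for label, i in arr.tip_label_to_index.items():
        if label not in chars.data:
            raise ValidationError(f"tip {label!r} has no state in the character matrix")
        s = chars.state_index(label)
        if s is not None:
            L[i] = 0.0
            L[i, s] = 1.0
    return L


def _root_prior(root_prior, Q: np.ndarray, k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.full(k, 1.0 / k)
        if root_prior == "stationary":
            # left null vector of Q
            w, V = np.linalg.eig(Q.T)
            pi = np.abs(V[:, np.argmin(np.abs(w))].real)
            return pi / pi.sum()
        raise ValidationError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not math.isclose(pi.sum(), 1.0, rel_tol=1e-6):
        raise ValidationError("root prior must be a length-k probability vector")
    return pi / pi.sum()


def _conditional_likelihoods(arr, chars, Q):
    """Postorder partial likelihoods with per-node rescaling.

    Returns (L, log_scale, P) where P[j] is the transition matrix along the
    edge into node j.
    """
    P = transition_matrices(Q, arr.edge_len)
    L = _tip_partials(arr, chars)
    log_scale = 0.0
    for i in range(arr.n):
        if arr.is_tip[i]:
            continue
        part = np.ones(chars.k)
        for j in arr.children[i]:
            part = part * (P[j] @ L[j])
        s = part.max()
        if s <= 0:
            raise ValidationError("data has zero likelihood under Q (impossible states)")
        L[i] = part / s
        log_scale += math.log(s)
    return L, log_scale, P


def mk_loglik(tree, chars: CharacterMatrix, Q, root_prior="flat") -> float:
    """Log-likelihood of tip states under the Mk process with generator Q,
    by Felsenstein pruning."""
    arr = tree if isinstance(tree, _TreeArrays) else _TreeArrays(tree)
    Q = _validate_generator(Q, chars.k)
    L, log_scale, _ = _conditional_likelihoods(arr, chars, Q)
    pi = _root_prior(root_prior, Q, chars.k)
    lik = float(pi @ L[arr.root])
    if lik <= 0:
        return -np.inf
    return math.log(lik) + log_scale


# ---------------------------------------------------------------------------
# model fitting


def _n_free_params(model: str, k: int) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def _build_q(model: str, rates: np.ndarray, k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    elif model == "ARD":
        off = ~np.eye(k, dtype=bool)
        Q[off] = rates
    else:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class RateModelFit:
    model: str
    Q: np.ndarray
    log_likelihood: float
    aic: float
    k_params: int
    states: tuple
    akaike_weight: float | None = None
    tree: object = None
    chars: CharacterMatrix | None = None
    root_prior: object = "flat"


def fit_mk(
    tree,
    chars: CharacterMatrix,
    model: str = "ER",
    n_starts: int = 5,
    seed: int = 0,
    root_prior="flat",
) -> RateModelFit:
    """Maximum-likelihood Mk fit with multistart bounded optimisation over
    log rates. ER is solved first and seeds the SYM/ARD starts, which keeps
    the nested-model likelihood ordering ER <= SYM <= ARD."""
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    k = chars.k
    observed = {s for s in chars.data.values() if s is not None}
    if len(observed) < 2:
        raise DegenerateDataError(
            "all observed tips share one state; no transition rate is identifiable"
        )
    arr = _TreeArrays(tree)
    p = _n_free_params(model, k)
    bounds = [(-18.0, 8.0)] * p

    def negloglik(x):
        Q = _build_q(model, np.exp(x), k)
        ll = mk_loglik(arr, chars, Q, root_prior=root_prior)
        return 1e10 if not np.isfinite(ll) else -ll

    # crude scale: a handful of changes across the whole tree
    base_rate = max(len(observed) - 1, 1) / max(arr.total_length, _EPS)
    log_base = math.log(base_rate)

    from scipy.optimize import minimize, minimize_scalar

    er_res = minimize_scalar(
        lambda v: (
            -mk_loglik(arr, chars, _build_q("ER", np.exp([v]), k), root_prior=root_prior)
        ),
        bounds=(log_base - 9.0, log_base + 9.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    er_log_rate = float(er_res.x)

    rng = np.random.default_rng(seed)
    starts = [np.full(p, er_log_rate), np.full(p, log_base)]
    while len(starts) < max(n_starts, 2):
        starts.append(er_log_rate + rng.normal(0.0, 1.5, size=p))

    if model == "ER":
        best_x, best_f = np.array([er_log_rate]), float(er_res.fun)
        for x0 in starts[1:]:
            res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds, tol=1e-8)
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
    else:
        best_x, best_f = None, np.inf
        for x0 in starts:
            res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds, tol=1e-8)
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)

    ll = -best_f
    return RateModelFit(
        model=model,
        Q=_build_q(model, np.exp(best_x), k),
        log_likelihood=ll,
        aic=2.0 * p - 2.0 * ll,
        k_params=p,
        states=chars.states,
        tree=tree,
        chars=chars,
        root_prior=root_prior,
    )


def akaike_weights(fits: Sequence[RateModelFit]) -> list:
    """Akaike weights w_m = exp(-Δ_m/2) / Σ exp(-Δ/2), Δ_m = AIC_m - min AIC."""
    if not fits:
        raise ValidationError("no fits supplied")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    return list(fits)


# ---------------------------------------------------------------------------
# stochastic character mapping


@dataclass
class StochasticMap:
    """One sampled character history: states at every node plus, per branch,
    the piecewise-constant state path (state, dwell time) parent -> child."""

    node_states: dict
    histories: dict
    model: str
    states: tuple

    def dwell_total(self, label: str) -> float:
        return sum(d for _, d in self.histories[label])


def _sample_path_rejection(Q, a, b, t, rng):
    """Simulate an unconditioned path from a and accept if it ends in b."""
    events = []
    s = a
    tau = 0.0
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            break
        tau += rng.exponential(1.0 / rate)
        if tau >= t:
            break
        probs = np.clip(Q[s], 0, None)
        probs[s] = 0.0
        s = rng.choice(len(probs), p=probs / probs.sum())
        events.append((tau, s))
    return (events, s == b)


def _sample_path_uniformization(Q, a, b, t, rng, p_ab):
    """Endpoint-conditioned path via uniformization (dominating Poisson
    process with virtual jumps)."""
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return []
    R = np.eye(k) + Q / mu
    powers = [np.eye(k)]
    terms = []
    log_pois0 = -mu * t
    n = 0
    total = 0.0
    # accumulate P(N=n, end=b | start=a) terms until they cover p_ab
    while n < 500:
        term = math.exp(log_pois0 + n * math.log(mu * t) - math.lgamma(n + 1)) * powers[n][a, b]
        terms.append(term)
        total += term
        if total >= p_ab * (1.0 - 1e-12) and n >= 1:
            break
        powers.append(powers[-1] @ R)
        n += 1
    if total <= 0:
        raise ValidationError("zero-probability endpoint pair under Q")
    u = rng.uniform(0, total)
    N = min(int(np.searchsorted(np.cumsum(terms), u)), len(terms) - 1)
    # jump-chain states, bridged to b
    states = [a]
    for i in range(1, N):
        prev = states[-1]
        weights = R[prev] * powers[N - i][:, b]
        weights = np.clip(weights, 0, None)
        states.append(rng.choice(k, p=weights / weights.sum()))
    if N >= 1:
        states.append(b)
    times = np.sort(rng.uniform(0.0, t, size=N))
    events = []
    cur = a
    for time, s in zip(times, states[1:]):
        if s != cur:  # drop virtual jumps
            events.append((float(time), int(s)))
            cur = s
    return events


def _events_to_segments(events, a, t):
    segs = []
    cur, last = a, 0.0
    for time, s in events:
        segs.append((cur, time - last))
        cur, last = s, time
    segs.append((cur, t - last))
    return segs


def _sample_branch_history(Q, a, b, t, p_ab, rng, max_rejections=1000):
    if t <= 0:
        if a != b:
            raise ValidationError("state change across a zero-length branch")
        return [(a, 0.0)]
    for _ in range(max_rejections):
        events, ok = _sample_path_rejection(Q, a, t=t, b=b, rng=rng)
        if ok:
            return _events_to_segments(events, a, t)
    events = _sample_path_uniformization(Q, a, b, t, rng, p_ab)
    return _events_to_segments(events, a, t)


def simmap_sample(
    tree,
    chars: CharacterMatrix,
    Q,
    n_maps: int = 1,
    seed: int | None = None,
    root_prior="flat",
    rng: np.random.Generator | None = None,
    model_label: str = "custom",
) -> list:
    """Sample full character histories conditional on the observed tips.

    Node states are drawn from their joint conditional distribution (root
    from prior x partial likelihood, then each child given its parent);
    branch histories are endpoint-conditioned continuous-time Markov paths
    (rejection sampling, capped at 1000 attempts, then uniformization).
    """
    if n_maps < 1:
        raise ValidationError("n_maps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    arr = tree if isinstance(tree, _TreeArrays) else _TreeArrays(tree)
    Q = _validate_generator(Q, chars.k)
    L, _, P = _conditional_likelihoods(arr, chars, Q)
    pi = _root_prior(root_prior, Q, chars.k)
    k = chars.k

    maps = []
    preorder = list(range(arr.n - 1, -1, -1))  # reverse postorder
    for _ in range(n_maps):
        state = np.empty(arr.n, dtype=int)
        p_root = pi * L[arr.root]
        if p_root.sum() <= 0:
            raise ValidationError("zero-probability data under Q and root prior")
        state[arr.root] = rng.choice(k, p=p_root / p_root.sum())
        histories = {}
        for j in preorder:
            if j == arr.root:
                continue
            i = arr.parent[j]
            w = P[j][state[i]] * L[j]
            if w.sum() <= 0:
                raise ValidationError("zero-probability endpoint pair under Q")
            state[j] = rng.choice(k, p=w / w.sum())
            segs = _sample_branch_history(
                Q, int(state[i]), int(state[j]), float(arr.edge_len[j]),
                float(P[j][state[i], state[j]]), rng,
            )
            histories[arr.labels[j]] = [(chars.states[s], d) for s, d in segs]
        maps.append(
            StochasticMap(
                node_states={
                    arr.labels[i]: chars.states[state[i]] for i in range(arr.n)
                },
                histories=histories,
                model=model_label,
                states=chars.states,
            )
        )
    return maps


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of an integer budget to weights."""
    exact = weights * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def model_averaged_maps(
    fits: Sequence[RateModelFit], total: int = 1000, seed: int | None = None
):
    """Stochastic maps pooled across models in proportion to Akaike weight.

    Returns ``(maps, summary)`` where summary is the per-node state-frequency
    table across all maps (rows: node labels, columns: states); the root row
    is the ancestral-state estimate (``summary.attrs['root']`` names it).
    """
    fits = list(fits)
    if any(f.akaike_weight is None for f in fits):
        fits = akaike_weights(fits)
    weights = np.array([f.akaike_weight for f in fits])
    n_nonzero = int(np.sum(weights > 0))
    if total < n_nonzero:
        raise AllocationError(
            f"total maps ({total}) below the number of models with nonzero weight"
        )
    alloc = _allocate(weights, total)
    rng = np.random.default_rng(seed)
    maps = []
    for f, n in zip(fits, alloc):
        if n == 0:
            continue
        maps.extend(
            simmap_sample(
                f.tree, f.chars, f.Q, n_maps=int(n), rng=rng,
                root_prior=f.root_prior, model_label=f.model,
            )
        )
    arr = _TreeArrays(fits[0].tree)
    summary = node_state_summary(maps, fits[0].states)
    summary.attrs["root"] = arr.labels[arr.root]
    return maps, summary


def node_state_summary(maps: Sequence[StochasticMap], states: Sequence[str]) -> pd.DataFrame:
    """Per-node state frequencies across a collection of stochastic maps."""
    if not maps:
        raise ValidationError("no maps to summarise")
    labels = list(maps[0].node_states)
    lidx = {l: i for i, l in enumerate(labels)}
    sidx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(labels), len(states)))
    for m in maps:
        for label, s in m.node_states.items():
            counts[lidx[label], sidx[s]] += 1.0
    return pd.DataFrame(counts / len(maps), index=labels, columns=list(states))


def branch_history_table(maps: Sequence[StochasticMap]) -> pd.DataFrame:
    """Long-format table of every branch segment of every map."""
    rows = []
    for mi, m in enumerate(maps):
        for label, segs in m.histories.items():
            for si, (state, dwell) in enumerate(segs):
                rows.append(
                    {
                        "map": mi,
                        "model": m.model,
                        "child_node": label,
                        "segment": si,
                        "state": state,
                        "dwell_myr": dwell,
                    }
                )
    return pd.DataFrame(rows)
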