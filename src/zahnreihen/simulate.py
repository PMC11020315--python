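"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, each deterministic under a fixed seed and each returning
its ground truth in a provenance dict so recovery tests never peek at the
implementation:

* :func:`simulate_dentition` — a jaw tooth row whose replacement indices
  follow a degressive sawtooth wave of known period (the true Z-spacing, in
  tooth positions). Every alveolus holds a functional tooth and one
  replacement germ whose length is the index times the functional length;
  multiplicative lognormal noise emulates measurement error and individual
  variation. Functional lengths follow a unimodal profile peaking mid-row
  (position 8 by default), as real maxillary rows do.
* :func:`simulate_increments` — daily von Ebner couplet widths, lognormal
  around a chosen mean so the increment count and mean width are known.
* :func:`simulate_mk_tips` — a discrete character evolved root→tips along a
  dated tree under a known rate matrix, retaining the true internal states.

A sawtooth is the exact noise-free idealisation of the published replacement
plots, which are piecewise-linear degressive sequences; what these generators
do *not* emulate (missing teeth, broken elements, intra-row period drift) is
spelled out in the methods note.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .dentition import (
    Element,
    GrowthStage,
    Side,
    Specimen,
    ToothClass,
    ToothRecord,
    build_specimens,
)
from .errors import ValidationError
from .histology import IncrementSeries, SectionPlane
from .phylo import (
    DEFAULT_STATES,
    CalibratedTree,
    CharacterMatrix,
    _node_label,
    _root_prior,
    _sample_path_rejection,
    _validate_generator,
)

__all__ = [
    "DentitionSimSpec",
    "IncrementSimSpec",
    "MkSimSpec",
    "simulate_dentition",
    "simulate_increments",
    "simulate_mk_tips",
    "random_calibrated_tree",
    "default_length_profile",
]


def default_length_profile(position: int, peak: float = 8.0) -> float:
    """Functional crown length (mm) peaking mid-row, tapering to the ends."""
    return 4.0 + 4.0 * float(np.exp(-((position - peak) ** 2) / (2 * 3.5**2)))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass
class DentitionSimSpec:
    """Study conditions for one synthetic tooth row.

    ``period`` is the true Z-spacing (tooth positions per replacement wave);
    ``phase`` shifts where waves reset along the row. ``noise_cv`` is the
    coefficient of variation of independent multiplicative lognormal noise on
    every tooth length. ``growth_per_day_fraction`` converts a replacement
    index into an age in days for provenance (index / fraction).
    """

    n_positions: int = 14
    period: float = 2.5
    phase: float = 0.0
    functional_length_profile: Callable[[int], float] = default_length_profile
    growth_per_day_fraction: float = 0.02
    noise_cv: float = 0.0
    seed: int | None = None
    specimen_id: str = "SYNTH-1"
    element: Element = Element.MAXILLA
    side: Side = Side.LEFT

    def __post_init__(self):
        if self.n_positions < 4:
            raise ValidationError("n_positions must be >= 4")
        if not self.period > 1:
            raise ValidationError("period must be > 1 tooth position")
        if not 0 <= self.noise_cv < 0.5:
            raise ValidationError("noise_cv must lie in [0, 0.5)")


def simulate_dentition(spec: DentitionSimSpec) -> tuple[Specimen, dict]:
    """One tooth row with replacement indices on a degressive sawtooth.

    The noise-free replacement index at position x is
    ``RI(x) = 1 - frac((x - phase) / period)`` mapped onto (0, 1], so the
    index falls by 1/period per position and resets one full wave every
    ``period`` positions; the replacement germ's length is RI times the
    functional tooth's length. Returns the Specimen plus a provenance dict
    carrying the generating period, phase and seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    true_indices = {}
    for pos in range(1, spec.n_positions + 1):
        frac = (pos - spec.phase) / spec.period % 1.0
        ri = 1.0 - frac if frac > 0 else 1.0
        true_indices[pos] = ri
        base_len = spec.functional_length_profile(pos)
        func_len = base_len * _lognormal_factor(rng, spec.noise_cv)
        repl_len = ri * base_len * _lognormal_factor(rng, spec.noise_cv)
        records.append(
            ToothRecord(
                specimen_id=spec.specimen_id,
                element=spec.element,
                side=spec.side,
                position=pos,
                tooth_class=ToothClass.FUNCTIONAL,
                generation=0,
                total_length=float(func_len),
            )
        )
        records.append(
            ToothRecord(
                specimen_id=spec.specimen_id,
                element=spec.element,
                side=spec.side,
                position=pos,
                tooth_class=ToothClass.REPLACEMENT,
                generation=1,
                total_length=float(repl_len),
            )
        )
    (specimen,) = build_specimens(records)
    provenance = {
        "generator": "simulate_dentition",
        "period": spec.period,
        "phase": spec.phase,
        "n_positions": spec.n_positions,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "true_replacement_indices": true_indices,
        "true_germ_age_days": {
            p: ri / spec.growth_per_day_fraction for p, ri in true_indices.items()
        },
    }
    return specimen, provenance


@dataclass
class IncrementSimSpec:
    n_days: int = 46
    mean_width: float = 12.0  # µm
    cv: float = 0.0
    seed: int | None = None
    tooth_id: str = "synthM1"
    specimen_id: str = "SYNTH-1"
    section_plane: SectionPlane = SectionPlane.CORONAL

    def __post_init__(self):
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if not self.mean_width > 0:
            raise ValidationError("mean_width must be > 0")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")


def simulate_increments(spec: IncrementSimSpec) -> tuple[IncrementSeries, dict]:
    """Daily dentine increment widths, lognormal around ``mean_width`` with
    the stated CV (exactly constant when cv = 0). The increment count always
    equals ``n_days``."""
    rng = np.random.default_rng(spec.seed)
    widths = spec.mean_width * _lognormal_factor(rng, spec.cv, size=spec.n_days)
    series = IncrementSeries(
        tooth_id=spec.tooth_id,
        specimen_id=spec.specimen_id,
        widths=widths,
        section_plane=spec.section_plane,
    )
    provenance = {
        "generator": "simulate_increments",
        "n_days": spec.n_days,
        "mean_width": spec.mean_width,
        "cv": spec.cv,
        "seed": spec.seed,
        "empirical_mean_width": float(np.mean(widths)),
    }
    return series, provenance


@dataclass
class MkSimSpec:
    tree: object  # CalibratedTree or dendropy.Tree with branch lengths
    Q: np.ndarray = None
    states: tuple = DEFAULT_STATES
    root_state: str | None = None  # None: draw from root_prior
    root_prior: object = "flat"
    seed: int | None = None

    def __post_init__(self):
        _validate_generator(self.Q, len(self.states))


def simulate_mk_tips(spec: MkSimSpec) -> tuple[CharacterMatrix, dict]:
    """Evolve a discrete character root→tips by exponential waiting times
    under Q. Returns the tip character matrix and provenance holding the
    true state of every node (keyed by node label)."""
    rng = np.random.default_rng(spec.seed)
    Q = np.asarray(spec.Q, dtype=float)
    k = len(spec.states)
    dtree = spec.tree.tree if isinstance(spec.tree, CalibratedTree) else spec.tree

    if spec.root_state is not None:
        root_idx = spec.states.index(spec.root_state)
    else:
        pi = _root_prior(spec.root_prior, Q, k)
        root_idx = int(rng.choice(k, p=pi))

    node_state: dict = {}
    true_states: dict = {}
    for i, node in enumerate(dtree.preorder_node_iter()):
        if node.parent_node is None:
            node_state[id(node)] = root_idx
        else:
            t = node.edge.length if node.edge.length is not None else 0.0
            start = node_state[id(node.parent_node)]
            events, _ = _sample_path_rejection(Q, start, None, t, rng)
            node_state[id(node)] = events[-1][1] if events else start
        label = _node_label(node) or f"nd{i}"
        true_states[label] = spec.states[node_state[id(node)]]

    tips = {
        leaf.taxon.label: spec.states[node_state[id(leaf)]]
        for leaf in dtree.leaf_node_iter()
    }
    chars = CharacterMatrix(data=tips, states=spec.states)
    provenance = {
        "generator": "simulate_mk_tips",
        "root_state": spec.states[root_idx],
        "seed": spec.seed,
        "true_node_states": true_states,
    }
    return chars, provenance


def random_calibrated_tree(
    n_tips: int, seed: int = 0, root_age: float = 100.0
) -> CalibratedTree:
    """A random birth-death (pure-birth) ultrametric tree rescaled so the
    root sits at ``root_age`` Ma — a convenient stand-in phylogeny for
    parameter-recovery experiments."""
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_random.Random(seed),
    )
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * root_age / depth
    # ages from depths; tips exactly at 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.age = root_age
        else:
            node.age = max(node.parent_node.age - node.edge.length, 0.0)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i}"
    i = 0
    for node in tree.postorder_internal_node_iter():
        if node.taxon is None and not node.label:
            i += 1
            node.label = f"n{i}"
    return CalibratedTree(tree=tree)
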