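"""Synthetic alignment generation under the reference model.

Elements are simulated column-wise i.i.d.: each column draws a Gamma
rate category, a root base from the stationary frequencies, and then
evolves down the tree with GTR transition matrices whose branch lengths
are multiplied by the branch's class scale (foreground/background).

Three validation scenarios are supported, mirroring how group data can
depart from the null:

1. every element of the group fully accelerated in one lineage;
2. a fraction L of each element's columns accelerated (motif-like);
3. a fraction M of the group's elements accelerated, the rest null.

Eight standard *cases* name the accelerated lineage on the bundled
10-taxon primate fixture tree: human; Hominini (human+chimp); the
African apes plus human; all great apes plus human; and the four
mis-specification controls chimp, gorilla, orangutan, macaque.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model_fit import ReferenceModel, define_foreground
from .phylo_engine import (
    Alignment,
    BranchScalingMap,
    GTRParams,
    Tree,
    discretize_gamma,
    gtr_rate_matrix,
    parse_newick,
    _eigendecompose,
)

#: Accelerated tip sets for the eight simulation cases.
CASE_LINEAGES: dict[int, frozenset[str]] = {
    1: frozenset({"human"}),
    2: frozenset({"human", "chimp"}),
    3: frozenset({"human", "chimp", "gorilla"}),
    4: frozenset({"human", "chimp", "gorilla", "orangutan"}),
    5: frozenset({"chimp"}),
    6: frozenset({"gorilla"}),
    7: frozenset({"orangutan"}),
    8: frozenset({"macaque"}),
}


def primate_tree() -> Tree:
    """The bundled 10-taxon primate fixture tree (branch lengths in
    expected substitutions/site)."""
    text = (
        resources.files("groupacc").joinpath("data/primate10.nwk").read_text()
    )
    return parse_newick(text)


def default_reference_model(alpha: float = 1.5) -> ReferenceModel:
    """Fixture reference model on the primate tree.

    GTR exchangeabilities follow the usual transition/transversion
    asymmetry of mammalian noncoding DNA (AG and CT about four-fold the
    transversions, GT fixed to 1) with mildly AT-rich base composition;
    alpha = 1.5 gives moderate among-site rate variation.
    """
    gtr = GTRParams(
        exchangeabilities=(1.2, 4.0, 0.8, 0.9, 4.4, 1.0),
        frequencies=(0.30, 0.20, 0.21, 0.29),
    )
    return ReferenceModel(
        tree=primate_tree(), gtr=gtr, rates=discretize_gamma(alpha, 4)
    )


@dataclass(frozen=True)
class SimScenarioConfig:
    """Configuration of one simulated group.

    ``fold`` is the true foreground/background rate ratio r1/r2.
    Scenario 2 sets ``partial_length`` (L, fraction of each element's
    columns accelerated); scenario 3 sets ``partial_elements`` (M,
    fraction of the group's elements accelerated); scenario 1 sets
    neither.
    """

    scenario: int
    case: int
    fold: float
    n_elements: int = 10_000
    element_length: int = 200
    partial_length: float | None = None   # L
    partial_elements: float | None = None  # M
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError(f"unknown scenario {self.scenario}")
        if self.case not in CASE_LINEAGES:
            raise ValueError(f"unknown case {self.case}")
        if self.fold <= 0 or self.n_elements <= 0 or self.element_length <= 0:
            raise ValueError("fold, n_elements, element_length must be positive")
        if self.scenario == 1 and (
            self.partial_length is not None or self.partial_elements is not None
        ):
            raise ValueError("scenario 1 takes neither L nor M")
        if self.scenario == 2:
            if self.partial_length is None or self.partial_elements is not None:
                raise ValueError("scenario 2 takes L (partial_length) only")
            if not 0 < self.partial_length <= 1:
                raise ValueError("L must be in (0, 1]")
        if self.scenario == 3:
            if self.partial_elements is None or self.partial_length is not None:
                raise ValueError("scenario 3 takes M (partial_elements) only")
            if not 0 < self.partial_elements <= 1:
                raise ValueError("M must be in (0, 1]")

    @property
    def accelerated_tips(self) -> frozenset[str]:
        return CASE_LINEAGES[self.case]


class _Evolver:
    """Cached per-(model, scaling) machinery for column-wise simulation."""

    def __init__(self, ref: ReferenceModel, scaling: BranchScalingMap):
        tree = ref.tree
        pi = np.asarray(ref.gtr.frequencies)
        q = gtr_rate_matrix(ref.gtr)
        lam, right, left = _eigendecompose(q, pi)
        scales = scaling.scales()
        k = ref.rates.k
        t_eff = (
            tree.branch_lengths[: tree.n_branches, None]
            * scales[:, None]
            * np.asarray(ref.rates.rates)[None, :]
        )
        ev = np.exp(lam[None, None, :] * t_eff[:, :, None])
        p = np.einsum("ij,bkj,jl->bkil", right, ev, left)
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=3, keepdims=True)
        self.cum = np.cumsum(p, axis=3)  # (branch, K, parent_state, child)
        self.pi_cum = np.cumsum(pi)
        self.tree = tree
        self.k = k

    def simulate_columns(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate ``n`` columns; returns states (n_nodes, n) in {0..3}."""
        tree = self.tree
        cats = rng.integers(0, self.k, size=n)
        states = np.empty((tree.n_nodes, n), dtype=np.int8)
        states[tree.root] = np.searchsorted(self.pi_cum, rng.random(n))
        for node in reversed(range(tree.n_nodes)):  # pre-order (root first)
            for child in tree.children[node]:
                u = rng.random(n)
                rows = self.cum[child, cats, states[node], :]
                states[child] = (u[:, None] > rows).sum(axis=1)
        return states


def _states_to_alignment(tree: Tree, states: np.ndarray, element_id=None):
    bases = np.array(list("ACGT"))
    seqs = {
        tree.tip_labels[i]: "".join(bases[states[i]]) for i in tree.tip_indices
    }
    return Alignment(seqs, element_id=element_id)


def simulate_alignment(
    ref: ReferenceModel,
    scaling: BranchScalingMap | None = None,
    length: int = 200,
    rng: np.random.Generator | int | None = None,
) -> Alignment:
    """Simulate one alignment of ``length`` columns under the scaled model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if scaling is None:
        scaling = BranchScalingMap(ref.tree.n_branches)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ev = _Evolver(ref, scaling)
    return _states_to_alignment(ref.tree, ev.simulate_columns(length, rng))


@dataclass
class SimTruth:
    """Ground truth for one simulated element."""

    element_id: str
    accelerated: bool
    scaled_columns: int


def make_scenario(
    config: SimScenarioConfig, ref: ReferenceModel
) -> tuple[list[Alignment], list[SimTruth]]:
    """Generate a group of elements plus their ground-truth labels.

    One RNG stream is derived per element from (seed, element index), so
    changing ``n_elements`` never perturbs earlier elements.  Scenario 2
    places each element's accelerated segment contiguously at the start.
    """
    fg_map = define_foreground(ref.tree, config.accelerated_tips)
    scaled = fg_map.with_scales(config.fold, 1.0)
    neutral = BranchScalingMap(ref.tree.n_branches)
    ev_scaled = _Evolver(ref, scaled)
    ev_neutral = _Evolver(ref, neutral)
    length = config.element_length

    if config.scenario == 2:
        n_scaled_cols = int(np.ceil(length * config.partial_length))
    n_accel_elems = (
        config.n_elements
        if config.scenario in (1, 2)
        else int(np.ceil(config.n_elements * config.partial_elements))
    )

    elements, truth = [], []
    for i in range(config.n_elements):
        rng = np.random.default_rng([config.seed, i])
        eid = f"sim_s{config.scenario}_c{config.case}_e{i:05d}"
        if config.scenario == 1:
            states = ev_scaled.simulate_columns(length, rng)
            cols = length if config.fold != 1.0 else 0
            accel = config.fold != 1.0
        elif config.scenario == 2:
            left = ev_scaled.simulate_columns(n_scaled_cols, rng)
            right = ev_neutral.simulate_columns(length - n_scaled_cols, rng)
            states = np.concatenate([left, right], axis=1)
            cols, accel = n_scaled_cols, config.fold != 1.0
        else:
            if i < n_accel_elems:
                states = ev_scaled.simulate_columns(length, rng)
                cols, accel = length, config.fold != 1.0
            else:
                states = ev_neutral.simulate_columns(length, rng)
                cols, accel = 0, False
        elements.append(_states_to_alignment(ref.tree, states, element_id=eid))
        truth.append(SimTruth(eid, accel, cols))
    return elements, truth


def weighted_fold_estimate(fold_hat: float, fraction: float) -> float:
    """Group-average fold implied by a fitted fold on a partial signal.

    When only a fraction (L of columns, or M of elements) carries a true
    fold f, the group behaves like fraction*f + (1 - fraction); applying
    the same weighting to the fitted fold makes estimates comparable to
    that group-average truth.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fold_hat <= 0:
        raise ValueError("fold must be positive")
    return fraction * fold_hat + (1.0 - fraction)


def write_fasta(alignment: Alignment, path, header_extra: str = "") -> None:
    """Write one element as multi-FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for taxon, seq in alignment.sequences.items():
            extra = f" {header_extra}" if header_extra else ""
            fh.write(f">{taxon}{extra}\n{seq}\n")
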