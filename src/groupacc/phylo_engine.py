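"""Core phylogenetic likelihood machinery.

Trees with stable branch identifiers, general time-reversible (GTR)
nucleotide rate matrices, discrete-Gamma among-site rate variation, and
the pruning (Felsenstein) algorithm with per-branch rate scaling.

All substitution-rate tests in this package are built on one primitive:
the log-likelihood of a nucleotide alignment under a fixed tree and GTR+G
model in which every branch length is multiplied by a class-specific
scale factor (foreground vs background).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import gamma as _gamma_dist

NUCLEOTIDES = "ACGT"

# IUPAC codes -> set of consistent bases; gaps and unknowns marginalize
# over all four states (missing-data convention).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}


def _char_partials() -> dict[str, np.ndarray]:
    out = {}
    for ch, bases in _IUPAC.items():
        v = np.zeros(4)
        for b in bases:
            v[NUCLEOTIDES.index(b)] = 1.0
        out[ch] = v
    return out


_CHAR_PARTIALS = _char_partials()


class PhyloError(ValueError):
    """Raised for invalid trees, models, or alignments."""


class Tree:
    """Rooted tree with branch lengths, stored as flat post-order arrays.

    Branch identifiers are the post-order index of the branch's child
    node, so they are deterministic for a given newick string.  Topology
    is immutable after construction.

    Attributes
    ----------
    n_nodes : total node count; nodes are indexed in post-order, so the
        root is index ``n_nodes - 1``.
    parent : parent index per node (-1 for the root).
    children : tuple of child-index tuples per node (empty for tips).
    branch_lengths : length of the branch above each node (expected
        substitutions per site under the reference model); NaN for root.
    tip_labels : taxon label per tip index (tips occupy the node indices
        with no children).
    """

    def __init__(self, parent, children, branch_lengths, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.children = tuple(tuple(c) for c in children)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.n_nodes = len(self.parent)
        self._labels = tuple(labels)
        self.tip_indices = tuple(
            i for i in range(self.n_nodes) if not self.children[i]
        )
        self.tip_labels = {i: self._labels[i] for i in self.tip_indices}
        self.label_to_tip = {v: k for k, v in self.tip_labels.items()}
        if len(self.label_to_tip) != len(self.tip_indices):
            raise PhyloError("duplicate tip labels in tree")
        lengths = self.branch_lengths[: self.n_nodes - 1]
        if np.any(~np.isfinite(lengths)) or np.any(lengths < 0):
            raise PhyloError("all non-root branches need a length >= 0")

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.tip_labels[i] for i in self.tip_indices)

    def postorder_internal(self):
        """Internal node indices in post-order (root last)."""
        return [i for i in range(self.n_nodes) if self.children[i]]

    def ancestors(self, node: int) -> list[int]:
        """Node indices on the path from ``node`` (exclusive) to the root."""
        out = []
        p = self.parent[node]
        while p != -1:
            out.append(int(p))
            p = self.parent[p]
        return out

    def clade_tips(self, node: int) -> frozenset[str]:
        """Tip labels of the clade rooted at ``node``."""
        stack, tips = [node], []
        while stack:
            n = stack.pop()
            if self.children[n]:
                stack.extend(self.children[n])
            else:
                tips.append(self.tip_labels[n])
        return frozenset(tips)

    def mrca(self, labels) -> int:
        """Most recent common ancestor node index of a set of tip labels."""
        labels = set(labels)
        unknown = labels - set(self.label_to_tip)
        if unknown:
            raise PhyloError(f"unknown tips: {sorted(unknown)}")
        tips = [self.label_to_tip[t] for t in labels]
        if len(tips) == 1:
            return tips[0]
        paths = [[t] + self.ancestors(t) for t in tips]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node = first along any tip-to-root path
        for n in paths[0]:
            if n in common:
                return n
        raise PhyloError("tree has no root on tip paths")  # pragma: no cover

    def with_scaled_lengths(self, factor: float) -> "Tree":
        bl = self.branch_lengths.copy()
        bl[: self.n_nodes - 1] *= factor
        return Tree(self.parent, self.children, bl, self._labels)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                s = self.tip_labels[i]
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i != self.root:
                s += f":{self.branch_lengths[i]:.10g}"
            return s

        return render(self.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a rooted newick string (branch lengths required) into a Tree.

    Branch IDs are post-order indices of each branch's child node.
    Raises :class:`PhyloError` on malformed input, duplicate tip labels,
    or a non-root edge with no length.
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise PhyloError(f"malformed newick: {exc}") from exc
    nodes = list(dt.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent, children, lengths, labels = [], [], [], []
    for i, n in enumerate(nodes):
        parent.append(index[id(n.parent_node)] if n.parent_node else -1)
        children.append(tuple(index[id(c)] for c in n.child_nodes()))
        if n.parent_node is None:
            lengths.append(np.nan)
        else:
            if n.edge.length is None:
                tok = n.taxon.label if n.taxon else "(internal node)"
                raise PhyloError(f"missing branch length at {tok!r}")
            lengths.append(float(n.edge.length))
        labels.append(n.taxon.label if n.taxon is not None else None)
    if nodes and not nodes[-1].parent_node and len(nodes[-1].child_nodes()) == 0:
        raise PhyloError("empty tree")
    return Tree(parent, children, lengths, labels)


@dataclass(frozen=True)
class GTRParams:
    """General time-reversible model parameters.

    ``exchangeabilities`` holds the six symmetric rate multipliers in the
    order (AC, AG, AT, CG, CT, GT); the GT term is conventionally fixed
    to 1 for identifiability.  ``frequencies`` are the stationary base
    frequencies in A, C, G, T order.
    """

    exchangeabilities: tuple[float, float, float, float, float, float]
    frequencies: tuple[float, float, float, float]

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, float)
        fr = np.asarray(self.frequencies, float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise PhyloError("need 6 positive exchangeabilities")
        if fr.shape != (4,) or np.any(fr <= 0):
            raise PhyloError("need 4 positive frequencies")
        if abs(fr.sum() - 1.0) > 1e-8:
            raise PhyloError("frequencies must sum to 1")


def gtr_rate_matrix(params: GTRParams) -> np.ndarray:
    """Instantaneous GTR rate matrix, normalized to mean rate 1.

    Rows sum to zero and the chain satisfies detailed balance
    pi_i q_ij = pi_j q_ji; the expected substitution rate at
    stationarity, -sum_i pi_i q_ii, equals 1 so that branch lengths are
    in expected substitutions per site.
    """
    ex = np.asarray(params.exchangeabilities, float)
    pi = np.asarray(params.frequencies, float)
    s = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    s[iu] = ex
    s += s.T
    q = s * pi[None, :]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    return q / scale


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = exp(Qt) for t >= 0."""
    if t < 0:
        raise PhyloError("branch length must be non-negative")
    from scipy.linalg import expm

    return expm(q * t)


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete-Gamma among-site rate variation.

    K equal-probability categories of a Gamma(alpha, alpha) distribution
    (mean 1), each represented by the mean rate within its quantile bin;
    the probability-weighted mean of the rates is exactly 1.
    """

    alpha: float
    rates: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def probabilities(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def discretize_gamma(alpha: float, k: int = 4) -> SiteRateModel:
    """Mean-of-bin discretization of Gamma(alpha, alpha) into k categories.

    The rate of category j is E[X | X in bin j] for equal-probability
    quantile bins, computed from the incomplete-gamma identity
    E[X; X<=q] = F_{alpha+1}(q) (for a mean-1 gamma), which keeps the
    weighted mean rate exactly 1.
    """
    if alpha <= 0:
        raise PhyloError("gamma shape alpha must be positive")
    if k < 1:
        raise PhyloError("need at least one rate category")
    if k == 1:
        return SiteRateModel(alpha=alpha, rates=(1.0,))
    edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # partial expectation of Gamma(a, a) up to q equals CDF of Gamma(a+1, a)
    pe = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = (pe[1:] - pe[:-1]) * k
    rates = rates / np.mean(rates)  # absorb ppf round-off
    return SiteRateModel(alpha=alpha, rates=tuple(rates))


@dataclass
class Alignment:
    """A multiple sequence alignment over a tree's taxa.

    ``sequences`` maps taxon label -> equal-length string over
    A/C/G/T/IUPAC ambiguity codes and gaps.  Taxa must be a subset of
    the tips of the tree it is scored against; missing taxa and
    ambiguous characters are marginalized as missing data.
    """

    sequences: dict[str, str]
    element_id: str | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise PhyloError("alignment rows have unequal lengths")
        bad = set("".join(self.sequences.values()).upper()) - set(_IUPAC)
        if bad:
            raise PhyloError(f"unknown characters in alignment: {sorted(bad)}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __len__(self) -> int:
        return self.n_columns

    @staticmethod
    def concatenate(alignments, element_id=None) -> "Alignment":
        alignments = list(alignments)
        if not alignments:
            raise PhyloError("nothing to concatenate")
        taxa = set(alignments[0].sequences)
        for a in alignments[1:]:
            if set(a.sequences) != taxa:
                raise PhyloError("taxon sets differ between elements")
        seqs = {
            t: "".join(a.sequences[t] for a in alignments) for t in alignments[0].taxa
        }
        return Alignment(seqs, element_id=element_id)


@dataclass(frozen=True)
class BranchScalingMap:
    """Foreground/background branch classes and the scale for each class.

    ``foreground`` holds branch IDs (post-order child-node indices)
    whose lengths are multiplied by ``foreground_scale``; every other
    branch is background and gets ``background_scale``.
    """

    n_branches: int
    foreground: frozenset[int] = frozenset()
    foreground_scale: float = 1.0
    background_scale: float = 1.0

    def __post_init__(self):
        if self.foreground_scale <= 0 or self.background_scale <= 0:
            raise PhyloError("branch scales must be positive")
        if any(b < 0 or b >= self.n_branches for b in self.foreground):
            raise PhyloError("foreground branch id out of range")

    def scales(self) -> np.ndarray:
        s = np.full(self.n_branches, self.background_scale)
        for b in self.foreground:
            s[b] = self.foreground_scale
        return s

    def with_scales(self, foreground: float, background: float) -> "BranchScalingMap":
        return BranchScalingMap(
            self.n_branches, self.foreground, foreground, background
        )


def _eigendecompose(q: np.ndarray, pi: np.ndarray):
    # reversible Q: symmetrize with sqrt(pi), eigh is stable and real
    d = np.sqrt(pi)
    s = (q * d[:, None]) / d[None, :]
    lam, v = np.linalg.eigh((s + s.T) / 2.0)
    return lam, v / d[:, None], (v * d[:, None]).T


class PruningKernel:
    """Cached pruning-algorithm evaluator for one alignment on one tree.

    Compresses site patterns once, encodes tip partial likelihoods, and
    exposes :meth:`loglik` as a function of per-branch scale factors.
    Transition matrices are built from a single eigendecomposition of Q,
    so each evaluation costs one small matrix product per branch per
    rate category.
    """

    def __init__(self, tree: Tree, gtr: GTRParams, rates: SiteRateModel,
                 alignment: Alignment, compress: bool = True):
        if alignment.n_columns == 0 or not alignment.sequences:
            raise PhyloError("empty alignment")
        extra = set(alignment.sequences) - set(tree.label_to_tip)
        if extra:
            raise PhyloError(f"alignment taxa not in tree: {sorted(extra)}")
        self.tree = tree
        self.set_model(gtr, rates)

        ncol = alignment.n_columns
        codes = np.zeros((len(tree.tip_indices), ncol), dtype=np.uint8)
        chars = sorted(_IUPAC)
        char_idx = {c: i for i, c in enumerate(chars)}
        missing = char_idx["N"]
        for row, tip in enumerate(tree.tip_indices):
            label = tree.tip_labels[tip]
            seq = alignment.sequences.get(label)
            if seq is None:
                codes[row, :] = missing
            else:
                codes[row, :] = [char_idx[c] for c in seq.upper()]
        if compress:
            patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
            patterns = patterns.T
        else:
            patterns, counts = codes, np.ones(ncol)
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        lut = np.stack([_CHAR_PARTIALS[c] for c in chars])
        k = rates.k
        # tip partials broadcast over rate categories: (K, n_pat, 4)
        self._tip_partials = {
            tip: np.ascontiguousarray(
                np.broadcast_to(lut[patterns[row]], (k, self.n_patterns, 4))
            )
            for row, tip in enumerate(tree.tip_indices)
        }
        self._postorder_internal = tree.postorder_internal()

    def set_model(self, gtr: GTRParams, rates: SiteRateModel) -> None:
        """Swap in new GTR/Gamma parameters, keeping the compressed patterns.

        The rate-category count must match the one used at construction.
        """
        if hasattr(self, "rates") and rates.k != self.rates.k:
            raise PhyloError("category count is fixed per kernel")
        self.gtr = gtr
        self.rates = rates
        self.pi = np.asarray(gtr.frequencies)
        q = gtr_rate_matrix(gtr)
        self._lam, self._right, self._left = _eigendecompose(q, self.pi)
        self._rate_vec = np.asarray(rates.rates)

    def _transition_matrices(self, branch_scales: np.ndarray) -> np.ndarray:
        """P^T for every (branch, category): shape (n_branches, K, 4, 4).

        The transpose is stored so the pruning step is a plain batched
        matmul, partial(child) @ P(child)^T.
        """
        t_eff = (
            self.tree.branch_lengths[: self.tree.n_branches, None]
            * branch_scales[:, None]
            * self._rate_vec[None, :]
        )
        ev = np.exp(self._lam[None, None, :] * t_eff[:, :, None])
        # P = right @ diag(ev) @ left; build P^T = left^T @ diag(ev) @ right^T
        pt = np.matmul(self._left.T[None, None] * ev[:, :, None, :],
                       self._right.T)
        np.maximum(pt, 0.0, out=pt)
        return pt

    def loglik(self, branch_scales) -> float:
        """Alignment log-likelihood with each branch scaled by its factor."""
        branch_scales = np.asarray(branch_scales, float)
        pt = self._transition_matrices(branch_scales)
        partials = {}
        logscale = np.zeros((self.rates.k, self.n_patterns))
        for node in self._postorder_internal:
            part = None
            for child in self.tree.children[node]:
                cp = partials.pop(child, None)
                if cp is None:
                    cp = self._tip_partials[child]
                msg = np.matmul(cp, pt[child])
                if part is None:
                    part = msg
                else:
                    part *= msg
            # rescale to avoid underflow on deep trees / long alignments
            mx = part.max(axis=2)
            safe = np.where(mx > 0, mx, 1.0)
            part /= safe[:, :, None]
            logscale += np.log(safe)
            partials[node] = part
        root_part = partials[self.tree.root]
        site_by_cat = root_part @ self.pi  # (K, n_pat)
        with np.errstate(divide="ignore"):
            # mix over categories in the rescaled domain, per column
            m = logscale.max(axis=0)
            site = np.exp(logscale - m[None, :]) * site_by_cat
            site_mean = self.rates.probabilities @ site
            ll = float(np.dot(self.counts, np.log(site_mean) + m))
        if not np.isfinite(ll):
            return -np.inf
        return ll

    def loglik_map(self, scaling: BranchScalingMap) -> float:
        return self.loglik(scaling.scales())


def alignment_log_likelihood(
    alignment: Alignment,
    tree: Tree,
    gtr: GTRParams,
    rates: SiteRateModel,
    scaling: BranchScalingMap | None = None,
    compress: bool = True,
) -> float:
    """Log-likelihood of an alignment under GTR+Gamma with branch scaling.

    Gaps, Ns, partially ambiguous IUPAC codes, and taxa missing from the
    alignment are marginalized as missing data.  Identical columns are
    collapsed to shared site patterns unless ``compress`` is False.
    """
    kernel = PruningKernel(tree, gtr, rates, alignment, compress=compress)
    if scaling is None:
        scaling = BranchScalingMap(tree.n_branches)
    return kernel.loglik_map(scaling)
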