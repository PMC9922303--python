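"""Model fitting and the group-level likelihood ratio test.

The analysis is anchored on a *reference model*: tree branch lengths,
GTR exchangeabilities and base frequencies, and the Gamma shape fitted
by maximum likelihood to the concatenation of all elements.  Group-level
hypotheses then scale the reference branch lengths only:

* H0 — one global scale r applied to every branch;
* Ha — a foreground scale r1 and a background scale r2.

Twice the log-likelihood difference between Ha and H0 is compared to a
chi-square distribution with one degree of freedom, and a group is
called accelerated when the test rejects with r1 > r2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .phylo_engine import (
    Alignment,
    BranchScalingMap,
    GTRParams,
    PhyloError,
    PruningKernel,
    SiteRateModel,
    Tree,
    discretize_gamma,
)

SCALE_BOUNDS = (1e-4, 1e3)
_LOG_BOUNDS = (np.log(SCALE_BOUNDS[0]), np.log(SCALE_BOUNDS[1]))


@dataclass
class ReferenceModel:
    """Calibrated backbone model that all group tests scale."""

    tree: Tree
    gtr: GTRParams
    rates: SiteRateModel
    log_likelihood: float | None = None

    def kernel(self, alignment: Alignment) -> PruningKernel:
        return PruningKernel(self.tree, self.gtr, self.rates, alignment)

    # -- plain-text serialization (versioned, round-trips exactly) ----
    def to_text(self) -> str:
        lines = ["#groupacc-reference-model v1"]
        lines.append("tree\t" + self.tree.to_newick())
        ex = "\t".join(repr(x) for x in self.gtr.exchangeabilities)
        fr = "\t".join(repr(x) for x in self.gtr.frequencies)
        lines.append("exchangeabilities\t" + ex)
        lines.append("frequencies\t" + fr)
        lines.append(f"alpha\t{self.rates.alpha!r}")
        lines.append(f"categories\t{self.rates.k}")
        if self.log_likelihood is not None:
            lines.append(f"loglik\t{self.log_likelihood!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReferenceModel":
        from .phylo_engine import parse_newick

        fields = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("\t")
            fields[key] = rest
        tree = parse_newick(fields["tree"])
        gtr = GTRParams(
            tuple(float(x) for x in fields["exchangeabilities"].split("\t")),
            tuple(float(x) for x in fields["frequencies"].split("\t")),
        )
        rates = discretize_gamma(float(fields["alpha"]), int(fields["categories"]))
        ll = float(fields["loglik"]) if "loglik" in fields else None
        return cls(tree=tree, gtr=gtr, rates=rates, log_likelihood=ll)


@dataclass
class GroupFitNull:
    """H0 fit: one global branch-length scale for the whole tree."""

    scale: float
    log_likelihood: float
    converged: bool = True

    @property
    def n_parameters(self) -> int:
        return 1


@dataclass
class GroupFitAlt:
    """Ha fit: separate foreground (r1) and background (r2) scales."""

    r1: float
    r2: float
    log_likelihood: float
    scaling: BranchScalingMap
    converged: bool = True

    @property
    def fold(self) -> float:
        return self.r1 / self.r2

    @property
    def n_parameters(self) -> int:
        return 2


@dataclass
class LRTResult:
    statistic: float
    p_value: float
    p_bonferroni: float
    foreground_faster: bool
    fold: float


def fit_reference_model(
    concat: Alignment,
    topology: Tree,
    k_categories: int = 4,
    max_cycles: int = 10,
    tol: float = 1e-3,
) -> ReferenceModel:
    """Fit branch lengths, GTR parameters, and Gamma shape to a concatenation.

    The topology is fixed; parameters are optimized in coordinate blocks
    (branch lengths | exchangeabilities + frequencies | alpha), cycling
    until the log-likelihood improves by less than ``tol``.
    """
    gtr0 = _empirical_gtr_start(concat)
    rates = discretize_gamma(1.0, k_categories)
    kernel = PruningKernel(topology, gtr0, rates, concat)
    if kernel.n_patterns < 2:
        raise PhyloError("fewer than 2 distinct site patterns: nothing to fit")

    gtr, alpha = gtr0, 1.0
    scales = np.ones(topology.n_branches)
    ll = kernel.loglik(scales)
    for _ in range(max_cycles):
        ll_start = ll
        # 1) branch lengths, as per-branch log scales of the input lengths
        res = minimize(
            lambda x: -kernel.loglik(np.exp(x)),
            np.log(np.clip(scales, 1e-8, None)),
            method="L-BFGS-B",
            bounds=[(-12.0, 6.0)] * topology.n_branches,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        scales = np.exp(res.x)
        # 2) GTR exchangeabilities (GT fixed to 1) and frequencies
        def gtr_obj(x):
            g = _vector_to_gtr(x)
            kernel.set_model(g, kernel.rates)
            return -kernel.loglik(scales)

        x0 = np.concatenate(
            [np.log(np.asarray(gtr.exchangeabilities[:5])
                    / gtr.exchangeabilities[5]),
             np.log(np.asarray(gtr.frequencies[:3]) / gtr.frequencies[3])]
        )
        res = minimize(gtr_obj, x0, method="L-BFGS-B",
                       bounds=[(-8, 8)] * 8, options={"maxiter": 200})
        gtr = _vector_to_gtr(res.x)
        # 3) gamma shape
        def alpha_obj(log_a):
            kernel.set_model(gtr, discretize_gamma(float(np.exp(log_a)), k_categories))
            return -kernel.loglik(scales)

        res = minimize_scalar(alpha_obj, bounds=(np.log(0.02), np.log(100.0)),
                              method="bounded",
                              options={"xatol": 1e-4})
        alpha = float(np.exp(res.x))
        kernel.set_model(gtr, discretize_gamma(alpha, k_categories))
        ll = kernel.loglik(scales)
        if ll - ll_start < tol:
            break

    fitted_tree = Tree(
        topology.parent,
        topology.children,
        np.append(topology.branch_lengths[:-1] * scales, np.nan),
        [topology.tip_labels.get(i) for i in range(topology.n_nodes)],
    )
    return ReferenceModel(
        tree=fitted_tree,
        gtr=gtr,
        rates=discretize_gamma(alpha, k_categories),
        log_likelihood=ll,
    )


def _empirical_gtr_start(aln: Alignment) -> GTRParams:
    counts = np.ones(4)
    for seq in aln.sequences.values():
        for i, b in enumerate("ACGT"):
            counts[i] += seq.upper().count(b)
    freqs = counts / counts.sum()
    return GTRParams((1.0,) * 6, tuple(freqs))


def _vector_to_gtr(x: np.ndarray) -> GTRParams:
    ex = np.append(np.exp(x[:5]), 1.0)
    f = np.append(np.exp(x[5:8]), 1.0)
    f = f / f.sum()
    return GTRParams(tuple(ex), tuple(f))


def _fit_scalar(kernel: PruningKernel, to_scales, coarse_grid=None):
    """Maximize loglik over one positive scale: log grid, then Brent."""
    if coarse_grid is None:
        coarse_grid = np.exp(np.linspace(*_LOG_BOUNDS, 15))
    vals = [kernel.loglik(to_scales(r)) for r in coarse_grid]
    i = int(np.argmax(vals))
    lo = np.log(coarse_grid[max(i - 1, 0)])
    hi = np.log(coarse_grid[min(i + 1, len(coarse_grid) - 1)])
    if lo == hi:  # degenerate single-point grid
        return float(coarse_grid[i]), float(vals[i]), True
    res = minimize_scalar(
        lambda lr: -kernel.loglik(to_scales(np.exp(lr))),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-7},
    )
    r = float(np.exp(res.x))
    ll = float(-res.fun)
    if vals[i] > ll:  # keep grid point if refinement slipped
        r, ll = float(coarse_grid[i]), float(vals[i])
    at_bound = i in (0, len(coarse_grid) - 1)
    return r, ll, not at_bound


def fit_global_scale(
    group_aln: Alignment, ref: ReferenceModel, kernel: PruningKernel | None = None
) -> GroupFitNull:
    """H0: one global branch-length scale, all other parameters fixed."""
    if kernel is None:
        kernel = ref.kernel(group_aln)
    n = kernel.tree.n_branches
    r, ll, ok = _fit_scalar(kernel, lambda r: np.full(n, r))
    if not ok:
        warnings.warn("global scale at optimization bound", RuntimeWarning)
    return GroupFitNull(scale=r, log_likelihood=ll, converged=ok)


def define_foreground(tree: Tree, clade_tips) -> BranchScalingMap:
    """Branch classes for a foreground clade given by its tip labels.

    The foreground is the clade's stem branch plus every branch inside
    the clade; a single tip yields just that terminal branch.  The tip
    set must be monophyletic in the rooted tree.
    """
    if isinstance(clade_tips, str):
        clade_tips = {clade_tips}
    clade_tips = frozenset(clade_tips)
    mrca = tree.mrca(clade_tips)
    observed = tree.clade_tips(mrca)
    if observed != clade_tips:
        extra = sorted(observed - clade_tips)
        raise PhyloError(
            f"tips {sorted(clade_tips)} are not monophyletic; their MRCA "
            f"also contains {extra}"
        )
    fg = []
    stack = [mrca]
    while stack:
        n = stack.pop()
        fg.append(n)  # branch above n (the stem branch for n == mrca)
        stack.extend(tree.children[n])
    return BranchScalingMap(tree.n_branches, frozenset(fg))


def fit_two_scales(
    group_aln: Alignment,
    ref: ReferenceModel,
    fg: BranchScalingMap,
    kernel: PruningKernel | None = None,
    null_fit: GroupFitNull | None = None,
    multistart: bool = True,
) -> GroupFitAlt:
    """Ha: joint ML fit of foreground scale r1 and background scale r2.

    Started from the H0 global scale (and optionally from half and twice
    it — the surface can be flat in r1 for short foreground branches).
    """
    if kernel is None:
        kernel = ref.kernel(group_aln)
    if null_fit is None:
        null_fit = fit_global_scale(group_aln, ref, kernel=kernel)
    base = fg.scales()
    fg_mask = base.copy()
    for b in fg.foreground:
        fg_mask[b] = np.nan
    fg_idx = np.isnan(fg_mask)

    def to_scales(r1, r2):
        s = np.full(kernel.tree.n_branches, r2)
        s[fg_idx] = r1
        return s

    def obj(x):
        return -kernel.loglik(to_scales(np.exp(x[0]), np.exp(x[1])))

    r0 = np.clip(null_fit.scale, *SCALE_BOUNDS)
    starts = [r0] + ([0.5 * r0, 2.0 * r0] if multistart else [])
    best = None
    for s0 in starts:
        res = minimize(
            obj,
            np.log([s0, s0]),
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS, _LOG_BOUNDS],
            options={"maxiter": 100, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    r1, r2 = np.exp(best.x)
    ll = float(-best.fun)
    # nesting guarantee: Ha contains H0, never report worse than the null
    if ll < null_fit.log_likelihood:
        r1 = r2 = null_fit.scale
        ll = null_fit.log_likelihood
    at_bound = bool(
        np.any(np.isclose(best.x, _LOG_BOUNDS[0])) or
        np.any(np.isclose(best.x, _LOG_BOUNDS[1]))
    )
    return GroupFitAlt(
        r1=float(r1), r2=float(r2), log_likelihood=ll,
        scaling=fg.with_scales(float(r1), float(r2)),
        converged=not at_bound,
    )


def group_lrt(
    null: GroupFitNull, alt: GroupFitAlt, m_tests: int = 1
) -> LRTResult:
    """Chi-square (1 df) test of Ha (r1, r2) against H0 (single scale).

    The statistic is twice the log-likelihood difference, clipped at
    zero; acceleration additionally requires r1 > r2 (direction flag).
    """
    stat = 2.0 * (alt.log_likelihood - null.log_likelihood)
    if stat < -1e-4:
        warnings.warn(
            f"alternative fit worse than null by {stat / 2:.4g}; "
            "check optimizer convergence", RuntimeWarning,
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1))
    return LRTResult(
        statistic=stat,
        p_value=p,
        p_bonferroni=float(min(1.0, m_tests * p)),
        foreground_faster=alt.r1 > alt.r2,
        fold=alt.fold,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)
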