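"""BIC scan over nested candidate foreground clades.

Rejecting the null with a focal-tip foreground says a rate shift touches
that tip's history, but not *when* it happened.  The scan fits the
two-scale alternative model once per candidate foreground — the focal
tip alone, then every monophyletic clade containing it (excluding the
whole tree) — and ranks the fits by BIC = -2*l + k*log(n) with k = 2
(r1 and r2) and n the number of alignment columns.  The candidate with
the lowest BIC, ties broken toward the smaller (tip-ward) clade, is the
best-fit lineage for the rate shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_fit import (
    GroupFitAlt,
    ReferenceModel,
    define_foreground,
    fit_global_scale,
    fit_two_scales,
)
from .phylo_engine import Alignment, PhyloError, Tree


@dataclass
class CandidateFit:
    label: str                 # M1 (focal tip) .. Mk (near-root clade)
    clade_tips: frozenset[str]
    fit: GroupFitAlt
    bic: float
    n_parameters: int = 2


@dataclass
class LineageScanResult:
    candidates: list[CandidateFit]
    n_columns: int
    best_index: int

    @property
    def best(self) -> CandidateFit:
        return self.candidates[self.best_index]


def enumerate_focal_clades(tree: Tree, focal_tip: str) -> list[frozenset[str]]:
    """Nested candidate foregrounds containing a focal tip, tip-to-root.

    The first candidate is the focal tip alone; each subsequent one is
    the clade of the next ancestor, stopping short of the root (the full
    tree is not a candidate: with every branch in the foreground, r1 and
    r2 are not separately identifiable).
    """
    if focal_tip not in tree.label_to_tip:
        raise PhyloError(f"unknown tip {focal_tip!r}")
    tip = tree.label_to_tip[focal_tip]
    out = [frozenset({focal_tip})]
    for anc in tree.ancestors(tip):
        if anc == tree.root:
            break
        out.append(tree.clade_tips(anc))
    return out


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2*l + k*log(n); lower is better."""
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    return -2.0 * loglik + k * np.log(n)


def scan_lineages(
    group_aln: Alignment,
    ref: ReferenceModel,
    focal_tip: str,
) -> LineageScanResult:
    """Fit the two-scale model for every candidate foreground, rank by BIC.

    The sample size n is the number of alignment columns of the group
    concatenation.  The null fit is shared across candidates as the
    optimizer's starting point.
    """
    kernel = ref.kernel(group_aln)
    null = fit_global_scale(group_aln, ref, kernel=kernel)
    n = group_aln.n_columns
    candidates = []
    for i, tips in enumerate(enumerate_focal_clades(ref.tree, focal_tip)):
        fg = define_foreground(ref.tree, tips)
        fit = fit_two_scales(
            group_aln, ref, fg, kernel=kernel, null_fit=null
        )
        candidates.append(
            CandidateFit(
                label=f"M{i + 1}",
                clade_tips=tips,
                fit=fit,
                bic=bic(fit.log_likelihood, 2, n),
            )
        )
    bics = np.array([c.bic for c in candidates])
    # argmin takes the first minimum: ties resolve toward the smaller clade
    best = int(np.argmin(bics))
    return LineageScanResult(candidates=candidates, n_columns=n, best_index=best)
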