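import itertools

import numpy as np
import pytest
from hypothesis import settings

import groupacc as ga

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def primate_tree():
    return ga.primate_tree()


@pytest.fixture(scope="session")
def ref_model():
    return ga.default_reference_model()


@pytest.fixture(scope="session")
def human_foreground(ref_model):
    return ga.define_foreground(ref_model.tree, {"human"})


@pytest.fixture
def gtr_params():
    return ga.GTRParams(
        exchangeabilities=(1.2, 4.0, 0.8, 0.9, 4.4, 1.0),
        frequencies=(0.30, 0.20, 0.21, 0.29),
    )


@pytest.fixture
def jc_params():
    return ga.GTRParams((1.0,) * 6, (0.25,) * 4)


def random_alignment(tree, n_columns, seed=0):
    rng = np.random.default_rng(seed)
    return ga.Alignment(
        {t: "".join(rng.choice(list("ACGT"), n_columns)) for t in tree.taxa}
    )


def brute_force_loglik(aln, tree, gtr, rates):
    """Exhaustive sum over internal-node state assignments.

    Independent oracle for the pruning algorithm: per column and rate
    category, enumerates every assignment of A/C/G/T to the internal
    nodes, multiplying stationary root probability and per-branch
    transition probabilities.  Ambiguity codes contribute a sum over
    their consistent tip states.
    """
    from groupacc.phylo_engine import _CHAR_PARTIALS, gtr_rate_matrix
    from scipy.linalg import expm

    q = gtr_rate_matrix(gtr)
    pi = np.asarray(gtr.frequencies)
    internal = tree.postorder_internal()
    tips = list(tree.tip_indices)
    ll = 0.0
    for col in range(aln.n_columns):
        site = 0.0
        for rate in rates.rates:
            p_mats = {
                b: expm(q * rate * tree.branch_lengths[b])
                for b in range(tree.n_branches)
            }
            tot = 0.0
            tip_state_sets = []
            for t in tips:
                seq = aln.sequences.get(tree.tip_labels[t])
                ch = seq[col].upper() if seq is not None else "N"
                mask = _CHAR_PARTIALS[ch]
                tip_state_sets.append([s for s in range(4) if mask[s] > 0])
            for tip_states in itertools.product(*tip_state_sets):
                for int_states in itertools.product(range(4), repeat=len(internal)):
                    st = dict(zip(internal, int_states))
                    st.update(zip(tips, tip_states))
                    pr = pi[st[tree.root]]
                    for b in range(tree.n_branches):
                        pr *= p_mats[b][st[tree.parent[b]], st[b]]
                    tot += pr
            site += tot / rates.k
        ll += np.log(site)
    return ll
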