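import numpy as np
import pytest

from clonalfam import (
    SizeLaw,
    default_parameter_set,
    fixture_germline_set,
)
from clonalfam.simulate import simulate_repertoire
from clonalfam.sw import SequenceRecord, annotate_reads


@pytest.fixture(scope="session")
def germline():
    return fixture_germline_set()


@pytest.fixture(scope="session")
def params(germline):
    return default_parameter_set(germline)


@pytest.fixture(scope="session")
def identity_read(germline):
    """Exact V+D+J concatenation of the first fixture gene of each region."""
    v, d, j = (germline.region_genes(r)[0] for r in "VDJ")
    return v.seq + d.seq + j.seq, (v, d, j)


@pytest.fixture(scope="session")
def small_sample(germline, params):
    """~10 families x ~10 leaves at 5% mutation, annotated; with truth."""
    rep = simulate_repertoire(params, germline, SizeLaw("geometric", mean=10), 100, seed=1)
    records = annotate_reads(
        [SequenceRecord(rid, seq) for rid, seq in rep.reads.items()], germline
    )
    return rep, records


@pytest.fixture(scope="session")
def trained_params(germline, small_sample):
    from clonalfam.sw import viterbi_train

    _, records = small_sample
    return viterbi_train(records, germline)


def random_hmm(rng, n_states=None, alphabet="HT"):
    """A random small generic HMM for oracle comparisons."""
    from clonalfam.hmm import HmmModel

    S = int(n_states or rng.integers(2, 9))
    A = len(alphabet)
    init = rng.dirichlet(np.ones(S))
    emit = rng.dirichlet(np.ones(A), size=S)
    out = rng.dirichlet(np.ones(S + 1), size=S)  # last column = end
    trans, end = out[:, :S].copy(), out[:, S].copy()
    # knock out some transitions to exercise impossible paths
    mask = rng.random((S, S)) < 0.2
    trans[mask] = 0.0
    rowsum = trans.sum(axis=1)
    keep = rowsum + end > 0
    trans[keep] = trans[keep] * (1 - end[keep, None]) / np.where(rowsum[keep] > 0, rowsum[keep], 1.0)[:, None]
    trans[~keep] = 0.0
    end[~keep] = 1.0
    with np.errstate(divide="ignore"):
        return HmmModel(
            state_names=[f"s{i}" for i in range(S)],
            log_init=np.log(init),
            log_trans=np.log(trans),
            log_end=np.log(end),
            log_emit=np.log(emit),
            alphabet=alphabet,
            ambiguous="N",
        )


def enumerate_paths(seqs, model):
    """Exhaustive oracle: sum and max of joint path probabilities.

    Returns (log sum, log max) over every state path of the right
    length, computed in plain probability space.
    """
    from itertools import product

    L = len(seqs[0])
    S = model.n_states
    sym = {c: i for i, c in enumerate(model.alphabet)}
    init = np.exp(model.log_init)
    trans = np.exp(model.log_trans)
    end = np.exp(model.log_end)
    emit = np.exp(model.log_emit)

    def e(state, t):
        p = 1.0
        for s in seqs:
            if s[t] != model.ambiguous:
                p *= emit[state, sym[s[t]]]
        return p

    total = 0.0
    best = 0.0
    for path in product(range(S), repeat=L):
        p = init[path[0]] * e(path[0], 0)
        for t in range(1, L):
            p *= trans[path[t - 1], path[t]] * e(path[t], t)
        p *= end[path[-1]]
        total += p
        best = max(best, p)
    return (
        np.log(total) if total > 0 else float("-inf"),
        np.log(best) if best > 0 else float("-inf"),
    )
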