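"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the Viterbi oracle
enumerates every legal state path recursively; the Bayes oracle applies
Bayes' rule with plain arithmetic.
"""

from __future__ import annotations

import math

from cdpsmine.hmmcore import AA_INDEX


def enumerate_viterbi(hmm, protein: str) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Paths enter at any match state on any residue, move through
    M/I/D states under the model's transition scores, and exit from any
    match state. Exponential; only for tiny models/proteins.
    """
    enc = [AA_INDEX.get(a, -1) for a in protein]
    k = hmm.n_states
    n = len(enc)
    m = hmm._m_score
    best = 0.0

    def emit(j: int, i: int) -> float:
        return float(m[j][enc[i]]) if enc[i] >= 0 else 0.0

    def walk(state: str, j: int, i: int, score: float) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)
        if state == "M":
            if i < n:
                walk("I", j, i + 1, score + hmm._l_mi[j])
            if j + 1 < k:
                if i < n:
                    walk("M", j + 1, i + 1, score + hmm._l_mm[j] + emit(j + 1, i))
                walk("D", j + 1, i, score + hmm._l_md[j])
        elif state == "I":
            if i < n:
                walk("I", j, i + 1, score + hmm._l_ii[j])
            if j + 1 < k and i < n:
                walk("M", j + 1, i + 1, score + hmm._l_im[j] + emit(j + 1, i))
        elif state == "D":
            if j + 1 < k:
                walk("D", j + 1, i, score + hmm._l_dd[j])
                if i < n:
                    walk("M", j + 1, i + 1, score + hmm._l_dm[j] + emit(j + 1, i))

    for j in range(k):
        for i in range(n):
            walk("M", j, i + 1, emit(j, i))
    return best


def bayes_posterior(priors: dict, likelihoods: list[dict], vector: str) -> dict:
    """Posterior over classes by direct Bayes-rule arithmetic."""
    unnorm = {}
    for c, prior in priors.items():
        p = prior
        for pos, cat in enumerate(vector):
            p *= likelihoods[pos][c][cat]
        unnorm[c] = p
    z = sum(unnorm.values())
    return {c: v / z for c, v in unnorm.items()}


def random_profile_hmm(rng, n_states: int, name: str = "toy"):
    """A random valid ProfileHmm for oracle-equivalence testing."""
    import numpy as np

    from cdpsmine.hmmcore import ProfileHmm

    emissions = rng.dirichlet([0.5] * 20, size=n_states)
    t3 = rng.dirichlet([1.0] * 3, size=n_states)
    t2a = rng.dirichlet([1.0] * 2, size=n_states)
    t2b = rng.dirichlet([1.0] * 2, size=n_states)
    return ProfileHmm(
        name=name,
        match_emissions=emissions,
        t_mm=t3[:, 0],
        t_mi=t3[:, 1],
        t_md=t3[:, 2],
        t_im=t2a[:, 0],
        t_ii=t2a[:, 1],
        t_dm=t2b[:, 0],
        t_dd=t2b[:, 1],
        column_index=list(range(n_states)),
    )
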