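"""Independent reference computations used only by the tests.

These deliberately avoid the package's likelihood code paths: the
enumeration oracle walks every assembly history of the sequential
immigration/copy process by dynamic programming over canonical states, and
the Ewens formula is written directly from its closed form.
"""

from __future__ import annotations

import math


def enumerate_sad_probs(theta: float, I: float, J: int) -> dict:
    """Exact probability of every unordered SAD of J individuals under the
    neutral sampling process, by exhaustive dynamic programming.

    State: sorted tuple of species, each species a sorted tuple of
    immigrant-lineage sizes.  Step n adds one individual: a new immigrant
    lineage with probability I/(I+n) (species chosen by a Chinese-restaurant
    step at rate theta over lineages), else a copy of a uniformly chosen
    earlier individual.  Probabilities of histories reaching the same
    canonical state are accumulated, so the result is exact.
    """
    states: dict[tuple, float] = {(): 1.0}
    for n in range(J):
        new: dict[tuple, float] = {}

        def add(key, pr):
            new[key] = new.get(key, 0.0) + pr

        for state, prob in states.items():
            T = sum(len(sp) for sp in state)
            p_imm = 1.0 if n == 0 else I / (I + n)
            # immigration joining an existing species
            for si, sp in enumerate(state):
                f = p_imm * len(sp) / (theta + T)
                ns = list(state)
                ns[si] = tuple(sorted(sp + (1,)))
                add(tuple(sorted(ns)), prob * f)
            # immigration founding a new species
            add(tuple(sorted(state + ((1,),))),
                prob * p_imm * theta / (theta + T))
            # copy of an existing individual
            if n > 0:
                p_copy = n / (I + n)
                for si, sp in enumerate(state):
                    for li, size in enumerate(sp):
                        lg = list(sp)
                        lg[li] = size + 1
                        ns = list(state)
                        ns[si] = tuple(sorted(lg))
                        add(tuple(sorted(ns)), prob * p_copy * size / n)
        states = new
    out: dict[tuple, float] = {}
    for state, prob in states.items():
        sad = tuple(sorted(sum(sp) for sp in state))
        out[sad] = out.get(sad, 0.0) + prob
    return out


def ewens_prob(abundances, theta: float) -> float:
    """Closed-form Ewens sampling formula for an unordered configuration."""
    n = list(abundances)
    J, S = sum(n), len(n)
    phi: dict[int, int] = {}
    for a in n:
        phi[a] = phi.get(a, 0) + 1
    num = math.factorial(J) * theta**S
    den = 1.0
    for k in range(J):
        den *= theta + k
    for a in n:
        den *= a
    for c in phi.values():
        den *= math.factorial(c)
    return num / den


def sloan_triple(N_i: int, N_T: int, m: float, p_i: float):
    """Direct transcription of the three transition probabilities."""
    up = (1 - N_i / N_T) * (m * p_i + (1 - m) * N_i / (N_T - 1))
    down = (N_i / N_T) * (m * (1 - p_i) + (1 - m) * (N_T - N_i) / (N_T - 1))
    return up, down, 1 - up - down
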