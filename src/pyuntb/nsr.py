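"""Stochasticity quantification: Ruzicka similarity, null models, SR and NSR.

The premise: deterministic assembly drives communities to be more similar
(or more dissimilar) than expected under a null model of stochastic
assembly.  For each pair of samples the observed Ruzicka similarity C_ij
(the abundance-weighted Jaccard index, sum of per-species minima over sum of
maxima of relative abundances) is compared with the mean similarity E_ij of
the pair over many null-model randomizations of the metacommunity:

    pairs with C_ij > E_ij (determinism makes them more similar):
        SR_ij = E_ij / C_ij
    pairs with C_ij < E_ij (determinism makes them less similar):
        SR_ij = (1 - E_ij) / (1 - C_ij)

and the stochasticity ratio SR is the average of these per-pair ratios over
all non-tied pairs.  SR runs from 0 (fully deterministic) to 1 (observed
similarity indistinguishable from the null, fully stochastic).  Exact ties
C_ij = E_ij are excluded from both counts: the defining inequalities are
strict, and with continuous abundances ties have measure zero.

Because SR can overstate stochasticity when the null expectation is low,
the normalized ratio NSR rescales SR between its attainable extremes: the
fully deterministic configuration (observed similarity pushed to 1 for
more-similar pairs and 0 for less-similar pairs) maps to 0 and the
null-coincident configuration maps to 1.

Null algorithms are pluggable:

* ``proportional_frequency`` (default): each null sample keeps the observed
  sample's richness, draws that many species without replacement with
  probability proportional to their regional occupancy frequency, and
  assigns them relative abundances proportional to their regional mean
  relative abundances, renormalized.
* ``richness_uniform``: keeps richness, draws species uniformly from the
  regional pool, equal relative abundances.
* ``identity``: returns the observed data (a degenerate null for testing:
  the expected similarity then equals the observed similarity exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .community import CommunityMatrix, to_relative_abundance

__all__ = ["StochasticityResult", "ruzicka_similarity", "pairwise_ruzicka",
           "null_expected_similarity", "stochasticity_ratio",
           "normalized_sr", "compute_stochasticity", "NULL_ALGORITHMS"]


def ruzicka_similarity(p, q) -> float:
    """Sum of componentwise minima over sum of maxima (in [0, 1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("entries must be >= 0")
    denom = np.maximum(p, q).sum()
    if denom == 0:
        raise ValueError("similarity undefined for two all-zero vectors")
    return float(np.minimum(p, q).sum() / denom)


def pairwise_ruzicka(rel: np.ndarray) -> np.ndarray:
    """Symmetric similarity matrix over the columns of a species x sample
    relative-abundance matrix."""
    n = rel.shape[1]
    C = np.ones((n, n))
    for i in range(n):
        pi = rel[:, i:i + 1]
        mins = np.minimum(pi, rel[:, i + 1:]).sum(axis=0)
        maxs = np.maximum(pi, rel[:, i + 1:]).sum(axis=0)
        C[i, i + 1:] = C[i + 1:, i] = mins / maxs
    return C


# ---------------------------------------------------------------------------
# null models

def _regional_stats(cm: CommunityMatrix):
    rel = to_relative_abundance(cm)
    richness = (cm.counts > 0).sum(axis=0)
    occupancy = (cm.counts > 0).mean(axis=1)
    mean_rel = rel.mean(axis=1)
    return rel, richness, occupancy, mean_rel


def _null_proportional_frequency(cm, rng, pool_size=None):
    _, richness, occupancy, mean_rel = _regional_stats(cm)
    n_pool = len(occupancy)
    probs = occupancy / occupancy.sum()
    rel = np.zeros((n_pool, cm.n_samples))
    for j, s in enumerate(richness):
        chosen = rng.choice(n_pool, size=int(s), replace=False, p=probs)
        w = mean_rel[chosen]
        if w.sum() == 0:
            w = np.ones(len(chosen))
        rel[chosen, j] = w / w.sum()
    return rel

def _null_richness_uniform(cm, rng, pool_size=None):
    richness = (cm.counts > 0).sum(axis=0)
    n_pool = int(pool_size) if pool_size else cm.n_otus
    rel = np.zeros((n_pool, cm.n_samples))
    for j, s in enumerate(richness):
        chosen = rng.choice(n_pool, size=int(s), replace=False)
        rel[chosen, j] = 1.0 / s
    return rel

def _null_identity(cm, rng, pool_size=None):
    return to_relative_abundance(cm)


NULL_ALGORITHMS = {
    "proportional_frequency": _null_proportional_frequency,
    "richness_uniform": _null_richness_uniform,
    "identity": _null_identity,
}


def null_expected_similarity(cm: CommunityMatrix, n_null: int = 1000,
                             null_algorithm: str = "proportional_frequency",
                             seed=None, pool_size: int | None = None,
                             return_draws: bool = False):
    """Mean pairwise Ruzicka similarity over ``n_null`` null metacommunities.

    ``pool_size`` widens the species pool beyond the observed OTUs for the
    ``richness_uniform`` null.  With ``return_draws=True`` the per-draw
    similarity matrices (n_null, n, n) are returned alongside the mean.
    """
    if null_algorithm not in NULL_ALGORITHMS:
        raise ValueError(f"unknown null algorithm {null_algorithm!r}; "
                         f"known: {sorted(NULL_ALGORITHMS)}")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if cm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    gen = NULL_ALGORITHMS[null_algorithm]
    rng = np.random.default_rng(seed)
    n = cm.n_samples
    acc = np.zeros((n, n))
    draws = np.empty((n_null, n, n)) if return_draws else None
    for r in range(n_null):
        C = pairwise_ruzicka(gen(cm, rng, pool_size=pool_size))
        acc += C
        if return_draws:
            draws[r] = C
    E_bar = acc / n_null
    return (E_bar, draws) if return_draws else E_bar


# ---------------------------------------------------------------------------
# SR and NSR

def stochasticity_ratio(C: np.ndarray, E_bar: np.ndarray):
    """Per-pair stochasticity ratios and their average SR.

    Returns ``(SR, n_A, n_B, ratios)`` where ratios is a dict
    ``{(i, j): ratio}`` over non-tied pairs i < j.
    """
    C = np.asarray(C, dtype=float)
    E = np.asarray(E_bar, dtype=float)
    if C.shape != E.shape or C.shape[0] != C.shape[1]:
        raise ValueError("C and E_bar must be square matrices of equal shape")
    iu, ju = np.triu_indices(C.shape[0], k=1)
    ratios: dict[tuple[int, int], float] = {}
    n_A = n_B = 0
    total = 0.0
    for i, j in zip(iu, ju):
        c, e = C[i, j], E[i, j]
        if c > e:
            r = e / c
            n_A += 1
        elif c < e:
            r = (1.0 - e) / (1.0 - c)
            n_B += 1
        else:
            continue  # strict inequalities only; ties carry no information
        ratios[(int(i), int(j))] = float(r)
        total += r
    if n_A + n_B == 0:
        warnings.warn("all pairs tied with the null expectation; "
                      "SR defined as 1 (pure-null coincidence)")
        return 1.0, 0, 0, ratios
    return total / (n_A + n_B), n_A, n_B, ratios


def normalized_sr(C: np.ndarray, E_bar: np.ndarray | None = None,
                  null_draws: np.ndarray | None = None) -> float:
    """Min-max rescaling of SR: 0 at the fully deterministic extreme, 1 when
    observed similarities coincide with the null expectation.

    For each more-similar (type A) pair the deterministic extreme replaces
    C_ij by 1 (ratio E_ij); for each less-similar (type B) pair by 0 (ratio
    1 - E_ij); averaging gives SR_min, while SR_max = 1 by construction.
    """
    if E_bar is None:
        if null_draws is None:
            raise ValueError("provide E_bar or null_draws")
        E_bar = np.asarray(null_draws, dtype=float).mean(axis=0)
    SR, n_A, n_B, _ = stochasticity_ratio(C, E_bar)
    if n_A + n_B == 0:
        return float(SR)
    iu, ju = np.triu_indices(np.asarray(C).shape[0], k=1)
    lo = 0.0
    for i, j in zip(iu, ju):
        c, e = C[i, j], E_bar[i, j]
        if c > e:
            lo += e
        elif c < e:
            lo += 1.0 - e
    SR_min = lo / (n_A + n_B)
    if SR_min >= 1.0:
        warnings.warn("degenerate normalization (SR_min = SR_max); NSR = SR")
        return float(SR)
    return float(np.clip((SR - SR_min) / (1.0 - SR_min), 0.0, 1.0))


@dataclass
class StochasticityResult:
    """Observed and null similarities with SR/NSR for one metacommunity."""

    C: np.ndarray
    E_bar: np.ndarray
    SR: float
    NSR: float
    n_A: int
    n_B: int
    n_null: int
    null_algorithm: str
    seed: object

    @property
    def n_pairs(self) -> int:
        n = self.C.shape[0]
        return n * (n - 1) // 2

    @property
    def mean_pairwise_similarity(self) -> float:
        iu, ju = np.triu_indices(self.C.shape[0], k=1)
        return float(self.C[iu, ju].mean())

    def to_dict(self) -> dict:
        return {"n_pairs": self.n_pairs,
                "mean_pairwise_similarity": self.mean_pairwise_similarity,
                "SR": self.SR, "NSR": self.NSR,
                "n_A": self.n_A, "n_B": self.n_B,
                "n_null": self.n_null,
                "null_algorithm": self.null_algorithm}


def compute_stochasticity(cm: CommunityMatrix, n_null: int = 1000,
                          null_algorithm: str = "proportional_frequency",
                          seed=None,
                          pool_size: int | None = None) -> StochasticityResult:
    """Observed similarities, null expectation, SR and NSR in one call."""
    C = pairwise_ruzicka(to_relative_abundance(cm))
    E_bar = null_expected_similarity(cm, n_null=n_null,
                                     null_algorithm=null_algorithm,
                                     seed=seed, pool_size=pool_size)
    SR, n_A, n_B, _ = stochasticity_ratio(C, E_bar)
    NSR = normalized_sr(C, E_bar)
    return StochasticityResult(C, E_bar, float(SR), float(NSR), n_A, n_B,
                               n_null, null_algorithm, seed)
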