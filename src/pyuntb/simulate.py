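"""Synthetic community assembly: neutral and non-neutral generators.

Local communities are assembled by a sequential urn: individuals are added
one at a time, the (n+1)-th being an immigrant from the metacommunity with
probability I/(I+n) (I = m(J-1)/(1-m) is the immigration number implied by
migration probability m) or otherwise the offspring of an individual already
present.  Under neutrality the parent is chosen uniformly, which reproduces
the stationary Hubbell local community conditioned on the metacommunity
relative abundances.

Two non-neutral variants perturb the offspring step only as far as needed to
express each effect with a single scalar control parameter:

* IF (intrinsic fitness): each species carries a fecundity f_k drawn once per
  dataset from a Gamma distribution with mean 1 and coefficient of variation
  ``cv``; parents are chosen with probability proportional to N_k * f_k and
  immigrants with probability proportional to beta_k * f_k.  cv = 0 gives
  f_k = 1 and reduces exactly (bit-for-bit, same seed) to the neutral urn.
* PC (density dependence): parents are chosen with probability proportional
  to N_k**(1 - eps), giving rare species a reproductive advantage; eps = 0
  reduces exactly to the neutral urn.

These two urns are the simplest dynamics with the required neutral-reduction
and effect-direction properties; they are approximations, not transcriptions
of any published non-neutral simulator.

Metacommunity relative abundances come from a stick-breaking process
(truncated at ``s_max`` and renormalized), a log-series profile, or an even
profile in which all species are equally abundant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityMatrix, SADSample

_META_MODELS = ("stick_breaking", "log_series", "even")


@dataclass
class MetacommunityProfile:
    """Relative species abundances of the regional pool."""

    beta: np.ndarray
    model: str
    theta_or_param: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if (self.beta < 0).any():
            raise ValueError("beta entries must be >= 0")
        if abs(self.beta.sum() - 1.0) > 1e-12:
            raise ValueError("beta must sum to 1")

    @property
    def s_max(self) -> int:
        return len(self.beta)


@dataclass
class SimConfig:
    """Per-treatment simulation settings: J individuals at each of
    n_sites sites, migration probability m, non-neutral control parameter
    ``effect`` (cv for IF, eps for PC; ignored for the neutral model)."""

    J: int
    m: float
    n_sites: int = 1
    effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.m <= 1:
            raise ValueError("m must be in (0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.J < 1 or self.n_sites < 1:
            raise ValueError("J and n_sites must be >= 1")


def simulate_metacommunity(model: str, param: float, s_max: int,
                           seed: int | None = None) -> MetacommunityProfile:
    """Draw (or construct) metacommunity relative abundances.

    ``param`` is theta for ``stick_breaking``, the log-series x parameter
    (in (0,1)) for ``log_series``, and is ignored for ``even``.
    """
    if model not in _META_MODELS:
        raise ValueError(f"unknown metacommunity model {model!r}")
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    if model == "even":
        beta = np.full(s_max, 1.0 / s_max)
        return MetacommunityProfile(beta, model, float(param))
    if param <= 0:
        raise ValueError("param must be > 0")
    if model == "log_series":
        if not 0 < param < 1:
            raise ValueError("log-series parameter must be in (0, 1)")
        k = np.arange(1, s_max + 1, dtype=float)
        beta = param ** k / k
        beta /= beta.sum()
        return MetacommunityProfile(beta, model, float(param))
    # stick-breaking with concentration theta, truncated and renormalized
    rng = np.random.default_rng(seed)
    v = rng.beta(1.0, param, size=s_max)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    beta = v * remaining
    beta /= beta.sum()
    return MetacommunityProfile(beta, model, float(param))


def immigration_number(m: float, J: int) -> float:
    """I = m (J - 1) / (1 - m); +inf at m = 1."""
    if m >= 1.0:
        return np.inf
    return m * (J - 1) / (1.0 - m)


def _urn(beta: np.ndarray, J: int, m: float, rng: np.random.Generator,
         fecundity: np.ndarray | None = None,
         eps: float = 0.0) -> np.ndarray:
    """Shared urn core.  Returns per-species counts over the metacommunity
    pool.  ``fecundity`` (IF) and ``eps`` (PC) both default to neutral; the
    neutral path consumes the RNG identically for all three models."""
    I = immigration_number(m, J)
    if fecundity is not None:
        q = beta * fecundity
        q = q / q.sum()
    else:
        q = beta
    q_cum = np.cumsum(q)
    counts = np.zeros(len(beta), dtype=np.int64)
    for n in range(J):
        p_imm = 1.0 if np.isinf(I) else I / (I + n)
        if n == 0 or rng.random() < p_imm:
            k = int(np.searchsorted(q_cum, rng.random() * q_cum[-1]))
        else:
            if fecundity is not None:
                w = counts * fecundity
            elif eps > 0.0:
                w = np.where(counts > 0, counts, 0.0) ** (1.0 - eps)
                w[counts == 0] = 0.0
            else:
                w = counts.astype(float)
            w_cum = np.cumsum(w)
            k = int(np.searchsorted(w_cum, rng.random() * w_cum[-1]))
        counts[k] += 1
    return counts


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Wrap ints (and int tuples) as a SeedSequence; pass one through."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _spawn_rngs(seed) -> tuple[np.random.Generator, np.random.Generator]:
    """(parameter stream, urn stream) so that parameter draws (e.g. IF
    fecundities) never shift the urn stream."""
    params_ss, urn_ss = as_seed_sequence(seed).spawn(2)
    return np.random.default_rng(params_ss), np.random.default_rng(urn_ss)


def _counts_to_sad(counts: np.ndarray) -> SADSample:
    return SADSample(counts[counts > 0])


def simulate_local_neutral(meta: MetacommunityProfile, J: int, m: float,
                           seed=None, _return_counts: bool = False):
    """One neutral local community of J individuals."""
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    _, rng = _spawn_rngs(seed)
    counts = _urn(meta.beta, J, m, rng)
    return counts if _return_counts else _counts_to_sad(counts)


def simulate_local_IF(meta: MetacommunityProfile, J: int, m: float,
                      effect: float = 0.0, seed=None,
                      _return_counts: bool = False):
    """Intrinsic-fitness urn; ``effect`` is the fecundity coefficient of
    variation (Gamma with mean 1).  effect = 0 is exactly neutral."""
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if effect < 0:
        raise ValueError("cv must be >= 0")
    param_rng, rng = _spawn_rngs(seed)
    if effect == 0.0:
        counts = _urn(meta.beta, J, m, rng)
    else:
        # Gamma(shape, scale) with mean 1, cv = effect: shape = 1/cv^2
        shape = 1.0 / effect**2
        f = param_rng.gamma(shape, 1.0 / shape, size=meta.s_max)
        f = np.maximum(f, 1e-300)
        counts = _urn(meta.beta, J, m, rng, fecundity=f)
    return counts if _return_counts else _counts_to_sad(counts)


def simulate_local_PC(meta: MetacommunityProfile, J: int, m: float,
                      effect: float = 0.0, seed=None,
                      _return_counts: bool = False):
    """Density-dependent urn (rare-species advantage); ``effect`` is the
    exponent deficit eps in [0, 1].  effect = 0 is exactly neutral."""
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("eps must be in [0, 1]")
    _, rng = _spawn_rngs(seed)
    counts = _urn(meta.beta, J, m, rng, eps=effect)
    return counts if _return_counts else _counts_to_sad(counts)


_LOCAL_MODELS = {
    "neutral": lambda meta, J, m, effect, seed: simulate_local_neutral(
        meta, J, m, seed=seed, _return_counts=True),
    "IF": lambda meta, J, m, effect, seed: simulate_local_IF(
        meta, J, m, effect=effect, seed=seed, _return_counts=True),
    "PC": lambda meta, J, m, effect, seed: simulate_local_PC(
        meta, J, m, effect=effect, seed=seed, _return_counts=True),
}


def simulate_treatment(meta: MetacommunityProfile, config: SimConfig,
                       model: str = "neutral") -> CommunityMatrix:
    """n_sites independent local communities sharing one metacommunity.

    Per-site seeds are derived deterministically from ``config.seed``;
    OTUs with zero total count across all sites are dropped.
    """
    if model not in _LOCAL_MODELS:
        raise ValueError(f"unknown local model {model!r}")
    local = _LOCAL_MODELS[model]
    site_seeds = as_seed_sequence(config.seed).spawn(config.n_sites)
    cols = [local(meta, config.J, config.m, config.effect, s)
            for s in site_seeds]
    counts = np.column_stack(cols)
    keep = counts.sum(axis=1) > 0
    otu_ids = [f"OTU_{k + 1:05d}" for k in np.flatnonzero(keep)]
    sample_ids = [f"site_{i + 1:03d}" for i in range(config.n_sites)]
    return CommunityMatrix(otu_ids, sample_ids, counts[keep])
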