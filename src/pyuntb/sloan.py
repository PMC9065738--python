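"""Sloan near-neutral model: source/destination fit and species classification.

The model couples a large source community ("mainland") to local destination
communities ("islands") of N_T individuals.  At each renewal one individual
dies and is replaced by an immigrant from the source with probability m or by
local reproduction with probability 1 - m.  For the i-th OTU with local
abundance N_i and source relative abundance p_i the single-step transition
probabilities are

    P(N_i + 1 | N_i) = (1 - N_i/N_T) [ m p_i + (1 - m) N_i/(N_T - 1) ]
    P(N_i - 1 | N_i) = (N_i/N_T) [ m (1 - p_i) + (1 - m) (N_T - N_i)/(N_T - 1) ]
    P(N_i | N_i)     = 1 - P(N_i + 1 | N_i) - P(N_i - 1 | N_i)

Unlike the strictly neutral model this sets up a per-species test: the
stationary distribution of the local relative abundance x_i = N_i/N_T is
approximated by the beta diffusion limit Beta(N_T m p_i, N_T m (1 - p_i)),
and a species whose observed x_i falls outside the central 95% interval of
that beta is judged above neutral (positively selected) or below neutral
(negatively selected); species inside are consistent with neutral drift.

m is estimated by least squares between the observed occurrence frequency of
each species across destination samples (fraction of samples where its
relative abundance exceeds a detection threshold d) and the occurrence
frequency predicted by the stationary beta, the standard fitting recipe for
this model.  A negative R^2 marks a failed fit; it is reported, not raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from scipy.stats import beta as beta_dist, binom

from .community import CommunityMatrix, to_relative_abundance

__all__ = ["SloanFit", "SpeciesClassification", "sloan_transition_probs",
           "fit_sloan", "classify_species"]


def sloan_transition_probs(N_i: int, N_T: int, m: float,
                           p_i: float) -> tuple[float, float, float]:
    """(P_up, P_down, P_stay) for one renewal step; they sum to 1."""
    if N_T < 2:
        raise ValueError("N_T must be >= 2")
    if not 0 <= N_i <= N_T:
        raise ValueError("require 0 <= N_i <= N_T")
    if not 0 <= m <= 1 or not 0 <= p_i <= 1:
        raise ValueError("m and p_i must lie in [0, 1]")
    frac = N_i / N_T
    p_up = (1 - frac) * (m * p_i + (1 - m) * N_i / (N_T - 1))
    p_down = frac * (m * (1 - p_i) + (1 - m) * (N_T - N_i) / (N_T - 1))
    return p_up, p_down, 1.0 - p_up - p_down


def _stationary_beta_params(N_T: float, m: float,
                            p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return N_T * m * p, N_T * m * (1.0 - p)


def predicted_occurrence(p: np.ndarray, N_T: float, m: float,
                         d: float) -> np.ndarray:
    """Neutral prediction of the fraction of destination samples in which a
    species with source frequency p exceeds detection threshold d: the
    upper tail of the stationary beta beyond d."""
    a, b = _stationary_beta_params(N_T, m, p)
    return 1.0 - betainc(a, b, d)


@dataclass
class SloanFit:
    """Fitted migration parameter and goodness of fit."""

    m: float
    N_T: int
    r_squared: float
    detection_threshold: float
    n_species: int
    failed: bool  # negative R^2

    def to_dict(self) -> dict:
        return {"m": self.m, "N_T": self.N_T, "r_squared": self.r_squared,
                "NT_m": self.N_T * self.m,
                "detection_threshold": self.detection_threshold,
                "n_species": self.n_species, "failed": self.failed}


@dataclass
class SpeciesClassification:
    """Per-species neutral / above / below verdicts and summary fractions."""

    otu_ids: list
    p: np.ndarray
    x: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    labels: np.ndarray  # "below_neutral" | "neutral" | "above_neutral"
    excluded: list      # (otu_id, reason)

    @property
    def fractions(self) -> dict:
        n = len(self.labels)
        if n == 0:
            return {"below_neutral": 0.0, "neutral": 0.0, "above_neutral": 0.0}
        return {lab: float(np.mean(self.labels == lab))
                for lab in ("below_neutral", "neutral", "above_neutral")}

    def to_dict(self) -> dict:
        return {"n_classified": int(len(self.labels)),
                "n_excluded": len(self.excluded), **self.fractions}


def _align(source: CommunityMatrix, dest: CommunityMatrix):
    """Shared OTU universe: union of labels, rows aligned by id."""
    otus = sorted(set(source.otu_ids) | set(dest.otu_ids))
    def expand(cm):
        out = np.zeros((len(otus), cm.n_samples), dtype=np.int64)
        pos = {o: i for i, o in enumerate(otus)}
        for r, o in enumerate(cm.otu_ids):
            out[pos[o]] = cm.counts[r]
        return CommunityMatrix(otus, list(cm.sample_ids), out)
    return expand(source), expand(dest)


def fit_sloan(source: CommunityMatrix, dest: CommunityMatrix,
              detection_threshold: float | None = None,
              min_dest_samples: int = 5) -> tuple[SloanFit, SpeciesClassification]:
    """Fit m between a source and a destination community set and classify
    destination species against the 95% neutral interval.

    ``source`` and ``dest`` may be the same object (the same-set scheme, in
    which each community acts as both mainland and island).  The local
    community size N_T defaults to the rounded mean destination sample
    total, and the detection threshold to 1/N_T.
    """
    if dest.n_samples < min_dest_samples:
        raise ValueError(
            f"need >= {min_dest_samples} destination samples, "
            f"got {dest.n_samples}")
    source, dest = _align(source, dest)
    N_T = int(round(dest.sample_sizes().mean()))
    if N_T < 2:
        raise ValueError("mean destination sample total must be >= 2")
    d = detection_threshold if detection_threshold is not None else 1.0 / N_T
    p = to_relative_abundance(source).mean(axis=1)
    rel_dest = to_relative_abundance(dest)
    occ_obs = (rel_dest > d).mean(axis=1)
    x = rel_dest.mean(axis=1)

    present = p > 0
    if present.sum() < 5:
        raise ValueError("fewer than 5 species with nonzero source frequency")
    pf, of = p[present], occ_obs[present]

    def sse(m: float) -> float:
        resid = of - predicted_occurrence(pf, N_T, m, d)
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    m_hat = float(res.x)
    ss_res = sse(m_hat)
    ss_tot = float(((of - of.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    failed = not np.isfinite(r2) or r2 < 0
    if failed:
        warnings.warn(f"Sloan fit failed (R^2 = {r2:.3f}); "
                      "m estimate retained for reporting")
    fit = SloanFit(m_hat, N_T, float(r2), float(d), int(present.sum()), failed)
    cls = classify_species(fit, p, x, otu_ids=dest.otu_ids)
    return fit, cls


def classify_species(fit: SloanFit, p, x, otu_ids=None,
                     mode: str = "abundance",
                     n_dest_samples: int | None = None) -> SpeciesClassification:
    """Label each species neutral / above_neutral / below_neutral.

    ``mode="abundance"`` (default) compares the mean local relative
    abundance x_i with the [2.5%, 97.5%] quantiles of its stationary beta.
    ``mode="occurrence"`` instead compares the observed occurrence frequency
    with the binomial interval around the predicted occurrence frequency
    over ``n_dest_samples`` samples (x must then hold occurrence
    frequencies).  Species with p_i in {0, 1} have a degenerate beta and are
    excluded with a logged reason.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise ValueError("p and x must have the same length")
    if otu_ids is None:
        otu_ids = [f"sp_{i}" for i in range(len(p))]
    ok = (p > 0) & (p < 1)
    excluded = [(otu_ids[i], f"degenerate beta (p_i = {p[i]:g})")
                for i in np.flatnonzero(~ok)]
    pf, xf = p[ok], x[ok]
    ids = [otu_ids[i] for i in np.flatnonzero(ok)]
    if mode == "abundance":
        a, b = _stationary_beta_params(fit.N_T, fit.m, pf)
        lower = beta_dist.ppf(0.025, a, b)
        upper = beta_dist.ppf(0.975, a, b)
    elif mode == "occurrence":
        if n_dest_samples is None:
            raise ValueError("occurrence mode needs n_dest_samples")
        pred = predicted_occurrence(pf, fit.N_T, fit.m,
                                    fit.detection_threshold)
        lower = binom.ppf(0.025, n_dest_samples, pred) / n_dest_samples
        upper = binom.ppf(0.975, n_dest_samples, pred) / n_dest_samples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.where(xf < lower, "below_neutral",
                      np.where(xf > upper, "above_neutral", "neutral"))
    return SpeciesClassification(ids, pf, xf, lower, upper, labels, excluded)
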