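"""Hubbell standard neutral model: exact SAD likelihood, MLE, pseudo-P test.

The probability of an observed species abundance distribution
D = (n_1, ..., n_S), J = sum n_i, under the neutral model with fundamental
biodiversity number theta and immigration number I is the Etienne sampling
formula

    P(D | theta, I, J) = J! / (prod_i n_i * prod_j Phi_j!)
                         * theta^S / (I)_J
                         * sum_{A=S}^{J} K(D, A) I^A / (theta)_A

where Phi_j is the number of species with abundance j, (x)_N is the rising
factorial, and

    K(D, A) = sum_{a_1+...+a_S = A, 1 <= a_i <= n_i}
              prod_i s(n_i, a_i) * s(a_i, 1) / s(n_i, 1)

with s(n, a) the unsigned Stirling numbers of the first kind.  A is the
number of immigrant ancestors of the J sampled individuals.  Everything is
computed in log space: the K coefficients via a log-domain convolution of
per-species Stirling vectors, so no intermediate can overflow.

K(D, A) does not depend on (theta, I); it is computed once per SAD and the
likelihood is then cheap to evaluate anywhere in parameter space, which is
what makes maximum-likelihood fitting and parametric-bootstrap testing
affordable.

The pseudo-P neutrality test simulates ``n_sim`` SADs from the fitted model
and reports the smoothed proportion of simulated likelihoods not exceeding
the observed one; values above the threshold mean neutrality cannot be
rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .community import SADSample

__all__ = [
    "NeutralFit", "NeutralityTestResult", "EtienneLikelihood",
    "neutral_loglik", "ewens_loglik", "fit_hnm", "simulate_neutral_sad",
    "hnm_neutrality_test", "passing_rate_curve",
]

# optimization bounds (theta in [1e-3, 1e5], m in [1e-6, 1 - 1e-6])
_LOG_THETA_BOUNDS = (np.log(1e-3), np.log(1e5))
_LOGIT_M_BOUNDS = (np.log(1e-6) - np.log1p(-1e-6),
                   np.log1p(-1e-6) - np.log(1e-6))
_THETA_STARTS = (0.5, 20.0, 800.0)
_M_STARTS = (0.1, 0.5, 0.9)
_SUBSAMPLE_LIMIT = 30_000


# ---------------------------------------------------------------------------
# unsigned Stirling numbers of the first kind, log domain, cached by row

class _StirlingCache:
    """Rows log s(n, a), a = 1..n, built by the ascending recurrence
    s(n+1, a) = s(n, a-1) + n s(n, a).  Only requested rows are retained;
    the sweep keeps a single transient row and resumes from the last
    checkpoint, so memory stays linear in the largest requested n."""

    def __init__(self) -> None:
        self._rows: dict[int, np.ndarray] = {1: np.zeros(1)}
        self._sweep_n = 1
        self._sweep_row = np.zeros(1)

    def rows(self, ns) -> dict[int, np.ndarray]:
        wanted = sorted(set(int(n) for n in ns))
        if wanted and wanted[0] < 1:
            raise ValueError("abundances must be >= 1")
        missing = [n for n in wanted if n not in self._rows]
        if missing:
            n_max = missing[-1]
            if missing[0] <= self._sweep_n:
                # resume from the largest cached row below the first gap
                start = max(n for n in self._rows if n <= missing[0])
                self._sweep_n, self._sweep_row = start, self._rows[start]
            row = self._sweep_row
            n = self._sweep_n
            while n < n_max:
                new = np.empty(n + 1)
                new[0] = np.log(n) + row[0]              # a = 1: n * s(n, 1)
                new[-1] = 0.0                            # a = n + 1: s = 1
                if n > 1:
                    np.logaddexp(row[:-1], np.log(n) + row[1:], out=new[1:-1])
                elif n == 1:
                    pass  # row length 1: handled by the two ends
                row = new
                n += 1
                if n in self._rows:
                    continue
                if n in wanted or n == n_max:
                    self._rows[n] = row
            self._sweep_row = row
            self._sweep_n = n
        return {n: self._rows[n] for n in wanted}


_STIRLING = _StirlingCache()


def log_stirling_row(n: int) -> np.ndarray:
    """log s(n, a) for a = 1..n (unsigned, first kind)."""
    return _STIRLING.rows([n])[n]


# ---------------------------------------------------------------------------
# likelihood

class EtienneLikelihood:
    """Per-SAD precomputation of log K(D, A) and the combinatorial constant;
    ``loglik(theta, I)`` is then a fast log-sum-exp over ancestor counts."""

    def __init__(self, sad: SADSample):
        n = np.sort(np.asarray(sad.abundances, dtype=np.int64))
        self.J = int(n.sum())
        self.S = int(len(n))
        # log[ J! / (prod n_i * prod_j Phi_j!) ]
        _, phi = np.unique(n, return_counts=True)
        self.logconst = (gammaln(self.J + 1) - np.log(n).sum()
                         - gammaln(phi + 1).sum())
        self.logK = self._log_k(n)          # over A = S..J
        self.A = np.arange(self.S, self.J + 1, dtype=float)

    @staticmethod
    def _log_k(n: np.ndarray) -> np.ndarray:
        """Log-domain convolution of per-species coefficient vectors
        c_i(a) = s(n_i, a) (a-1)! / (n_i-1)!, a = 1..n_i."""
        big = n[n > 1]
        conv = np.zeros(1)                   # placeholder for the singletons
        rows = _STIRLING.rows(big) if len(big) else {}
        for ni in big:
            a = np.arange(1, ni + 1, dtype=float)
            v = rows[int(ni)] + gammaln(a) - gammaln(ni)
            out = np.full(len(conv) + ni - 1, -np.inf)
            for j, vj in enumerate(v):
                np.logaddexp(out[j:j + len(conv)], conv + vj,
                             out=out[j:j + len(conv)])
            conv = out
        # singletons contribute a pure index shift (coefficient 1 at a = 1),
        # already implicit: conv index 0 corresponds to A = S
        return conv

    def loglik(self, theta: float, I: float) -> float:
        if theta <= 0 or I <= 0:
            raise ValueError("theta and I must be > 0")
        A = self.A
        if np.isinf(I):
            # Ewens limit: only A = J survives
            return float(self.logconst + self.S * np.log(theta)
                         - (gammaln(theta + self.J) - gammaln(theta))
                         + self.logK[-1])
        body = self.logK + A * np.log(I) - (gammaln(theta + A) - gammaln(theta))
        bmax = body.max()
        lse = bmax + np.log(np.exp(body - bmax).sum())
        return float(self.logconst + self.S * np.log(theta)
                     - (gammaln(I + self.J) - gammaln(I)) + lse)

    def loglik_grad(self, theta: float, I: float):
        """(loglik, d/dtheta, d/dI) for the optimizer."""
        A = self.A
        body = self.logK + A * np.log(I) - (gammaln(theta + A) - gammaln(theta))
        bmax = body.max()
        w = np.exp(body - bmax)
        wsum = w.sum()
        lse = bmax + np.log(wsum)
        w /= wsum
        ll = (self.logconst + self.S * np.log(theta)
              - (gammaln(I + self.J) - gammaln(I)) + lse)
        d_theta = self.S / theta - float(w @ (digamma(theta + A)
                                              - digamma(theta)))
        d_I = float(w @ A) / I - (digamma(I + self.J) - digamma(I))
        return float(ll), d_theta, d_I


def neutral_loglik(sad: SADSample, theta: float, I: float) -> float:
    """Log Etienne sampling-formula probability of ``sad`` given (theta, I)."""
    return EtienneLikelihood(sad).loglik(theta, I)


def ewens_loglik(sad: SADSample, theta: float) -> float:
    """Ewens sampling formula (the I -> infinity limit of the neutral model)."""
    n = np.asarray(sad.abundances, dtype=np.int64)
    J, S = int(n.sum()), len(n)
    _, phi = np.unique(n, return_counts=True)
    return float(gammaln(J + 1) + S * np.log(theta)
                 - (gammaln(theta + J) - gammaln(theta))
                 - np.log(n).sum() - gammaln(phi + 1).sum())


# ---------------------------------------------------------------------------
# fitting

@dataclass
class NeutralFit:
    """Maximum-likelihood neutral-model parameters for one SAD."""

    theta: float
    m: float
    I: float
    loglik: float
    J: int
    S: int
    boundary: bool = False

    def to_dict(self) -> dict:
        return {"theta": self.theta, "m": self.m, "I": self.I,
                "loglik": self.loglik, "J": self.J, "S": self.S,
                "boundary": self.boundary}


def _m_from_I(I: float, J: int) -> float:
    if np.isinf(I):
        return 1.0
    return I / (I + J - 1)


def _optimize(lik: EtienneLikelihood, starts) -> tuple[float, float, float]:
    """Bounded quasi-Newton over (log theta, logit m) with the analytic
    gradient; returns (theta, m, loglik) of the best optimum over the
    start list."""
    J = lik.J

    def nll(x):
        theta = np.exp(x[0])
        I = (J - 1) * np.exp(x[1])  # m/(1-m) = exp(logit m)
        ll, d_theta, d_I = lik.loglik_grad(theta, max(I, 1e-300))
        return -ll, np.array([-d_theta * theta, -d_I * I])

    best = None
    for theta0, m0 in starts:
        x0 = np.array([np.log(theta0), np.log(m0) - np.log1p(-m0)])
        res = minimize(nll, x0, method="L-BFGS-B", jac=True,
                       bounds=[_LOG_THETA_BOUNDS, _LOGIT_M_BOUNDS])
        if best is None or res.fun < best.fun:
            best = res
    theta = float(np.exp(best.x[0]))
    m = float(1.0 / (1.0 + np.exp(-best.x[1])))
    return theta, m, float(-best.fun)


def fit_hnm(sad: SADSample, _warm_start: tuple[float, float] | None = None,
            _lik: EtienneLikelihood | None = None) -> NeutralFit:
    """Maximum-likelihood (theta, m) for one SAD.

    Uses a deterministic 3 x 3 start grid in (log theta, logit m); refits of
    bootstrap replicates may pass a single warm start instead.  Degenerate
    SADs (S <= 1, or all singletons, where theta diverges) are returned as
    boundary fits with a warning rather than raising.
    """
    lik = _lik if _lik is not None else EtienneLikelihood(sad)
    J, S = lik.J, lik.S
    degenerate = S <= 1 or J == S
    if degenerate and J == S and S > 1:
        warnings.warn("all-singleton SAD: theta estimate diverges; "
                      "capped at 1e5 (boundary fit)")
        theta = 1e5
        # with all singletons the likelihood is monotone in theta; m barely
        # identified -- report the profile optimum at the cap
        starts = [(theta, m0) for m0 in _M_STARTS]
        _, m, ll = _optimize(lik, starts)
        I = m * (J - 1) / (1.0 - m)
        return NeutralFit(theta, m, I, lik.loglik(theta, I), J, S, True)
    if degenerate:
        warnings.warn("degenerate SAD (S <= 1): boundary fit")
    if _warm_start is not None:
        starts = [_warm_start]
    else:
        starts = [(t, m) for t in _THETA_STARTS for m in _M_STARTS]
    theta, m, ll = _optimize(lik, starts)
    I = m * (J - 1) / (1.0 - m)
    at_bound = (theta <= 1.1e-3 or theta >= 0.9e5
                or m <= 1.1e-6 or m >= 1 - 1.1e-6)
    if degenerate or at_bound:
        warnings.warn(f"boundary fit: theta={theta:.4g}, m={m:.4g}")
    return NeutralFit(theta, m, I, ll, J, S, degenerate or at_bound)


# ---------------------------------------------------------------------------
# simulation from the sampling formula and the pseudo-P test

def simulate_neutral_sad(theta: float, I: float, J: int,
                         rng: np.random.Generator) -> SADSample:
    """Draw one SAD of size J exactly from the Etienne sampling formula.

    Sequential two-stage urn: the (n+1)-th individual is a new immigrant
    lineage with probability I/(I+n), in which case the lineage's species is
    chosen by a Chinese-restaurant step at rate theta over lineages;
    otherwise it copies a uniformly chosen earlier individual.
    """
    if theta <= 0 or I <= 0 or J < 1:
        raise ValueError("require theta > 0, I > 0, J >= 1")
    abund: list[int] = []        # individuals per species
    lineages: list[int] = []     # immigrant lineages per species
    species_of = np.empty(J, dtype=np.int64)   # parent lookup, O(1) copies
    total_lineages = 0
    uniforms = rng.random(J)
    for n in range(J):
        if n == 0 or np.isinf(I) or uniforms[n] * (I + n) < I:
            # new immigrant lineage; assign its species via CRP(theta)
            u = rng.random() * (theta + total_lineages)
            if u < theta or not lineages:
                k = len(abund)
                abund.append(1)
                lineages.append(1)
            else:
                k = int(np.searchsorted(np.cumsum(lineages), u - theta))
                k = min(k, len(lineages) - 1)
                abund[k] += 1
                lineages[k] += 1
            total_lineages += 1
        else:
            k = int(species_of[int(rng.random() * n)])
            abund[k] += 1
        species_of[n] = k
    return SADSample(np.array(abund, dtype=np.int64))


@dataclass
class NeutralityTestResult:
    """Outcome of the pseudo-P exact neutrality test for one SAD."""

    observed_loglik: float
    simulated_logliks: np.ndarray
    pseudo_p: float
    alpha: float
    verdict: str
    fit: NeutralFit | None = None
    subsampled: bool = False
    n_sim: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_sim = int(len(self.simulated_logliks))

    def to_dict(self) -> dict:
        d = {"pseudo_p": self.pseudo_p, "alpha": self.alpha,
             "verdict": self.verdict, "n_sim": self.n_sim,
             "observed_loglik": self.observed_loglik,
             "subsampled": self.subsampled}
        if self.fit is not None:
            d.update({"theta": self.fit.theta, "m": self.fit.m,
                      "J": self.fit.J, "S": self.fit.S})
        return d


def _subsample_sad(sad: SADSample, limit: int,
                   rng: np.random.Generator) -> SADSample:
    sub = rng.multivariate_hypergeometric(sad.abundances, limit)
    return SADSample(sub[sub > 0], sample_id=sad.sample_id)


def hnm_neutrality_test(sad: SADSample, n_sim: int = 500, seed=None,
                        alpha: float = 0.05, refit: bool = True,
                        fit: NeutralFit | None = None) -> NeutralityTestResult:
    """Pseudo-P exact neutrality test (parametric bootstrap).

    Fits (theta, I), simulates ``n_sim`` SADs of the same J from the fitted
    model, and computes pseudo-P as the +1-smoothed proportion of simulated
    log-likelihoods <= the observed log-likelihood.  With ``refit=True``
    (default, full parametric bootstrap) each replicate is refitted and the
    comparison is between maximized log-likelihoods; ``refit=False`` is a
    faster approximation that evaluates all replicates at the observed fit.

    Samples larger than 30,000 reads are first subsampled without
    replacement to 30,000 (flagged in the result): simulation cost grows
    with the number of individuals and abundance-model information saturates
    well below that depth.
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 (pseudo-P resolution)")
    rng = np.random.default_rng(seed)
    subsampled = False
    if sad.J > _SUBSAMPLE_LIMIT:
        sad = _subsample_sad(sad, _SUBSAMPLE_LIMIT, rng)
        subsampled = True
    lik = EtienneLikelihood(sad)
    if fit is None:
        fit = fit_hnm(sad, _lik=lik)
    observed = fit.loglik if refit else lik.loglik(fit.theta, fit.I)
    sim_ll = np.empty(n_sim)
    warm = (fit.theta, fit.m)
    with warnings.catch_warnings():
        # replicate refits may legitimately sit on a parameter bound
        warnings.simplefilter("ignore")
        for r in range(n_sim):
            rep = simulate_neutral_sad(fit.theta, fit.I, sad.J, rng)
            rep_lik = EtienneLikelihood(rep)
            if not refit:
                sim_ll[r] = rep_lik.loglik(fit.theta, fit.I)
            elif rep_lik.S <= 1 or rep_lik.S == rep_lik.J:
                sim_ll[r] = fit_hnm(rep, _lik=rep_lik).loglik
            else:
                sim_ll[r] = fit_hnm(rep, _warm_start=warm,
                                    _lik=rep_lik).loglik
    pseudo_p = (1.0 + np.count_nonzero(sim_ll <= observed)) / (1.0 + n_sim)
    verdict = "neutral_not_rejected" if pseudo_p > alpha else "rejected"
    return NeutralityTestResult(observed, sim_ll, float(pseudo_p), alpha,
                                verdict, fit=fit, subsampled=subsampled)


def passing_rate_curve(pvalues, thresholds) -> np.ndarray:
    """Fraction of p-values strictly above each threshold (non-increasing).

    Raising the P-threshold raises the bar for accepting neutrality; the
    curve replaces FDR correction, which is inapplicable under the
    neutrality-test convention (larger P favors the null)."""
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or ((t < 0) | (t > 1)).any():
        raise ValueError("p-values and thresholds must lie in [0, 1]")
    return (p[np.newaxis, :] > t[:, np.newaxis]).mean(axis=1)
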