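"""Sparklet trace analysis: coupled gating, quantal idealization, nPs, kappa.

A sparklet site holds N two-state (closed/open) Ca2+ channels sampled at
fs_hz. Coupling between the channels is summarized by a coefficient kappa
in [0, 1]: 0 means the channels gate independently, 1 means they open and
close as one unit. The generative model used here is a per-frame mixture —
with probability kappa a coordination event forces all N channels into a
single common state (open with probability p), otherwise each channel draws
its state independently. This realizes both endpoints exactly and keeps the
per-channel marginal open probability at p for every kappa, which makes the
frame likelihood closed-form:

    P(k) = kappa * [(1-p) 1{k=0} + p 1{k=N}] + (1-kappa) * Binomial(N, p, k)

Site activity is nPs, the time-averaged open-channel count Sum_t k(t) / T
(n quantal levels times the probability of sparklet occurrence); sites are
split into low and high activity at an nPs cutoff of 0.2. kappa is
estimated by maximum likelihood over the frame histogram of k, with a
bootstrap confidence interval.

The per-frame exchangeability assumption means no dwell-time kinetics are
modeled; kappa is a per-site summary, not a kinetic rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CoupledGatingParams",
    "SparkletIdealization",
    "SiteStats",
    "simulate_coupled_gating",
    "idealize_trace",
    "estimate_quantal_amplitude",
    "compute_nps",
    "classify_site",
    "estimate_kappa",
    "coupled_log_likelihood",
    "NPS_CUTOFF",
]

#: nPs threshold separating low- from high-activity sparklet sites
NPS_CUTOFF = 0.2


@dataclass(frozen=True)
class CoupledGatingParams:
    """N coupled two-state channels with marginal open probability p_open."""

    N: int
    p_open: float
    kappa: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 < self.p_open < 1.0:
            raise ValueError("p_open must be in (0, 1)")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class SparkletIdealization:
    """Per-frame open-channel count k(t) with its quantal calibration."""

    k: np.ndarray
    quantal_dF: float
    fs_hz: float = 100.0
    N_max: int | None = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        if self.k.size and (self.k.min() < 0 or (self.N_max is not None and self.k.max() > self.N_max)):
            raise ValueError("k must lie in [0, N_max]")


@dataclass
class SiteStats:
    """Per-site activity and coupling summary."""

    nPs: float
    activity_class: str
    kappa_hat: float
    kappa_ci: tuple[float, float]
    n_quantal_levels: int


def simulate_coupled_gating(params: CoupledGatingParams) -> np.ndarray:
    """Simulate the per-frame open-channel count k(t).

    Per frame: with probability kappa all channels copy one common
    Bernoulli(p_open) state; otherwise k ~ Binomial(N, p_open).
    """
    rng = np.random.default_rng(params.seed)
    coord = rng.random(params.n_frames) < params.kappa
    k = rng.binomial(params.N, params.p_open, size=params.n_frames)
    common_open = rng.random(params.n_frames) < params.p_open
    k[coord] = np.where(common_open[coord], params.N, 0)
    return k


def idealize_trace(trace, quantal_dF: float, N_max: int) -> SparkletIdealization:
    """Quantize a fluorescence trace to integer open-channel counts.

    k(t) is the nearest integer in [0, N_max] to trace(t)/quantal_dF.
    Accepts an array of dF values or a DataFrame with a 'dF' column.
    """
    if quantal_dF <= 0:
        raise ValueError("quantal_dF must be positive")
    if hasattr(trace, "columns"):
        values = np.asarray(trace["dF"], dtype=float)
    else:
        values = np.asarray(trace, dtype=float)
    k = np.clip(np.rint(values / quantal_dF), 0, N_max).astype(int)
    return SparkletIdealization(k=k, quantal_dF=quantal_dF, N_max=N_max)


def _mixture_loglik(values: np.ndarray, spacing: float, sigma: float,
                    weights: np.ndarray) -> float:
    means = spacing * np.arange(weights.size)
    comp = weights[None, :] * stats.norm.pdf(values[:, None], means[None, :], sigma)
    dens = comp.sum(axis=1)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _em_profile(values: np.ndarray, spacing: float, n_levels: int,
                n_iter: int = 40) -> float:
    """Profile log-likelihood over weights and sigma with means fixed at j*spacing."""
    means = spacing * np.arange(n_levels)
    weights = np.full(n_levels, 1.0 / n_levels)
    sigma = max(np.std(values) / max(n_levels, 2), 1e-3 * max(spacing, 1.0))
    for _ in range(n_iter):
        resp = weights[None, :] * stats.norm.pdf(values[:, None], means[None, :], sigma)
        resp_sum = resp.sum(axis=1, keepdims=True)
        resp = resp / np.maximum(resp_sum, 1e-300)
        weights = resp.mean(axis=0)
        var = float(np.sum(resp * (values[:, None] - means[None, :]) ** 2) / values.size)
        sigma = max(np.sqrt(var), 1e-6 * max(spacing, 1.0))
    return _mixture_loglik(values, spacing, sigma, weights)


def estimate_quantal_amplitude(trace, N_max: int = 4) -> float:
    """Estimate the quantal fluorescence step from the all-points histogram.

    Fits a 1D Gaussian mixture with equally spaced means (0, q, 2q, ...,
    N_max*q) and returns the spacing q that maximizes the profile
    likelihood. Raises if the amplitude histogram is unimodal (no events) —
    supply the quantal amplitude manually in that case.
    """
    if hasattr(trace, "columns"):
        values = np.asarray(trace["dF"], dtype=float)
    else:
        values = np.asarray(trace, dtype=float)
    if values.size < 10:
        raise ValueError("trace too short to estimate a quantal amplitude")
    ptp = float(values.max() - values.min())

    # noiseless / quantized traces: spacing is the minimum positive gap
    uniq = np.unique(values)
    if uniq.size <= N_max + 1 and uniq.size >= 2:
        gaps = np.diff(uniq)
        if np.allclose(gaps / gaps.min(), np.round(gaps / gaps.min())):
            return float(gaps.min())

    # robust noise scale from successive differences (events are sparse
    # relative to frames, so the median difference reflects noise alone)
    diffs = np.abs(np.diff(values))
    noise_sd = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
    if ptp < 6 * noise_sd or noise_sd == 0:
        raise ValueError(
            "amplitude histogram looks unimodal (no events detected); "
            "supply quantal_dF manually"
        )

    n_levels = N_max + 1
    # coarse grid over plausible spacings, then local refinement
    q_grid = np.linspace(ptp / (N_max + 1), ptp, 25)
    lls = [_em_profile(values, q, n_levels, n_iter=25) for q in q_grid]
    q0 = q_grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda q: -_em_profile(values, q, n_levels),
        bounds=(max(q0 * 0.6, 1e-9), q0 * 1.4),
        method="bounded",
        options={"xatol": 1e-4 * q0},
    )
    q_hat = float(res.x)

    # guard against a spurious multi-level fit of a single noisy mode
    ll_single = float(np.sum(stats.norm.logpdf(values, values.mean(), max(values.std(), 1e-12))))
    if _em_profile(values, q_hat, n_levels) <= ll_single + 2.0:
        raise ValueError(
            "no quantal structure beyond a single Gaussian mode; "
            "supply quantal_dF manually"
        )
    return q_hat


def compute_nps(ideal: SparkletIdealization | np.ndarray) -> float:
    """Site activity nPs = time-averaged open-channel count Sum_t k(t) / T."""
    k = ideal.k if isinstance(ideal, SparkletIdealization) else np.asarray(ideal)
    if k.size == 0:
        raise ValueError("empty idealization")
    return float(np.mean(k))


def classify_site(nps: float, cutoff: float = NPS_CUTOFF) -> str:
    """'high' iff nPs >= cutoff (boundary counts as high), else 'low'."""
    if nps < 0:
        raise ValueError("nPs must be >= 0")
    return "high" if nps >= cutoff else "low"


def coupled_log_likelihood(counts: np.ndarray, N: int, p: float, kappa: float) -> float:
    """Log-likelihood of a k-histogram under the coupled-gating mixture.

    ``counts[k]`` is the number of frames with k open channels. The
    histogram is a sufficient statistic because frames are exchangeable.
    """
    ks = np.arange(N + 1)
    binom = stats.binom.pmf(ks, N, p)
    coord = np.zeros(N + 1)
    coord[0] = 1.0 - p
    coord[N] = p
    pmf = kappa * coord + (1.0 - kappa) * binom
    pmf = np.maximum(pmf, 1e-300)
    return float(np.dot(counts, np.log(pmf)))


def _kappa_mle(counts: np.ndarray, N: int, p: float) -> float:
    neg = lambda kap: -coupled_log_likelihood(counts, N, p, kap)
    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    kap = float(np.clip(res.x, 0.0, 1.0))
    # bounded Brent can stall short of a boundary optimum; check endpoints
    for edge in (0.0, 1.0):
        if neg(edge) < neg(kap):
            kap = edge
    return kap


def estimate_kappa(
    ideal: SparkletIdealization | np.ndarray,
    N: int,
    p_open: float | None = None,
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Maximum-likelihood coupling coefficient with a bootstrap CI.

    The estimate maximizes the mixture likelihood over kappa in [0, 1] with
    p fixed at mean(k)/N when not supplied (the marginal open probability is
    p for every kappa, so this moment estimate is consistent). The CI is a
    percentile bootstrap over frames.
    """
    k = ideal.k if isinstance(ideal, SparkletIdealization) else np.asarray(ideal, dtype=int)
    if N < 2:
        raise ValueError("kappa estimation requires N >= 2")
    if k.size == 0:
        raise ValueError("empty idealization")
    if k.min() < 0 or k.max() > N:
        raise ValueError("k values outside [0, N]")
    if k.size < 500:
        warnings.warn("fewer than 500 frames; kappa estimate will be noisy", stacklevel=2)

    counts = np.bincount(k, minlength=N + 1).astype(float)
    if p_open is None:
        p = float(np.mean(k)) / N
    else:
        p = float(p_open)
    if not 0.0 < p < 1.0:
        warnings.warn("all frames identical: coupling degenerate at the boundary",
                      stacklevel=2)
        kap = 1.0 if counts[0] == k.size or counts[N] == k.size else 0.0
        return kap, (kap, kap)

    kappa_hat = _kappa_mle(counts, N, p)
    if n_boot <= 0:
        return kappa_hat, (float("nan"), float("nan"))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = k.size
    probs = counts / n
    for b in range(n_boot):
        bcounts = rng.multinomial(n, probs).astype(float)
        pb = float(np.dot(np.arange(N + 1), bcounts)) / (n * N) if p_open is None else p
        if not 0.0 < pb < 1.0:
            boots[b] = 1.0 if (bcounts[0] == n or bcounts[N] == n) else 0.0
            continue
        boots[b] = _kappa_mle(bcounts, N, pb)
    alpha = 1.0 - ci_level
    ci = (float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2)))
    return kappa_hat, ci


def analyze_site(
    trace,
    quantal_dF: float | None,
    N: int,
    fs_hz: float = 100.0,
    cutoff: float = NPS_CUTOFF,
    n_boot: int = 200,
    seed: int = 0,
) -> SiteStats:
    """Full per-site analysis: idealize, nPs, activity class, kappa."""
    if quantal_dF is None:
        quantal_dF = estimate_quantal_amplitude(trace, N_max=N)
    ideal = idealize_trace(trace, quantal_dF, N_max=N)
    ideal.fs_hz = fs_hz
    nps = compute_nps(ideal)
    cls = classify_site(nps, cutoff)
    if N >= 2:
        kap, ci = estimate_kappa(ideal, N, n_boot=n_boot, seed=seed)
    else:
        kap, ci = float("nan"), (float("nan"), float("nan"))
    return SiteStats(
        nPs=nps,
        activity_class=cls,
        kappa_hat=kap,
        kappa_ci=ci,
        n_quantal_levels=int(ideal.k.max()) if ideal.k.size else 0,
    )
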