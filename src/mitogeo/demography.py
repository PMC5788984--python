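"""Mismatch-distribution demography and neutrality tests.

Sudden-expansion model
----------------------
For a pair of mtDNA sequences from a haploid population whose scaled size
jumped from ``theta0`` to ``theta1`` at time ``tau`` (in units of mutational
time, tau = 2*u*t) before present, the probability of observing ``i``
pairwise differences is, with the equilibrium distribution
``Fhat_i(theta) = theta^i / (1+theta)^(i+1)`` and ``x = tau*(1+theta1)/theta1``::

    F_i = Fhat_i(theta1) * P[Gamma(i+1) <= x]
        + exp(-x) * sum_{j=0}^{i} Fhat_j(theta0) * tau^(i-j) / (i-j)!

This closed form follows from conditioning the pair's coalescence time on
whether it falls before or after the size change; both pieces are finite
sums, so no series truncation is needed.  It reduces to the geometric
equilibrium when ``theta0 == theta1`` and to the ``theta0`` equilibrium when
``tau == 0``.

Model fitting minimizes the sum of squared deviations (SSD) between the
observed relative mismatch frequencies and ``F_i`` over a multistart grid
with local refinement.  Goodness of fit uses a parametric bootstrap:
coalescent samples are simulated under the fitted demography, refitted, and
the observed SSD and raggedness are ranked against the replicates.

Neutrality tests
----------------
Tajima's D uses the 1989 constants; Fu's F_S uses the Ewens sampling
distribution with unsigned Stirling numbers of the first kind in log space.
P-values for both come from neutral constant-size coalescent simulation
conditioned on the sample size (Tajima's beta approximation is available as
an alternative for D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaln, logsumexp

from .data_io import Alignment, DiffMatrix

__all__ = [
    "MismatchHistogram",
    "mismatch_histogram",
    "expected_mismatch",
    "raggedness",
    "ExpansionFit",
    "fit_sudden_expansion",
    "expansion_gof",
    "SuddenExpansionModel",
    "ExpansionFitResults",
    "tajima_constants",
    "tajimas_d",
    "fus_fs",
    "NeutralityStats",
    "neutrality_tests",
    "neutral_coalescent_stats",
]


# ---------------------------------------------------------------------------
# mismatch histogram


@dataclass(frozen=True)
class MismatchHistogram:
    """Histogram of pairwise difference counts among n sequences."""

    counts: np.ndarray  # counts[i] = number of pairs with i differences
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if (c < 0).any() or c.sum() != self.n * (self.n - 1) // 2:
            raise ValueError("histogram mass must equal n(n-1)/2 with counts >= 0")

    @property
    def rel_freqs(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    @property
    def mean(self) -> float:
        c = np.asarray(self.counts, dtype=float)
        return float((np.arange(c.size) * c).sum() / c.sum())

    @property
    def modality(self) -> int:
        """Number of local maxima after unit (3-point) smoothing.

        Note that a 3-point smoother can never resolve two modes separated
        by a single dip class (e.g. haplotype clusters two steps apart);
        use :meth:`n_modes` with ``smooth=False`` for the raw count.
        """
        return self.n_modes(smooth=True)

    def n_modes(self, smooth: bool = True) -> int:
        x = np.concatenate([[0.0], self.rel_freqs, [0.0]])
        y = np.convolve(x, np.ones(3) / 3.0, mode="same") if smooth else x
        peaks = 0
        i = 1
        while i < y.size - 1:
            if y[i] > y[i - 1]:
                j = i
                while j + 1 < y.size and y[j + 1] == y[j]:
                    j += 1
                if j + 1 >= y.size or y[j + 1] < y[j]:
                    peaks += 1
                i = j + 1
            else:
                i += 1
        return peaks


def mismatch_histogram(d: DiffMatrix | np.ndarray) -> MismatchHistogram:
    """Histogram over all unordered pairs of a difference matrix."""
    m = d.matrix if isinstance(d, DiffMatrix) else np.asarray(d)
    n = m.shape[0]
    if n < 2:
        raise ValueError("mismatch histogram requires n >= 2")
    iu = np.triu_indices(n, k=1)
    diffs = m[iu]
    counts = np.bincount(diffs.astype(int))
    return MismatchHistogram(counts, n)


# ---------------------------------------------------------------------------
# expected mismatch (sudden-expansion model)


def _log_fhat(i: np.ndarray, theta: float) -> np.ndarray:
    """log of the equilibrium mismatch distribution theta^i/(1+theta)^(i+1)."""
    i = np.asarray(i, dtype=float)
    if theta == 0.0:
        out = np.full(i.shape, -np.inf)
        out[i == 0] = 0.0
        return out
    return i * math.log(theta) - (i + 1.0) * math.log1p(theta)


def expected_mismatch(
    tau: float,
    theta0: float,
    theta1: float,
    i_max: int,
    renormalize: bool = False,
) -> np.ndarray:
    """Expected relative mismatch frequencies F_0..F_{i_max}.

    The raw vector sums to <= 1 (the deficit is the mass beyond ``i_max``);
    with ``renormalize=True`` it is rescaled to sum to exactly 1.
    """
    for name, v in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    i = np.arange(i_max + 1)
    if theta1 == 0.0:
        x = np.inf if tau > 0 else 0.0
    else:
        x = tau * (1.0 + theta1) / theta1
    # recent-epoch piece: coalescence before the size change
    with np.errstate(over="ignore"):
        A = np.exp(_log_fhat(i, theta1)) * gammainc(i + 1.0, x)
    # ancient-epoch piece: Poisson(tau) jitter on the theta0 equilibrium
    if tau == 0.0:
        B = np.exp(_log_fhat(i, theta0))  # x == 0 here
    elif np.isinf(x):
        B = np.zeros(i.size)
    else:
        fhat0 = np.exp(_log_fhat(i, theta0))
        # exp(m log tau - log m! - x) <= Poisson pmf since x >= tau: no overflow
        pois = np.exp(i * math.log(tau) - gammaln(i + 1.0) - x)
        B = np.convolve(fhat0, pois)[: i_max + 1]
    F = A + B
    F = np.clip(F, 0.0, None)
    if renormalize:
        F = F / F.sum()
    return F


def raggedness(rel_freqs: Sequence[float]) -> float:
    """Harpending-style raggedness: squared successive differences of the
    relative mismatch frequencies, zero-padded at both ends."""
    x = np.concatenate([[0.0], np.asarray(rel_freqs, dtype=float), [0.0]])
    return float((np.diff(x) ** 2).sum())


# ---------------------------------------------------------------------------
# sudden-expansion fit


@dataclass(frozen=True)
class ExpansionFit:
    """Least-squares sudden-expansion parameters for one mismatch histogram."""

    tau: float
    theta0: float
    theta1: float
    ssd: float
    degenerate: bool = False
    p_ssd: float | None = None
    rg: float | None = None
    p_rg: float | None = None
    n_boot: int = 0


def _ssd(params: np.ndarray, obs: np.ndarray) -> float:
    tau, th0, dth = params
    F = expected_mismatch(max(tau, 0.0), max(th0, 0.0), max(th0 + dth, 0.0), obs.size - 1)
    return float(((obs - F) ** 2).sum())


def _start_grid(mean_diff: float, i_max: int) -> list[tuple[float, float, float]]:
    taus = sorted({0.5, max(0.5, 0.5 * mean_diff), max(1.0, mean_diff),
                   min(1.5 * mean_diff + 1.0, 2.0 * i_max)})
    starts = []
    for t in taus:
        for th0 in (0.1, 1.0):
            for th1 in (5.0, 50.0, 500.0):
                starts.append((t, th0, max(th1 - th0, 0.0)))
    return starts


def fit_sudden_expansion(
    hist: MismatchHistogram | np.ndarray,
) -> ExpansionFit:
    """Fit (tau, theta0, theta1) by SSD minimization, multistart + refinement.

    Accepts either an observed :class:`MismatchHistogram` or a raw vector of
    relative frequencies (the infinite-sample case, useful for
    self-consistency checks against :func:`expected_mismatch`).
    """
    from scipy.optimize import minimize

    if isinstance(hist, MismatchHistogram):
        if hist.n < 4:
            raise ValueError("sudden-expansion fit requires n >= 4")
        obs = hist.rel_freqs
    else:
        obs = np.asarray(hist, dtype=float)
        obs = obs / obs.sum()
        hist = None
    i_max = obs.size - 1
    if i_max == 0:
        return ExpansionFit(0.0, 0.0, 0.0, 0.0, degenerate=True)
    mean_diff = float((np.arange(obs.size) * obs).sum())
    bounds = [(0.0, 2.0 * i_max), (0.0, 1e4), (0.0, 1e4)]
    best = None
    for start in _start_grid(mean_diff, i_max):
        res = minimize(_ssd, np.asarray(start), args=(obs,), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(_ssd, best.x, args=(obs,), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    if polish.fun <= best.fun:
        best = polish
    tau, th0, dth = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return ExpansionFit(float(tau), float(th0), float(th0 + dth), float(best.fun))


def expansion_gof(
    hist: MismatchHistogram,
    fit: ExpansionFit,
    L: int,
    n_boot: int = 100,
    seed: int | None = None,
) -> ExpansionFit:
    """Parametric-bootstrap goodness of fit for a sudden-expansion fit.

    Simulates ``n_boot`` coalescent samples of the same size and length under
    the fitted demography, refits each, and returns the fit augmented with
    ``p_ssd``/``p_rg`` (the proportion of replicates whose SSD/raggedness is
    at least the observed value).
    """
    import warnings

    from .coalsim import sudden_expansion_demography
    from .data_io import pairwise_diff_matrix

    if n_boot < 10:
        warnings.warn(f"n_boot={n_boot} < 10 gives a very coarse p-value")
    rg_obs = raggedness(hist.rel_freqs)
    rng = np.random.default_rng(seed)
    ssd_sims = np.empty(n_boot)
    rg_sims = np.empty(n_boot)
    for b in range(n_boot):
        aln, _ = sudden_expansion_demography(
            fit.theta0, fit.theta1, fit.tau, hist.n, L,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        h_sim = mismatch_histogram(pairwise_diff_matrix(aln))
        fit_sim = fit_sudden_expansion(h_sim)
        ssd_sims[b] = fit_sim.ssd
        rg_sims[b] = raggedness(h_sim.rel_freqs)
    return ExpansionFit(
        fit.tau, fit.theta0, fit.theta1, fit.ssd, fit.degenerate,
        p_ssd=float((ssd_sims >= fit.ssd).mean()),
        rg=rg_obs,
        p_rg=float((rg_sims >= rg_obs).mean()),
        n_boot=n_boot,
    )


class SuddenExpansionModel:
    """Sudden-expansion mismatch model for one sample group.

    Parameters
    ----------
    hist
        Observed mismatch histogram.
    L
        Sequence length in sites (needed for the parametric bootstrap).

    Examples
    --------
    >>> model = SuddenExpansionModel(hist, L=866)
    >>> res = model.fit(n_boot=100, seed=1)
    >>> res.params  # (tau, theta0, theta1)
    """

    def __init__(self, hist: MismatchHistogram, L: int = 866):
        self.hist = hist
        self.L = int(L)

    @classmethod
    def from_alignment(cls, aln: Alignment, ids: Sequence[str] | None = None,
                       policy: str = "complete_deletion") -> "SuddenExpansionModel":
        from .data_io import pairwise_diff_matrix

        sub = aln.subset(list(ids)) if ids is not None else aln
        return cls(mismatch_histogram(pairwise_diff_matrix(sub, policy)), aln.L)

    def fit(self, n_boot: int = 0, seed: int | None = None) -> "ExpansionFitResults":
        fit = fit_sudden_expansion(self.hist)
        if n_boot:
            fit = expansion_gof(self.hist, fit, self.L, n_boot=n_boot, seed=seed)
        return ExpansionFitResults(self, fit)


@dataclass
class ExpansionFitResults:
    """Estimates and diagnostics from :class:`SuddenExpansionModel`."""

    model: SuddenExpansionModel
    fit: ExpansionFit

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.fit.tau, self.fit.theta0, self.fit.theta1)

    def expected(self, renormalize: bool = False) -> np.ndarray:
        return expected_mismatch(*self.params, self.model.hist.counts.size - 1,
                                 renormalize=renormalize)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Sudden-expansion mismatch fit",
            "-----------------------------",
            f"n sequences          {self.model.hist.n}",
            f"mean pairwise diffs  {self.model.hist.mean:.4f}",
            f"modality             {self.model.hist.modality}",
            f"tau                  {f.tau:.4f}",
            f"theta0               {f.theta0:.4f}",
            f"theta1               {f.theta1:.4f}",
            f"SSD                  {f.ssd:.6f}",
        ]
        if f.n_boot:
            lines += [
                f"p(SSD)               {f.p_ssd:.3f}   ({f.n_boot} bootstrap reps)",
                f"raggedness rg        {f.rg:.4f}",
                f"p(rg)                {f.p_rg:.3f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs expected mismatch distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.hist.rel_freqs
        ax.plot(np.arange(obs.size), obs, "o-", label="observed")
        ax.plot(np.arange(obs.size), self.expected(), "--", label="expected")
        ax.set_xlabel("pairwise differences")
        ax.set_ylabel("relative frequency")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# neutral constant-size coalescent null engine (vectorized)


def _random_distinct_pairs(rng: np.random.Generator, k: int, reps: int):
    i = rng.integers(0, k, size=reps)
    j = rng.integers(0, k - 1, size=reps)
    j = j + (j >= i)
    return np.minimum(i, j), np.maximum(i, j)


def neutral_coalescent_stats(
    n: int, theta: float | np.ndarray, reps: int, rng: np.random.Generator
):
    """Simulate (S, kbar, K) under the neutral constant-size coalescent.

    Fully vectorized over replicates: coalescent intervals are exponential,
    mutations fall on lineages as Poisson marks (infinite sites), each
    mutation on a branch subtending ``i`` leaves contributes ``i*(n-i)``
    discordant pairs, and the number of distinct haplotypes ``K`` is tracked
    by sealing mutation-free leaf clusters.

    ``theta`` may be a scalar or a per-replicate array (scaled mutation rate
    2*N*u per locus).

    Returns
    -------
    (S, kbar, K) : integer, float and integer arrays of length ``reps``.
    """
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (reps,))
    sizes = np.ones((reps, n), dtype=np.int64)
    clean = np.ones((reps, n), dtype=np.int64)
    K = np.zeros(reps, dtype=np.int64)
    S = np.zeros(reps, dtype=np.int64)
    pairsum = np.zeros(reps, dtype=np.float64)
    r = np.arange(reps)
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2.0
        T = rng.exponential(1.0 / rate, size=reps)
        M = rng.poisson((theta / 2.0 * T)[:, None] * np.ones((1, k)))
        sz = sizes[:, :k]
        pairsum += (M * sz * (n - sz)).sum(axis=1)
        S += M.sum(axis=1)
        sealed = (M > 0) & (clean[:, :k] > 0)
        K += sealed.sum(axis=1)
        cl = clean[:, :k]
        cl[sealed] = 0
        lo, hi = _random_distinct_pairs(rng, k, reps)
        sizes[r, lo] += sizes[r, hi]
        clean[r, lo] += clean[r, hi]
        sizes[r, hi] = sizes[r, k - 1]
        clean[r, hi] = clean[r, k - 1]
    K += (clean[:, 0] > 0).astype(np.int64)
    kbar = pairsum / (n * (n - 1) / 2.0)
    return S, kbar, K


# ---------------------------------------------------------------------------
# Tajima's D


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _tajima_d_stat(S, kbar, n: int):
    c = tajima_constants(n)
    S = np.asarray(S, dtype=float)
    kbar = np.asarray(kbar, dtype=float)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(S > 0, (kbar - S / c["a1"]) / np.sqrt(var), np.nan)


def tajimas_d(
    S: int,
    kbar: float,
    n: int,
    reps: int = 10_000,
    seed: int | None = None,
    method: str = "simulation",
) -> tuple[float, float | None]:
    """Tajima's D with a two-tailed p-value.

    The default p-value simulates ``reps`` neutral constant-size coalescent
    samples of size ``n`` at the Watterson estimate ``theta = S/a1``
    (replicates with S = 0, where D is undefined, are dropped).  The beta
    approximation of the original derivation is available via
    ``method="beta"``.  Returns ``(nan, None)`` when ``S == 0``.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S == 0:
        return float("nan"), None
    c = tajima_constants(n)
    d_obs = float(_tajima_d_stat(S, kbar, n))
    if method == "beta":
        from scipy.stats import beta as beta_dist

        dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
        dmax = ((n + 1.0) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
        alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
        bpar = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
        u = (d_obs - dmin) / (dmax - dmin)
        cdf = float(beta_dist.cdf(np.clip(u, 0, 1), bpar, alpha))
        return d_obs, float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    rng = np.random.default_rng(seed)
    theta_hat = S / c["a1"]
    S_sim, kbar_sim, _ = neutral_coalescent_stats(n, theta_hat, reps, rng)
    keep = S_sim > 0
    d_sim = _tajima_d_stat(S_sim[keep], kbar_sim[keep], n)
    if d_sim.size == 0:
        return d_obs, None
    lo = float((d_sim <= d_obs).mean())
    hi = float((d_sim >= d_obs).mean())
    return d_obs, float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# Fu's F_S


@lru_cache(maxsize=None)
def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        cur[1:] = np.logaddexp(prev[:-1], math.log(m - 1) + prev[1:]
                               if m > 1 else -np.inf)
        prev = cur
    return prev


def _log_ewens_terms(n: int, log_theta: np.ndarray) -> np.ndarray:
    """log [|s(n,k)| theta^k] for k = 1..n, rows = replicates."""
    ls = _log_stirling_first(n)[1:]  # k = 1..n
    k = np.arange(1, n + 1, dtype=float)
    return ls[None, :] + k[None, :] * log_theta[:, None]


def _fs_from_counts(n: int, kbar: np.ndarray, K: np.ndarray) -> np.ndarray:
    """F_S for arrays of (kbar, K); +inf where K == 1 or kbar == 0."""
    kbar = np.asarray(kbar, dtype=float)
    K = np.asarray(K, dtype=int)
    out = np.full(kbar.shape, np.inf)
    ok = (K > 1) & (kbar > 0)
    if not ok.any():
        return out
    log_theta = np.log(kbar[ok])
    terms = _log_ewens_terms(n, log_theta)  # (m, n)
    denom = logsumexp(terms, axis=1)
    Kok = K[ok]
    upper = np.array(
        [logsumexp(t[k - 1:]) for t, k in zip(terms, Kok)]
    )  # Pr(K >= k_obs), numerator
    lower = np.array(
        [logsumexp(t[: k - 1]) if k > 1 else -np.inf for t, k in zip(terms, Kok)]
    )
    out[ok] = (upper - denom) - (lower - denom)
    return out


def fus_fs(
    n: int,
    kbar: float,
    k_obs: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Fu's F_S and its simulation p-value.

    ``S' = Pr(K >= k_obs)`` under the Ewens sampling distribution at
    ``theta = kbar``; ``F_S = ln(S'/(1-S'))``.  ``k_obs = 1`` gives
    ``S' = 1`` and an undefined (+inf) statistic, flagged by the +inf value
    and a ``None`` p-value; the same applies for ``kbar = 0``.  The p-value
    is the proportion of neutral constant-size coalescent replicates (at
    ``theta = kbar``) with a simulated F_S at most the observed one.
    """
    if n < 3:
        raise ValueError("Fu's F_S requires n >= 3")
    if k_obs < 1 or k_obs > n:
        raise ValueError("k_obs must be in 1..n")
    fs_obs = float(_fs_from_counts(n, np.array([kbar]), np.array([k_obs]))[0])
    if not np.isfinite(fs_obs):
        return fs_obs, None
    rng = np.random.default_rng(seed)
    _, kbar_sim, K_sim = neutral_coalescent_stats(n, kbar, reps, rng)
    fs_sim = _fs_from_counts(n, kbar_sim, K_sim)
    return fs_obs, float((fs_sim <= fs_obs).mean())


def ewens_prob_k_at_least(n: int, k_obs: int, theta: float) -> float:
    """S' = Pr(K >= k_obs | theta) under the Ewens sampling distribution."""
    if theta <= 0:
        return 1.0 if k_obs <= 1 else 0.0
    terms = _log_ewens_terms(n, np.log(np.array([theta])))[0]
    return float(np.exp(logsumexp(terms[k_obs - 1:]) - logsumexp(terms)))


# ---------------------------------------------------------------------------
# combined per-group neutrality report


@dataclass(frozen=True)
class NeutralityStats:
    n: int
    S: int
    kbar: float
    k_obs: int
    D: float
    p_D: float | None
    Fs: float
    p_Fs: float | None
    d_undefined: bool = False

    @property
    def d_significant(self) -> bool | None:
        """Significance flag at the conventional alpha = 0.05 for D."""
        return None if self.p_D is None else self.p_D < 0.05

    @property
    def fs_significant(self) -> bool | None:
        """Significance flag at the conventional alpha = 0.02 for F_S."""
        return None if self.p_Fs is None else self.p_Fs < 0.02


def neutrality_tests(
    aln: Alignment,
    ids: Sequence[str] | None = None,
    reps: int = 10_000,
    seed: int | None = None,
    d_method: str = "simulation",
) -> NeutralityStats:
    """Tajima's D and Fu's F_S for one group of an alignment."""
    from .diversity import mean_pairwise_differences, segregating_sites

    sub = aln.subset(list(ids)) if ids is not None else aln
    S = segregating_sites(sub)
    kbar = mean_pairwise_differences(sub)
    # distinct haplotypes on the complete-deletion mask
    k_obs = int(np.unique(_row_classes(sub)).size)
    ss = np.random.SeedSequence(seed).spawn(2)
    D, p_D = tajimas_d(S, kbar, sub.n, reps=reps,
                       seed=int(ss[0].generate_state(1)[0] % (2**31)),
                       method=d_method) if S > 0 else (float("nan"), None)
    Fs, p_Fs = fus_fs(sub.n, kbar, k_obs, reps=reps,
                      seed=int(ss[1].generate_state(1)[0] % (2**31)))
    return NeutralityStats(sub.n, S, kbar, k_obs, D, p_D, Fs, p_Fs,
                           d_undefined=(S == 0))


def _row_classes(aln: Alignment) -> np.ndarray:
    from .data_io import usable_sites

    mask = usable_sites(aln)
    keyed = aln.matrix[:, mask]
    _, inv = np.unique(keyed, axis=0, return_inverse=True)
    return inv
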