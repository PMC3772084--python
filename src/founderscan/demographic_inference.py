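"""Coalescent composite-likelihood inference of founding parameters.

Model: a selfing population was founded at scaled time ``T`` (units of
``N_R`` generations, where ``N_R`` is the effective number of chromosomes and
a pair of lineages coalesces at rate 1 per unit time) by ``k`` founding
chromosomes sampled from a large ancestral outcrossing population.  Sampled
lineages run a Kingman coalescent back to ``T``; survivors are assigned
uniformly at random to the ``k`` founders, and lineages sharing a founder
merge instantly at ``T`` (a founder is a single chromosome).

Two summaries of the data carry the signal:

* the probability ``P_H1(k, T)`` that all sampled lineages trace to a single
  founding chromosome, observed as the count ``x`` of independent genomic
  regions (out of ``n_regions``) where every sample shares one founding
  haplotype -> a binomial likelihood term;
* the site frequency spectrum of derived alleles within those single-founder
  regions, whose expected shape ``phi`` follows from expected branch lengths:
  ``E[eta_i]`` is proportional to ``sum_j j * E[t_j] * p(i | j, n)`` with
  ``p(i|j,n) = C(n-i-1, j-2) / C(n-1, j-1)`` -> a multinomial term.

The composite log-likelihood (their sum) is maximized over a simulated
``(k, T)`` grid using common random numbers, with approximate confidence
sets taken as all grid cells within two log-likelihood units of the maximum.
The compound scaled time is resolved into natural units (``N_R`` chromosomes
and years) by matching observed within-founder diversity to the expected
pair coalescence time conditional on a shared founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from founderscan.errors import ConfigurationError, FittingError, ValidationError

#: Sentinel for log-likelihoods of impossible configurations.
NEG_INF = -1e300

DEFAULT_MU = 1.5e-8  # per-site per-generation neutral mutation rate
DEFAULT_K_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 50, 100, 200, 1000)


def _default_t_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 4.0001, 0.05), 10)


@dataclass
class InferenceConfig:
    """Grid, sample size and replication settings for the grid search."""

    n_samples: int = 4
    n_regions: int = 339
    t_grid: np.ndarray = field(default_factory=_default_t_grid)
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.replicates < 100:
            raise ConfigurationError("replicates must be >= 100")
        if self.t_grid.size == 0 or len(self.k_grid) == 0:
            raise ConfigurationError("empty parameter grid")
        if any(k < 1 for k in self.k_grid):
            raise ConfigurationError("founder counts must be >= 1")
        if (self.t_grid < 0).any():
            raise ConfigurationError("scaled times must be >= 0")


@dataclass
class CellResult:
    """Monte-Carlo summaries of one (k, T) grid cell."""

    k: int
    t_scaled: float
    p_h1: float
    phi: np.ndarray  # expected SFS proportions, derived counts 1..n-1
    n_mono: int
    replicates: int


@dataclass
class GridFit:
    """Composite log-likelihood surface with MLE and 2-delta-lnL intervals."""

    table: pd.DataFrame  # columns: k, t_scaled, p_h1, phi_1.., lnl
    k_hat: int
    t_hat: float
    ci_t: tuple[float, float]
    ci_k: tuple[int, int]
    config: InferenceConfig


@dataclass
class ResolvedDemography:
    """Natural-scale parameters resolved from the grid fit."""

    mu: float
    generation_years: float
    pi_within: float
    g: float  # E[pair coalescence time | shared founder], N_R-generation units
    n_r: float  # effective number of chromosomes
    t_f_years: float
    t_f_years_ci: tuple[float, float]


def sfs_branch_prob(i: int, j: int, n: int) -> float:
    """P(a branch present while j ancestral lineages remain subtends i of n leaves)."""
    if j < 2 or i < 1 or i > n - j + 1:
        return 0.0
    return comb(n - i - 1, j - 2) / comb(n - 1, j - 1)


def _branch_weight_matrix(n: int) -> np.ndarray:
    """W[j_idx, i_idx] = j * p(i|j,n) for epochs j=n..2 and counts i=1..n-1."""
    w = np.zeros((n - 1, n - 1))
    for idx, j in enumerate(range(n, 1, -1)):
        for i in range(1, n):
            w[idx, i - 1] = j * sfs_branch_prob(i, j, n)
    return w


class CoalescentEngine:
    """Vectorized truncated-coalescent simulator with common random numbers.

    One set of exponential epoch durations is drawn at construction; every
    grid cell reuses them (durations do not depend on (k, T); only the
    truncation does), and the founder assignment is integrated out exactly
    per replicate.  The likelihood surface is therefore smooth in (k, T)
    and the MLE is stable at moderate replicate counts.
    """

    def __init__(self, n_samples: int = 4, replicates: int = 10_000, seed: int = 0):
        if n_samples < 2:
            raise ConfigurationError("need at least 2 samples")
        self.n = n_samples
        self.replicates = replicates
        rng = np.random.default_rng(seed)
        # epoch j has total coalescence rate C(j,2); columns ordered j=n..2
        rates = np.array([comb(j, 2) for j in range(self.n, 1, -1)], dtype=float)
        self.epochs = rng.exponential(1.0 / rates, size=(replicates, self.n - 1))
        self.cum = np.cumsum(self.epochs, axis=1)
        self._w = _branch_weight_matrix(self.n)

    # -- per-cell quantities ----------------------------------------------
    def _truncate(self, t_scaled: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-replicate epoch durations clipped at T and surviving lineage counts."""
        capped = np.minimum(self.cum, t_scaled)
        prev = np.concatenate(
            [np.zeros((self.replicates, 1)), capped[:, :-1]], axis=1
        )
        durations = capped - prev
        m = self.n - (self.cum < t_scaled).sum(axis=1)
        np.maximum(m, 1, out=m)
        return durations, m

    def cell(self, k: int, t_scaled: float) -> CellResult:
        """Simulate one grid cell: P_H1 and the conditional expected SFS.

        The founder assignment is integrated out exactly: conditional on the
        epoch times, the probability that all ``m`` surviving lineages land
        on one of ``k`` founders is ``k**(1 - m)``, so each replicate
        contributes that weight instead of a Bernoulli draw.  Combined with
        the shared epoch times this removes all founder-assignment noise
        from the surface, so cells differ only through the deterministic
        dependence on (k, T) — the maximum is not chased by Monte-Carlo
        winner's-curse fluctuations.
        """
        durations, m = self._truncate(t_scaled)
        w = np.power(float(k), 1.0 - m)
        p_h1 = float(w.mean())
        w_sum = w.sum()
        if w_sum <= 0:
            phi = np.full(self.n - 1, np.nan)
        else:
            eta = (w[:, None] * (durations @ self._w)).sum(axis=0)
            total = eta.sum()
            phi = eta / total if total > 0 else np.full(self.n - 1, np.nan)
        return CellResult(
            k=k, t_scaled=t_scaled, p_h1=p_h1, phi=phi,
            n_mono=int(round(w_sum)), replicates=self.replicates,
        )

    def lineage_counts(self, t_scaled: float) -> np.ndarray:
        """Surviving lineage count at T per replicate (for distribution checks)."""
        return self._truncate(t_scaled)[1]


def expected_sfs(durations: np.ndarray, n_samples: int) -> np.ndarray:
    """Normalized expected SFS from per-replicate epoch durations.

    ``durations`` has one column per epoch, ordered from ``n_samples`` ancestral
    lineages down to 2, already truncated at the founding time; rows are
    replicates conditional on all samples tracing to one founder.  The
    population mutation rate cancels in the normalization.
    """
    durations = np.atleast_2d(np.asarray(durations, dtype=float))
    if durations.shape[1] != n_samples - 1:
        raise ValidationError(
            f"expected {n_samples - 1} epoch columns, got {durations.shape[1]}"
        )
    if durations.shape[0] == 0:
        raise FittingError("no replicates with a single founder; cell uninformative")
    eta = (durations @ _branch_weight_matrix(n_samples)).sum(axis=0)
    total = eta.sum()
    if total <= 0:
        if n_samples == 2:
            return np.array([1.0])
        raise FittingError("zero total branch length; cell uninformative")
    return eta / total


def composite_loglik(
    observed_sfs: np.ndarray | None,
    observed_mono: tuple[int, int] | None,
    cell: CellResult,
) -> float:
    """Multinomial SFS term plus binomial single-founder term at one cell.

    Either term may be omitted by passing None.  Returns a large negative
    sentinel when the cell's probabilities make the observations impossible.
    """
    lnl = 0.0
    if observed_sfs is not None:
        counts = np.asarray(observed_sfs, dtype=float)
        if (counts < 0).any():
            raise ValidationError("negative SFS counts")
        if counts.sum() > 0:
            phi = cell.phi
            if phi is None or np.isnan(phi).any():
                return NEG_INF
            with np.errstate(divide="ignore"):
                logphi = np.log(phi)
            if np.any((counts > 0) & ~np.isfinite(logphi)):
                return NEG_INF
            lnl += float(np.sum(counts[counts > 0] * logphi[counts > 0]))
    if observed_mono is not None:
        x, n_regions = observed_mono
        if x < 0 or n_regions < x:
            raise ValidationError("need 0 <= x <= n_regions")
        p = cell.p_h1
        if (p == 0.0 and x > 0) or (p == 1.0 and x < n_regions):
            return NEG_INF
        if x > 0:
            lnl += x * np.log(p)
        if n_regions - x > 0:
            lnl += (n_regions - x) * np.log1p(-p)
    return lnl


def fit_grid(
    observed_sfs: np.ndarray | None,
    observed_mono: tuple[int, int] | None,
    config: InferenceConfig | None = None,
) -> GridFit:
    """Composite log-likelihood over the (k, T) grid with CRN; MLE and CIs.

    The 2-delta-lnL confidence intervals are reported on the grid itself
    (no interpolation): the T interval is profiled over k and vice versa.
    """
    if config is None:
        config = InferenceConfig()
    if observed_sfs is None and observed_mono is None:
        raise ConfigurationError("need at least one observation term")
    engine = CoalescentEngine(
        n_samples=config.n_samples, replicates=config.replicates, seed=config.seed
    )
    rows = []
    for k in config.k_grid:
        for t in config.t_grid:
            c = engine.cell(k, t)
            lnl = composite_loglik(observed_sfs, observed_mono, c)
            row = {"k": k, "t_scaled": t, "p_h1": c.p_h1, "lnl": lnl}
            for i, v in enumerate(c.phi, start=1):
                row[f"phi_{i}"] = v
            rows.append(row)
    table = pd.DataFrame(rows)
    best = table["lnl"].idxmax()
    if table.loc[best, "lnl"] <= NEG_INF:
        raise FittingError("likelihood is degenerate everywhere on the grid")
    k_hat = int(table.loc[best, "k"])
    t_hat = float(table.loc[best, "t_scaled"])
    within = table[table["lnl"] >= table.loc[best, "lnl"] - 2.0]
    ci_t = (float(within["t_scaled"].min()), float(within["t_scaled"].max()))
    ci_k = (int(within["k"].min()), int(within["k"].max()))
    return GridFit(table=table, k_hat=k_hat, t_hat=t_hat, ci_t=ci_t, ci_k=ci_k,
                   config=config)


# ---------------------------------------------------------------------------
# Pair-level quantities and natural-scale resolution
# ---------------------------------------------------------------------------


def pair_same_founder_prob(k: int, t_scaled: float) -> float:
    """Closed-form probability that two lineages share a founding haplotype.

    Either they coalesce before the founding time (prob 1 - e^-T) or they
    survive and are assigned to the same of k founders (prob e^-T / k).
    """
    return 1.0 - np.exp(-t_scaled) + np.exp(-t_scaled) / k


def expected_pair_time_shared(k: int, t_scaled: float) -> float:
    """Closed-form E[pair coalescence time | shared founder] in N_R units."""
    t = t_scaled
    num = 1.0 - np.exp(-t) * (1.0 + t) + (t / k) * np.exp(-t)
    den = pair_same_founder_prob(k, t)
    return num / den


def simulate_pair_time_shared(
    k: int, t_scaled: float, replicates: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo E[pair coalescence time | shared founder]."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0, size=replicates)
    coalesced = t < t_scaled
    same_founder = coalesced | (rng.random(replicates) < 1.0 / k)
    times = np.where(coalesced, t, t_scaled)
    if not same_founder.any():
        raise FittingError("no shared-founder pairs simulated")
    return float(times[same_founder].mean())


def resolve_natural_scale(
    fit: GridFit,
    pi_within: float,
    mu: float = DEFAULT_MU,
    generation_years: float = 1.0,
    replicates: int = 200_000,
    seed: int = 0,
) -> ResolvedDemography:
    """Resolve (k, T) MLE plus within-founder diversity into N_R and years.

    Within-founder pairwise diversity satisfies ``pi = 2 mu N_R g`` where
    ``g`` is the expected pair coalescence time conditional on a shared
    founder (in N_R-generation units), so ``N_R = pi / (2 mu g)`` and
    ``T_f = T * N_R`` generations.  The CI on calendar time is propagated
    from the T interval, recomputing g at each interval endpoint.
    """
    if pi_within <= 0:
        raise FittingError("pi_within must be positive to resolve N_R")
    g = simulate_pair_time_shared(fit.k_hat, fit.t_hat, replicates, seed)
    n_r = pi_within / (2.0 * mu * g)
    t_f = fit.t_hat * n_r * generation_years
    ci = []
    for t_bound in fit.ci_t:
        if t_bound <= 0:
            ci.append(0.0)
            continue
        g_b = simulate_pair_time_shared(fit.k_hat, t_bound, replicates, seed)
        n_r_b = pi_within / (2.0 * mu * g_b)
        ci.append(t_bound * n_r_b * generation_years)
    return ResolvedDemography(
        mu=mu,
        generation_years=generation_years,
        pi_within=pi_within,
        g=g,
        n_r=n_r,
        t_f_years=t_f,
        t_f_years_ci=(min(ci), max(ci)),
    )


def hudson_split_time(
    d_between: float,
    pi_ancestral_proxy: float,
    mu: float = DEFAULT_MU,
    generation_years: float = 1.0,
) -> float:
    """Split time in years from net between-species divergence.

    Under a clean split with constant ancestral diversity,
    ``d = pi_anc + 2 mu T`` so ``T = (d - pi_anc) / (2 mu)`` generations.
    Exact closed form; raises if divergence falls below the ancestral proxy.
    """
    if d_between < pi_ancestral_proxy:
        raise ValidationError(
            "between-species divergence below ancestral diversity: negative time"
        )
    return (d_between - pi_ancestral_proxy) / (2.0 * mu) * generation_years
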