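"""Independent oracles for coalescent expectations.

These deliberately avoid the package's branch-length bookkeeping: the
truncated genealogy is simulated with explicit topology (which lineages
merge), mutations are attributed to branches via per-branch descendant
counts, and the lineage-count distribution comes from the exact spectral
formula.  The package's expected-SFS mapping must agree with these within
Monte-Carlo error.
"""

from __future__ import annotations

from math import comb, factorial

import numpy as np


def simulate_topology_sfs(
    k: int,
    t_scaled: float,
    n: int,
    replicates: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected SFS conditional on a single founder, by explicit topology.

    Each replicate runs a Kingman coalescent on ``n`` labelled lineages,
    truncated at ``t_scaled``; survivors are assigned uniformly to ``k``
    founders.  Conditional on all samples tracing to one founder, every
    branch segment contributes (duration x 1) expected mutations per unit
    rate, each carried by the branch's descendant leaves.  Returns
    ``(eta_mean, eta_se, p_h1)`` where ``eta[i-1]`` accumulates expected
    counts for derived class ``i``.
    """
    rng = np.random.default_rng(seed)
    etas = []
    n_mono = 0
    for _ in range(replicates):
        active = [frozenset([i]) for i in range(n)]
        t = 0.0
        eta = np.zeros(n - 1)
        while len(active) > 1:
            j = len(active)
            dt = rng.exponential(1.0 / comb(j, 2))
            if t + dt > t_scaled:
                dt = t_scaled - t
                for lin in active:
                    if len(lin) < n:
                        eta[len(lin) - 1] += dt
                t = t_scaled
                break
            for lin in active:
                if len(lin) < n:
                    eta[len(lin) - 1] += dt
            t += dt
            a, b = rng.choice(j, size=2, replace=False)
            merged = active[a] | active[b]
            active = [x for i_, x in enumerate(active) if i_ not in (a, b)] + [merged]
        founders = rng.integers(0, k, size=len(active))
        if len(active) == 1 or len(set(founders)) == 1:
            n_mono += 1
            etas.append(eta)
    if not etas:
        raise RuntimeError("no single-founder replicates")
    etas = np.array(etas)
    return etas.mean(axis=0), etas.std(axis=0) / np.sqrt(len(etas)), n_mono / replicates


def tavare_lineage_pmf(n: int, t: float, j: int) -> float:
    """P(A_n(t) = j): exact ancestral-lineage-count distribution.

    Standard spectral form with rising/falling factorials; pair coalescence
    rate 1 (time in units of the effective chromosome count).
    """
    if t == 0:
        return 1.0 if j == n else 0.0

    def rising(a, b):
        out = 1.0
        for x in range(b):
            out *= a + x
        return out

    def falling(a, b):
        out = 1.0
        for x in range(b):
            out *= a - x
        return out

    total = 0.0
    for i in range(j, n + 1):
        rho = np.exp(-i * (i - 1) / 2.0 * t)
        num = (2 * i - 1) * (-1) ** (i - j) * rising(j, i - 1) * falling(n, i)
        den = factorial(j) * factorial(i - j) * rising(n, i)
        total += rho * num / den
    return total
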