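"""Independent brute-force oracles used to cross-check the pipelines.

These deliberately use different algorithms from the package (pairwise
transitive closure instead of sorted chaining; generic numerical likelihood
maximization instead of IRLS) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def _components(dates, max_gap):
    """Connected components of days under |di - dj| <= max_gap, by pairwise
    closure (no reliance on sorted-order chaining)."""
    n = len(dates)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs((dates[i] - dates[j]).days) <= max_gap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def brute_force_dedup(records, gap_days=2, absence_window=2):
    """Exhaustive reimplementation of the presence/absence de-duplication.

    Returns the kept records as a set of (site, date) pairs.
    """
    kept = set()
    sites = {r.site for r in records}
    for site in sites:
        recs = [r for r in records if r.site == site]
        pres = [r for r in recs if r.count > 0]
        pres_dates = [r.date for r in pres]
        for comp in _components(pres_dates, gap_days):
            members = [pres[i] for i in comp]
            top = max(m.count for m in members)
            winner = min(
                (m for m in members if m.count == top), key=lambda m: m.date
            )
            kept.add((site, winner.date))
        absences = [
            r
            for r in recs
            if r.count == 0
            and not any(
                abs((r.date - d).days) <= absence_window for d in pres_dates
            )
        ]
        abs_dates = [r.date for r in absences]
        for comp in _components(abs_dates, gap_days):
            kept.add((site, min(abs_dates[i] for i in comp)))
    return kept


def logistic_negloglik(beta, x, y):
    """Negative Bernoulli log-likelihood; x includes the intercept column."""
    eta = x @ beta
    # numerically safe log(1+exp)
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def brute_force_logistic(x, y, beta0=None):
    """Maximize the Bernoulli likelihood with derivative-free Nelder-Mead."""
    from scipy.optimize import minimize

    if beta0 is None:
        beta0 = np.zeros(x.shape[1])
    res = minimize(
        logistic_negloglik,
        beta0,
        args=(x, y),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 40000},
    )
    return res.x, -res.fun


def random_sighting_fixture(rng, max_records=30):
    """A random small monitoring fixture for oracle cross-checks."""
    from datetime import date, timedelta

    from gullcast import SightingRecord

    n = int(rng.integers(1, max_records + 1))
    sites = ["a", "b"][: int(rng.integers(1, 3))]
    chosen = set()
    recs = []
    base = date(2015, 11, 1)
    while len(recs) < n:
        site = sites[int(rng.integers(len(sites)))]
        d = base + timedelta(days=int(rng.integers(0, 40)))
        if (site, d) in chosen:
            continue
        chosen.add((site, d))
        count = int(rng.integers(0, 6)) if rng.random() < 0.5 else 0
        recs.append(SightingRecord(d, site, float(rng.integers(15, 120)), count))
    return recs
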