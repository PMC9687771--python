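"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coopbind import speciation as sp
from coopbind.config import default_chelator


@pytest.fixture(scope="session")
def ida():
    return default_chelator()


@pytest.fixture(scope="session")
def scenario_lib():
    from coopbind.synthetic import scenario_library

    return scenario_library()


# ---------------------------------------------------------------------------
# nested-bisection oracle for the speciation solver: reduce the three coupled
# balances to a one-dimensional equation in free metal, solving the chelator
# sub-balance by an inner bisection at every trial metal concentration.
# Deliberately independent of the Newton-Raphson implementation.
# ---------------------------------------------------------------------------

def _log_bisect(fn, lo, hi, iters=200):
    """Root of monotone-increasing fn on [lo, hi] by bisection in log space."""
    flo, fhi = fn(lo), fn(hi)
    if flo > 0:
        return lo
    if fhi < 0:
        return hi
    llo, lhi = math.log(lo), math.log(hi)
    for _ in range(iters):
        mid = 0.5 * (llo + lhi)
        if fn(math.exp(mid)) > 0:
            lhi = mid
        else:
            llo = mid
    return math.exp(0.5 * (llo + lhi))


def free_metal_bisection_oracle(C_M, C_L, C_P, pH, chelator=None, peptide=None):
    """Free-metal concentration by nested bisection on the reduced balance."""
    species = sp.conditional_constants(chelator, pH) if chelator is not None and C_L > 0 else []
    K1 = peptide.K1 if peptide is not None and C_P > 0 else 0.0
    beta2 = K1 * peptide.K2 if peptide is not None and peptide.K2 else 0.0

    def l_of_m(m):
        if C_L == 0 or not species:
            return C_L

        def g(l):
            return l + sum(q * 10.0 ** lb * m**a * l**q for _, a, q, lb in species) - C_L

        return _log_bisect(g, C_L * 1e-30, C_L)

    def balance(m):
        l = l_of_m(m)
        p = C_P / (1.0 + K1 * m + beta2 * m * m) if C_P > 0 else 0.0
        bound = sum(a * 10.0 ** lb * m**a * l**q for _, a, q, lb in species)
        bound += K1 * m * p + 2.0 * beta2 * m * m * p
        return m + bound - C_M

    if C_M == 0:
        return 0.0
    return _log_bisect(balance, C_M * 1e-30, C_M)


def random_speciation_system(rng):
    """One random chemical system within the titration-relevant regime:
    1-3 chelator species, 1-2 peptide sites, totals log-uniform 1e-7..1e-3 M,
    log10 K in 4..12."""
    n_species = rng.integers(1, 4)
    species = []
    seen = set()
    for _ in range(n_species):
        a = int(rng.integers(1, 3))
        q = int(rng.integers(1, 3))
        if (a, q) in seen:
            continue
        seen.add((a, q))
        logb = float(rng.uniform(4.0, 12.0)) * max(a, q) ** 0.5
        species.append(sp.ComplexSpecies(a, q, logb))
    pkas = sorted(rng.uniform(2.0, 10.0, size=rng.integers(1, 3)), reverse=True)
    chelator = sp.ChelatorModel(tuple(pkas), tuple(species))
    n_sites = int(rng.integers(1, 3))
    K1 = 10.0 ** rng.uniform(4.0, 12.0)
    K2 = 10.0 ** rng.uniform(4.0, 12.0) if n_sites == 2 else None
    if n_sites == 2 and K2 is not None and K2 > K1:
        K1, K2 = K2, K1
    peptide = sp.PeptideBindingModel(n_sites, K1, K2)
    totals = 10.0 ** rng.uniform(-7.0, -3.0, size=3)
    pH = float(rng.uniform(4.0, 8.0))
    return totals, pH, chelator, peptide
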