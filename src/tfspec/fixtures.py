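"""Deterministic test fixtures: small parameter sets, genotypes covering
every macrostate, explicit sequence samples, and brute-force oracle tables.

Everything is regenerated from a seed at call time; nothing is stored on
disk, so fixtures can never go stale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import combinatorics, oracles, thermo
from .params import ModelParams

__all__ = ["fixture_generator"]


def fixture_generator(seed: int = 0, size: str = "small") -> dict:
    """Build the fixture collection.

    ``size='small'`` uses L=2 and L=3 parameter sets (full-enumeration
    oracles are cheap there); ``size='baseline'`` adds the L=5 baseline.
    Fixed seed gives identical output.
    """
    if size not in ("small", "baseline"):
        raise ValueError("size must be 'small' or 'baseline'")
    rng = np.random.default_rng(seed)

    params_sets = {
        "L2": ModelParams(L=2, n_G=1),
        "L2_pair": ModelParams(L=2, n_G=2),
        "L3": ModelParams(L=3, n_G=2),
    }
    if size == "baseline":
        params_sets["baseline"] = ModelParams()

    # constructive search: one reduced genotype per macrostate label
    p_search = params_sets["L3"]
    space = combinatorics.enumerate_states(p_search)
    labels = thermo.classify_states(space, p_search)
    per_label = {}
    for z in thermo.MACROSTATES:
        idx = np.flatnonzero(labels == z)
        if len(idx):
            i = int(idx[0])
            per_label[z] = thermo.ReducedGenotype(
                int(space.M[i]),
                tuple(map(tuple, space.k[i].tolist())),
                tuple(int(s) for s in space.sigma[i]),
            )

    # explicit sequences realising a nontrivial reduced genotype
    g = per_label.get("Partial", next(iter(per_label.values())))
    cons1, cons2, sites, sigma = combinatorics.sample_full_genotype(
        g.M, g.k_array, g.sigma, p_search.L, rng)

    # brute-force sequence-count table at L=2 (the oracle, not the formula)
    L = 2
    rows = [
        {"M": M, "k1": k1, "k2": k2,
         "count": oracles.nseq_bruteforce(k1, k2, M, L)}
        for M in range(L + 1)
        for k1 in range(L + 1)
        for k2 in range(L + 1)
    ]
    nseq_table = pd.DataFrame(rows)

    return {
        "params": params_sets,
        "genotypes_by_macrostate": per_label,
        "explicit_genotype": {
            "reduced": g, "cons1": cons1, "cons2": cons2,
            "sites": sites, "sigma": sigma,
        },
        "infeasible_env": {"f1": 0.9, "f2": 0.9, "rho": -0.9},
        "nseq_table_L2": nseq_table,
    }
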