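"""Promiscuity-promoting mutations and multi-gene specialization experiments.

A promiscuity-promoting mutation renders one position of a TF's recognition
sequence insensitive to the corresponding DNA base; the effective mismatch
to any site then counts only the remaining specific positions.  Promiscuity
temporarily relieves the pressure on binding sites to track consensus
changes: instead of a tight series of compensatory point mutations,
TF-binding-site co-evolution can pass through a promiscuous intermediate and
re-specify later, at the cost of one extra (back) mutation and of transient
crosstalk binding.  This matters most when each TF regulates several genes
(n_G > 2), where the fitness landscape develops sign epistasis and
specialization times would otherwise grow with selection strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fullseq import ExplicitGenotype, simulate_full_sequences
from .gillespie import classify_pathway
from .params import ModelParams

__all__ = [
    "PromiscuityMask",
    "effective_mismatch",
    "promiscuity_moves",
    "multigene_experiment",
]


@dataclass(frozen=True)
class PromiscuityMask:
    """Per-position specificity of one TF: ``promiscuous[p]`` True means the
    position ignores the site's base; specific positions carry the preferred
    letter in the consensus sequence."""

    promiscuous: tuple

    @classmethod
    def all_specific(cls, L: int) -> "PromiscuityMask":
        return cls(tuple([False] * L))

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.promiscuous, dtype=bool)

    def to_string(self) -> str:
        return "".join("*" if p else "." for p in self.promiscuous)

    @classmethod
    def from_string(cls, s: str) -> "PromiscuityMask":
        if set(s) - {"*", "."}:
            raise ValueError("mask string must contain only '*' and '.'")
        return cls(tuple(c == "*" for c in s))


def effective_mismatch(consensus, mask: PromiscuityMask | np.ndarray, site) -> int:
    """Mismatch count over specific positions only.

    Promiscuous positions contribute zero regardless of the site letter, so
    adding promiscuity never increases any mismatch.
    """
    consensus = np.asarray(consensus)
    site = np.asarray(site)
    m = mask.as_array if isinstance(mask, PromiscuityMask) else np.asarray(mask, bool)
    if not (len(consensus) == len(site) == len(m)):
        raise ValueError("consensus, mask and site must have equal lengths")
    return int(((consensus != site) & ~m).sum())


def promiscuity_moves(g: ExplicitGenotype, params: ModelParams,
                      revert: str = "uniform") -> list[dict]:
    """Catalog of promiscuity toggles available from an explicit genotype.

    Each specific position can become promiscuous at rate ``r_P * mu``; each
    promiscuous position reverts at total rate ``r_P * mu``, to a preferred
    letter drawn uniformly from the four bases (``revert='uniform'``, rate
    split per letter) or to the stored letter (``revert='stored'``).  The
    moves enter the simulator's acceptance step through the fitness of the
    resulting effective mismatches; with ``r_P = 0`` the catalog is empty.
    """
    moves: list[dict] = []
    if params.r_P <= 0:
        return moves
    for i in range(2):
        for p in range(g.L):
            if not g.promiscuous[i, p]:
                moves.append({"kind": "gain", "tf": i, "pos": p,
                              "rate": params.r_P * params.mu})
            elif revert == "stored":
                moves.append({"kind": "revert", "tf": i, "pos": p,
                              "letter": int(g.cons[i, p]),
                              "rate": params.r_P * params.mu})
            else:
                for letter in range(4):
                    moves.append({"kind": "revert", "tf": i, "pos": p,
                                  "letter": letter,
                                  "rate": params.r_P * params.mu / 4.0})
    return moves


def multigene_experiment(
    params: ModelParams,
    n_G_values=(2, 4),
    Ns_values=(25.0,),
    promiscuity=(False, True),
    r_P: float = 1.0,
    replicates: int = 100,
    horizon: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Time to full specialization across gene counts and selection strengths.

    For each (n_G, Ns, promiscuity) cell, runs ``replicates`` explicit-
    sequence simulations from the post-duplication state until the
    generalized 'Specialize Both' macrostate (each TF strongly binds exactly
    one signal group's genes, sensing matched one-to-one) or the horizon.
    Returns mean arrival time tau in 1/mu units (horizon-censored mean when
    some replicates are unresolved), its standard error, the unresolved
    fraction, and the fraction of deleterious fixations en route.  The
    ``speedup`` column reports tau(off)/tau(on) at matched (n_G, Ns).
    """
    if any(n % 2 for n in n_G_values):
        raise ValueError("n_G values must be even")
    if horizon is None:
        horizon = 50.0 / params.mu
    rows = []
    for n_G in n_G_values:
        for Ns in Ns_values:
            for prom in promiscuity:
                p = params.replace(n_G=int(n_G), r_P=(r_P if prom else 0.0)
                                   ).with_Ns(float(Ns))
                taus, censored, ndel, nsub = [], 0, 0, 0
                for rep in range(replicates):
                    rng = np.random.default_rng([seed, int(n_G), int(Ns * 1000),
                                                 int(prom), rep])
                    tr = simulate_full_sequences(p, horizon=horizon, rng=rng,
                                                 stop_at="SpecializeBoth")
                    kind, tau = classify_pathway(tr)
                    if tau is None:
                        censored += 1
                        taus.append(horizon)
                        d = tr.dF
                    else:
                        taus.append(tau)
                        d = tr.dF[:int(np.searchsorted(tr.times, tau))]
                    ndel += int((d < 0).sum())
                    nsub += len(d)
                taus = np.array(taus) * params.mu
                rows.append({
                    "n_G": int(n_G), "Ns": float(Ns), "promiscuity": bool(prom),
                    "replicates": replicates,
                    "tau_mean": float(taus.mean()),
                    "tau_se": float(taus.std(ddof=1) / np.sqrt(len(taus))),
                    "unresolved_fraction": censored / replicates,
                    "deleterious_fraction": ndel / nsub if nsub else float("nan"),
                })
    df = pd.DataFrame(rows)
    df["speedup"] = np.nan
    for (n_G, Ns), grp in df.groupby(["n_G", "Ns"]):
        if set(grp["promiscuity"]) == {False, True}:
            off = float(grp.loc[~grp["promiscuity"], "tau_mean"].iloc[0])
            on = float(grp.loc[grp["promiscuity"], "tau_mean"].iloc[0])
            df.loc[grp.index[grp["promiscuity"]], "speedup"] = off / on
    return df
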