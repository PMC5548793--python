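"""Exact combinatorics of the reduced-genotype space.

A reduced genotype lumps all explicit sequences (two TF consensus sequences of
length ``L`` plus one binding site per gene) into the sufficient statistics
``{M, k_ij, sigma_i}``: the number of positions ``M`` at which the two
consensus sequences agree, the mismatch counts ``k_ij`` between TF ``i`` and
the site of gene ``j``, and the sensing alleles.

Given ``M``, a binding site decomposes position-by-position into five classes:

=====  =============================  =========================
count  consensus positions            site letter
=====  =============================  =========================
``a``  agreement (same letter)        matches both TFs
``b``  agreement                      mismatches both (3 letters)
``c``  disagreement                   matches TF1 only
``d``  disagreement                   matches TF2 only
``e``  disagreement                   matches neither (2 letters)
=====  =============================  =========================

with ``a + b = M``, ``c + d + e = L - M``, ``k1 = b + d + e``,
``k2 = b + c + e``.  Summing the number of letter arrangements over the free
index ``a`` gives the exact count ``N_seq(k1, k2 | M)`` of binding-site
sequences realising a mismatch pair, and from it the neutral (mutation-drift)
weight of every reduced genotype.  All counts use exact integer arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, SENSING_ALLELES

__all__ = [
    "SiteComposition",
    "nseq",
    "composition_support",
    "composition_distribution",
    "composition_expectations",
    "feasible_pairs",
    "neutral_weight",
    "StateSpace",
    "enumerate_states",
    "sample_consensus_pair",
    "sample_site",
    "sample_full_genotype",
    "reduced_from_sequences",
]

ALPHABET = 4


class StateSpaceTooLarge(MemoryError):
    pass


class InfeasibleGenotype(ValueError):
    pass


@dataclass(frozen=True)
class SiteComposition:
    """Position-class counts (a, b, c, d, e) of one binding site; see module docs."""

    a: int
    b: int
    c: int
    d: int
    e: int

    @property
    def k1(self) -> int:
        return self.b + self.d + self.e

    @property
    def k2(self) -> int:
        return self.b + self.c + self.e

    @property
    def n_arrangements(self) -> int:
        """Number of explicit site sequences with this composition, for a
        fixed consensus pair."""
        M = self.a + self.b
        Lm = self.c + self.d + self.e
        return (
            math.comb(M, self.a)
            * 3 ** self.b
            * math.comb(Lm, self.c)
            * math.comb(Lm - self.c, self.d)
            * 2 ** self.e
        )


def composition_support(k1: int, k2: int, M: int, L: int) -> list[SiteComposition]:
    """All feasible compositions for mismatch pair (k1, k2) given (M, L)."""
    out = []
    for a in range(0, M + 1):
        b = M - a
        c = L - k1 - a
        d = L - k2 - a
        e = k1 + k2 + 2 * a - M - L
        if min(b, c, d, e) < 0:
            continue
        out.append(SiteComposition(a, b, c, d, e))
    return out


def nseq(k1: int, k2: int, M: int, L: int) -> int:
    """Exact number of length-``L`` sites with mismatches (k1, k2) to two
    consensus sequences agreeing at ``M`` positions; 0 when infeasible."""
    if not (0 <= k1 <= L and 0 <= k2 <= L and 0 <= M <= L):
        return 0
    return sum(comp.n_arrangements for comp in composition_support(k1, k2, M, L))


def composition_distribution(
    k1: int, k2: int, M: int, L: int
) -> list[tuple[SiteComposition, float]]:
    """Distribution over compositions for a site drawn uniformly from the
    ``nseq`` sequences compatible with (k1, k2, M)."""
    support = composition_support(k1, k2, M, L)
    total = sum(c.n_arrangements for c in support)
    if total == 0:
        raise InfeasibleGenotype(f"no sequences with k=({k1},{k2}) at M={M}, L={L}")
    return [(c, c.n_arrangements / total) for c in support]


def composition_expectations(k1: int, k2: int, M: int, L: int) -> np.ndarray:
    """Expected (a, b, c, d, e) under the uniform within-class distribution."""
    dist = composition_distribution(k1, k2, M, L)
    out = np.zeros(5)
    for comp, p in dist:
        out += p * np.array([comp.a, comp.b, comp.c, comp.d, comp.e], dtype=float)
    return out


def feasible_pairs(M: int, L: int) -> list[tuple[int, int]]:
    """All (k1, k2) with at least one realising sequence at this (M, L)."""
    return [
        (k1, k2)
        for k1 in range(L + 1)
        for k2 in range(L + 1)
        if nseq(k1, k2, M, L) > 0
    ]


def neutral_weight(M: int, k: np.ndarray, L: int) -> int:
    """Exact number of explicit sequence genotypes (consensus pair + sites)
    mapping to reduced state (M, k); the sensing alleles add multiplicity 1.

    ``k`` has shape (2, n_G).  Equals ``C(L, M) * 3^(L-M) * prod_j
    nseq(k_1j, k_2j | M)``; 0 when any gene is infeasible.
    """
    w = math.comb(L, M) * 3 ** (L - M)
    for j in range(k.shape[1]):
        w *= nseq(int(k[0, j]), int(k[1, j]), M, L)
    return w


# ---------------------------------------------------------------------------
# state-space enumeration


@dataclass
class StateSpace:
    """Enumerated reduced-genotype space with exact neutral weights.

    Arrays are aligned by state index: ``M[i]``, ``k[i]`` (shape (2, n_G)),
    ``sigma[i]`` (shape (2,)), ``weights[i]`` (exact int), ``log_weight[i]``.
    """

    params: ModelParams
    M: np.ndarray
    k: np.ndarray
    sigma: np.ndarray
    weights: list = field(repr=False)
    log_weight: np.ndarray = field(repr=False)
    _codes: np.ndarray = field(repr=False)
    _order: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.M)

    @property
    def n_states(self) -> int:
        return len(self.M)

    def encode(self, M, k, sigma) -> np.ndarray:
        """Mixed-radix integer code of states; vectorised over leading axes."""
        L = self.params.L
        base = L + 1
        M = np.asarray(M, dtype=np.int64)
        k = np.asarray(k, dtype=np.int64)
        sigma = np.asarray(sigma, dtype=np.int64)
        code = M
        kflat = k.reshape(*k.shape[:-2], -1)
        for t in range(kflat.shape[-1]):
            code = code * base + kflat[..., t]
        code = code * 16 + sigma[..., 0] * 4 + sigma[..., 1]
        return code

    def index_of(self, M, k, sigma):
        """State index/indices for given reduced coordinates; -1 if absent."""
        code = self.encode(M, k, sigma)
        return self.lookup_codes(np.atleast_1d(code))

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self._codes, codes)
        pos = np.clip(pos, 0, len(self._codes) - 1)
        found = self._codes[pos] == codes
        idx = np.where(found, self._order[pos], -1)
        return idx

    def neutral_distribution(self) -> np.ndarray:
        """Normalised neutral (mutation-drift) distribution P0 over states."""
        lw = self.log_weight
        w = np.exp(lw - lw.max())
        return w / w.sum()

    def state_tuple(self, i: int) -> tuple:
        return (
            int(self.M[i]),
            tuple(map(tuple, self.k[i].tolist())),
            tuple(self.sigma[i].tolist()),
        )


def enumerate_states(params: ModelParams, max_states: int = 5_000_000) -> StateSpace:
    """Enumerate all feasible reduced genotypes for ``params``.

    A state is feasible iff every gene's (k_1j, k_2j) pair has ``nseq > 0`` at
    its ``M``.  The count is ``sum_M (#feasible pairs at M)^n_G * 16``; an
    explicit size estimate guards against blowing memory at large L or n_G.
    """
    L, n_G = params.L, params.n_G
    pairs_by_M = {M: feasible_pairs(M, L) for M in range(L + 1)}
    est = sum(len(p) ** n_G for p in pairs_by_M.values()) * 16
    if est > max_states:
        raise StateSpaceTooLarge(
            f"state space has {est} states, above the {max_states} guard"
        )

    Ms, ks, sigmas, weights = [], [], [], []
    sigma_combos = list(itertools.product(SENSING_ALLELES, repeat=2))
    for M in range(L + 1):
        pairs = pairs_by_M[M]
        base = math.comb(L, M) * 3 ** (L - M)
        pair_counts = {p: nseq(p[0], p[1], M, L) for p in pairs}
        for combo in itertools.product(pairs, repeat=n_G):
            k = np.array(combo, dtype=np.int8).T  # (2, n_G)
            w = base
            for p in combo:
                w *= pair_counts[p]
            for sg in sigma_combos:
                Ms.append(M)
                ks.append(k)
                sigmas.append(sg)
                weights.append(w)

    M_arr = np.array(Ms, dtype=np.int16)
    k_arr = np.array(ks, dtype=np.int8)
    sigma_arr = np.array(sigmas, dtype=np.int8)
    log_w = np.array([math.log(w) for w in weights])

    space = StateSpace(
        params=params,
        M=M_arr,
        k=k_arr,
        sigma=sigma_arr,
        weights=weights,
        log_weight=log_w,
        _codes=np.empty(0, dtype=np.int64),
        _order=np.empty(0, dtype=np.int64),
    )
    codes = space.encode(M_arr, k_arr, sigma_arr)
    order = np.argsort(codes)
    space._codes = codes[order]
    space._order = order
    if len(np.unique(space._codes)) != len(codes):
        raise RuntimeError("duplicate state codes in enumeration")
    return space


# ---------------------------------------------------------------------------
# uniform sampling of explicit sequences


def sample_consensus_pair(M: int, L: int, rng: np.random.Generator):
    """Uniformly sample two consensus sequences (int arrays, letters 0..3)
    agreeing at exactly M positions."""
    cons1 = rng.integers(0, ALPHABET, size=L)
    cons2 = cons1.copy()
    disagree = rng.choice(L, size=L - M, replace=False)
    # shift by 1..3 guarantees a different letter, uniform over the other 3
    cons2[disagree] = (cons2[disagree] + rng.integers(1, ALPHABET, size=L - M)) % ALPHABET
    return cons1, cons2


def sample_site(
    cons1: np.ndarray, cons2: np.ndarray, k1: int, k2: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly sample a binding site with mismatches (k1, k2) to the given
    consensus pair."""
    L = len(cons1)
    agree = np.flatnonzero(cons1 == cons2)
    disagree = np.flatnonzero(cons1 != cons2)
    M = len(agree)
    dist = composition_distribution(k1, k2, M, L)
    probs = [p for _, p in dist]
    comp = dist[rng.choice(len(dist), p=probs)][0]

    site = np.empty(L, dtype=cons1.dtype)
    perm_a = rng.permutation(agree)
    match_both, mis_both = perm_a[: comp.a], perm_a[comp.a :]
    site[match_both] = cons1[match_both]
    site[mis_both] = (cons1[mis_both] + rng.integers(1, 4, size=comp.b)) % ALPHABET

    perm_d = rng.permutation(disagree)
    pos_c = perm_d[: comp.c]
    pos_d = perm_d[comp.c : comp.c + comp.d]
    pos_e = perm_d[comp.c + comp.d :]
    site[pos_c] = cons1[pos_c]
    site[pos_d] = cons2[pos_d]
    for p in pos_e:
        choices = [x for x in range(ALPHABET) if x != cons1[p] and x != cons2[p]]
        site[p] = choices[rng.integers(0, 2)]
    return site


def sample_full_genotype(
    M: int, k: np.ndarray, sigma, L: int, rng: np.random.Generator
):
    """Sample explicit sequences uniformly from the set compatible with the
    reduced genotype (M, k, sigma).

    Returns ``(cons1, cons2, sites, sigma)`` with ``sites`` of shape
    (n_G, L).  Raises :class:`InfeasibleGenotype` if the reduced state has no
    realisation.
    """
    k = np.asarray(k)
    if neutral_weight(M, k, L) == 0:
        raise InfeasibleGenotype(f"reduced state M={M}, k={k.tolist()} infeasible")
    cons1, cons2 = sample_consensus_pair(M, L, rng)
    sites = np.stack(
        [sample_site(cons1, cons2, int(k[0, j]), int(k[1, j]), rng)
         for j in range(k.shape[1])]
    )
    return cons1, cons2, sites, tuple(int(x) for x in np.atleast_1d(sigma))


def reduced_from_sequences(cons1, cons2, sites) -> tuple[int, np.ndarray]:
    """Recover (M, k) from explicit sequences; inverse of sampling."""
    cons1 = np.asarray(cons1)
    cons2 = np.asarray(cons2)
    sites = np.atleast_2d(np.asarray(sites))
    M = int((cons1 == cons2).sum())
    k = np.stack(
        [(sites != cons1).sum(axis=1), (sites != cons2).sum(axis=1)]
    ).astype(int)
    return M, k
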