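"""Brute-force oracles over explicit sequences.

These routines enumerate full sequence genotypes directly -- no lumping, no
combinatorial formulas -- and exist to validate the reduced-genotype
machinery: the sequence-counting formula, the class-averaged lumped mutation
rates, and the steady state of the lumped chain.  They are exponential in L
and only usable at toy sizes (L <= 3 for chains, L <= 6 for counting).
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.sparse as sps

from . import thermo
from .chain import fixation_probability
from .combinatorics import StateSpace, enumerate_states, reduced_from_sequences
from .params import ENVIRONMENTS, ModelParams, SENSING_ALLELES

__all__ = [
    "nseq_bruteforce",
    "nseq_bruteforce_table",
    "FullChain",
    "enumerate_full_chain",
]


def nseq_bruteforce(k1: int, k2: int, M: int, L: int) -> int:
    """Count length-L sites with mismatches (k1, k2) to a fixed consensus
    pair agreeing at M positions, by scanning all 4^L sequences."""
    cons1 = np.zeros(L, dtype=int)
    cons2 = np.zeros(L, dtype=int)
    cons2[M:] = 1  # any fixed pair with M agreements will do, by symmetry
    count = 0
    for site in itertools.product(range(4), repeat=L):
        s = np.array(site)
        if (s != cons1).sum() == k1 and (s != cons2).sum() == k2:
            count += 1
    return count


def nseq_bruteforce_table(M: int, L: int) -> np.ndarray:
    """All sequence counts for one M at once: entry (k1, k2) of the returned
    (L+1, L+1) array counts the sites at those mismatches to a fixed
    consensus pair, scanning all 4^L sequences vectorised."""
    cons1 = np.zeros(L, dtype=np.int8)
    cons2 = np.zeros(L, dtype=np.int8)
    cons2[M:] = 1
    codes = np.arange(4 ** L)
    digits = np.empty((len(codes), L), dtype=np.int8)
    tmp = codes.copy()
    for d in range(L):
        digits[:, d] = tmp % 4
        tmp //= 4
    k1 = (digits != cons1).sum(axis=1)
    k2 = (digits != cons2).sum(axis=1)
    table = np.zeros((L + 1, L + 1), dtype=np.int64)
    np.add.at(table, (k1, k2), 1)
    return table


class FullChain:
    """Origin-fixation chain over explicit sequence genotypes.

    State layout: digits base 4 = [cons1 (L), cons2 (L), site_1..site_nG
    (L each)], plus two sensing alleles; all enumerated densely.
    """

    def __init__(self, params: ModelParams, digits: np.ndarray,
                 sigma: np.ndarray, Q: sps.csr_matrix, F: np.ndarray):
        self.params = params
        self.digits = digits
        self.sigma = sigma
        self.Q = Q
        self.F = F

    @property
    def n_states(self) -> int:
        return len(self.F)

    def reduced_index(self, space: StateSpace) -> np.ndarray:
        """Index of each full state in the reduced state space."""
        L, n_G = self.params.L, self.params.n_G
        cons1 = self.digits[:, :L]
        cons2 = self.digits[:, L:2 * L]
        sites = self.digits[:, 2 * L:].reshape(-1, n_G, L)
        M = (cons1 == cons2).sum(axis=1)
        k1 = (sites != cons1[:, None, :]).sum(axis=2)
        k2 = (sites != cons2[:, None, :]).sum(axis=2)
        k = np.stack([k1, k2], axis=1)  # (n, 2, n_G)
        idx = space.lookup_codes(space.encode(M, k, self.sigma))
        if (idx < 0).any():
            raise RuntimeError("full state projects outside the reduced space")
        return idx

    def steady_state(self) -> np.ndarray:
        """Stationary distribution.  All microscopic mutation rates are
        symmetric, so the chain is reversible with respect to
        exp(2(N-1) F) (Kimura fixation-rate ratio); validated against the
        generator's balance residual."""
        w = np.exp(2.0 * (self.params.N - 1) * (self.F - self.F.max()))
        pi = w / w.sum()
        resid = np.abs(self.Q.T @ pi).max() / np.abs(self.Q.data).max()
        if resid > 1e-10:
            raise RuntimeError(f"full-chain stationarity residual {resid}")
        return pi


def enumerate_full_chain(params: ModelParams) -> FullChain:
    """Build the explicit-sequence origin-fixation chain by enumerating all
    4^(L*(2+n_G)) * 16 genotypes.  Feasible only at toy sizes."""
    L, n_G = params.L, params.n_G
    n_seq_digits = L * (2 + n_G)
    n_seq = 4 ** n_seq_digits
    n = n_seq * 16
    if n > 2_000_000:
        raise MemoryError(f"full chain with {n} states is too large")

    # state index = seq_code * 16 + sigma1 * 4 + sigma2
    seq_code = np.arange(n_seq, dtype=np.int64)
    digits = np.empty((n_seq, n_seq_digits), dtype=np.int8)
    tmp = seq_code.copy()
    for d in range(n_seq_digits):
        digits[:, d] = tmp % 4
        tmp //= 4
    digits_full = np.repeat(digits, 16, axis=0)
    sig_combo = np.array([(s1, s2) for s1 in SENSING_ALLELES for s2 in SENSING_ALLELES],
                         dtype=np.int8)
    sigma_full = np.tile(sig_combo, (n_seq, 1))

    F = _fitness_full(params, digits_full, sigma_full)

    rows, cols, mus = [], [], []
    state = np.arange(n, dtype=np.int64)
    # sequence point mutations
    for d in range(n_seq_digits):
        if d < L:
            rate = params.r_TF * params.mu / 3.0  # TF1 consensus
        elif d < 2 * L:
            rate = params.r_TF * params.mu / 3.0  # TF2 consensus
        else:
            rate = params.mu / 3.0  # binding sites
        old = digits_full[:, d].astype(np.int64)
        for shift in (1, 2, 3):
            new = (old + shift) % 4
            tgt = state + (new - old) * (4 ** d) * 16
            rows.append(state); cols.append(tgt)
            mus.append(np.full(n, rate))
    # sensing flips
    for i, place in ((0, 4), (1, 1)):
        old = sigma_full[:, i].astype(np.int64)
        for bit in (0b01, 0b10):
            new = old ^ bit
            tgt = state + (new - old) * place
            rows.append(state); cols.append(tgt)
            mus.append(np.full(n, params.r_S * params.mu))

    src = np.concatenate(rows); dst = np.concatenate(cols)
    mu = np.concatenate(mus)
    rate = 2.0 * params.N * mu * fixation_probability(F[dst] - F[src], params.N)
    Q = sps.coo_matrix((rate, (src, dst)), shape=(n, n)).tocsr()
    Q = (Q - sps.diags(np.asarray(Q.sum(axis=1)).ravel())).tocsr()
    return FullChain(params, digits_full, sigma_full, Q, F)


def _fitness_full(params: ModelParams, digits: np.ndarray,
                  sigma: np.ndarray) -> np.ndarray:
    L, n_G = params.L, params.n_G
    cons1 = digits[:, :L]
    cons2 = digits[:, L:2 * L]
    sites = digits[:, 2 * L:].reshape(len(digits), n_G, L)
    k = np.stack([
        (sites != cons1[:, None, :]).sum(axis=2),
        (sites != cons2[:, None, :]).sum(axis=2),
    ], axis=1).astype(float)  # (n, 2, n_G)
    E = np.exp(-params.eps * k)
    env = np.array(ENVIRONMENTS)
    act = ((sigma[:, :, None] & env[None, None, :]) != 0).astype(float)
    x = params.C0 * np.einsum("nim,nij->njm", act, E)
    p = x / (1.0 + x)
    if params.mode == "repressor":
        p = 1.0 - p
    alpha = params.env.as_array
    resid = (p - params.ideal_profile()[None]) ** 2
    loss = np.einsum("njm,jm,m->n", resid, params.weight_profile(), alpha)
    return -params.s * loss


def lumped_mutation_oracle(params: ModelParams, space: StateSpace | None = None):
    """Class-averaged mutation-rate matrix computed from the full chain.

    Averages the microscopic mutation rates into each target class over the
    uniform distribution of explicit genotypes within each source class (the
    neutral within-class law).  This is the quantity the analytic lumped
    rates must reproduce.
    """
    full = enumerate_full_chain(params)
    if space is None:
        space = enumerate_states(params)
    idx = full.reduced_index(space)
    n_red = len(space)

    # rebuild the microscopic mu matrix (rates without fixation factor)
    # from Q by dividing out Phi -- simpler: recompute as in enumerate_full_chain
    neutral = params.replace(s=0.0)
    fullN = enumerate_full_chain(neutral)
    Qn = fullN.Q.tocoo()
    keep = Qn.row != Qn.col
    mu_micro = Qn.data[keep] / 2.0  # neutral rate = 2*N*mu*(1/N) = 2*mu
    rows = idx[Qn.row[keep]]
    cols = idx[Qn.col[keep]]
    M = sps.coo_matrix((mu_micro, (rows, cols)), shape=(n_red, n_red)).tocsr()
    class_size = np.bincount(idx, minlength=n_red).astype(float)
    D = sps.diags(1.0 / class_size)
    lumped = (D @ M).tocsr()
    lumped.setdiag(0.0)
    lumped.eliminate_zeros()
    return lumped
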