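"""Origin-fixation Markov chain on reduced genotypes.

In the weak-mutation regime the population is monomorphic between sequential
fixations, and evolution is a continuous-time Markov chain over genotypes
with rates

    r_xy = 2 N mu_xy Phi(F(x) - F(y)),

the product of the population mutation rate toward x and the Kimura fixation
probability of a single mutant.  The reduced state {M, k_ij, sigma_i} is not
strongly lumpable -- the position-class composition of a binding site varies
within a class -- so the lumped mutation rate mu_xy is the *exact expectation*
of the microscopic rate over the uniform (neutral) distribution of
compositions within the source class.  Site compositions are independent
across genes given the consensus pair, which makes the class average a product
of small per-gene factors; no Monte-Carlo averaging is needed.

Mutation classes and their per-event rates:

* binding-site point mutations: rate mu/3 per site position per target letter;
* TF consensus point mutations: rate r_TF*mu/3 per consensus position per
  target letter, jointly moving M and the whole mismatch row k_i;
* sensing-allele bit flips: rate r_S*mu per bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from . import thermo
from .combinatorics import StateSpace, composition_expectations, enumerate_states
from .params import ModelParams

__all__ = [
    "ChainModel",
    "HittingTimeResult",
    "fixation_probability",
    "build_chain",
    "steady_state",
    "propagate",
    "hitting_time",
    "dwell_time",
    "macrostate_probabilities",
    "dominant_macrostate_map",
]


def fixation_probability(dF, N: int):
    """Kimura fixation probability of a single mutant with fitness advantage dF.

    Phi = (1 - exp(-2 dF)) / (1 - exp(-2 N dF)); the dF -> 0 limit is 1/N.
    Vectorised and numerically safe for strongly deleterious mutants, where
    Phi ~ exp(2 (N-1) dF) underflows smoothly to zero.
    """
    if N < 2:
        raise ValueError("population size must be >= 2")
    dF = np.asarray(dF, dtype=float)
    a = -2.0 * dF
    out = np.empty_like(a)

    neutral = np.abs(N * a) < 1e-10
    big = (N * a) > 700.0  # denominator would overflow
    normal = ~(neutral | big)

    out[neutral] = 1.0 / N
    with np.errstate(over="ignore", invalid="ignore"):
        out[normal] = np.expm1(a[normal]) / np.expm1(N * a[normal])
    out[big] = np.exp(np.clip(a[big] * (1.0 - N), -745.0, 0.0))
    return out if out.ndim else float(out)


@dataclass
class ChainModel:
    """Rate matrix of the origin-fixation chain over an enumerated state space.

    ``Q`` is the generator in row-source convention (``Q[x, y]`` = rate x->y,
    diagonal = -exit rate); the column-source convention (P' = R P) is ``Q.T``.
    ``mu_matrix`` holds the class-averaged mutation rates without the fixation
    factor, and ``F`` the per-state fitness.
    """

    params: ModelParams
    space: StateSpace
    Q: sps.csr_matrix = field(repr=False)
    mu_matrix: sps.csr_matrix = field(repr=False)
    F: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.space)

    @property
    def R(self) -> sps.csr_matrix:
        """Column-source generator (P' = R P)."""
        return self.Q.T.tocsr()

    def transition_matrix(self, t_g: float | None = None) -> sps.csr_matrix:
        """Per-generation transition matrix A = I + Q*t_g (row-stochastic)."""
        t_g = self.params.t_g if t_g is None else t_g
        n = self.n_states
        A = sps.eye(n, format="csr") + self.Q * t_g
        return A

    def initial_distribution(self) -> np.ndarray:
        """Point mass on the post-duplication state (M=L, k=0, sigma=(11,11))."""
        g = thermo.initial_genotype(self.params)
        idx = self.state_index(g)
        P = np.zeros(self.n_states)
        P[idx] = 1.0
        return P

    def state_index(self, g: thermo.ReducedGenotype) -> int:
        idx = self.space.index_of(g.M, g.k_array[None], np.array([g.sigma]))
        if idx[0] < 0:
            raise KeyError(f"state {g} not in enumerated space")
        return int(idx[0])


# ---------------------------------------------------------------------------
# chain construction


def _expectation_tables(L: int):
    """E[a..e] per feasible (M, k1, k2); NaN elsewhere.  Shape (L+1,)*3 + (5,)."""
    tab = np.full((L + 1, L + 1, L + 1, 5), np.nan)
    from .combinatorics import feasible_pairs

    for M in range(L + 1):
        for k1, k2 in feasible_pairs(M, L):
            tab[M, k1, k2] = composition_expectations(k1, k2, M, L)
    return tab


def _mutation_moves(space: StateSpace, params: ModelParams):
    """All lumped mutation moves as (src, dst, mu_rate) arrays.

    Rates are exact class averages; every positive-rate target is feasible by
    construction and its absence from the space is treated as a bug.
    """
    L, n_G, mu = params.L, params.n_G, params.mu
    n = len(space)
    M = space.M.astype(np.int64)
    k = space.k.astype(np.int64)  # (n, 2, n_G)
    sigma = space.sigma.astype(np.int64)
    tab = _expectation_tables(L)

    # per-state per-gene composition expectations E[a..e]
    Ea = np.empty((n, n_G)); Eb = np.empty((n, n_G))
    Ec = np.empty((n, n_G)); Ed = np.empty((n, n_G)); Ee = np.empty((n, n_G))
    for j in range(n_G):
        vals = tab[M, k[:, 0, j], k[:, 1, j]]
        Ea[:, j], Eb[:, j], Ec[:, j], Ed[:, j], Ee[:, j] = vals.T

    srcs, dsts, rates = [], [], []
    all_src = np.arange(n)

    def push(src, Mt, kt, st, rate):
        keep = rate > 0.0
        if not keep.any():
            return
        src = src[keep]
        code = space.encode(Mt[keep], kt[keep], st[keep])
        dst = space.lookup_codes(code)
        if (dst < 0).any():
            raise RuntimeError("positive-rate move to a state outside the space")
        srcs.append(src); dsts.append(dst); rates.append(rate[keep])

    # --- binding-site point mutations -------------------------------------
    site_classes = [
        ((+1, +1), lambda j: mu * Ea[:, j]),
        ((-1, -1), lambda j: (mu / 3.0) * Eb[:, j]),
        ((+1, -1), lambda j: (mu / 3.0) * Ec[:, j]),
        ((+1, 0), lambda j: (2.0 * mu / 3.0) * Ec[:, j]),
        ((-1, +1), lambda j: (mu / 3.0) * Ed[:, j]),
        ((0, +1), lambda j: (2.0 * mu / 3.0) * Ed[:, j]),
        ((-1, 0), lambda j: (mu / 3.0) * Ee[:, j]),
        ((0, -1), lambda j: (mu / 3.0) * Ee[:, j]),
    ]
    for j in range(n_G):
        for (d1, d2), rate_fn in site_classes:
            kt = k.copy()
            kt[:, 0, j] += d1
            kt[:, 1, j] += d2
            push(all_src, M, kt, sigma, rate_fn(j))

    # --- sensing-allele bit flips ------------------------------------------
    if params.r_S > 0:
        for i in range(2):
            for bit in (0b01, 0b10):
                st = sigma.copy()
                st[:, i] ^= bit
                push(all_src, M, k, st,
                     np.full(n, params.r_S * mu))

    # --- TF consensus point mutations --------------------------------------
    # For a mutation in TF t's consensus, a position is either an agreement
    # position (prob. weight M; any of 3 letters; M -> M-1) or a disagreement
    # position, where the new letter either equals the other TF's letter
    # (1 of 3; M -> M+1) or not (2 of 3; M unchanged).  Per gene, the site's
    # letter class at that position gives the change of k_tj; classes are
    # independent across genes, so the joint distribution over
    # (dk_t1..dk_tnG) is a product of per-gene three-point laws.
    if params.r_TF > 0:
        Mf = M.astype(float)
        Lm = (L - M).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(Mf[:, None] > 0, Ea / Mf[:, None], 0.0)
            u_match = np.stack([Ec, Ed]) / Lm[None, :, None]   # (2, n, n_G)
            u_other = np.stack([Ed, Ec]) / Lm[None, :, None]
            u_e = np.stack([Ee, Ee]) / Lm[None, :, None]
        u_match = np.nan_to_num(u_match)
        u_other = np.nan_to_num(u_other)
        u_e = np.nan_to_num(u_e)

        deltas = list(itertools.product((-1, 0, 1), repeat=n_G))
        for t in range(2):
            # class rates and per-gene delta laws: dict delta -> prob array (n, n_G)
            classes = [
                # agreement position, any letter: M -> M-1
                (Mf * params.r_TF * mu, -1, {
                    +1: q,
                    -1: (1.0 - q) / 3.0,
                    0: 2.0 * (1.0 - q) / 3.0,
                }),
                # disagreement position, new letter = other consensus: M -> M+1
                (Lm * params.r_TF * mu / 3.0, +1, {
                    +1: u_match[t],
                    -1: u_other[t],
                    0: u_e[t],
                }),
                # disagreement position, new letter neither consensus: M fixed
                (Lm * 2.0 * params.r_TF * mu / 3.0, 0, {
                    +1: u_match[t],
                    -1: u_e[t] / 2.0,
                    0: u_other[t] + u_e[t] / 2.0,
                }),
            ]
            for class_rate, dM, law in classes:
                for dvec in deltas:
                    if dM == 0 and all(d == 0 for d in dvec):
                        continue  # self loop
                    prob = np.ones(n)
                    for j, d in enumerate(dvec):
                        prob = prob * law[d][:, j]
                    rate = class_rate * prob
                    kt = k.copy()
                    kt[:, t, :] += np.array(dvec)
                    push(all_src, M + dM, kt, sigma, rate)

    src = np.concatenate(srcs)
    dst = np.concatenate(dsts)
    rate = np.concatenate(rates)
    return src, dst, rate


def build_chain(params: ModelParams, space: StateSpace | None = None) -> ChainModel:
    """Assemble the origin-fixation generator over the reduced-genotype space."""
    if space is None:
        space = enumerate_states(params)
    F = thermo.fitness_array(space, params)
    labels = thermo.classify_states(space, params)
    src, dst, mu_rate = _mutation_moves(space, params)

    n = len(space)
    phi = fixation_probability(F[dst] - F[src], params.N)
    rate = 2.0 * params.N * mu_rate * phi

    mu_mat = sps.coo_matrix((mu_rate, (src, dst)), shape=(n, n)).tocsr()
    Q = sps.coo_matrix((rate, (src, dst)), shape=(n, n)).tocsr()
    Q = Q - sps.diags(np.asarray(Q.sum(axis=1)).ravel())
    return ChainModel(params=params, space=space, Q=Q.tocsr(),
                      mu_matrix=mu_mat, F=F, labels=labels)


# ---------------------------------------------------------------------------
# steady state


def steady_state(chain: ChainModel, method: str = "closed_form") -> np.ndarray:
    """Stationary distribution over reduced genotypes.

    ``closed_form``: P_SS proportional to P0 * exp(2N*F) (mutation-selection-
    drift balance).  ``null_space``: left null vector of the generator,
    solved sparsely; with Kimura fixation this equals P0 * exp(2(N-1)*F), so
    the two agree up to O(1/N) in the exponent.
    """
    if method == "closed_form":
        logw = chain.space.log_weight + 2.0 * chain.params.N * chain.F
        w = np.exp(logw - logw.max())
        return w / w.sum()
    if method != "null_space":
        raise ValueError("method must be 'closed_form' or 'null_space'")

    n = chain.n_states
    ncomp, _ = csgraph.connected_components(chain.Q, directed=True,
                                            connection="strong")
    if ncomp != 1:
        raise ValueError(f"chain is reducible ({ncomp} strongly connected components)")
    # fix pi at a reference state and solve the remaining balance equations:
    # Q^T pi = 0, pi_ref = 1  =>  Q^T[-ref, -ref] x = -Q^T[-ref, ref]
    ref = int(np.argmax(chain.space.log_weight + 2.0 * chain.params.N * chain.F))
    keep = np.ones(n, dtype=bool)
    keep[ref] = False
    QT = chain.Q.T.tocsr()
    A = QT[keep][:, keep].tocsc()
    b = -np.asarray(QT[keep][:, [ref]].todense()).ravel()
    if n <= 5000:
        x = spla.spsolve(A, b)
    else:
        ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=15)
        M = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.gmres(A, b, M=M, rtol=1e-12, maxiter=500, restart=50)
        if info != 0:
            x = spla.spsolve(A, b)
    pi = np.empty(n)
    pi[keep] = x
    pi[ref] = 1.0
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    resid = np.abs(QT @ pi).max() / np.abs(chain.Q.data).max()
    if resid > 1e-8:
        raise RuntimeError(f"null-space solve did not converge (residual {resid:g})")
    return pi


# ---------------------------------------------------------------------------
# dynamics


def propagate(
    chain: ChainModel,
    P_init: np.ndarray,
    T: float,
    method: str = "uniformization",
    times: np.ndarray | None = None,
    max_step_mass: float = 0.1,
):
    """Evolve a distribution for time ``T`` (in generations).

    ``euler`` applies the per-generation update P <- P + t_g * R P, with
    automatic substepping when the largest per-step exit probability exceeds
    ``max_step_mass``; ``uniformization`` computes the exact matrix
    exponential action via the Poissonised jump chain.  If ``times`` is
    given, returns the distribution at each requested time (shape
    (len(times), n)); otherwise returns the final distribution.
    """
    P = np.asarray(P_init, dtype=float).copy()
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("P_init must be normalised")
    t_g = chain.params.t_g
    Qt = chain.Q.T.tocsr()
    checkpoints = np.atleast_1d(times if times is not None else [T]).astype(float)
    if (np.diff(checkpoints) < 0).any() or checkpoints[0] < 0:
        raise ValueError("times must be nondecreasing and nonnegative")
    out = np.empty((len(checkpoints), len(P)))

    if method == "euler":
        lam = float(-chain.Q.diagonal().min())
        sub = max(1, int(np.ceil(lam * t_g / max_step_mass)))
        dt = t_g / sub
        t = 0.0
        for i, tc in enumerate(checkpoints):
            nsteps = int(round((tc - t) / dt))
            for _ in range(nsteps):
                P = P + dt * (Qt @ P)
            t += nsteps * dt
            out[i] = P
        return out if times is not None else out[-1]

    if method != "uniformization":
        raise ValueError("method must be 'euler' or 'uniformization'")

    lam = float(-chain.Q.diagonal().min()) * 1.0001 + 1e-300
    B = sps.eye(chain.n_states, format="csr") + Qt / lam
    from scipy.stats import poisson

    t = 0.0
    for i, tc in enumerate(checkpoints):
        dt = tc - t
        if dt > 0:
            mean = lam * dt
            kmax = int(poisson.ppf(1.0 - 1e-12, mean)) + 1
            weights = poisson.pmf(np.arange(kmax + 1), mean)
            acc = weights[0] * P
            v = P
            for kk in range(1, kmax + 1):
                v = B @ v
                acc = acc + weights[kk] * v
            P = acc / acc.sum()
        t = tc
        out[i] = P
    return out if times is not None else out[-1]


# ---------------------------------------------------------------------------
# hitting and dwell times


@dataclass
class HittingTimeResult:
    """Mean first hitting times to a target set, per state, in generations."""

    target_mask: np.ndarray
    times: np.ndarray

    def in_mu_units(self, params: ModelParams) -> np.ndarray:
        return self.times * params.mu


def hitting_time(chain: ChainModel, target_mask: np.ndarray) -> HittingTimeResult:
    """Mean first hitting time from every state to the target set.

    Solves the linear system -Q~ T = 1 on the non-target states (the exact
    continuous-time version of the one-generation recursion
    T = t_g + A^T T); T = 0 on the target.  Errors if some state cannot
    reach the target.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if not target_mask.any():
        raise ValueError("target set is empty")
    T = np.zeros(chain.n_states)
    rest = ~target_mask
    if rest.any():
        # reachability: in the reversed graph, every non-target state must be
        # reachable from the target set
        reach = csgraph.breadth_first_order(
            chain.Q.T, i_start=int(np.flatnonzero(target_mask)[0]),
            return_predecessors=False)
        reachable = np.zeros(chain.n_states, dtype=bool)
        reachable[reach] = True
        for i0 in np.flatnonzero(target_mask)[1:]:
            if reachable.all():
                break
            more = csgraph.breadth_first_order(chain.Q.T, i_start=int(i0),
                                               return_predecessors=False)
            reachable[more] = True
        bad = np.flatnonzero(rest & ~reachable)
        if len(bad):
            raise ValueError(
                f"target unreachable from {len(bad)} states, e.g. indices {bad[:5]}")
        Qrr = (-chain.Q[rest][:, rest]).tocsr()
        rhs = np.ones(int(rest.sum()))
        T[rest] = _solve_absorbing(chain, Qrr, rest, rhs)
    return HittingTimeResult(target_mask=target_mask, times=T)


def _solve_absorbing(chain: ChainModel, A: sps.csr_matrix, rest: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """Solve A x = b for an absorbing-chain system A = -Q[rest, rest].

    The lumped origin-fixation chain is exactly reversible with respect to
    P0 * exp(2(N-1) F): the class-averaged mutation rates inherit detailed
    balance from the symmetric microscopic rates, and the Kimura ratio
    Phi(dF)/Phi(-dF) = exp(2(N-1) dF) supplies the selective tilt.  The
    similarity transform by those weights therefore symmetrises A, and a
    Jacobi-scaled conjugate-gradient solve converges in tens of iterations.
    The residual of the *original* system is always verified; on failure
    (or for small systems) a direct sparse LU solve is used.
    """
    n = A.shape[0]
    if n <= 3000:
        return spla.spsolve(A.tocsc(), b)
    logpi = chain.space.log_weight + 2.0 * (chain.params.N - 1) * chain.F
    w = np.exp(logpi[rest] - logpi[rest].max())
    S = sps.diags(w) @ A  # symmetric positive definite under reversibility
    d = S.diagonal()
    if (d <= 0).any():
        return spla.spsolve(A.tocsc(), b)
    Dinv = sps.diags(1.0 / np.sqrt(d))
    Ss = (Dinv @ S @ Dinv).tocsr()
    bs = Dinv @ (w * b)
    z, info = spla.cg(Ss, bs, rtol=1e-14, maxiter=10_000)
    x = Dinv @ z
    scale = np.abs(b).max()
    if info == 0 and np.abs(A @ x - b).max() <= 1e-7 * scale:
        return x
    ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=15)
    M = spla.LinearOperator(A.shape, ilu.solve)
    x, info = spla.gmres(A, b, M=M, rtol=1e-12, maxiter=500, restart=50)
    if info != 0 or np.abs(A @ x - b).max() > 1e-7 * scale:
        x = spla.spsolve(A.tocsc(), b)
    return x


def dwell_time(
    chain: ChainModel,
    z: str,
    weighting: str = "steady_state",
    P_ss: np.ndarray | None = None,
) -> float:
    """Mean residence time of macrostate ``z``: the mean first hitting time
    from its genotypes to any other macrostate, averaged with steady-state-
    conditional (default) or uniform weights.  Returns generations; multiply
    by mu for 1/mu units.  Infinite if ``z`` is the whole space."""
    in_z = chain.labels == z
    if not in_z.any():
        raise ValueError(f"macrostate {z!r} is empty")
    if in_z.all():
        return float("inf")
    res = hitting_time(chain, target_mask=~in_z)
    if weighting == "uniform":
        w = in_z.astype(float)
    elif weighting == "steady_state":
        if P_ss is None:
            P_ss = steady_state(chain)
        w = np.where(in_z, P_ss, 0.0)
    else:
        raise ValueError("weighting must be 'steady_state' or 'uniform'")
    w = w / w.sum()
    return float(np.sum(w * res.times))


# ---------------------------------------------------------------------------
# macrostate maps


def macrostate_probabilities(
    space: StateSpace, params: ModelParams,
    P: np.ndarray, labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Aggregate a distribution over states into macrostate probabilities."""
    if labels is None:
        labels = thermo.classify_states(space, params)
    return {z: float(P[labels == z].sum()) for z in thermo.MACROSTATES}


def dominant_macrostate_map(
    params: ModelParams,
    Ns_values: np.ndarray,
    rho_values: np.ndarray,
    f_values: np.ndarray | None = None,
    space: StateSpace | None = None,
) -> np.ndarray:
    """Most probable steady-state macrostate on a parameter grid.

    With ``f_values`` None the grid is (Ns, rho) at the params' frequencies;
    otherwise it is (f, rho) at fixed Ns (``Ns_values`` must then have length
    one) with f1 = f2 = f.  Infeasible (f, rho) cells are labelled
    "Impossible".  Uses the closed-form steady state, so the sweep over Ns is
    a pure reweighting.
    """
    from .params import InfeasibleSignalStatistics

    if space is None:
        space = enumerate_states(params)
    labels = thermo.classify_states(space, params)
    codes = np.array([thermo.MACROSTATES.index(z) for z in labels])
    n_codes = len(thermo.MACROSTATES)
    logw0 = space.log_weight

    outer = f_values if f_values is not None else [None]
    grid = np.empty((len(outer), len(rho_values), len(Ns_values)), dtype=object)
    for a, f in enumerate(outer):
        for b, rho in enumerate(rho_values):
            try:
                p_env = params.replace(rho=float(rho)) if f is None else \
                    params.replace(f1=float(f), f2=float(f), rho=float(rho))
            except InfeasibleSignalStatistics:
                grid[a, b, :] = "Impossible"
                continue
            loss = thermo.loss_array(space, p_env)
            for c, Ns in enumerate(Ns_values):
                logw = logw0 - 2.0 * float(Ns) * loss
                w = np.exp(logw - logw.max())
                agg = np.bincount(codes, weights=w, minlength=n_codes)
                grid[a, b, c] = thermo.MACROSTATES[int(agg.argmax())]
    if f_values is None:
        return grid[0]  # (rho, Ns)
    return grid[:, :, 0] if len(Ns_values) == 1 else grid
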