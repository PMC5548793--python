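"""Explicit-sequence origin-fixation simulator.

Unlike the lumped chain, this engine tracks the actual consensus sequences,
binding sites and sensing alleles, proposing every possible single mutation
with its microscopic rate and accepting through the Kimura fixation
probability.  It serves two purposes: an independent oracle for the lumped
dynamics (its reduced projection must reproduce the class-averaged chain),
and the host for the promiscuity-promoting-mutation extension and the
multi-gene (n_G > 2) experiments, whose lumped bookkeeping would be
intractable.

Promiscuity-promoting mutations make one consensus position insensitive to
the corresponding base ('promiscuous'); the effective mismatch then counts
only the remaining specific positions.  A promiscuous position regains
specificity by a back mutation whose new preferred letter is drawn uniformly
from the four bases (or restores the stored letter, by configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import fixation_probability
from .gillespie import Trajectory
from .params import ENVIRONMENTS, ModelParams
from .thermo import _classify

__all__ = [
    "ExplicitGenotype",
    "initial_explicit_genotype",
    "effective_mismatch_matrix",
    "simulate_full_sequences",
]


@dataclass
class ExplicitGenotype:
    """Explicit sequences: consensus (2, L), sites (n_G, L), sensing alleles
    (2,), and the per-position promiscuity mask (2, L); letters are 0..3."""

    cons: np.ndarray
    sites: np.ndarray
    sigma: np.ndarray
    promiscuous: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.cons = np.asarray(self.cons, dtype=np.int8)
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=np.int8))
        self.sigma = np.asarray(self.sigma, dtype=np.int8)
        if self.promiscuous is None:
            self.promiscuous = np.zeros_like(self.cons, dtype=bool)
        self.promiscuous = np.asarray(self.promiscuous, dtype=bool)
        if self.cons.shape != self.promiscuous.shape or self.cons.shape[0] != 2:
            raise ValueError("consensus and mask must both have shape (2, L)")
        if self.sites.shape[1] != self.cons.shape[1]:
            raise ValueError("sites and consensus must have equal length")

    @property
    def L(self) -> int:
        return self.cons.shape[1]

    @property
    def n_G(self) -> int:
        return self.sites.shape[0]

    def copy(self) -> "ExplicitGenotype":
        return ExplicitGenotype(self.cons.copy(), self.sites.copy(),
                                self.sigma.copy(), self.promiscuous.copy())

    @property
    def M(self) -> int:
        """Raw consensus-consensus match count (mask-independent)."""
        return int((self.cons[0] == self.cons[1]).sum())


def initial_explicit_genotype(params: ModelParams) -> ExplicitGenotype:
    """Post-duplication start: identical all-zero consensus sequences
    perfectly matching every site, sigma = (11, 11), fully specific."""
    L, n_G = params.L, params.n_G
    return ExplicitGenotype(
        cons=np.zeros((2, L), dtype=np.int8),
        sites=np.zeros((n_G, L), dtype=np.int8),
        sigma=np.array([0b11, 0b11], dtype=np.int8),
    )


def effective_mismatch_matrix(g: ExplicitGenotype) -> np.ndarray:
    """Mismatches k_ij counting only specific positions, shape (2, n_G)."""
    spec = ~g.promiscuous  # (2, L)
    mis = g.sites[None, :, :] != g.cons[:, None, :]  # (2, n_G, L)
    return (mis & spec[:, None, :]).sum(axis=2).astype(np.int64)


def _loss_many(k: np.ndarray, act: np.ndarray, params: ModelParams,
               alpha: np.ndarray, beta: np.ndarray, pstar: np.ndarray) -> np.ndarray:
    """Vectorised expression loss for a batch of (k, activity) candidates.

    ``k``: (P, 2, n_G); ``act``: (P, 2, 4) active-TF indicators.
    """
    E = np.exp(-params.eps * k)
    x = params.C0 * np.einsum("pim,pij->pjm", act, E)
    p = x / (1.0 + x)
    if params.mode == "repressor":
        p = 1.0 - p
    resid = (p - pstar[None]) ** 2
    return np.einsum("pjm,jm,m->p", resid, beta, alpha)


def _activity(sigma: np.ndarray) -> np.ndarray:
    """(..., 2) sigma -> (..., 2, 4) activity indicators."""
    env = np.array(ENVIRONMENTS, dtype=np.int8)
    return ((sigma[..., :, None] & env) != 0).astype(float)


def simulate_full_sequences(
    params: ModelParams,
    start: ExplicitGenotype | None = None,
    horizon: float = 1e7,
    rng: np.random.Generator | int | None = None,
    stop_at: str | None = None,
    promiscuity_revert: str = "uniform",
    max_events: int = 10_000_000,
) -> Trajectory:
    """Gillespie simulation of the substitution process on explicit sequences.

    Every single mutation (site / consensus point mutations, sensing flips,
    and promiscuity toggles when ``params.r_P > 0``) is proposed at its
    microscopic rate and fixed with probability Phi(dF); event times are
    exact.  Returns the induced reduced-genotype :class:`Trajectory`
    (times, macrostate labels, fitness, TF-TF match M).  With ``r_P = 0``
    the proposal catalog contains no promiscuity moves, so the extension
    reduces bit-for-bit to the base model under the same seed.
    """
    rng = np.random.default_rng(rng)
    g = (initial_explicit_genotype(params) if start is None else start).copy()
    L, n_G = g.L, g.n_G
    if n_G != params.n_G or L != params.L:
        raise ValueError("genotype dimensions disagree with params")
    if promiscuity_revert not in ("uniform", "stored"):
        raise ValueError("promiscuity_revert must be 'uniform' or 'stored'")

    alpha = params.env.as_array
    beta = params.weight_profile()
    pstar = params.ideal_profile()
    kstrong = params.k_strong

    def label_of(k_eff, sigma) -> str:
        return _classify(k_eff < kstrong, sigma, n_G)

    k_eff = effective_mismatch_matrix(g)
    loss_cur = float(_loss_many(k_eff[None].astype(float),
                                _activity(g.sigma[None]), params,
                                alpha, beta, pstar)[0])

    t = 0.0
    times = [0.0]
    Ms = [g.M]
    Fs = [-params.s * loss_cur]
    labels = [label_of(k_eff, g.sigma)]
    dFs: list[float] = []
    reached_horizon = False

    mu = params.mu
    for _ in range(max_events):
        if stop_at is not None and labels[-1] == stop_at:
            break

        fams = []  # (family, data, mu_rate, k_new, sigma_new)
        # --- binding-site point mutations (rate mu/3 each) ----------------
        J, Pp, Dl = np.meshgrid(np.arange(n_G), np.arange(L),
                                np.arange(1, 4), indexing="ij")
        J, Pp, Dl = J.ravel(), Pp.ravel(), Dl.ravel()
        s_cur = g.sites[J, Pp]
        Lt = (s_cur + Dl) % 4
        spec = (~g.promiscuous)[:, Pp]  # (2, n)
        dk = spec * ((Lt[None] != g.cons[:, Pp]).astype(np.int64)
                     - (s_cur[None] != g.cons[:, Pp]).astype(np.int64))
        kn = np.repeat(k_eff[None], len(J), axis=0)
        kn[np.arange(len(J)), :, J] += dk.T
        fams.append(("site", (J, Pp, Lt), np.full(len(J), mu / 3.0), kn, None, None))

        # --- consensus point mutations (rate r_TF*mu/3 each) --------------
        if params.r_TF > 0:
            I, Pp2, Dl2 = np.meshgrid(np.arange(2), np.arange(L),
                                      np.arange(1, 4), indexing="ij")
            I, Pp2, Dl2 = I.ravel(), Pp2.ravel(), Dl2.ravel()
            c_cur = g.cons[I, Pp2]
            Lt2 = (c_cur + Dl2) % 4
            spec2 = (~g.promiscuous)[I, Pp2]  # (n,)
            dk2 = spec2[None] * ((g.sites[:, Pp2] != Lt2[None]).astype(np.int64)
                                 - (g.sites[:, Pp2] != c_cur[None]).astype(np.int64))
            kn2 = np.repeat(k_eff[None], len(I), axis=0)
            kn2[np.arange(len(I)), I, :] += dk2.T
            fams.append(("cons", (I, Pp2, Lt2),
                         np.full(len(I), params.r_TF * mu / 3.0), kn2, None, None))

        # --- sensing-allele bit flips (rate r_S*mu each) -------------------
        if params.r_S > 0:
            sig_new = []
            flips = []
            for i in range(2):
                for bit in (0b01, 0b10):
                    sn = g.sigma.copy()
                    sn[i] ^= bit
                    sig_new.append(sn)
                    flips.append((i, bit))
            sig_new = np.array(sig_new)
            kn3 = np.repeat(k_eff[None], len(sig_new), axis=0)
            fams.append(("sense", flips, np.full(len(sig_new), params.r_S * mu),
                         kn3, sig_new, None))

        # --- promiscuity toggles ------------------------------------------
        if params.r_P > 0:
            gi, gp = np.nonzero(~g.promiscuous)
            if len(gi):
                dkg = -(g.sites[:, gp] != g.cons[gi, gp][None]).astype(np.int64)
                kg = np.repeat(k_eff[None], len(gi), axis=0)
                kg[np.arange(len(gi)), gi, :] += dkg.T
                fams.append(("prom_gain", (gi, gp),
                             np.full(len(gi), params.r_P * mu), kg, None, None))
            ri, rp = np.nonzero(g.promiscuous)
            if len(ri):
                if promiscuity_revert == "stored":
                    Lt3 = g.cons[ri, rp]
                    rr = np.full(len(ri), params.r_P * mu)
                else:
                    ri = np.repeat(ri, 4); rp = np.repeat(rp, 4)
                    Lt3 = np.tile(np.arange(4, dtype=np.int8), len(ri) // 4)
                    rr = np.full(len(ri), params.r_P * mu / 4.0)
                dkr = (g.sites[:, rp] != Lt3[None]).astype(np.int64)
                kr = np.repeat(k_eff[None], len(ri), axis=0)
                kr[np.arange(len(ri)), ri, :] += dkr.T
                fams.append(("prom_revert", (ri, rp, Lt3), rr, kr, None, None))

        # --- rates -------------------------------------------------------
        k_all = np.concatenate([f[3] for f in fams]).astype(float)
        n_all = len(k_all)
        act_all = np.repeat(_activity(g.sigma[None]), n_all, axis=0)
        ofs = 0
        for f in fams:
            if f[4] is not None:
                act_all[ofs:ofs + len(f[4])] = _activity(f[4])
            ofs += len(f[3])
        loss_all = _loss_many(k_all, act_all, params, alpha, beta, pstar)
        dF_all = -params.s * (loss_all - loss_cur)
        rates = (2.0 * params.N * np.concatenate([f[2] for f in fams])
                 * fixation_probability(dF_all, params.N))
        total = float(rates.sum())
        if total <= 0:
            reached_horizon = True
            t = horizon
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > horizon:
            reached_horizon = True
            t = horizon
            break
        t += dt
        pick = int(rng.choice(n_all, p=rates / total))

        # --- apply --------------------------------------------------------
        ofs = 0
        for fam, data, _, kn_f, sig_f, _ in fams:
            if pick < ofs + len(kn_f):
                loc = pick - ofs
                if fam == "site":
                    J, Pp, Lt = data
                    g.sites[J[loc], Pp[loc]] = Lt[loc]
                elif fam == "cons":
                    I, Pp2, Lt2 = data
                    g.cons[I[loc], Pp2[loc]] = Lt2[loc]
                elif fam == "sense":
                    i, bit = data[loc]
                    g.sigma[i] ^= bit
                elif fam == "prom_gain":
                    gi, gp = data
                    g.promiscuous[gi[loc], gp[loc]] = True
                elif fam == "prom_revert":
                    ri, rp, Lt3 = data
                    g.promiscuous[ri[loc], rp[loc]] = False
                    g.cons[ri[loc], rp[loc]] = Lt3[loc]
                break
            ofs += len(kn_f)

        k_eff = np.asarray(np.rint(k_all[pick]), dtype=np.int64)
        loss_cur = float(loss_all[pick])
        dFs.append(float(dF_all[pick]))
        times.append(t)
        Ms.append(g.M)
        Fs.append(-params.s * loss_cur)
        labels.append(label_of(k_eff, g.sigma))
    else:
        raise RuntimeError(f"exceeded {max_events} substitutions before horizon")

    traj = Trajectory(
        times=np.array(times),
        states=np.full(len(times), -1, dtype=np.int64),
        labels=np.array(labels, dtype=object),
        dF=np.array(dFs),
        M=np.array(Ms),
        F=np.array(Fs),
        horizon=horizon,
        reached_horizon=reached_horizon,
    )
    traj.final_genotype = g  # end state, for chained runs and audits
    return traj
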