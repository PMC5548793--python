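"""Thermodynamic occupancy, fitness, binding phenotypes and macrostates.

The occupancy of a gene's binding site by any active TF follows the
two-state thermodynamic model

    p = sum_i C_i e^(-eps*k_i) / (1 + sum_i C_i e^(-eps*k_i)),

and fitness penalises squared deviations of expression from the ideal
signal-matched pattern, weighted by environment probabilities alpha_m and
error weights beta_jm:

    F = -s * sum_jm alpha_m beta_jm (p_jm - p*_jm)^2 .

Because occupancy is sigmoidal in the mismatch k, every TF-gene interaction
can be called 'strong' (single-TF occupancy above 1/2) or 'weak', and the
pattern of strong bonds plus the sensing alleles classifies every genotype
into one of six coarse network phenotypes (macrostates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import combinatorics
from .params import ENVIRONMENTS, ModelParams, SIGNAL_1, SIGNAL_2, gene_signal

__all__ = [
    "MACROSTATES",
    "ReducedGenotype",
    "binding_probability",
    "expression_profile",
    "fitness",
    "binding_phenotypes",
    "classify_macrostate",
    "free_fitness",
    "loss_profile",
    "expression_profiles_array",
    "loss_array",
    "fitness_array",
    "classify_states",
    "macrostate_free_fitness",
]

#: Canonical macrostate labels, in classification precedence order.
MACROSTATES = (
    "SpecializeBoth",
    "SpecializeBinding",
    "Initial",
    "OneTFLost",
    "NoRegulation",
    "Partial",
)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ReducedGenotype:
    """Lumped genotype {M, k_ij, sigma_i}.

    ``k`` has shape (2, n_G); ``sigma`` is a pair of 2-bit sensing alleles.
    """

    M: int
    k: tuple
    sigma: tuple

    def __post_init__(self) -> None:
        k = self.k_array
        object.__setattr__(self, "k", tuple(map(tuple, k.tolist())))
        if len(self.sigma) != 2:
            raise ValueError("sigma must have one allele per TF")

    @property
    def k_array(self) -> np.ndarray:
        k = np.asarray(self.k, dtype=int)
        if k.ndim != 2 or k.shape[0] != 2:
            raise ValueError("k must have shape (2, n_G)")
        return k

    @property
    def n_G(self) -> int:
        return self.k_array.shape[1]

    def is_feasible(self, L: int) -> bool:
        return combinatorics.neutral_weight(self.M, self.k_array, L) > 0

    def validate(self, L: int) -> "ReducedGenotype":
        if not self.is_feasible(L):
            raise combinatorics.InfeasibleGenotype(
                f"no sequences realise M={self.M}, k={self.k} at L={L}"
            )
        return self


def initial_genotype(params: ModelParams) -> ReducedGenotype:
    """The state right after duplication: identical TFs perfectly matching
    every site, both responsive to both signals."""
    k = np.zeros((2, params.n_G), dtype=int)
    return ReducedGenotype(params.L, tuple(map(tuple, k.tolist())), (0b11, 0b11))


# ---------------------------------------------------------------------------
# occupancy and fitness


def binding_probability(k_row, C_row, eps: float) -> float:
    """Occupancy of one site by any active TF (two-state thermodynamics)."""
    k_row = np.asarray(k_row, dtype=float)
    C_row = np.asarray(C_row, dtype=float)
    x = float(np.sum(C_row * np.exp(-eps * k_row)))
    return x / (1.0 + x)


def expression_profile(g: ReducedGenotype, params: ModelParams) -> np.ndarray:
    """Expression p_jm for all genes and environments, shape (n_G, 4).

    In activator mode expression equals occupancy; in repressor mode a gene
    is on unless bound, so expression = 1 - occupancy.
    """
    k = g.k_array
    E = np.exp(-params.eps * k)  # (2, n_G)
    act = np.array(
        [[1.0 if (s & m) else 0.0 for m in ENVIRONMENTS] for s in g.sigma]
    )  # (2, 4)
    x = params.C0 * np.einsum("im,ij->jm", act, E)
    p = x / (1.0 + x)
    if params.mode == "repressor":
        p = 1.0 - p
    return p


def loss_profile(g: ReducedGenotype, params: ModelParams) -> float:
    """Selection-independent expression loss sum_jm alpha_m beta_jm (p-p*)^2."""
    p = expression_profile(g, params)
    alpha = params.env.as_array
    return float(
        np.sum(alpha[None, :] * params.weight_profile() * (p - params.ideal_profile()) ** 2)
    )


def fitness(g: ReducedGenotype, params: ModelParams) -> float:
    """Fitness F <= 0; 0 iff expression is ideal wherever alpha*beta > 0."""
    return -params.s * loss_profile(g, params)


def binding_phenotypes(g: ReducedGenotype, params: ModelParams) -> np.ndarray:
    """Strong/weak call per TF-gene interaction, shape (2, n_G) bool.

    Strong means the single TF at concentration C0 would occupy the site with
    probability > 1/2, i.e. k_ij < ln(C0)/eps.  The call depends on k_ij
    alone, not on the environment or the other TF.
    """
    return g.k_array < params.k_strong


# ---------------------------------------------------------------------------
# macrostates


def _group_mask(n_G: int) -> np.ndarray:
    """Boolean (2, n_G): row g is the indicator of signal-group g's genes."""
    sig = np.array([gene_signal(j, n_G) for j in range(n_G)])
    return np.stack([sig == SIGNAL_1, sig == SIGNAL_2])


def classify_macrostate(g: ReducedGenotype, params: ModelParams) -> str:
    """Assign the genotype to exactly one macrostate label.

    Rules are evaluated in precedence order (first match wins):

    1. SpecializeBoth — the strong matrix is a permutation matching each TF
       to one full gene group with no cross-binding, and each TF senses
       exactly its bound group's signal.
    2. SpecializeBinding — strong matrix is such a permutation and both TFs
       still sense something (sigma != 00), but sensing is not matched.
    3. Initial — every interaction strong and both TFs sense both signals.
    4. OneTFLost — one TF strongly binds every gene and senses something;
       the other TF binds nothing (its sensing is unconstrained).
    5. NoRegulation — no gene receives a strong bond from a signal-responsive
       TF.
    6. Partial — everything else.
    """
    strong = binding_phenotypes(g, params)
    return _classify(strong, np.asarray(g.sigma), params.n_G)


def _classify(strong: np.ndarray, sigma: np.ndarray, n_G: int) -> str:
    groups = _group_mask(n_G)
    signals = (SIGNAL_1, SIGNAL_2)
    # permutation assignments TF->group: (0,1) or (1,0)
    for assign in ((0, 1), (1, 0)):
        if all(np.array_equal(strong[i], groups[assign[i]]) for i in range(2)):
            if all(sigma[i] == signals[assign[i]] for i in range(2)):
                return "SpecializeBoth"
            if sigma[0] != 0 and sigma[1] != 0:
                return "SpecializeBinding"
    if strong.all() and sigma[0] == 0b11 and sigma[1] == 0b11:
        return "Initial"
    for i in (0, 1):
        if strong[i].all() and sigma[i] != 0 and not strong[1 - i].any():
            return "OneTFLost"
    if not (strong & (sigma[:, None] != 0)).any():
        return "NoRegulation"
    return "Partial"


# ---------------------------------------------------------------------------
# vectorised versions over an enumerated state space


def expression_profiles_array(space, params: ModelParams) -> np.ndarray:
    """Expression p_jm for every enumerated state, shape (n, n_G, 4)."""
    E = np.exp(-params.eps * space.k.astype(float))  # (n, 2, n_G)
    env = np.array(ENVIRONMENTS)
    act = (space.sigma[:, :, None] & env[None, None, :]) != 0  # (n, 2, 4)
    x = params.C0 * np.einsum("nim,nij->njm", act.astype(float), E)
    p = x / (1.0 + x)
    if params.mode == "repressor":
        p = 1.0 - p
    return p


def loss_array(space, params: ModelParams) -> np.ndarray:
    """Expression loss per state (fitness = -s * loss); shape (n,)."""
    p = expression_profiles_array(space, params)
    alpha = params.env.as_array
    resid = (p - params.ideal_profile()[None]) ** 2
    return np.einsum("njm,jm,m->n", resid, params.weight_profile(), alpha)


def fitness_array(space, params: ModelParams) -> np.ndarray:
    return -params.s * loss_array(space, params)


def classify_states(space, params: ModelParams) -> np.ndarray:
    """Macrostate label per enumerated state (vectorised)."""
    n, n_G = len(space), params.n_G
    strong = space.k < params.k_strong  # (n, 2, n_G)
    sigma = space.sigma
    groups = _group_mask(n_G)
    signals = (SIGNAL_1, SIGNAL_2)

    perm = np.zeros(n, dtype=bool)
    sigma_matched = np.zeros(n, dtype=bool)
    for assign in ((0, 1), (1, 0)):
        match = np.ones(n, dtype=bool)
        for i in range(2):
            match &= (strong[:, i, :] == groups[assign[i]][None, :]).all(axis=1)
        perm |= match
        smatch = match.copy()
        for i in range(2):
            smatch &= sigma[:, i] == signals[assign[i]]
        sigma_matched |= smatch

    responsive = sigma != 0  # (n, 2)
    spec_both = sigma_matched
    spec_bind = perm & responsive.all(axis=1) & ~spec_both
    initial = strong.all(axis=(1, 2)) & (sigma == 0b11).all(axis=1)
    one_lost = np.zeros(n, dtype=bool)
    for i in range(2):
        one_lost |= (
            strong[:, i, :].all(axis=1)
            & responsive[:, i]
            & ~strong[:, 1 - i, :].any(axis=1)
        )
    no_reg = ~(strong & responsive[:, :, None]).any(axis=(1, 2))

    labels = np.full(n, "Partial", dtype=object)
    # reverse precedence: later assignments win
    labels[no_reg] = "NoRegulation"
    labels[one_lost] = "OneTFLost"
    labels[initial] = "Initial"
    labels[spec_bind] = "SpecializeBinding"
    labels[spec_both] = "SpecializeBoth"
    return labels


def macrostate_free_fitness(
    space, params: ModelParams, labels: np.ndarray | None = None,
    F: np.ndarray | None = None,
) -> dict[str, float]:
    """Free fitness F^(z) = (1/2N) ln sum_{G in z} P0(G) exp(2N F(G)).

    Soft-max over the macrostate's genotypes, so the steady-state weight of a
    macrostate is exactly proportional to exp(2N * F^).  Empty macrostates get
    -inf.  The Ns -> 0 limit ranks macrostates by their neutral log-counts.
    """
    if labels is None:
        labels = classify_states(space, params)
    if F is None:
        F = fitness_array(space, params)
    twoN = 2.0 * params.N
    log_p0 = space.log_weight - logsumexp(space.log_weight)
    out = {}
    for z in MACROSTATES:
        mask = labels == z
        if not mask.any():
            out[z] = NEG_INF
        else:
            out[z] = float(logsumexp(log_p0[mask] + twoN * F[mask]) / twoN)
    return out


def free_fitness(z: str, space, params: ModelParams) -> float:
    """Free fitness of a single macrostate label."""
    return macrostate_free_fitness(space, params)[z]


def macrostate_counts(space, labels: np.ndarray | None = None,
                      params: ModelParams | None = None) -> dict[str, int]:
    """Exact number of explicit genotypes in each macrostate (neutral counts,
    sensing alleles counted with multiplicity 1)."""
    if labels is None:
        labels = classify_states(space, params or space.params)
    out = {z: 0 for z in MACROSTATES}
    for w, lab in zip(space.weights, labels):
        out[lab] += w
    return out
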