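"""Model parameters, environment statistics, sensing alleles and expression targets.

The model describes two transcription factors (TFs), freshly created by a gene
duplication, that regulate ``n_G`` downstream genes through binding sites of
length ``L``.  Two external signals can each be present or absent, giving four
environments ``m in {00, 01, 10, 11}``; each TF carries a two-bit sensing
allele ``sigma`` saying which signals activate it.  Selection favours genotypes
whose genes are expressed exactly when their cognate signal is present.

Environments and sensing alleles are encoded as 2-bit integers: bit 1 (value 2)
is signal 1, bit 0 (value 1) is signal 2, so the conventional label "10"
(signal 1 on, signal 2 off) is the integer ``0b10 == 2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ENVIRONMENTS",
    "SENSING_ALLELES",
    "EnvDist",
    "ModelParams",
    "environment_distribution",
    "active_concentration",
    "gene_signal",
    "ideal_expression",
    "error_weight",
]

#: The four environments / sensing alleles, as 2-bit integers 00,01,10,11.
ENVIRONMENTS = (0b00, 0b01, 0b10, 0b11)
SENSING_ALLELES = ENVIRONMENTS

SIGNAL_1 = 0b10
SIGNAL_2 = 0b01

_ALPHA_TOL = 1e-12


class InfeasibleSignalStatistics(ValueError):
    """Raised when (f1, f2, rho) admit no valid joint signal distribution."""


@dataclass(frozen=True)
class EnvDist:
    """Joint distribution over the four environments.

    ``alpha[m]`` is the probability of environment ``m`` (2-bit encoding).
    """

    alpha: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (4,):
            raise ValueError("alpha must have four components")
        if (a < -_ALPHA_TOL).any():
            raise InfeasibleSignalStatistics(
                f"impossible signal statistics: negative probability in {a}"
            )
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"alpha must sum to 1, got {a.sum()}")

    @property
    def as_array(self) -> np.ndarray:
        return np.clip(np.asarray(self.alpha, dtype=float), 0.0, 1.0)

    @property
    def f1(self) -> float:
        return self.alpha[0b10] + self.alpha[0b11]

    @property
    def f2(self) -> float:
        return self.alpha[0b01] + self.alpha[0b11]

    @property
    def rho(self) -> float:
        """Pearson correlation of the two signal indicators."""
        f1, f2 = self.f1, self.f2
        var = f1 * (1 - f1) * f2 * (1 - f2)
        if var <= 0:
            return 0.0
        return (self.alpha[0b11] - f1 * f2) / math.sqrt(var)


def environment_distribution(f1: float, f2: float, rho: float) -> EnvDist:
    """Joint environment probabilities from marginals and signal correlation.

    ``alpha_11 = f1*f2 + rho*sqrt(f1(1-f1)f2(1-f2))``; the remaining cells are
    fixed by the marginals.  Raises :class:`InfeasibleSignalStatistics` when the
    requested combination cannot be realised by any joint distribution
    (``alpha_11`` must lie in ``[max(0, f1+f2-1), min(f1, f2)]``).
    """
    if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
        raise ValueError("signal frequencies must lie in [0, 1]")
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    a11 = f1 * f2 + rho * math.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    a10 = f1 - a11
    a01 = f2 - a11
    a00 = 1.0 - a01 - a10 - a11
    alpha = [0.0] * 4
    alpha[0b11] = a11
    alpha[0b10] = a10
    alpha[0b01] = a01
    alpha[0b00] = a00
    if min(alpha) < -_ALPHA_TOL:
        raise InfeasibleSignalStatistics(
            f"impossible signal statistics: f1={f1}, f2={f2}, rho={rho} "
            f"give alpha={alpha}"
        )
    return EnvDist(tuple(max(x, 0.0) for x in alpha))


def active_concentration(sigma: int, m: int, C0: float) -> float:
    """Active-TF concentration in environment ``m`` for sensing allele ``sigma``.

    A TF is active (at concentration ``C0``) whenever it is responsive to at
    least one signal present in ``m``; activation is binary, never additive.
    """
    return C0 if (sigma & m) else 0.0


def gene_signal(gene: int, n_G: int) -> int:
    """Signal assigned to gene ``gene`` (0-based): first half -> signal 1."""
    if not 0 <= gene < n_G:
        raise ValueError(f"gene index {gene} outside 0..{n_G - 1}")
    return SIGNAL_1 if gene < (n_G + 1) // 2 else SIGNAL_2


def ideal_expression(gene: int, m: int, n_G: int = 2) -> int:
    """Target expression: 1 iff the gene's assigned signal is present in ``m``."""
    return 1 if (gene_signal(gene, n_G) & m) else 0


def error_weight(gene: int, m: int, params: "ModelParams") -> float:
    """Penalty weight beta_jm: ``beta_on`` where the gene should be induced,
    ``beta_off`` where it should stay silent."""
    return params.beta_on if ideal_expression(gene, m, params.n_G) else params.beta_off


@dataclass(frozen=True)
class ModelParams:
    """All biophysical and evolutionary constants of the model.

    Parameters
    ----------
    L : binding-site length in base pairs.
    eps : energy per consensus/site mismatch, in units of kB*T.
    C0 : dimensionless active-TF concentration scale.  The default
        ``exp(1.5 * eps)`` saturates consensus sites (p(k=0) ~ 0.99) while
        putting the single-TF half-occupancy point at mismatch 1.5 --
        strictly between integers, so the strong/weak binding call never
        sits on a tie, and only near-consensus sites (k <= 1) count as
        strong, the convention under which the specialization phase
        boundaries are independent of the site length L.
    n_G : number of regulated genes (even); genes 0..n_G/2-1 answer to
        signal 1, the rest to signal 2.
    mu : per-position binding-site mutation rate per generation.  Kept small
        (default 1e-5) so that 2*N*mu << 1 and the population is monomorphic
        between fixations (origin-fixation regime).
    r_S, r_TF, r_P : mutation-rate ratios for sensing-allele flips, TF
        consensus changes, and promiscuity toggles (extension; 0 disables).
    N, s : population size and selection intensity; the product Ns is the
        selection strength knob of the phase diagrams.
    f1, f2, rho : marginal signal frequencies and their correlation.
    beta_on, beta_off : error weights for a gene that fails to induce vs one
        that induces spuriously.
    t_g : generation time (time unit of the per-generation update).
    mode : "activator" (expression = occupancy) or "repressor"
        (expression = 1 - occupancy).
    """

    L: int = 5
    eps: float = 3.0
    C0: float | None = None
    n_TF: int = 2
    n_G: int = 2
    mu: float = 1e-5
    r_S: float = 1.0
    r_TF: float = 1.0
    r_P: float = 0.0
    N: int = 1000
    s: float = 0.025
    f1: float = 0.5
    f2: float = 0.5
    rho: float = 0.0
    beta_on: float = 1.0
    beta_off: float = 0.5
    t_g: float = 1.0
    mode: str = "activator"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_TF != 2:
            raise ValueError("the model is defined for exactly two TFs")
        if self.n_G < 1 or (self.n_G > 1 and self.n_G % 2):
            raise ValueError("n_G must be even (n_G=1 allowed for validation)")
        if self.C0 is None:
            object.__setattr__(self, "C0", math.exp(1.5 * self.eps))
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        if self.mu <= 0 or min(self.r_S, self.r_TF, self.r_P) < 0:
            raise ValueError("mutation rates must be positive (ratios >= 0)")
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.s < 0:
            raise ValueError("selection intensity must be >= 0")
        if self.mode not in ("activator", "repressor"):
            raise ValueError("mode must be 'activator' or 'repressor'")
        # validates (f1, f2, rho) feasibility as a side effect
        environment_distribution(self.f1, self.f2, self.rho)

    # -- derived quantities -------------------------------------------------

    @property
    def Ns(self) -> float:
        return self.N * self.s

    @property
    def env(self) -> EnvDist:
        return environment_distribution(self.f1, self.f2, self.rho)

    @property
    def k_strong(self) -> float:
        """Mismatch threshold below which a single TF at C0 occupies the site
        with probability > 1/2: ``k < ln(C0)/eps``."""
        return math.log(self.C0) / self.eps

    def with_Ns(self, Ns: float) -> "ModelParams":
        """Copy with the selection strength Ns set by adjusting s at fixed N."""
        return dataclasses.replace(self, s=Ns / self.N)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def ideal_profile(self) -> np.ndarray:
        """Target expression matrix p*_jm, shape (n_G, 4)."""
        return np.array(
            [[ideal_expression(j, m, self.n_G) for m in ENVIRONMENTS]
             for j in range(self.n_G)],
            dtype=float,
        )

    def weight_profile(self) -> np.ndarray:
        """Error-weight matrix beta_jm, shape (n_G, 4)."""
        return np.array(
            [[error_weight(j, m, self) for m in ENVIRONMENTS]
             for j in range(self.n_G)],
            dtype=float,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["Ns"] = self.Ns
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        Ns = d.pop("Ns", None)
        p = cls(**d)
        if Ns is not None and abs(Ns - p.Ns) > 1e-9 * max(1.0, abs(Ns)):
            raise ValueError(f"inconsistent Ns={Ns} with N={p.N}, s={p.s}")
        return p
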