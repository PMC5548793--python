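"""Macrostate census and steady-state outcomes at baseline.

Enumerates every reduced genotype {M, k_ij, sigma_i} at L = 5, counts the
explicit sequence genotypes behind each coarse network phenotype
(macrostate), and compares the neutral census with the selection-weighted
steady state P0 * exp(2NF) and the per-macrostate free fitness.
"""

import numpy as np

from tfspec import ModelParams, enumerate_states
from tfspec import chain, thermo

p = ModelParams()
space = enumerate_states(p)
labels = thermo.classify_states(space, p)
counts = thermo.macrostate_counts(space, labels, p)
cm = chain.build_chain(p, space)
P = chain.steady_state(cm)
probs = chain.macrostate_probabilities(space, p, P, labels)
fhat = thermo.macrostate_free_fitness(space, p, labels, cm.F)

print(f"{len(space)} reduced genotypes lump {sum(counts.values()):.3g} "
      f"sequence genotypes\n")
print(f"{'macrostate':<18}{'genotypes':>12}{'P_ss(Ns=25)':>14}{'free fitness':>14}")
for z in thermo.MACROSTATES:
    print(f"{z:<18}{counts[z]:>12.3g}{probs[z]:>14.4g}{fhat[z]:>14.5f}")

ratio = counts["NoRegulation"] / counts["SpecializeBoth"]
print(f"\nentropy bias: NoRegulation outnumbers SpecializeBoth {ratio:.3g}-fold,")
print("yet at Ns=25 selection still concentrates the steady state on the")
print("fully specialized network (highest free fitness).")

# match distribution: selection leaves almost no trace in M
P0 = space.neutral_distribution()
cond = (space.sigma[:, 0] == 0b10) & (space.sigma[:, 1] == 0b01)
sel = np.where(cond, P, 0.0)
sel /= sel.sum()
m_neutral = np.bincount(space.M, weights=P0, minlength=p.L + 1)
m_sel = np.bincount(space.M, weights=sel, minlength=p.L + 1)
print("\nTF-TF match M     :", " ".join(f"{m}" for m in range(p.L + 1)))
print("neutral P(M)      :", " ".join(f"{x:.3f}" for x in m_neutral))
print("selected P(M|spec):", " ".join(f"{x:.3f}" for x in m_sel))
print("Both peak at M=1: measured TF-pair divergence barely distinguishes")
print("selection for specialization from neutral drift.")
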