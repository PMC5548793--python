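"""Thermodynamic occupancy and the fitness of the post-duplication state.

Builds the baseline model (two TFs, two genes, binding sites of length 5,
mismatch energy eps = 3 kT) and shows how site occupancy collapses with
mismatch count, where the strong/weak binding call sits, and what the
freshly duplicated genotype pays in fitness for its regulatory crosstalk.
"""

import numpy as np

from tfspec import ModelParams, binding_probability, fitness, initial_genotype
from tfspec.thermo import classify_macrostate

p = ModelParams()
print(f"baseline: L={p.L}, eps={p.eps}, C0={p.C0:.1f}, Ns={p.Ns:.0f}")
print(f"strong-binding threshold: k < ln(C0)/eps = {p.k_strong:.2f}\n")

print("single-TF occupancy vs mismatch k (strong = occupancy > 1/2):")
for k in range(p.L + 1):
    occ = binding_probability([k], [p.C0], p.eps)
    call = "strong" if k < p.k_strong else "weak"
    print(f"  k={k}: p = {occ:.4f}  ({call})")

g = initial_genotype(p)
print(f"\npost-duplication genotype: M={g.M}, k={g.k}, sigma={g.sigma}")
print(f"macrostate: {classify_macrostate(g, p)}")
print(f"fitness F = {fitness(g, p):.6f}  (N*F = {p.N * fitness(g, p):.2f})")
print("\nBoth undifferentiated TFs answer both signals, so each gene is also")
print("induced when only the wrong signal is present; the quadratic penalty")
print("on that crosstalk expression is what selection will try to remove.")
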