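"""Phase diagram of duplication outcomes over selection and signal statistics.

Sweeps selection strength Ns and signal correlation rho (closed-form steady
state, so the sweep is cheap) and prints the dominant macrostate per cell;
then sweeps signal frequency f at fixed Ns = 25.
"""

import numpy as np

from tfspec import ModelParams, enumerate_states
from tfspec.chain import dominant_macrostate_map

ABBR = {"NoRegulation": "NR", "Partial": "Pa", "OneTFLost": "1L",
        "SpecializeBoth": "SB", "SpecializeBinding": "Sb", "Initial": "In",
        "Impossible": "--"}

p = ModelParams()
space = enumerate_states(p)
Ns = np.array([0.5, 2, 5, 10, 15, 20, 25, 35, 50])
rho = np.linspace(-0.9, 0.9, 13)

grid = dominant_macrostate_map(p, Ns, rho, space=space)
print("dominant macrostate over (Ns, rho); NR=NoRegulation, Pa=Partial,")
print("1L=OneTFLost, Sb=SpecializeBinding, SB=SpecializeBoth\n")
print("rho\\Ns " + "".join(f"{n:>5g}" for n in Ns))
for i, r in enumerate(rho):
    print(f"{r:+5.2f}  " + "".join(f"{ABBR[grid[i, j]]:>5}" for j in range(len(Ns))))

print("\nWeak selection loses all regulation to mutational entropy; strong")
print("selection specializes both TFs unless the two signals are nearly")
print("redundant (rho -> 1), where keeping a single generalist TF wins.")

fs = np.linspace(0.1, 0.9, 9)
g2 = dominant_macrostate_map(p, np.array([25.0]), rho, f_values=fs, space=space)
print("\ndominant macrostate over (f, rho) at Ns=25 ('--' = impossible):\n")
print("f\\rho " + "".join(f"{r:+5.1f}" for r in rho))
for a, f in enumerate(fs):
    print(f"{f:4.1f}  " + "".join(f"{ABBR[g2[a, b]]:>5}" for b in range(len(rho))))
print("\nRare signals cannot pay for specific regulation even at Ns=25;")
print("frequent, correlated signals again favour losing one TF.")
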