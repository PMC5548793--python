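"""Promiscuity-promoting mutations with multiple regulated genes.

With four regulated genes (two per TF) the landscape becomes frustrated:
a consensus mutation hits several binding sites at once, so co-evolution
must pass through deleterious intermediates.  Promiscuity-promoting
mutations, which make one TF position insensitive to its base, relieve that
constraint.  This example measures the time to full specialization and the
fraction of deleterious fixations with and without them.
"""

from tfspec import ModelParams
from tfspec.promiscuity import multigene_experiment

p = ModelParams()
df = multigene_experiment(p, n_G_values=(2, 4), Ns_values=(25.0,),
                          promiscuity=(False, True), replicates=40,
                          horizon=50 / p.mu, seed=7)
cols = ["n_G", "Ns", "promiscuity", "tau_mean", "tau_se",
        "deleterious_fraction", "speedup"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\ntau is the mean time to full specialization in units of 1/mu.")
print("Promiscuity cuts tau several-fold and lowers the share of")
print("deleterious substitutions along the way -- most visibly at n_G=4,")
print("where without it the TF consensus is pinned by multiple sites.")
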