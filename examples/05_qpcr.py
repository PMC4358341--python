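"""Livak 2^-ddCt quantification of qPCR verification data.

Simulates a Ct table in which one candidate AMP is induced ~156-fold by
septic injury (relative to naive eggs, normalized by the RPL13a reference
gene) and recovers that fold change with the Livak method.
"""

from eggimmune import livak_table, simulate_ct

ct = simulate_ct({"TC007858": {"septic": 156.0, "sterile": 2.0}},
                 seed=8, noise_sd=0.05)
print(f"Ct table: {len(ct)} wells "
      "(2 biological x 2 technical replicates per group)")

folds = livak_table(ct, reference="RPL13a", calibrator_group="naive")
print(folds.round(2).to_string(index=False))
print("\nfold_change is 2^-ddCt vs naive eggs; the calibrator group is 1"
      " by construction, and the SE is over biological replicates")
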