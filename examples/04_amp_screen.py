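"""Screening infection-induced peptides for antimicrobial-peptide traits.

AMPs are short (<200 residues), not net-negative and often hydrophobic or
glycine-rich. The screen combines those sequence properties with at least
twofold induction after septic injury; running it on the published
Tribolium reference compilation reproduces its candidate list.
"""

from eggimmune import load_reference_table, n_new_candidates, screen_candidates
from eggimmune.amp import compute_properties

ref = load_reference_table()
known = set(ref.index[ref["known"]])
scr = screen_candidates(ref, ref["fold_wildtype"], ref["fold_control"],
                        known_amps=known)

print(f"peptides screened: {len(scr)} ({len(known)} known AMPs as reference)")
print(f"new candidate AMPs: {n_new_candidates(scr)}")

gly = scr.loc["TC009336"]
print(f"\nTC009336: net charge {gly['net_charge']:+.0f}, glycine "
      f"{gly['glycine_pct']:.0f}% -> passes via the {gly['pass_route']}")
print("a net-negative peptide is rescued only by very high glycine content")

p = compute_properties("GIGKFLKKAKKFGKAFVKILKK")  # a cecropin-like sequence
print(f"\nexample peptide properties: length {p.length}, "
      f"{p.molecular_weight * 1000:.0f} Da, charge {p.net_charge:+d}, "
      f"hydrophobic {p.hydrophobic_ratio}%")
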