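"""Evaluate the iQ/hiQ composite confidence scores at chosen inputs.

The hetero composite weights normalised pi-score 40%, ipTM_pTM 30% and
pDockQ 30%; the homo-oligomer composite weights the mean interface pi-score
60% and ipTM_pTM 40%.  Both live on a 0-100 scale with retention above 50.
"""

from ppiscorekit import compute_hiq_score, compute_iq_score

# At the constituent thresholds (pi=0.05, ipTM_pTM=0.5, pDockQ=0.5) the
# composites sit just above the retention cutoff of 50:
print(f"iQ(0.05, 0.5, 0.5)   = {compute_iq_score(0.05, 0.5, 0.5):.2f}")
print(f"hiQ([0.05], 0.5)     = {compute_hiq_score([0.05], 0.5):.2f}")

# A confidently predicted pair scores much higher:
print(f"iQ(1.0, 0.8, 0.7)    = {compute_iq_score(1.0, 0.8, 0.7):.2f}")

# A trimer whose three interfaces average a weak pi-score stays below 50:
print(f"hiQ 3 interfaces     = {compute_hiq_score([-0.4, -0.2, -0.3], 0.4):.2f}")
# Values above 50 would be retained as probable interactions; the first two
# lines show the scores exactly at the constituent score thresholds.
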