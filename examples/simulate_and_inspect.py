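"""Generate one synthetic beta protein and inspect its contact map.

The generator draws a strand topology (segments plus parallel/antiparallel
pairings), embeds the implied beta-beta contacts as Gaussian ridge bumps in
a noisy background with decoy segments, and corrupts the secondary
structure profile to the accuracy of a modern 3-state predictor.
"""

import numpy as np

from betaridge import generate_protein

p = generate_protein("demo", L=100, seed=42)

print(f"protein length L          : {p.length}")
print(f"beta strands              : {p.strands}")
for a, b, orient, off in p.pairings:
    print(f"  pairing {p.strands[a]} -- {p.strands[b]}  {orient}, register {off:+d}")
print(f"true beta-beta contacts   : {len(p.truth.contacts)}")
print(f"secondary structure       : {p.ss_truth}")

truth_mask = np.zeros((p.length, p.length), bool)
for i, j in p.truth.contacts:
    truth_mask[i, j] = truth_mask[j, i] = True
sig = p.cmap.scores[truth_mask].mean()
bg = p.cmap.scores[~truth_mask].mean()
acc = np.mean([a == b for a, b in zip(p.ss_profile.argmax_string(), p.ss_truth)])
print(f"map score at true contacts: {sig:.3f}  elsewhere: {bg:.3f}")
print(f"SS profile argmax accuracy: {acc:.2f}")
print()
print("True contacts sit on diagonal/anti-diagonal ridges a few times")
print("brighter than the noise floor -- visible but entangled with decoys,")
print("which is the regime the ridge detector and forests are built for.")
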