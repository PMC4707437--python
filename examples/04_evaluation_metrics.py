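"""Q3/Q8 accuracy vs the SOV segment-overlap score.

SOV forgives small boundary displacements but punishes predictions that break
a segment in the middle — two errors that cost the same residues can differ a
lot in segment quality.
"""

from deepcnf import q_accuracy, sov

true = "HHHHHHHHHHHHCCCC"  # one 12-residue helix, then coil

boundary_error = "HHHHHHHHHHCCCCCC"  # helix ends two residues early
broken_helix = "HHHHHCCHHHHHCCCC"  # two wrong residues in the middle

for name, pred in [("boundary error", boundary_error), ("broken helix", broken_helix)]:
    print(f"{name:15s}  Q3 = {q_accuracy(pred, true):6.2f}%   SOV = {sov(pred, true):6.2f}%")

# Both predictions get the same Q3 (2 of 16 residues wrong), but breaking the
# helix in half costs far more SOV than trimming its end: segment integrity is
# what the score measures.
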