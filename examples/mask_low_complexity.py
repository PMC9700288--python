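"""Annotate low-complexity and tandem-repeat content of sequences.

Long reads are error-prone in low-complexity DNA, so candidate novel
sequences that are mostly repeat are unreliable; the pipeline drops any
candidate with >= 80% of its bases masked.
"""

import numpy as np

from afns.mask import annotate

rng = np.random.default_rng(3)
random_part = "".join(rng.choice(list("ACGT"), 600))

cases = {
    "random_600bp": random_part,
    "polyA_300bp": "A" * 300,
    "AT_microsatellite": random_part[:100] + "AT" * 40 + random_part[100:200],
    "mostly_repeat": random_part[:150] + "CAG" * 250,
}

for name, seq in cases.items():
    ann = annotate(name, seq)
    classes = {}
    for iv, cls in ann.segments:
        classes.setdefault(cls, 0)
        classes[cls] += len(iv)
    verdict = "DROPPED" if ann.masked_fraction >= 0.8 else "kept"
    print(f"{name:20s} len={len(seq):4d}  masked={ann.masked_fraction:5.1%}"
          f"  {classes}  -> {verdict}")

# masked is the fraction of bases inside DUST windows (low_complexity) or
# tandem runs of unit 1-6 (simple_repeat); only sequences at >= 80% are
# removed from the final novel set.
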