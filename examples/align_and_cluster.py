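"""The built-in aligner and coverage clustering on a toy redundancy set.

Three error-bearing copies of the same fragment plus one unrelated
fragment: the all-vs-all overlaps link the copies (>80% coverage of the
shorter sequence), and the longest copy represents the cluster.
"""

import numpy as np

from afns.align import all_vs_all
from afns.cluster import build_clusters, representatives
from afns.io import SeqRecord

rng = np.random.default_rng(5)
bases = list("ACGT")
core = "".join(rng.choice(bases, 1500))


def noisy_copy(seq, rate):
    return "".join(
        str(rng.choice([b for b in bases if b != c])) if rng.random() < rate else c
        for c in seq
    )


fragments = [
    SeqRecord("copy_full", noisy_copy(core, 0.03)),
    SeqRecord("copy_trunc", noisy_copy(core[200:1400], 0.03)),
    SeqRecord("copy_short", noisy_copy(core[400:1300], 0.05)),
    SeqRecord("unrelated", "".join(rng.choice(bases, 1200))),
]

overlaps = all_vs_all(fragments)
print(f"{len(overlaps)} pairwise overlaps:")
for rec in overlaps:
    print(f"  {rec.query_id} vs {rec.target_id}: "
          f"identity={rec.identity:.3f} q[{rec.q_start},{rec.q_end})")

clusters = build_clusters(fragments, overlaps, cov_threshold=0.8)
for cl, rep in zip(clusters, representatives(clusters, fragments)):
    print(f"{cl.cluster_id}: members={sorted(cl.member_ids)} "
          f"representative={rep.id} ({len(rep.sequence)} bp)")

# The three copies collapse into one cluster represented by the longest
# member; the unrelated fragment stays a singleton.
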