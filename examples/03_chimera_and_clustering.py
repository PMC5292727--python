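"""De-novo chimera detection and abundance-seeded clustering on a toy set.

Two haplotypes 10% apart, a planted two-parent chimera, and a 3'-truncated
copy: the chimera is flagged (its two-parent crossover model beats any
single parent), the truncated copy joins its full-length cluster at 100%
overlap identity, and two clusters remain.
"""

import numpy as np

from ampliqc.cluster import cluster_sequences, detect_chimeras, remove_chimeras
from ampliqc.model import PreparedSequence, Stream

rng = np.random.default_rng(0)
hap_a = "".join(rng.choice(list("ACGT"), size=400))
pos = rng.choice(400, size=40, replace=False)
hap_b = "".join(
    rng.choice([x for x in "ACGT" if x != b]) if i in pos else b
    for i, b in enumerate(hap_a)
)
chimera = hap_a[:200] + hap_b[200:]

def u(seq, n):
    return PreparedSequence("sp1", "COI", seq, n, Stream.MERGED)

uniques = [u(hap_a, 30), u(hap_b, 15), u(hap_a[:-60], 5), u(chimera, 2)]
flags = detect_chimeras(uniques, min_parent_ratio=2.0, min_score=3)
print("chimera flags:", flags)          # only the planted splice

kept, _ = remove_chimeras(uniques)
clusters = cluster_sequences(kept, min_overlap=100, min_identity=0.97)
for c in clusters:
    print(f"cluster rank {c.rank}: {c.total_reads} reads, "
          f"{len(c.members)} uniques, consensus {len(c.consensus)} nt")
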