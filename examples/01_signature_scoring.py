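"""Score SNV sites and pick out the signature ones.

Builds a small three-source panel by hand: a backbone of uninformative sites
(all sources agree), one site where only the mother carries the infant's
alternative allele, and one site whose alternative allele occurs in no
source at all.  Runs the coverage filter, the two-hypothesis likelihood-
ratio scoring and the windowed selection, and prints the result.  A large
positive score means the sink's allele counts are far better explained by
one source alone than by any mixture of the others - exactly the sites
worth tracking.
"""

import numpy as np
import pandas as pd

from snvtrack import AlleleCountPanel, FilterConfig, compute_signatures

rng = np.random.default_rng(0)
n_boring = 18

positions = sorted(rng.choice(190_000, size=n_boring, replace=False) + 1) + [195_000, 198_000]
sink_ref, sink_alt = [], []
src_ref, src_alt = [], []
for _ in range(n_boring):  # all samples fixed for the reference allele
    sink_ref.append(20), sink_alt.append(0)
    src_ref.append([30, 25, 41]), src_alt.append([0, 0, 1])
# only the mother carries the infant's alternative allele
sink_ref.append(2), sink_alt.append(18)
src_ref.append([3, 28, 33]), src_alt.append([27, 0, 0])
# infant-only alternative allele: no source carries it
sink_ref.append(11), sink_alt.append(9)
src_ref.append([25, 28, 19]), src_alt.append([0, 0, 0])

panel = AlleleCountPanel(
    keys=pd.DataFrame(
        {
            "species_id": "b_longum",
            "contig_id": "b_longum_c1",
            "position": positions,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    ),
    sink_name="infant",
    source_names=["mother", "father", "neighbour"],
    sink_ref=np.array(sink_ref),
    sink_alt=np.array(sink_alt),
    source_ref=np.array(src_ref),
    source_alt=np.array(src_alt),
)

filtered, signatures, scores = compute_signatures(panel, FilterConfig(min_site_depth=10))
cols = ["position", "score", "best_source", "sink_unique"]
report = scores[cols].assign(selected=signatures.selected_mask)
print(report[report["score"] > 0].to_string(index=False))
print(f"\n{len(signatures)} of {filtered.n_sites} sites selected "
      f"({signatures.rescue_count} via the sink-unique rescue)")
print("position 195000 stands out of its 200-kb window: only the mother explains")
print("the infant's alt reads; 198000 is rescued because its alt allele occurs in")
print("no source, hinting at an unknown contributor")
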