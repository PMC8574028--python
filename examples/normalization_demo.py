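"""Median-of-ratios normalization on a hand-sized count matrix.

Sample 2 has twice the sequencing depth of sample 1; the estimated size
factors recover that 2:1 ratio and division by them equalizes the columns.
"""

import numpy as np
import pandas as pd

from overlapnet.data import CountMatrix, SampleSheet
from overlapnet.preprocess import normalize_and_average, size_factors

sheet = SampleSheet(
    pd.DataFrame(
        [
            {"sample": "s1", "genotype": "g1", "condition": "control", "replicate": 1},
            {"sample": "s2", "genotype": "g1", "condition": "treatment", "replicate": 1},
        ]
    )
)
counts = CountMatrix(
    gene_ids=["geneA", "geneB", "geneC", "geneD"],
    samples=sheet,
    values=np.array([[10, 20], [30, 60], [5, 10], [100, 200]]),
)

sf = size_factors(counts)
print(f"size factors: {np.round(sf, 4)} (ratio {sf[1]/sf[0]:.1f} recovers the 2x depth)")
d1, _ = normalize_and_average(counts, sf)
print("normalized matrix (columns now comparable):")
print(pd.DataFrame(np.round(d1.values, 2), index=counts.gene_ids, columns=["s1", "s2"]))
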