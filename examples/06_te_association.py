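"""Tail length versus translation efficiency (TE).

Genes are binned by geometric-mean tail length; log2 TE is compared between
bins with two-tailed Welch t-tests.  Under a positive tail-TE coupling the
group medians rise monotonically with tail length.
"""

import numpy as np
import pandas as pd

from tailatlas import group_and_test, simulate_te

rng = np.random.default_rng(1)
n = 3000
summaries = pd.DataFrame(
    {
        "gene": [f"g{i}" for i in range(n)],
        "geom_mean_tail_length": np.exp(rng.normal(np.log(80), 0.4, size=n)),
    }
)
te = simulate_te(summaries, slope=0.5, noise_sd=1.0, rng=rng)

grouping = group_and_test(te, summaries, n_bins=5)
print("genes per tail-length bin:", grouping.bin_counts.to_dict())
print("\nmedian log2 TE per bin (should rise with tail length):")
print(grouping.group_medians().round(3).to_string())
print("\npairwise Welch t-tests (p-values):")
print(grouping.pairwise.to_string(index=False, float_format=lambda p: f"{p:.2e}"))
# Adjacent bins separate weakly, distant bins decisively - the same pattern
# as grouping real MII-oocyte tail lengths against polysome-derived TE.
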