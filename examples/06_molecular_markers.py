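"""Find per-cluster molecular markers: one-vs-rest likelihood-ratio
logistic tests with a sex covariate and per-cluster Bonferroni correction.
"""

import numpy as np
import pandas as pd

from riskcarver.markers import de_markers, results_frame, top_markers

rng = np.random.default_rng(51)
n, p, k = 1200, 60, 8
omics = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"prot{j:02d}" for j in range(p)])
clusters = rng.integers(0, k, n)
sex = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float)})

# plant two markers: one protein up in cluster 2, one down in cluster 5
omics.loc[clusters == 2, "prot04"] += 1.5
omics.loc[clusters == 5, "prot11"] -= 1.5

results = de_markers(omics, clusters, covariates=sex)
frame = results_frame(results)
sig = frame[frame["p_adjusted"] <= 0.05].sort_values("p_adjusted")
print(f"{len(frame)} (cluster, protein) tests; "
      f"{len(sig)} significant after per-cluster Bonferroni:")
print(sig[["cluster", "feature", "coef", "p_adjusted", "direction"]]
      .round(4).to_string(index=False))

panel = top_markers(results, k=2)
print(f"\nheatmap panel (top 2 up/down per cluster, deduplicated): {panel['panel']}")
print("\nThe planted proteins dominate the significant list. Note the mirror")
print("hits: because each test is one-vs-rest, a protein shifted up in one")
print("cluster sits relatively lower (or higher) in the others and can reach")
print("significance there with the opposite sign.")
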