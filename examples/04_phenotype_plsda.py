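"""Discriminate pluripotency phenotypes from lipid profiles (day 6).

Labels cells TRA-1-81+ or SSEA-1+ by 2-means clustering of their marker
fluorescence, trains a PLS-DA classifier on the lipid features, trims
variables by VIP, and validates on an independent replicate.
"""

import numpy as np

import lipidcolony as lc
from lipidcolony import cells as C, models as M

config = lc.ColonyPhantomConfig(n_cells=800, seed=7)
series = lc.generate_day_series(config)
d6, d6_val = series.tables[6], series.replicate_tables[6]
feats = C.feature_columns(d6)

labels = M.label_by_kmeans(d6[["tra181_mean", "ssea1_mean"]].to_numpy(),
                           ("TRA181", "SSEA1"), seed=0)
labels_val = M.label_by_kmeans(d6_val[["tra181_mean", "ssea1_mean"]].to_numpy(),
                               ("TRA181", "SSEA1"), seed=0)
print("training mixture:", dict(zip(*np.unique(labels, return_counts=True))))

model = M.trim_variables(d6[feats].to_numpy(), labels,
                         d6_val[feats].to_numpy(), labels_val, feats)
print(f"validation accuracy after VIP trimming: "
      f"{model.metrics['validation_accuracy']:.3f} "
      f"({model.metrics['n_retained']} features retained)")

idx = {f: i for i, f in enumerate(model.feature_names)}
for f in ("mz_748.5", "mz_940.6"):
    if f in idx:
        print(f"{f.replace('mz_', 'm/z ')} loading: "
              f"{model.loadings[idx[f], 0]:+.3f}")
# Opposite loading signs: the ether PE rises with differentiation (SSEA-1+
# arm) while the unannotated 940.6 species marks the pluripotent-like arm.
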