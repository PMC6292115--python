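"""Rank candidate driver genes by weight W and test driver enrichment.

Each alteration feature gets W = mean over pathway models of
(-log10 p-value in the unpenalised refit) x (model R2_pred, clamped at 0).
Features that are significant predictors in well-predicted pathways rise to
the top; a one-sided Wilcoxon rank-sum test checks whether a list of known
drivers is enriched among high weights.
"""

import numpy as np

import mutpath as mp

design = mp.SimulationDesign(
    n_samples=200, n_genes=1500, n_pathways=8, pathway_size_range=(40, 60),
    n_mut_genes=40, n_cnv_genes=40, n_driver_features=6, seed=3,
)
expr, mut, cnv, collection, truth = mp.simulate_dataset(design)
scores = mp.score_collection(expr, collection)
X = mp.build_feature_matrix(mut, cnv)
models = mp.fit_all_pathways(scores, X, mp.RegressionConfig(n_folds=5, seed=0))

weights = mp.predictor_weights(models, feature_names=X.feature_names)
print("top 10 features by driver weight W:")
print(weights.head(10).to_string(index=False))
print("\nplanted drivers:", ", ".join(truth.driver_features))

driver_genes = frozenset(f.split(" (")[0] for f in truth.driver_features)
enr = mp.driver_enrichment(weights, mp.GeneList(driver_genes, "planted"))
print(f"\nrank-sum enrichment of planted drivers: U={enr.u_statistic:.0f}, "
      f"one-sided p={enr.p_value:.2e}")
print("A small p means planted drivers concentrate at the top of the W")
print("ranking — the weight recovers the genes that actually drive activity.")
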