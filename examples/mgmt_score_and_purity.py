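"""Two-probe methylation scoring and sparse-PLS tumor purity (HMP index).

Calibrates a two-probe logistic score on one dataset, scores the rest,
trains the sparse-PLS purity predictor on unmethylated intergenic probes,
and checks how much of the score's variance purity explains.
"""

import numpy as np

import ddrmeth as dm

cfg = dm.SimConfig(seed=3)
bundle = dm.simulate_study(cfg)
ms, ann, truth = bundle.methylation, bundle.annotation, bundle.truth
samp = ms.samples

# remove experimental batch effects first; purity signal on intergenic
# probes is subtle and batch shifts would otherwise confound it
M = dm.combat_adjust(ms.M, samp["batch"])
beta = dm.m_to_beta(M)

# two promoter probes of the designated score gene
probes = ann[(ann["gene"] == bundle.mgmt_gene)
             & (ann["region_class"] == "promoter")].index[:2]
train = samp.index[(samp["dataset"] == "TCGA1") & (samp["tissue_type"] == "tumor")]
model = dm.fit_mgmt_model(M.loc[train, probes],
                          samp.loc[train, "cimp"].astype(int))
tumor = samp.index[samp["tissue_type"] == "tumor"]
scores = dm.mgmt_score(M.loc[tumor, probes[0]], M.loc[tumor, probes[1]],
                       model)
print(f"scored {len(scores)} samples with probes {list(probes)}")
print(f"methylated calls (prob > {model.cutoff_prob}): "
      f"{(scores['status'] == 'methylated').sum()}")

# purity: train on one dataset against the reference purity, validate on another
predictors = dm.select_purity_predictors(beta.loc[tumor], ann)
valid = samp.index[(samp["dataset"] == "TCGA2") & (samp["tissue_type"] == "tumor")]
spls = dm.fit_spls(beta.loc[train, predictors], truth.purity.loc[train],
                   K=3, eta=0.4)
hmp = dm.predict_purity(spls, beta.loc[tumor])
rmse = float(np.sqrt(np.mean((hmp.loc[valid] - truth.purity.loc[valid]) ** 2)))
print(f"purity predictors: {len(predictors)} unmethylated intergenic probes")
print(f"held-out purity RMSE: {rmse:.3f}")

assoc = dm.score_purity_association(scores.loc[valid, "score"], hmp.loc[valid])
print(f"score~purity: R2 = {assoc['r2']:.3f}, robust Wald p = {assoc['wald_p']:.4f}")
# A small R2 means the methylation score is not merely a purity readout;
# adjust_score_for_purity removes the purity component when it matters.
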