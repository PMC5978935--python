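"""End-to-end orchestration: simulate -> preprocess -> select -> score ->
purity -> STATIS -> differential -> CNV -> survival.

Each stage is a pure function of (inputs, config, seed); per-stage child
seeds derive from the pipeline seed, outputs are written as TSV/JSON under
the output directory, and a manifest records thresholds, per-stage counts
and the SHA-256 of every file, so a re-run with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from . import io as dio
from .config import PipelineConfig
from .differential import (call_dmps, differential_expression, intersect_dmps,
                           moderated_t)
from .mgmt_purity import (adjust_score_for_purity, fit_mgmt_model, fit_spls,
                          mgmt_score, predict_purity,
                          score_purity_association, select_purity_predictors)
from .preprocess import combat_adjust, filter_probes, m_to_beta
from .probe_selection import (fit_ntb_mixture, functional_selection,
                              promoter_cpgs, unmethylated_in_ntb)
from .simulate import dataset_names, simulate_study
from .statis import statis
from .subtype_cnv import cimp_cluster, codel_calls
from .survival import cox_fit, expected_survival_surface, interaction_screen, km_by_cutoffs

__version__ = "0.1.0"


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, 1000 + k]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in canonical order and write a manifest.

    Later stages consume in-memory products of earlier ones; enabling a
    stage whose inputs were not produced raises.  Returns the manifest dict
    (also written as ``manifest.json``).
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    state: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {k: float(v) for k, v in th.items()},
        "stages": {},
    }

    enabled = set(cfg.stages)
    for stage in cfg.stages:
        missing = _DEPS.get(stage, set()) - enabled
        if missing:
            raise ValueError(f"stage '{stage}' requires stages {sorted(missing)}")

    for stage in cfg.stages:
        counts = _STAGES[stage](cfg, state, out, th)
        manifest["stages"][stage] = counts

    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(out))] = _sha256(path)
    manifest["files"] = files
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _stage_simulate(cfg, state, out, th):
    sim_cfg = cfg.sim
    sim_cfg.seed = cfg.seed
    bundle = simulate_study(sim_cfg)
    state["bundle"] = bundle
    d = out / "simulate"
    bundle.write(d)
    return {
        "n_samples": len(bundle.methylation.samples),
        "n_probes": bundle.methylation.beta.shape[1],
        "n_genes": int((bundle.annotation["gene"] != "").sum() and
                       bundle.annotation.loc[bundle.annotation["gene"] != "",
                                             "gene"].nunique()),
        "n_functional_genes_true": len(bundle.truth.functional_genes),
        "score_gene": bundle.mgmt_gene,
    }


def _stage_preprocess(cfg, state, out, th):
    bundle = state["bundle"]
    ms, log = filter_probes(bundle.methylation, bundle.annotation,
                            det_p_max=th["det_p_max"])
    # experimental batches first, then cross-dataset harmonization
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M_adj = combat_adjust(ms.M, ms.samples["batch"])
        M_adj = combat_adjust(M_adj, ms.samples["dataset"])
    state["ms_filtered"] = ms
    state["M_adj"] = M_adj
    state["beta_adj"] = m_to_beta(M_adj)
    d = out / "preprocess"
    d.mkdir(exist_ok=True)
    log.to_csv(d / "removed_probes.tsv", sep="\t", index=False)
    dio.write_matrix(M_adj, d / "m_adjusted.tsv")
    return {
        "n_probes_in": bundle.methylation.beta.shape[1],
        "n_probes_removed": bundle.methylation.beta.shape[1] - ms.beta.shape[1],
        "n_probes_out": ms.beta.shape[1],
    }


def _stage_select(cfg, state, out, th):
    bundle = state["bundle"]
    ms = state["ms_filtered"]
    M_adj = state["M_adj"]
    ann = bundle.annotation
    ntb = ms.samples.index[ms.samples["tissue_type"] == "NTB"]
    ntb_median = M_adj.loc[ntb].median(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_ntb_mixture(ntb_median, seed=_child_seed(cfg.seed, 1))
    u_probes = set(unmethylated_in_ntb(fit))
    prom_ddr = promoter_cpgs(ann, window=int(th["promoter_window"]), ddr_only=True)
    prom_ddr = [p for p in prom_ddr if p in ms.beta.columns]
    candidates = [p for p in prom_ddr if p in u_probes]

    names = dataset_names(cfg.sim.n_datasets)
    expr_ds = names[1:3] if len(names) >= 3 else names[:2]
    msamp = ms.samples
    tables = []
    for ds in expr_ds:
        idx = msamp.index[(msamp["dataset"] == ds) & (msamp["tissue_type"] == "tumor")]
        tables.append((ms.M.loc[idx], bundle.expression.loc[idx]))
    res = functional_selection(
        tables[0][0], tables[0][1], tables[1][0], tables[1][1],
        candidates, ann, r_max=th["r_max"], q_max=th["q_max"],
    )
    functional = sorted(res.index[res["functional"]])
    state["mixture_fit"] = fit
    state["candidates"] = candidates
    state["functional_probes"] = functional
    d = out / "select"
    d.mkdir(exist_ok=True)
    res.to_csv(d / "functional_selection.tsv", sep="\t")
    (d / "functional_probes.txt").write_text("\n".join(functional) + "\n")
    return {
        "mixture_means": [round(float(m), 4) for m in fit.means],
        "n_promoter_ddr": len(prom_ddr),
        "n_unmethylated_ntb": len(u_probes),
        "n_candidates": len(candidates),
        "n_functional_cpgs": len(functional),
        "n_functional_genes": int(res.loc[functional, "gene"].nunique()),
    }


def _stage_mgmt(cfg, state, out, th):
    bundle = state["bundle"]
    M_adj = state["M_adj"]
    ann = bundle.annotation
    gene = bundle.mgmt_gene
    probes = (ann[(ann["gene"] == gene) & (ann["region_class"] == "promoter")]
              .sort_values("pos").index)
    probes = [p for p in probes if p in M_adj.columns][:2]
    if len(probes) < 2:
        raise RuntimeError(f"score gene {gene} has fewer than 2 usable probes")
    samp = bundle.methylation.samples
    train = samp.index[(samp["dataset"] == dataset_names(cfg.sim.n_datasets)[1])
                       & (samp["tissue_type"] == "tumor")]
    labels = samp.loc[train, "cimp"].astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_mgmt_model(M_adj.loc[train, probes], labels,
                               cutoff_prob=th["mgmt_cutoff"])
    tumor = samp.index[samp["tissue_type"] == "tumor"]
    scores = mgmt_score(M_adj.loc[tumor, probes[0]], M_adj.loc[tumor, probes[1]],
                        model)
    state["mgmt_model"] = model
    state["mgmt_scores"] = scores
    d = out / "mgmt"
    d.mkdir(exist_ok=True)
    model.to_yaml(d / "mgmt_model.yaml")
    dio.write_table(scores, d / "mgmt_scores.tsv")
    return {
        "probes": list(probes),
        "n_scored": len(scores),
        "n_methylated": int((scores["status"] == "methylated").sum()),
    }


def _stage_purity(cfg, state, out, th):
    bundle = state["bundle"]
    beta_adj = state["beta_adj"]
    samp = bundle.methylation.samples
    names = dataset_names(cfg.sim.n_datasets)
    predictors = select_purity_predictors(
        beta_adj, bundle.annotation, beta_median_max=th["purity_beta_median_max"]
    )
    train = samp.index[(samp["dataset"] == names[1]) & (samp["tissue_type"] == "tumor")]
    valid = samp.index[(samp["dataset"] == names[min(2, len(names) - 1)])
                       & (samp["tissue_type"] == "tumor")]
    model = fit_spls(beta_adj.loc[train, predictors],
                     bundle.truth.purity.loc[train], K=3, eta=0.4)
    tumor = samp.index[samp["tissue_type"] == "tumor"]
    hmp = predict_purity(model, beta_adj.loc[tumor])
    rmse = float(np.sqrt(np.mean(
        (hmp.loc[valid].to_numpy() - bundle.truth.purity.loc[valid].to_numpy()) ** 2
    )))
    counts = {
        "n_predictors": len(predictors),
        "n_nonzero_weights": int((np.abs(model.weights).sum(axis=1) > 0).sum()),
        "validation_rmse": round(rmse, 4),
    }
    state["hmp"] = hmp
    if "mgmt_scores" in state:
        scores = state["mgmt_scores"]
        cohort = samp.index[(samp["dataset"] == names[0])
                            & (samp["tissue_type"] == "tumor") & samp["cimp"]]
        assoc = score_purity_association(scores.loc[cohort, "score"],
                                         hmp.loc[cohort])
        adj = adjust_score_for_purity(scores.loc[cohort, "score"], hmp.loc[cohort])
        state["mgmt_score_adjusted"] = adj
        counts["score_purity_r2"] = round(assoc["r2"], 4)
        counts["score_purity_wald_p"] = round(assoc["wald_p"], 4)
    d = out / "purity"
    d.mkdir(exist_ok=True)
    dio.write_table(hmp.to_frame(), d / "hmp_index.tsv")
    if "mgmt_score_adjusted" in state:
        dio.write_table(state["mgmt_score_adjusted"].to_frame(),
                        d / "mgmt_score_purity_adjusted.tsv")
    return counts


def _stage_statis(cfg, state, out, th):
    bundle = state["bundle"]
    M_adj = state["M_adj"]
    probes = state.get("functional_probes") or state.get("candidates")
    if not probes:
        raise RuntimeError("statis requires the probe selection stage")
    samp = bundle.methylation.samples
    tables = []
    for ds in dataset_names(cfg.sim.n_datasets):
        idx = samp.index[(samp["dataset"] == ds) & (samp["tissue_type"] == "tumor")]
        t = M_adj.loc[idx, probes]
        t.name = ds
        tables.append(t)
    res = statis(tables, B=int(th["statis_permutations"]),
                 seed=_child_seed(cfg.seed, 2))
    state["statis"] = res
    d = out / "statis"
    d.mkdir(exist_ok=True)
    res.rv.to_csv(d / "rv_matrix.tsv", sep="\t")
    res.column_coords.to_csv(d / "column_coords.tsv", sep="\t",
                             index_label="probe_id")
    summary = {
        "lambda1": res.lambda1,
        "table_weights": [float(w) for w in res.table_weights],
        "perm_p": res.perm_p,
        "B": res.B,
        "seed": res.seed,
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True)
                                    + "\n")
    return {"lambda1": round(res.lambda1, 4), "perm_p": res.perm_p,
            "min_rv": round(float(res.rv.to_numpy().min()), 4)}


def _stage_differential(cfg, state, out, th):
    bundle = state["bundle"]
    ms = state["ms_filtered"]
    ann = bundle.annotation
    samp = ms.samples
    candidates = state.get("candidates")
    if candidates is None:
        raise RuntimeError("differential requires the selection stage")
    names = dataset_names(cfg.sim.n_datasets)
    dmp_sets, directions, n_dmps = [], [], {}
    for ds in names:
        idx = samp.index[(samp["dataset"] == ds) & (samp["tissue_type"] == "tumor")
                         & samp["cimp"]]
        groups = np.where(samp.loc[idx, "codel"], "codel", "noncodel")
        res = moderated_t(ms.M.loc[idx, candidates], groups,
                          beta=ms.beta.loc[idx, candidates])
        dmps = call_dmps(res, delta_beta_min=th["delta_beta_min"],
                         q_max=th["q_max"])
        dmp_sets.append(dmps)
        directions.append(res["delta_beta"])
        n_dmps[ds] = len(dmps)
    inter = intersect_dmps(dmp_sets, directions)

    expr_ds = names[1:3] if len(names) >= 3 else names[:2]
    idx = samp.index[samp["dataset"].isin(expr_ds) & (samp["tissue_type"] == "tumor")
                     & samp["cimp"]]
    groups = np.where(samp.loc[idx, "codel"], "codel", "noncodel")
    ddr_genes = sorted(set(ann.loc[ann["ddr_flag"], "gene"]) &
                       set(bundle.expression.columns))
    de = differential_expression(bundle.expression.loc[idx, ddr_genes], groups,
                                 log2fc_min=th["log2fc_min"], q_max=th["q_max"])
    state["dmp_intersection"] = inter
    d = out / "differential"
    d.mkdir(exist_ok=True)
    (d / "dmp_intersection.txt").write_text("\n".join(inter) + "\n")
    de.to_csv(d / "differential_expression.tsv", sep="\t", index_label="gene")
    return {"n_dmps": n_dmps, "n_dmp_intersection": len(inter),
            "n_de_genes": int(de["de"].sum())}


def _stage_cnv(cfg, state, out, th):
    bundle = state["bundle"]
    samp = bundle.methylation.samples
    tumor = list(samp.index[samp["tissue_type"] == "tumor"])
    ntb = list(samp.index[samp["tissue_type"] == "NTB"])
    calls = codel_calls(
        bundle.intensities, bundle.annotation, samples=tumor, reference=ntb,
        loss_threshold=th["loss_threshold"], alpha=th["cbs_alpha"],
        n_perm=int(th["cbs_permutations"]), seed=_child_seed(cfg.seed, 3),
    )
    truth = bundle.truth.codel.loc[tumor]
    acc = float((calls["codel"].to_numpy() == truth.to_numpy()).mean())
    clust = cimp_cluster(state["M_adj"].loc[tumor, state["candidates"]]
                         if "candidates" in state else state["M_adj"].loc[tumor])
    state["codel_calls"] = calls
    d = out / "cnv"
    d.mkdir(exist_ok=True)
    dio.write_table(calls, d / "codel_calls.tsv")
    dio.write_table(clust, d / "cimp_clusters.tsv")
    return {"n_codel_called": int(calls["codel"].sum()),
            "codel_call_accuracy": round(acc, 4),
            "n_cimp_pos": int(clust["cimp"].sum())}


def _stage_survival(cfg, state, out, th):
    bundle = state["bundle"]
    M_adj = state["M_adj"]
    surv = bundle.survival
    probes = state.get("functional_probes") or state.get("candidates")
    if not probes:
        raise RuntimeError("survival requires the selection stage")
    data = surv.copy()
    samp = bundle.methylation.samples
    data["codel"] = samp.loc[data.index, "codel"].astype(float)
    if "mgmt_scores" in state:
        data["score"] = state["mgmt_scores"].loc[data.index, "score"]
    screen = interaction_screen(data[["time", "event", "arm", "codel"]],
                                M_adj.loc[data.index, probes],
                                adjust_codel=False,
                                q_max=th["interaction_q_max"])
    fit = cox_fit(data, "score + arm + score:arm", null_formula="score + arm")
    km = km_by_cutoffs(data, data["score"])
    score_grid = np.linspace(data["score"].min(), data["score"].max(), 21)
    time_grid = np.linspace(0.0, float(data["time"].max()), 25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surface = expected_survival_surface(fit, score_grid, time_grid)
    d = out / "survival"
    d.mkdir(exist_ok=True)
    screen.to_csv(d / "interaction_screen.tsv", sep="\t")
    fit.terms.to_csv(d / "cox_score_model.tsv", sep="\t", index_label="term")
    for arm, sf in surface.items():
        sf.to_csv(d / f"surface_{arm}.tsv", sep="\t")
    inter_term = [t for t in fit.terms.index if ":" in t][0]
    return {
        "n_screened": len(screen),
        "n_flagged": int(screen["flagged"].sum()),
        "score_interaction_coef": round(fit.coef(inter_term), 4),
        "score_interaction_hr": round(float(fit.terms.loc[inter_term, "hr"]), 4),
        "score_interaction_lrt_p": round(float(fit.lrt_p), 4),
        "km_logrank_p": {a: round(v["logrank_p"], 4)
                         for a, v in km["arms"].items()},
    }


_DEPS = {
    "preprocess": {"simulate"},
    "select": {"preprocess"},
    "mgmt": {"preprocess"},
    "purity": {"preprocess"},
    "statis": {"select"},
    "differential": {"select"},
    "cnv": {"preprocess"},
    "survival": {"select", "mgmt"},
}

_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "select": _stage_select,
    "mgmt": _stage_mgmt,
    "purity": _stage_purity,
    "statis": _stage_statis,
    "differential": _stage_differential,
    "cnv": _stage_cnv,
    "survival": _stage_survival,
}
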