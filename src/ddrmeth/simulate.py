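"""Seeded generator of synthetic HM-450K-style studies.

Emulates the statistical structure of a multi-dataset low-grade glioma
methylation study: a probe annotation with promoter / intergenic / other
context, trimodal probe methylation states in normal brain, CIMP
hypermethylation of normally-unmethylated promoters in IDH-mutant tumors
with an extra codeletion-associated shift, tumor purity acting as a convex
tumor/normal mixture on the beta scale, per-batch location/scale effects on
the M scale, channel intensities with arm-level loss on 1p/19q in codeleted
samples, negatively coupled expression for a designated functional gene
subset, and exponential progression-free survival with a treatment-by-score
interaction.

Every stage derives its own child seed from the master seed, so stages can
be regenerated independently and identical configs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import IntensitySet, MethylSet, SyntheticTruth, validate_annotation
from .preprocess import m_to_beta

_STAGE_SEEDS = {"annotation": 0, "methylation": 1, "expression": 2, "survival": 3}
_DATASET_NAMES = ["EORTC", "TCGA1", "TCGA2", "AGLIOMA"]
_GENE_CHROMS = ["1p", "19q", "2", "3", "7", "10"]
_GENE_CHROM_P = [0.15, 0.15, 0.175, 0.175, 0.175, 0.175]
_STATE_LABELS = np.array(["U", "H", "M"])
_GENE_SPACING = 100_000


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]))


def dataset_names(n: int) -> list[str]:
    names = list(_DATASET_NAMES[:n])
    names += [f"DS{i + 1}" for i in range(len(names), n)]
    return names


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Generate a probe annotation table (index = probe_id).

    Each gene receives 1+ promoter CpGs within +/-1500 nt of its TSS
    (even offsets), plus optional distal "other" probes (odd offsets);
    intergenic probes sit in the gaps far from every TSS; a block of
    chromosome-X probes and a random SNP subset exercise the filters.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "annotation")
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_chrom = rng.choice(len(_GENE_CHROMS), size=cfg.n_genes, p=_GENE_CHROM_P)
    # lay genes sequentially along their chromosome
    slot = {c: 0 for c in range(len(_GENE_CHROMS))}
    tss = np.empty(cfg.n_genes, dtype=int)
    for g in range(cfg.n_genes):
        slot[gene_chrom[g]] += 1
        tss[g] = slot[gene_chrom[g]] * _GENE_SPACING

    rows = []  # chrom, pos, gene, tss_distance, region_class
    lo, hi = cfg.cpgs_per_gene
    evens = np.arange(-750, 751) * 2  # even offsets in [-1500, 1500]
    for g, gene in enumerate(genes):
        k = int(rng.integers(lo, hi + 1))
        offs = rng.choice(evens, size=k, replace=False)
        for d in offs:
            rows.append((_GENE_CHROMS[gene_chrom[g]], tss[g] + int(d), gene,
                         int(d), "promoter"))
    for _ in range(cfg.n_other_probes):
        g = int(rng.integers(cfg.n_genes))
        d = int(rng.integers(1000, 20000)) * 2 + 1  # odd, 2001..40001
        d *= int(rng.choice([-1, 1]))
        rows.append((_GENE_CHROMS[gene_chrom[g]], tss[g] + d, genes[g], d, "other"))
    for _ in range(cfg.n_intergenic_probes):
        g = int(rng.integers(cfg.n_genes))
        d = int(rng.integers(21000, 29000)) * 2 + 1  # odd, mid-gap
        rows.append((_GENE_CHROMS[gene_chrom[g]], tss[g] + d, "", np.nan, "intergenic"))
    for i in range(cfg.n_sex_probes):
        rows.append(("X", (i + 1) * 1000 + 1, "", np.nan, "other"))

    ann = pd.DataFrame(rows, columns=["chrom", "pos", "gene", "tss_distance",
                                      "region_class"])
    # enforce strictly increasing (hence unique) positions per chromosome
    for chrom in ann["chrom"].unique():
        idx = ann.index[ann["chrom"] == chrom]
        pos = ann.loc[idx, "pos"].to_numpy().copy()
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        for j in range(1, len(sorted_pos)):
            if sorted_pos[j] <= sorted_pos[j - 1]:
                sorted_pos[j] = sorted_pos[j - 1] + 1
        pos[order] = sorted_pos
        ann.loc[idx, "pos"] = pos

    ann = ann.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ann.index = pd.Index([f"cg{i + 1:06d}" for i in range(len(ann))], name="probe_id")
    ann["snp_flag"] = rng.random(len(ann)) < cfg.snp_fraction
    ann["sex_chrom"] = ann["chrom"] == "X"
    n_ddr = max(1, round(cfg.ddr_fraction * cfg.n_genes))
    ddr_genes = set(rng.choice(genes, size=n_ddr, replace=False))
    ann["ddr_flag"] = ann["gene"].isin(ddr_genes)
    return validate_annotation(ann)


def _assign_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = dataset_names(cfg.n_datasets)
    subtypes = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in subtypes])
    recs = []
    for ds in names:
        for i in range(cfg.n_samples_per_dataset):
            sub = subtypes[int(rng.choice(len(subtypes), p=probs))]
            recs.append((f"{ds}_s{i + 1:03d}", ds, f"{ds}_b{i % cfg.batch_count + 1}",
                         "tumor", sub))
    for i in range(cfg.n_ntb):
        recs.append((f"NTB_s{i + 1:02d}", names[0], f"{names[0]}_b1", "NTB", "NTB"))
    df = pd.DataFrame(recs, columns=["sample_id", "dataset", "batch",
                                     "tissue_type", "subtype"]).set_index("sample_id")
    df["codel"] = df["subtype"] == "IDHmt-codel"
    df["cimp"] = df["subtype"].isin(["IDHmt-noncodel", "IDHmt-codel"])
    return df


def simulate_methylation(
    cfg: SimConfig, ann: pd.DataFrame
) -> tuple[MethylSet, IntensitySet, SyntheticTruth]:
    """Generate beta matrices, channel intensities and ground truth.

    The observed beta of a tumor sample is the convex mixture
    ``purity * beta_tumor + (1 - purity) * beta_normal`` computed on the
    beta scale; batch location/scale effects act on the M scale of both
    components before mixing, so the mixture identity holds exactly.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "methylation")
    samples = _assign_samples(cfg, rng)
    n_s, n_p = len(samples), len(ann)

    state = rng.choice(3, size=n_p, p=np.asarray(cfg.state_weights))
    means = np.asarray(cfg.state_means_M)
    sds = np.asarray(cfg.state_sds_M)
    mu_normal = means[state] + sds[state] * rng.normal(size=n_p)

    affected = ((ann["region_class"] == "promoter") & (state == 0)).to_numpy()
    cimp = samples["cimp"].to_numpy(float)
    codel = samples["codel"].to_numpy(float)
    shift = (cfg.cimp_shift_M * np.outer(cimp, affected)
             + cfg.codel_extra_shift_M * np.outer(codel, affected))
    # tumor cells drift away from normal at unmethylated intergenic sites;
    # this is what makes purity readable from those probes
    inter_u = ((ann["region_class"] == "intergenic") & (state == 0)).to_numpy()
    tumor = (samples["tissue_type"] == "tumor").to_numpy(float)
    shift = shift + cfg.tumor_intergenic_shift_M * np.outer(tumor, inter_u)

    M_normal = mu_normal[None, :] + rng.normal(0.0, cfg.ntb_noise_sd_M, (n_s, n_p))
    M_tumor = (mu_normal[None, :] + shift
               + rng.normal(0.0, cfg.probe_noise_sd_M, (n_s, n_p)))

    # batch location/scale on the M scale (where ComBat operates)
    batches = samples["batch"].unique()
    b_shift = dict(zip(batches, rng.normal(0.0, cfg.batch_shift_sd, len(batches))))
    b_scale = dict(zip(batches, np.exp(rng.normal(0.0, cfg.batch_scale_sd,
                                                  len(batches)))))
    sh = samples["batch"].map(b_shift).to_numpy()[:, None]
    sc = samples["batch"].map(b_scale).to_numpy()[:, None]
    M_normal = M_normal * sc + sh
    M_tumor = M_tumor * sc + sh

    beta_n = m_to_beta(M_normal)
    beta_t = m_to_beta(M_tumor)

    a, b = cfg.purity_beta_params
    alpha = np.where(samples["codel"], a + cfg.codel_purity_alpha_bonus, a)
    purity = rng.beta(alpha, b)
    purity[samples["tissue_type"] == "NTB"] = 0.0

    beta = purity[:, None] * beta_t + (1.0 - purity[:, None]) * beta_n

    det_p = rng.uniform(0.0, 0.005, (n_s, n_p))
    n_fail = int(round(cfg.detection_fail_fraction * n_p))
    if n_fail:
        fail_probes = rng.choice(n_p, size=n_fail, replace=False)
        fail_samples = rng.integers(n_s, size=n_fail)
        det_p[fail_samples, fail_probes] = rng.uniform(0.02, 0.5, n_fail)

    total = cfg.mean_total_intensity * np.exp(rng.normal(0.0, 0.1, (n_s, n_p)))
    arm_probe = ann["chrom"].isin(["1p", "19q"]).to_numpy()
    cn_factor = 1.0 - np.outer(codel * purity, arm_probe) * (
        1.0 - cfg.codel_intensity_factor
    )
    total = total * cn_factor
    unmeth = np.maximum((1.0 - beta) * (total + cfg.intensity_offset)
                        - cfg.intensity_offset, 1.0)
    meth = beta / (1.0 - beta) * (unmeth + cfg.intensity_offset)

    probe_ids = ann.index
    sample_ids = samples.index
    ms = MethylSet(
        beta=pd.DataFrame(beta, index=sample_ids, columns=probe_ids),
        samples=samples,
        detection_p=pd.DataFrame(det_p, index=sample_ids, columns=probe_ids),
    )
    its = IntensitySet(
        meth=pd.DataFrame(meth, index=sample_ids, columns=probe_ids),
        unmeth=pd.DataFrame(unmeth, index=sample_ids, columns=probe_ids),
        offset=cfg.intensity_offset,
    )

    # functional genes: DDR genes with at least one normally-unmethylated
    # promoter probe, so CIMP creates the methylation variation that the
    # expression coupling acts on
    u_prom_genes = sorted(set(ann.loc[affected, "gene"]))
    ddr_u = [g for g in u_prom_genes if g in set(ann.loc[ann["ddr_flag"], "gene"])]
    pool = ddr_u if len(ddr_u) >= cfg.n_functional_genes else u_prom_genes
    n_fun = min(cfg.n_functional_genes, len(pool))
    functional = sorted(rng.choice(pool, size=n_fun, replace=False))

    truth = SyntheticTruth(
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        probe_state=pd.Series(_STATE_LABELS[state], index=probe_ids, name="state"),
        functional_genes=list(functional),
        codel=samples["codel"].copy(),
        beta_tumor=pd.DataFrame(beta_t, index=sample_ids, columns=probe_ids),
        beta_normal=pd.DataFrame(beta_n, index=sample_ids, columns=probe_ids),
    )
    return ms, its, truth


def mean_promoter_m(ms: MethylSet, ann: pd.DataFrame,
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Per-sample mean promoter M value for each gene (samples x genes)."""
    prom = ann[ann["region_class"] == "promoter"]
    if genes is not None:
        prom = prom[prom["gene"].isin(genes)]
    M = ms.M
    cols = {}
    for gene, sub in prom.groupby("gene", sort=True):
        cols[gene] = M[sub.index].mean(axis=1)
    return pd.DataFrame(cols)


def simulate_expression(
    cfg: SimConfig, ms: MethylSet, ann: pd.DataFrame, truth: SyntheticTruth
) -> pd.DataFrame:
    """Normalized log-expression (samples x genes) coupled to methylation.

    Functional genes follow ``intercept + slope * (mean promoter M)`` with
    Gaussian noise and a negative slope; all other genes are independent of
    methylation.
    """
    rng = stage_rng(cfg.seed, "expression")
    genes = sorted(ann.loc[ann["gene"] != "", "gene"].unique())
    meanM = mean_promoter_m(ms, ann)
    n_s = len(ms.samples)
    intercepts = dict(zip(genes, rng.normal(8.0, 1.0, len(genes))))
    functional = set(truth.functional_genes)
    cols = {}
    for gene in genes:
        noise = rng.normal(0.0, cfg.expression_noise_sd, n_s)
        if gene in functional and gene in meanM.columns:
            cols[gene] = (intercepts[gene]
                          + cfg.coupling_slope * meanM[gene].to_numpy() + noise)
        else:
            cols[gene] = intercepts[gene] + rng.normal(0.0, 1.0, n_s) + noise
    return pd.DataFrame(cols, index=ms.samples.index)


def simulate_survival(
    cfg: SimConfig, scores: pd.Series, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Exponential PFS with a treatment-by-score interaction hazard.

    Arms are assigned 1:1 at random.  The log hazard is
    ``log(baseline) + b1*TMZ + b2*score + b3*TMZ*score``; censoring is an
    independent exponential.  Returns (table, true linear predictor).
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    if rng is None:
        rng = stage_rng(cfg.seed, "survival")
    hp = cfg.hazard_params
    n = len(scores)
    arm = np.array(["RT"] * (n - n // 2) + ["TMZ"] * (n // 2))
    rng.shuffle(arm)
    tmz = (arm == "TMZ").astype(float)
    s = scores.to_numpy(float)
    lp = hp.treat_coef * tmz + hp.score_coef * s + hp.interaction_coef * tmz * s
    rate = hp.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    table = pd.DataFrame(
        {"time": time, "event": event.astype(int), "arm": arm,
         "score": s},
        index=scores.index,
    )
    return table, pd.Series(lp, index=scores.index, name="linpred")


@dataclass
class SimBundle:
    """A complete simulated study plus its ground truth."""

    config: SimConfig
    annotation: pd.DataFrame
    methylation: MethylSet
    intensities: IntensitySet
    expression: pd.DataFrame
    survival: pd.DataFrame
    truth: SyntheticTruth
    mgmt_gene: str

    def write(self, outdir) -> list[str]:
        from . import io as dio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, fn):
            fn(out / name)
            written.append(name)

        _w("config.yaml", self.config.to_yaml)
        _w("annotation.tsv", lambda p: dio.write_annotation(self.annotation, p))
        _w("beta.tsv", lambda p: dio.write_matrix(self.methylation.beta, p))
        _w("m_values.tsv", lambda p: dio.write_matrix(self.methylation.M, p))
        _w("detection_p.tsv",
           lambda p: dio.write_matrix(self.methylation.detection_p, p))
        _w("samples.tsv", lambda p: dio.write_table(self.methylation.samples, p))
        _w("meth_intensity.tsv", lambda p: dio.write_matrix(self.intensities.meth, p))
        _w("unmeth_intensity.tsv",
           lambda p: dio.write_matrix(self.intensities.unmeth, p))
        _w("expression.tsv", lambda p: dio.write_matrix(self.expression, p))
        _w("survival.tsv", lambda p: dio.write_table(self.survival, p))
        _w("truth_purity.tsv",
           lambda p: dio.write_table(self.truth.purity.to_frame(), p))
        _w("truth_probe_state.tsv",
           lambda p: dio.write_table(self.truth.probe_state.to_frame(), p))
        _w("truth_functional_genes.txt",
           lambda p: Path(p).write_text("\n".join(self.truth.functional_genes) + "\n"))
        return written


def simulate_study(cfg: SimConfig) -> SimBundle:
    """Run all generator stages and bundle the results.

    Survival is generated for the first dataset's tumor samples from the
    true (gene-level) methylation score of a designated two-probe score
    gene, mimicking a randomized-trial cohort with outcome data.
    """
    ann = simulate_annotation(cfg)
    ms, its, truth = simulate_methylation(cfg, ann)
    expr = simulate_expression(cfg, ms, ann, truth)

    # designated score gene: the functional gene with most promoter probes
    prom = ann[ann["region_class"] == "promoter"]
    counts = prom[prom["gene"].isin(truth.functional_genes)]["gene"].value_counts()
    multi = counts[counts >= 2]
    mgmt_gene = (multi.index[0] if len(multi) else counts.index[0])

    first_ds = dataset_names(cfg.n_datasets)[0]
    cohort = ms.samples[(ms.samples["dataset"] == first_ds)
                        & (ms.samples["tissue_type"] == "tumor")
                        & (ms.samples["cimp"])].index
    gene_m = mean_promoter_m(ms, ann, [mgmt_gene])[mgmt_gene]
    score = gene_m.loc[cohort]
    score = (score - score.mean()) / (score.std(ddof=1) or 1.0)
    surv, lp = simulate_survival(cfg, score)
    truth.survival_linpred = lp
    return SimBundle(cfg, ann, ms, its, expr, surv, truth, mgmt_gene)
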