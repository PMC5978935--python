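import numpy as np
import pandas as pd
import pytest

from ddrmeth import MethylSet, SimConfig, simulate_annotation, simulate_methylation


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study: 2 datasets x 30 samples, ~40 genes."""
    return SimConfig(
        n_datasets=2,
        n_samples_per_dataset=30,
        n_genes=40,
        cpgs_per_gene=(1, 3),
        n_intergenic_probes=80,
        n_other_probes=20,
        n_functional_genes=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    ann = simulate_annotation(small_cfg)
    ms, its, truth = simulate_methylation(small_cfg, ann)
    return {"ann": ann, "ms": ms, "its": its, "truth": truth}


@pytest.fixture()
def toy_methylset():
    """10 probes, 6 samples; 2 SNP-flagged probes and 1 on chrX."""
    rng = np.random.default_rng(0)
    probes = [f"cg{i:02d}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (6, 10)), index=samples,
                        columns=probes)
    sample_ann = pd.DataFrame(
        {"dataset": "D1", "batch": ["b1"] * 3 + ["b2"] * 3,
         "tissue_type": "tumor"},
        index=pd.Index(samples, name="sample_id"),
    )
    det = pd.DataFrame(0.0, index=samples, columns=probes)
    ms = MethylSet(beta=beta, samples=sample_ann, detection_p=det)
    ann = pd.DataFrame(
        {
            "chrom": ["1p"] * 9 + ["X"],
            "pos": list(range(1000, 1000 + 9 * 10, 10)) + [500],
            "gene": ["G1"] * 5 + [""] * 5,
            "tss_distance": [0, 10, -20, 30, 40] + [np.nan] * 5,
            "region_class": ["promoter"] * 5 + ["intergenic"] * 4 + ["other"],
            "snp_flag": [False, True, False, False, False, True, False, False,
                         False, False],
            "sex_chrom": [False] * 9 + [True],
            "ddr_flag": [True] * 5 + [False] * 5,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ms, ann
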