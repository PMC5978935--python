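"""In-memory containers for HM-450K-style methylation studies.

Matrices are plain pandas DataFrames oriented samples x probes (rows are
samples), mirroring how the tables are written to disk.  The light dataclasses
below bundle a matrix with its sample annotation and enforce the basic shape
and range contracts once, so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "gene",
    "tss_distance",
    "region_class",
    "snp_flag",
    "sex_chrom",
    "ddr_flag",
]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a probe annotation table (index = probe_id) and return it.

    Contracts: promoter probes carry a gene and |tss_distance| <= 1500;
    intergenic probes carry no gene; positions strictly increase within a
    chromosome.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if not ann.index.is_unique:
        raise ValueError("duplicate probe ids in annotation")
    prom = ann["region_class"] == "promoter"
    if prom.any():
        bad = prom & ((ann["gene"] == "") | (ann["tss_distance"].abs() > 1500))
        if bad.any():
            raise ValueError(
                f"promoter contract violated for probes {list(ann.index[bad][:3])}"
            )
    inter = ann["region_class"] == "intergenic"
    if (inter & (ann["gene"] != "")).any():
        raise ValueError("intergenic probes must carry no gene")
    for chrom, sub in ann.groupby("chrom", sort=False):
        pos = sub.sort_values("pos")["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return ann


@dataclass
class MethylSet:
    """Beta-value matrix (samples x probes) plus per-sample annotation.

    ``samples`` is indexed by sample id and carries at least ``dataset``,
    ``batch`` and ``tissue_type`` (``tumor`` or ``NTB``).  M values are
    derived on demand (logit2 of beta); betas are the stored representation.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.samples.index):
            raise ValueError("beta rows and sample annotation must share the same index")
        if not self.beta.index.is_unique or not self.beta.columns.is_unique:
            raise ValueError("sample/probe ids must be unique")
        vals = self.beta.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("beta matrix contains non-finite values")
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("beta values must lie strictly in (0, 1)")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValueError("detection_p shape mismatch")

    @property
    def M(self) -> pd.DataFrame:
        from .preprocess import beta_to_m

        return beta_to_m(self.beta)

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_samples(self, mask) -> "MethylSet":
        return MethylSet(
            beta=self.beta.loc[mask],
            samples=self.samples.loc[mask],
            detection_p=None if self.detection_p is None else self.detection_p.loc[mask],
        )

    def subset_probes(self, probes) -> "MethylSet":
        probes = [p for p in probes if p in self.beta.columns]
        return MethylSet(
            beta=self.beta[probes],
            samples=self.samples,
            detection_p=None if self.detection_p is None else self.detection_p[probes],
        )


@dataclass
class IntensitySet:
    """Methylated / unmethylated channel intensities, samples x probes."""

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    offset: float = 100.0

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth/unmeth shape mismatch")
        if (self.meth.to_numpy() <= 0).any() or (self.unmeth.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")

    @property
    def total(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def beta(self) -> pd.DataFrame:
        return self.meth / (self.meth + self.unmeth + self.offset)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated study.

    Used by recovery tests only; real analyses never see these fields.
    """

    purity: pd.Series                 # per tumor/NTB sample, in [0, 1]
    probe_state: pd.Series            # per probe, in {U, H, M}
    functional_genes: list[str] = field(default_factory=list)
    codel: pd.Series | None = None    # per-sample boolean
    beta_tumor: pd.DataFrame | None = None
    beta_normal: pd.DataFrame | None = None
    survival_linpred: pd.Series | None = None
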