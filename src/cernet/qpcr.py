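"""Relative quantification of qPCR targets by the 2^-ddCt method.

Per patient, dCt = Ct(target) - Ct(reference) in each tissue, ddCt =
dCt(tumor) - dCt(normal), and relative expression = 2^-ddCt, so a target
amplifying earlier in tumor than matched normal tissue (after reference
normalization) yields a fold change above 1.  Tumor and normal are
compared with a paired t-test on the per-patient dCt values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelQuantResult", "delta_delta_ct", "paired_t", "read_ct_table"]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class RelQuantResult:
    """Per-patient ddCt quantities and the paired-test summary for one target."""

    target_gene: str
    per_patient: pd.DataFrame  # patient_id, delta_ct_tumor, delta_ct_normal, delta_delta_ct, fold_change
    mean_fold_change: float
    sd_fold_change: float
    t_stat: float
    df: int
    p_value: float
    excluded_patients: list[str]


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("all differences identical: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def delta_delta_ct(records: pd.DataFrame, target_gene: str | None = None) -> RelQuantResult:
    """Relative quantification from a Ct table.

    ``records`` has columns patient_id, tissue (tumor/normal), target_gene,
    ct_target, ct_reference; technical replicates (several rows per
    patient/tissue) are averaged on the Ct scale.  Patients missing either
    tissue are excluded and reported in the result.  The paired t-test is
    applied to the per-patient dCt values (tumor vs normal).
    """
    df = records.copy()
    if target_gene is not None:
        df = df[df["target_gene"] == target_gene]
    targets = df["target_gene"].unique()
    if len(targets) != 1:
        raise ValueError(f"expected one target gene, got {list(targets)}; pass target_gene=")
    target = str(targets[0])
    bad_tissue = set(df["tissue"].unique()) - {TUMOR, NORMAL}
    if bad_tissue:
        raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")

    # replicate averaging on the Ct scale, then dCt per patient/tissue
    agg = df.groupby(["patient_id", "tissue"])[["ct_target", "ct_reference"]].mean()
    dct = (agg["ct_target"] - agg["ct_reference"]).unstack("tissue")
    complete = dct.dropna(subset=[TUMOR, NORMAL]) if {TUMOR, NORMAL} <= set(dct.columns) else dct.iloc[0:0]
    excluded = sorted(set(dct.index.astype(str)) - set(complete.index.astype(str)))
    if complete.empty:
        raise ValueError("no complete tumor/normal pairs")

    ddct = complete[TUMOR] - complete[NORMAL]
    fold = np.power(2.0, -ddct)
    per_patient = pd.DataFrame(
        {
            "patient_id": complete.index.astype(str),
            "delta_ct_tumor": complete[TUMOR].to_numpy(),
            "delta_ct_normal": complete[NORMAL].to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold_change": fold.to_numpy(),
        }
    ).reset_index(drop=True)
    try:
        t, dfree, p = paired_t(complete[TUMOR].to_numpy(), complete[NORMAL].to_numpy())
    except ZeroDivisionError:
        # identical dCt differences in every patient: t undefined
        t, dfree, p = math.nan, len(complete) - 1, math.nan
    return RelQuantResult(
        target_gene=target,
        per_patient=per_patient,
        mean_fold_change=float(fold.mean()),
        sd_fold_change=float(fold.std(ddof=1)) if len(fold) > 1 else 0.0,
        t_stat=t,
        df=dfree,
        p_value=p,
        excluded_patients=excluded,
    )


def read_ct_table(path) -> pd.DataFrame:
    """Ct TSV: patient_id, tissue, target_gene, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "tissue": str, "target_gene": str})
    for col in ("ct_target", "ct_reference"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any():
            raise ValueError(f"{col} must be positive (cycle counts)")
    return df


def write_result(result: RelQuantResult, path) -> None:
    out = result.per_patient.copy()
    out.insert(0, "target_gene", result.target_gene)
    out.to_csv(path, sep="\t", index=False)
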