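"""Differential expression with empirical-Bayes variance moderation.

Implements the moderated t-statistic: per-feature sample variances are
shrunk toward a prior variance ``s0_sq`` carrying ``d0`` prior degrees of
freedom, estimated by moment-matching the distribution of log sample
variances.  Direction calls use a log2 fold-change cutoff together with a
Benjamini-Hochberg adjusted p-value threshold, and two studies can be
intersected sign-consistently (the Venn step of a two-dataset design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ExpressionStudy",
    "VariancePrior",
    "log2_normalize",
    "fit_variance_prior",
    "moderated_t_test",
    "bh_adjust",
    "call_directions",
    "intersect_de",
    "read_expression",
    "read_design",
    "write_de_table",
    "read_de_table",
]

TUMOR = "tumor"
NORMAL = "normal"


class PriorUnavailableError(ValueError):
    """Raised when too few usable features exist to fit a variance prior."""


@dataclass
class ExpressionStudy:
    """A feature-by-sample log2 expression matrix with its sample design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Features on rows (index = feature ids), samples on columns.
    design : pandas.DataFrame
        Indexed by sample id with a ``condition`` column in
        ``{"tumor", "normal"}`` and an optional ``pair_id`` column for
        matched tumor/normal designs.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.matrix.columns.has_duplicates or self.design.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if set(self.matrix.columns) != set(self.design.index):
            raise ValueError("matrix samples and design samples differ")
        cond = self.design["condition"]
        bad = set(cond.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        counts = cond.value_counts()
        if counts.get(TUMOR, 0) < 2 or counts.get(NORMAL, 0) < 2:
            raise ValueError("need at least 2 samples per condition")
        if "pair_id" in self.design.columns and self.design["pair_id"].notna().all():
            per_pair = self.design.groupby("pair_id")["condition"].value_counts()
            by_pair = per_pair.unstack(fill_value=0)
            if not ((by_pair.get(TUMOR, 0) == 1) & (by_pair.get(NORMAL, 0) == 1)).all():
                raise ValueError("each pair must have exactly one tumor and one normal sample")

    @property
    def paired(self) -> bool:
        return "pair_id" in self.design.columns and self.design["pair_id"].notna().all()


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 prior df and prior variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def log2_normalize(raw: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) transform of a nonnegative intensity matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.asarray(raw, dtype=float)
    if (values < 0).any():
        raise ValueError("negative entries are not allowed")
    return pd.DataFrame(np.log2(values + pseudocount), index=raw.index, columns=raw.columns)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0. trigamma is strictly decreasing."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    if f(lo) < 0:  # y above trigamma(1e-8): no practical solution, x -> 0
        return lo
    if f(hi) > 0:  # y below trigamma(1e8): x effectively infinite
        return math.inf
    return optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> VariancePrior:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    With z = log(s_sq), solves trigamma(d0/2) = var(z) - trigamma(df/2) for
    d0, then sets s0_sq = exp(mean(z) - digamma(df/2) + digamma(d0/2) +
    log(df/d0)).  When the observed log-variances are under-dispersed
    relative to a chi-square with ``df`` degrees of freedom the prior
    degrees of freedom are infinite and every feature shares one variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if s_sq.size < 2:
        raise PriorUnavailableError("need at least 2 positive variances to fit a prior")
    if df < 1:
        raise ValueError("df must be >= 1")
    z = np.log(s_sq)
    var_z = float(np.var(z, ddof=1))
    mean_z = float(np.mean(z))
    excess = var_z - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        s0_sq = math.exp(mean_z - special.digamma(df / 2.0) + math.log(df))
        return VariancePrior(d0=math.inf, s0_sq=s0_sq)
    half_d0 = _trigamma_inverse(excess)
    if math.isinf(half_d0):
        s0_sq = math.exp(mean_z - special.digamma(df / 2.0) + math.log(df))
        return VariancePrior(d0=math.inf, s0_sq=s0_sq)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(
        mean_z
        - special.digamma(df / 2.0)
        + special.digamma(d0 / 2.0)
        + math.log(df / d0)
    )
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def _effects_and_variances(study: ExpressionStudy, paired: bool):
    """Per-feature mean difference (tumor - normal), sample variance of the
    relevant contrast, residual df, and standard-error scale c."""
    mat = study.matrix
    design = study.design
    if paired:
        if not study.paired:
            raise ValueError("paired analysis requested but design has no complete pair ids")
        pairs = design.reset_index().pivot(index="pair_id", columns="condition", values=design.index.name or "index")
        tumor_cols = pairs[TUMOR].tolist()
        normal_cols = pairs[NORMAL].tolist()
        diffs = mat[tumor_cols].to_numpy() - mat[normal_cols].to_numpy()
        n = diffs.shape[1]
        log_fc = diffs.mean(axis=1)
        s_sq = diffs.var(axis=1, ddof=1)
        df = n - 1
        c = 1.0 / math.sqrt(n)
    else:
        tumor_cols = design.index[design["condition"] == TUMOR].tolist()
        normal_cols = design.index[design["condition"] == NORMAL].tolist()
        x1 = mat[tumor_cols].to_numpy()
        x2 = mat[normal_cols].to_numpy()
        n1, n2 = x1.shape[1], x2.shape[1]
        log_fc = x1.mean(axis=1) - x2.mean(axis=1)
        pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / (n1 + n2 - 2)
        s_sq = pooled
        df = n1 + n2 - 2
        c = math.sqrt(1.0 / n1 + 1.0 / n2)
    return log_fc, s_sq, df, c


def moderated_t_test(
    study: ExpressionStudy,
    prior: VariancePrior | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Moderated (or ordinary) t-test of tumor vs normal per feature.

    Returns a DataFrame indexed by feature id with columns ``log_fc``,
    ``t_stat``, ``df_total``, ``p_value``, ``zero_variance``.  With
    ``prior=None`` (or d0 = 0) this is the classical t-test.  Features with
    zero residual variance and no prior have undefined p-values: they are
    flagged via ``zero_variance`` and carry NaN statistics rather than being
    dropped.
    """
    log_fc, s_sq, df, c = _effects_and_variances(study, paired)
    d0 = 0.0 if prior is None else prior.d0
    s0_sq = 0.0 if prior is None else prior.s0_sq

    zero_var = s_sq <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        if math.isinf(d0):
            s_tilde_sq = np.full_like(s_sq, s0_sq)
            df_total = math.inf
        else:
            s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
            df_total = df + d0
        t = log_fc / (np.sqrt(s_tilde_sq) * c)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    undefined = zero_var & (d0 == 0)
    t = np.where(undefined, np.nan, t)
    p = np.where(undefined, np.nan, p)
    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "t_stat": t,
            "df_total": df_total,
            "p_value": p,
            "zero_variance": zero_var,
        },
        index=study.matrix.index.rename("feature_id"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    adj_(i) = min_{j>=i}( p_(j) * m / j ), capped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    finite = p[np.isfinite(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def call_directions(table: pd.DataFrame, lfc_cutoff: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Add a ``direction`` column (up / down / ns) to a DE table.

    up iff log_fc > lfc_cutoff and adj_p < alpha (strict inequalities);
    down symmetric; everything else, including boundary values, is ns.
    A cutoff of 0 gives the relaxed |logFC| > 0 rule.
    """
    if lfc_cutoff < 0:
        raise ValueError("lfc_cutoff must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if "adj_p" not in table.columns:
        raise ValueError("adjusted p-values missing; run bh_adjust first")
    out = table.copy()
    sig = out["adj_p"] < alpha
    direction = np.where(
        sig & (out["log_fc"] > lfc_cutoff),
        "up",
        np.where(sig & (out["log_fc"] < -lfc_cutoff), "down", "ns"),
    )
    out["direction"] = direction
    return out


def de_table(
    study: ExpressionStudy,
    prior: VariancePrior | None = None,
    paired: bool = False,
    lfc_cutoff: float = 1.5,
    alpha: float = 0.05,
    moderate: bool = True,
) -> pd.DataFrame:
    """One-stop DE analysis: moderated t, BH adjustment, direction calls.

    With ``moderate=True`` the prior is fitted from the data when not
    supplied; features with zero residual variance are excluded from prior
    fitting but retained (flagged) in the output.
    """
    if prior is None and moderate:
        _, s_sq, df, _ = _effects_and_variances(study, paired)
        try:
            prior = fit_variance_prior(s_sq[s_sq > 0], df)
        except PriorUnavailableError:
            prior = None
    tab = moderated_t_test(study, prior, paired)
    tab["adj_p"] = np.nan
    ok = tab["p_value"].notna()
    tab.loc[ok, "adj_p"] = bh_adjust(tab.loc[ok, "p_value"].to_numpy())
    return call_directions(tab, lfc_cutoff=lfc_cutoff, alpha=alpha)


def intersect_de(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, set[str]]:
    """Sign-consistent overlap of two direction-called DE tables.

    Returns ``{"up": ids up in both, "down": ids down in both}``; features
    with conflicting directions are excluded from both sets.
    """
    for name, tab in (("first", a), ("second", b)):
        if "direction" not in tab.columns:
            raise ValueError(f"{name} table has no direction calls")
    up_a = set(a.index[a["direction"] == "up"])
    dn_a = set(a.index[a["direction"] == "down"])
    up_b = set(b.index[b["direction"] == "up"])
    dn_b = set(b.index[b["direction"] == "down"])
    return {"up": up_a & up_b, "down": dn_a & dn_b}


# ---------------------------------------------------------------------------
# TSV interfaces

def read_expression(path) -> pd.DataFrame:
    """Expression TSV: first column feature id, header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path) -> pd.DataFrame:
    """Design TSV: sample_id, condition, optional pair_id."""
    design = pd.read_csv(path, sep="\t", index_col=0, dtype={"pair_id": "string"})
    return design


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table.reset_index().rename(
        columns={"log_fc": "logFC", "t_stat": "t", "p_value": "p"}
    )
    cols = ["feature_id", "logFC", "t", "p", "adj_p", "direction"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", index_col="feature_id")
    return tab.rename(columns={"logFC": "log_fc", "t": "t_stat", "p": "p_value"})
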