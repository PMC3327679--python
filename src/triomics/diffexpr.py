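"""Two-condition differential expression with empirical-Bayes moderation.

The model is the classic moderated t: per-feature ordinary two-sample
statistics (log fold change resistant vs sensitive, pooled residual
variance s2 on df = n1 + n2 - 2) are combined with a scaled
inverse-chi-square prior on the residual variance,

    s2 ~ s0^2 * chi2_df / df    given the true variance,
    prior: d0 degrees of freedom, scale s0^2,

giving the posterior variance  s~2 = (d0*s0^2 + df*s2) / (d0 + df)  and
the moderated statistic  t = logFC / sqrt(s~2 * (1/n1 + 1/n2))  with
d0 + df degrees of freedom.  (d0, s0^2) are estimated by matching the
mean and variance of log s2 to their theoretical values under the prior
(digamma/trigamma moment matching).

Layer-specific selection follows the study design: mRNA at FDR <= 0.01
and |logFC| >= 1; miRNA and protein at FDR <= 0.1 with no fold-change
gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_tables import ExpressionMatrix

__all__ = [
    "EBPrior",
    "SelectionThresholds",
    "LAYER_THRESHOLDS",
    "fit_two_group",
    "estimate_prior",
    "moderated_t",
    "bh_fdr",
    "select_differential",
    "ddct_fold_change",
    "ModeratedTTest",
    "DifferentialResults",
]


@dataclass(frozen=True)
class EBPrior:
    """Scaled inverse-chi-square prior on residual variances.

    d0 may be ``math.inf`` (all residual variances shrunk fully to
    s0_sq) and 0 is accepted as an explicit no-shrinkage override.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise ValueError(f"d0 must be >= 0 (or inf), got {self.d0}")
        if not self.s0_sq > 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class SelectionThresholds:
    """FDR cap and minimum absolute log2 fold change for calling DE."""

    fdr_max: float
    min_abs_logfc: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be non-negative")


LAYER_THRESHOLDS = {
    "mRNA": SelectionThresholds(fdr_max=0.01, min_abs_logfc=1.0),
    "miRNA": SelectionThresholds(fdr_max=0.1, min_abs_logfc=0.0),
    "protein": SelectionThresholds(fdr_max=0.1, min_abs_logfc=0.0),
}


# ---------------------------------------------------------------------------
# ordinary per-feature statistics


def fit_two_group(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature two-sample statistics, missing-aware.

    Returns a frame indexed by feature id with columns logFC (mean
    resistant minus mean sensitive), avg_expr, s2 (pooled residual
    variance), df (n1 + n2 - 2), n1, n2 and ``tested`` (False where a
    condition has fewer than 2 finite values; such features carry NaN
    statistics and are excluded from downstream inference).
    """
    res_mask = matrix.condition_mask("resistant")
    sen_mask = matrix.condition_mask("sensitive")
    if res_mask.sum() == 0 or sen_mask.sum() == 0:
        raise ValueError("matrix must contain samples of both conditions")
    X = matrix.values
    out = {}
    for name, mask in (("r", res_mask), ("s", sen_mask)):
        block = X[:, mask]
        finite = np.isfinite(block)
        n = finite.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, np.nansum(np.where(finite, block, 0), axis=1) / np.maximum(n, 1), np.nan)
            centered = np.where(finite, block - mean[:, None], 0.0)
            ss = (centered**2).sum(axis=1)
        out[name] = (n, mean, ss)
    n1, mean_r, ss_r = out["r"]
    n2, mean_s, ss_s = out["s"]
    tested = (n1 >= 2) & (n2 >= 2)
    df = np.where(tested, n1 + n2 - 2, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(tested, (ss_r + ss_s) / df, np.nan)
        logfc = np.where(tested, mean_r - mean_s, np.nan)
        avg = np.where(
            (n1 + n2) > 0,
            (np.nan_to_num(mean_r * n1) + np.nan_to_num(mean_s * n2)) / np.maximum(n1 + n2, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "logFC": logfc,
            "avg_expr": avg,
            "s2": s2,
            "df": df,
            "n1": n1,
            "n2": n2,
            "tested": tested,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation (digamma/trigamma moment matching)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBPrior:
    """Estimate (d0, s0_sq) from observed residual variances.

    Matches mean and variance of log(s2) to the theoretical moments of
    log of a scaled F variate: if s2 | sigma^2 ~ sigma^2 chi2_df / df and
    1/sigma^2 ~ chi2_d0 / (d0 s0^2), then

        E[log s2]  = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
        Var[log s2] = psi'(df/2) + psi'(d0/2).

    d0 = +inf when the spread of log s2 does not exceed what sampling
    alone (psi'(df/2)) explains.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if df.ndim == 0:
        df = np.full_like(s2, float(df))
    ok = np.isfinite(s2) & np.isfinite(df) & (df > 0) & (s2 > 0)
    if not np.any(np.asarray(s2)[np.isfinite(s2)] > 0):
        raise ValueError("all residual variances are zero; prior not estimable")
    if ok.sum() < 10:
        raise ValueError(
            f"only {int(ok.sum())} positive finite variances; need >= 10"
        )
    z = np.log(s2[ok])
    half_df = df[ok] / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, half_df)))
    if excess <= 0:
        return EBPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return EBPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t


def moderated_t(fit: pd.DataFrame, prior: EBPrior) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    s~2 = (d0 s0^2 + df s2)/(d0 + df); t = logFC / sqrt(s~2 (1/n1 + 1/n2));
    p two-sided from t with d0 + df degrees of freedom.  d0 = 0 gives the
    ordinary pooled two-sample t; d0 = inf gives s~2 = s0^2 with a normal
    reference.
    """
    out = fit.copy()
    s2 = fit["s2"].to_numpy(dtype=float)
    df = fit["df"].to_numpy(dtype=float)
    logfc = fit["logFC"].to_numpy(dtype=float)
    n1 = fit["n1"].to_numpy(dtype=float)
    n2 = fit["n2"].to_numpy(dtype=float)
    v = 1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)
    tested = fit["tested"].to_numpy(dtype=bool)

    t_mod = np.full(len(fit), np.nan)
    p = np.full(len(fit), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if math.isinf(prior.d0):
            s_tilde = np.full(len(fit), prior.s0_sq)
            t_mod[tested] = logfc[tested] / np.sqrt(s_tilde[tested] * v[tested])
            p[tested] = 2.0 * stats.norm.sf(np.abs(t_mod[tested]))
        else:
            s_tilde = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
            t_mod[tested] = logfc[tested] / np.sqrt(s_tilde[tested] * v[tested])
            df_total = prior.d0 + df
            p[tested] = 2.0 * stats.t.sf(np.abs(t_mod[tested]), df_total[tested])
    out["s_tilde_sq"] = s_tilde
    out["t_mod"] = t_mod
    out["p"] = p
    return out


# ---------------------------------------------------------------------------
# BH adjustment and selection


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p[np.isfinite(p)] < 0) | (p[np.isfinite(p)] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def select_differential(
    results: pd.DataFrame, thresholds: SelectionThresholds
) -> pd.DataFrame:
    """Attach up/down/ns status from FDR and fold-change gates.

    Boundary values are significant ("<=" throughout): up iff
    fdr <= fdr_max and logFC >= min_abs_logfc, down symmetric.  With
    min_abs_logfc = 0 the sign of logFC alone sets the direction (logFC
    exactly 0 is ns).
    """
    out = results.copy()
    fdr = out["fdr"].to_numpy(dtype=float)
    logfc = out["logFC"].to_numpy(dtype=float)
    sig = np.isfinite(fdr) & (fdr <= thresholds.fdr_max)
    gate = max(thresholds.min_abs_logfc, np.finfo(float).tiny)
    up = sig & (logfc >= gate)
    down = sig & (logfc <= -gate)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    out["status"] = status
    return out


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative fold change by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    returns 2 ** (-ddCt).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# model / results objects


class ModeratedTTest:
    """Empirical-Bayes moderated two-sample t model for one omics layer.

    Parameters
    ----------
    matrix
        Log-scale expression with both conditions present (technical
        replicates collapsed upstream).

    Examples
    --------
    >>> model = ModeratedTTest(matrix)
    >>> res = model.fit()
    >>> res.summary()            # doctest: +SKIP
    >>> table = res.frame        # per-feature statistics
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        conditions: dict[str, str],
        layer: str = "mRNA",
    ) -> "ModeratedTTest":
        """Build from a features x samples frame and a sample->condition map."""
        from .io_tables import SampleMeta

        samples = []
        counters: dict[str, int] = {}
        for name in values.columns:
            if name not in conditions:
                raise ValueError(f"sample {name!r} missing from condition map")
            cond = conditions[name]
            counters[cond] = counters.get(cond, 0) + 1
            samples.append(
                SampleMeta(name=name, condition=cond, bio_rep=counters[cond], tech_rep=1)
            )
        matrix = ExpressionMatrix(
            layer, list(values.index.astype(str)), samples, values.to_numpy(float)
        )
        return cls(matrix)

    def fit(
        self,
        prior: EBPrior | None = None,
        thresholds: SelectionThresholds | None = None,
    ) -> "DifferentialResults":
        """Fit per-feature statistics, estimate the prior, moderate, adjust.

        ``prior=None`` estimates (d0, s0^2) from the data; pass an
        explicit :class:`EBPrior` to override (d0 = 0 recovers the
        ordinary t).  ``thresholds=None`` uses the layer default.
        """
        fit = fit_two_group(self.matrix)
        if prior is None:
            prior = estimate_prior(
                fit.loc[fit["tested"], "s2"].to_numpy(),
                fit.loc[fit["tested"], "df"].to_numpy(),
            )
        table = moderated_t(fit, prior)
        fdr = np.full(len(table), np.nan)
        tested = table["tested"].to_numpy(dtype=bool)
        fdr[tested] = bh_fdr(table.loc[tested, "p"].to_numpy())
        table["fdr"] = fdr
        if thresholds is None:
            thresholds = LAYER_THRESHOLDS[self.matrix.layer]
        table = select_differential(table, thresholds)
        return DifferentialResults(self, prior, thresholds, table)


class DifferentialResults:
    """Results of :meth:`ModeratedTTest.fit`.

    Attributes
    ----------
    frame
        Per-feature table: logFC, avg_expr, s2, df, s_tilde_sq, t_mod,
        p, fdr, status.
    prior
        The (d0, s0_sq) empirical-Bayes prior used.
    """

    def __init__(
        self,
        model: ModeratedTTest,
        prior: EBPrior,
        thresholds: SelectionThresholds,
        frame: pd.DataFrame,
    ):
        self.model = model
        self.prior = prior
        self.thresholds = thresholds
        self.frame = frame

    @property
    def layer(self) -> str:
        return self.model.matrix.layer

    def status_of(self) -> dict[str, str]:
        return dict(zip(self.frame.index, self.frame["status"]))

    def logfc_of(self) -> dict[str, float]:
        return dict(zip(self.frame.index, self.frame["logFC"]))

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] != "ns"]

    def n_up(self) -> int:
        return int((self.frame["status"] == "up").sum())

    def n_down(self) -> int:
        return int((self.frame["status"] == "down").sum())

    def to_table(self) -> pd.DataFrame:
        """Export table with the columns the pipeline writes to disk."""
        cols = ["logFC", "avg_expr", "t_mod", "p", "fdr", "status"]
        return self.frame[cols].copy()

    def save(self, path) -> None:
        df = self.to_table()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")

    def summary(self) -> str:
        d0 = "inf" if math.isinf(self.prior.d0) else f"{self.prior.d0:.3f}"
        lines = [
            f"Moderated t-test summary — layer: {self.layer}",
            f"  features tested : {int(self.frame['tested'].sum())} of {len(self.frame)}",
            f"  prior           : d0 = {d0}, s0^2 = {self.prior.s0_sq:.5g}",
            (
                f"  thresholds      : FDR <= {self.thresholds.fdr_max}, "
                f"|logFC| >= {self.thresholds.min_abs_logfc}"
            ),
            f"  up / down / ns  : {self.n_up()} / {self.n_down()} / "
            f"{int((self.frame['status'] == 'ns').sum())}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DifferentialResults layer={self.layer} "
            f"up={self.n_up()} down={self.n_down()}>"
        )
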