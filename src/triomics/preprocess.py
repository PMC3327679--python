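"""Background correction, normalization and low-signal filtering.

Three array platforms are handled:

* two-color 44K gene arrays — background-subtracted log-ratios, lowess
  (MA) normalization;
* 725-antibody two-color arrays — normexp background correction and a
  rank-invariant normalization of the log-ratios;
* single-channel miRNA arrays — a variance-stabilizing (affine + arsinh,
  "generalized log") transform.

All functions operate on plain numpy vectors/matrices or the containers
from :mod:`triomics.io_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_tables import ExpressionMatrix, SampleMeta, TwoColorArraySet

__all__ = [
    "NormexpParams",
    "FilterReport",
    "normexp_correct",
    "estimate_normexp_params",
    "lowess_normalize",
    "vsn_like_normalize",
    "rank_invariant_normalize",
    "filter_low_signal",
    "collapse_replicates",
    "two_color_to_channels",
]


# ---------------------------------------------------------------------------
# normexp background correction


@dataclass(frozen=True)
class NormexpParams:
    """Parameters of the normal(background) + exponential(signal) model.

    mu, sigma
        Mean and sd of the additive background.
    alpha
        Mean of the exponential signal component.
    offset
        Constant added after correction to damp low-intensity ratio
        variance (default 16, a common practice value).
    """

    mu: float
    sigma: float
    alpha: float
    offset: float = 16.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


def estimate_normexp_params(
    fg: np.ndarray, bg: np.ndarray, offset: float = 16.0
) -> NormexpParams:
    """Method-of-moments fit of the normexp model.

    (mu, sigma) from the local-background distribution, alpha from the
    mean background-subtracted foreground.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    ok = np.isfinite(fg) & np.isfinite(bg)
    if ok.sum() < 4:
        raise ValueError("need at least 4 finite (fg, bg) pairs to estimate normexp")
    mu = float(np.mean(bg[ok]))
    sigma = float(np.std(bg[ok], ddof=1))
    sigma = max(sigma, 1e-6)
    alpha = float(np.mean(fg[ok] - bg[ok]))
    alpha = max(alpha, 1e-6)
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha, offset=offset)


def _normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """E[S | X = x] for X = B + S, B ~ N(mu, sigma^2), S ~ Exp(mean alpha).

    Equals the mean of a normal N(mu_sf, sigma^2) truncated to (0, inf)
    with mu_sf = x - mu - sigma^2/alpha, hence strictly positive.
    Evaluated through log_ndtr for stability deep in the left tail.
    """
    x = np.asarray(x, dtype=float)
    mu_sf = x - mu - sigma**2 / alpha
    z = mu_sf / sigma
    # phi(z)/Phi(z) via logs; for z << 0 use the asymptotic ratio -z.
    log_phi = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
    log_Phi = log_ndtr(z)
    ratio = np.exp(np.clip(log_phi - log_Phi, None, 700.0))
    out = mu_sf + sigma * ratio
    # truncated-normal mean is positive by construction; guard underflow
    return np.maximum(out, 1e-12)


def normexp_correct(
    fg: np.ndarray,
    bg: np.ndarray,
    params: NormexpParams | str = "estimate",
) -> np.ndarray:
    """Normexp background correction of foreground intensities.

    Returns ``E[signal | observed foreground] + offset`` under the
    normal-plus-exponential convolution model; all outputs are strictly
    positive, so log-ratios are always defined.  With ``"estimate"``
    (the default) parameters are fit per array by method of moments.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.shape != bg.shape:
        raise ValueError("fg and bg must have the same shape")
    if isinstance(params, str):
        if params != "estimate":
            raise ValueError(f"params must be NormexpParams or 'estimate', got {params!r}")
        params = estimate_normexp_params(fg, bg)
    return _normexp_signal(fg, params.mu, params.sigma, params.alpha) + params.offset


# ---------------------------------------------------------------------------
# lowess (MA) normalization


def lowess_normalize(
    log_ratio_M: np.ndarray,
    mean_log_A: np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
) -> np.ndarray:
    """Remove the intensity-dependent trend from log-ratios.

    Fits a robust lowess curve of M on A and returns the residuals
    M - fit(A).  Positions where either M or A is missing pass through
    unchanged.
    """
    M = np.asarray(log_ratio_M, dtype=float)
    A = np.asarray(mean_log_A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    ok = np.isfinite(M) & np.isfinite(A)
    if ok.sum() < 10:
        raise ValueError(
            f"only {int(ok.sum())} finite (M, A) pairs; need >= 10 for a lowess fit"
        )
    fitted = _sm_lowess(
        M[ok], A[ok], frac=span, it=iterations, return_sorted=False
    )
    out = M.copy()
    out[ok] = M[ok] - fitted
    return out


# ---------------------------------------------------------------------------
# variance-stabilizing transform for single-channel intensities


def vsn_like_normalize(matrix: ExpressionMatrix, cofactor: float | None = None) -> ExpressionMatrix:
    """Affine calibration + arsinh (generalized log) transform.

    Each sample is calibrated to the first sample by matching its first
    and third quartiles (an affine map), then ``glog2(y) = log2(y +
    sqrt(y^2 + c^2)) - 1`` is applied, which behaves like log2 for large
    intensities while damping the variance of near-background values.
    The cofactor ``c`` defaults to an estimate of the additive noise
    scale from the mean-variance relationship across samples.
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("matrix has no samples")
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(~np.isfinite(col) | (col == 0)):
            raise ValueError(
                f"sample {matrix.samples[j].name!r} has all-zero intensities"
            )
    # affine quartile-matching calibration to the first sample
    q1_ref, q3_ref = np.nanpercentile(X[:, 0], [25, 75])
    calibrated = np.empty_like(X)
    for j in range(X.shape[1]):
        q1, q3 = np.nanpercentile(X[:, j], [25, 75])
        scale = (q3_ref - q1_ref) / (q3 - q1) if q3 > q1 else 1.0
        calibrated[:, j] = q1_ref + scale * (X[:, j] - q1)
    if cofactor is None:
        cofactor = _estimate_glog_cofactor(calibrated)
    y = calibrated
    transformed = np.log2(y + np.sqrt(y * y + cofactor**2)) - 1.0
    return ExpressionMatrix(
        matrix.layer, matrix.feature_ids, matrix.samples, transformed
    )


def _estimate_glog_cofactor(X: np.ndarray) -> float:
    """Additive-noise scale from the variance-mean relationship.

    Under intensity = additive noise + signal * multiplicative noise,
    var across replicates ~ a + b * mean^2 and the stabilizing cofactor
    is sqrt(a / b).  a is taken as the median replicate variance in the
    lowest-intensity decile (additive noise dominates there) and b as
    the median of var/mean^2 in the top decile (multiplicative noise
    dominates); the chi-square small-sample bias of the variances
    cancels in the ratio.  Falls back to the lower quartile of the data
    when either estimate is degenerate (e.g. a single replicate).
    """
    m = np.nanmean(X, axis=1)
    with np.errstate(invalid="ignore"):
        v = np.nanvar(X, axis=1, ddof=1)
    ok = np.isfinite(m) & np.isfinite(v) & (m > 0)
    m, v = m[ok], v[ok]
    fallback = max(float(np.nanpercentile(X, 25)), 1.0)
    if m.size < 20:
        return fallback
    lo_cut, hi_cut = np.quantile(m, [0.1, 0.9])
    a = float(np.median(v[m <= lo_cut]))
    hi = m >= hi_cut
    b = float(np.median(v[hi] / m[hi] ** 2))
    if a <= 0 or b <= 0:
        return fallback
    c0 = float(np.sqrt(a / b))
    return _refine_glog_cofactor(X, c0)


def _refine_glog_cofactor(X: np.ndarray, c0: float) -> float:
    """Grid-refine the cofactor by maximizing variance flatness.

    The moment estimate is only as good as the additive+multiplicative
    model; the final cofactor is chosen from a log-grid around it to
    minimize the spread of replicate-residual scale across intensity
    strata — the quantity variance stabilization is meant to flatten.
    Requires >= 3 replicate columns to see residuals; otherwise the
    moment estimate is returned as is.
    """
    ok = np.all(np.isfinite(X), axis=1)
    if X.shape[1] < 3 or ok.sum() < 100:
        return c0
    Xf, mf = X[ok], np.mean(X[ok], axis=1)
    strata = np.clip(
        np.searchsorted(np.quantile(mf, [0.25, 0.5, 0.75]), mf), 0, 3
    )
    best_c, best_obj = c0, np.inf
    for c in c0 * np.geomspace(0.2, 5.0, 17):
        h = np.log2(Xf + np.sqrt(Xf * Xf + c * c))
        resid = h - h.mean(axis=1, keepdims=True)
        scale = np.array(
            [np.median(np.abs(resid[strata == s])) for s in range(4)]
        )
        if np.any(scale <= 0):
            continue
        obj = float(scale.max() / scale.min())
        if obj < best_obj:
            best_obj, best_c = obj, float(c)
    return best_c


# ---------------------------------------------------------------------------
# rank-invariant normalization (antibody arrays)


def rank_invariant_normalize(
    ch1: np.ndarray,
    ch2: np.ndarray,
    rank_tolerance: float = 0.05,
    max_iterations: int = 10,
    span: float = 0.5,
) -> np.ndarray:
    """Normalize log2(ch2/ch1) through a rank-invariant feature subset.

    Features whose within-channel ranks differ by less than
    ``rank_tolerance`` (as a fraction of the subset size) are assumed
    unchanged between channels; the selection is iterated on the
    shrinking subset until stable.  A lowess curve of the log-ratio on
    the average log-intensity fitted through that subset is subtracted
    from all features.
    """
    x1 = np.asarray(ch1, dtype=float)
    x2 = np.asarray(ch2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("channels must have the same length")
    if x1.size < 20:
        raise ValueError(f"need >= 20 features, got {x1.size}")
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("channel intensities must be strictly positive")

    M = np.log2(x2 / x1)
    A = 0.5 * (np.log2(x1) + np.log2(x2))

    selected = np.arange(x1.size)
    for _ in range(max_iterations):
        r1 = stats.rankdata(x1[selected])
        r2 = stats.rankdata(x2[selected])
        keep = np.abs(r1 - r2) / selected.size < rank_tolerance
        new = selected[keep]
        if new.size < 10:
            raise ValueError(
                f"rank-invariant set has only {new.size} features; "
                "fall back to lowess normalization"
            )
        if new.size == selected.size:
            selected = new
            break
        selected = new

    if np.ptp(A[selected]) < 1e-12:
        # invariant set at a single intensity: constant correction
        curve = np.full_like(M, np.median(M[selected]))
    else:
        order = np.argsort(A[selected])
        a_fit = A[selected][order]
        m_fit = _sm_lowess(
            M[selected][order], a_fit, frac=span, it=2, return_sorted=False
        )
        curve = np.interp(A, a_fit, m_fit)
    return M - curve


# ---------------------------------------------------------------------------
# low-signal filter


@dataclass
class FilterReport:
    """Outcome of the signal-to-background filter.

    A feature is removed iff its foreground falls below the local
    background in strictly more than ``max_fraction`` of the arrays in
    which it was measured.
    """

    kept: set[str]
    removed: set[str]
    below_fraction: dict[str, float]
    max_fraction: float

    def __post_init__(self) -> None:
        if self.kept & self.removed:
            raise ValueError("kept and removed sets overlap")


def filter_low_signal(
    feature_ids,
    fg: np.ndarray,
    bg: np.ndarray,
    max_fraction: float = 0.6,
) -> FilterReport:
    """Remove features mostly below their local background.

    ``fg`` and ``bg`` are features x arrays matrices (NaN = feature not
    measured on that array).  The fraction uses only arrays where the
    feature is present; the removal rule is strict (> max_fraction), so
    a feature below background in exactly 60% of arrays is kept under
    the default.
    """
    if not 0 <= max_fraction <= 1:
        raise ValueError(f"max_fraction must be in [0, 1], got {max_fraction}")
    fg = np.atleast_2d(np.asarray(fg, dtype=float))
    bg = np.atleast_2d(np.asarray(bg, dtype=float))
    if fg.shape != bg.shape or fg.shape[0] != len(feature_ids):
        raise ValueError("fg/bg must be features x arrays matrices matching feature_ids")
    present = np.isfinite(fg) & np.isfinite(bg)
    below = (fg < bg) & present
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_present > 0, below.sum(axis=1) / np.maximum(n_present, 1), 0.0)
    kept, removed, per_feature = set(), set(), {}
    for fid, f in zip(feature_ids, frac):
        per_feature[fid] = float(f)
        (removed if f > max_fraction else kept).add(fid)
    return FilterReport(kept, removed, per_feature, max_fraction)


# ---------------------------------------------------------------------------
# technical-replicate collapse


def collapse_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average technical replicates into one column per biological replicate.

    Log-ratio columns (dye != none) are first sign-flipped to the common
    orientation (positive = resistant over sensitive, i.e. as measured
    with the resistant sample on Cy5); dye-swapped columns (dye == Cy3)
    flip sign.  Averaging is missing-aware.  Groups are (condition,
    bio_rep); dye annotation within a group must be consistent in the
    sense of mapping to one orientation per column, which is always
    satisfiable, but a group mixing 'none' with dye-labelled columns is
    rejected.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault((s.condition, s.bio_rep), []).append(j)

    oriented = matrix.values.copy()
    for j, s in enumerate(matrix.samples):
        if s.dye == "Cy3":
            oriented[:, j] = -oriented[:, j]

    new_samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for (condition, bio_rep), idx in sorted(groups.items()):
        dyes = {matrix.samples[j].dye for j in idx}
        if "none" in dyes and len(dyes) > 1:
            raise ValueError(
                f"group (condition={condition}, bio_rep={bio_rep}) mixes "
                "single-channel and log-ratio columns"
            )
        block = oriented[:, idx]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(block, axis=1)
        cols.append(mean)
        out_dye = "none" if dyes == {"none"} else "Cy5"
        new_samples.append(
            SampleMeta(
                name=f"{condition}_b{bio_rep}",
                condition=condition,
                bio_rep=bio_rep,
                tech_rep=1,
                dye=out_dye,
            )
        )
    return ExpressionMatrix(
        matrix.layer, matrix.feature_ids, new_samples, np.column_stack(cols)
    )


# ---------------------------------------------------------------------------
# two-color helpers


def two_color_to_channels(
    arrays: TwoColorArraySet,
    normalized_M: np.ndarray,
    A: np.ndarray,
) -> ExpressionMatrix:
    """Split normalized two-color arrays into per-channel log2 columns.

    Given per-array normalized log-ratios M (channel2 over channel1) and
    average log-intensities A, each array contributes two samples,
    ``A - M/2`` for channel 1 and ``A + M/2`` for channel 2, labelled
    with the channel's condition.  This puts two-color data into the
    same two-group layout as single-channel data, so the downstream
    moderated-t fit is uniform across layers.
    """
    normalized_M = np.asarray(normalized_M, dtype=float)
    A = np.asarray(A, dtype=float)
    expected = (arrays.n_features, arrays.n_arrays)
    if normalized_M.shape != expected or A.shape != expected:
        raise ValueError(f"M and A must have shape {expected}")
    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for k, arr in enumerate(arrays.arrays):
        ch1 = A[:, k] - normalized_M[:, k] / 2.0
        ch2 = A[:, k] + normalized_M[:, k] / 2.0
        for value, condition, dye in (
            (ch1, arr.condition_of_channel1, arr.dye_of_channel1),
            (ch2, arr.condition_of_channel2, arr.dye_of_channel2),
        ):
            samples.append(
                SampleMeta(
                    name=f"{condition}_b{arr.bio_rep}_t{arr.tech_rep}",
                    condition=condition,
                    bio_rep=arr.bio_rep,
                    tech_rep=arr.tech_rep,
                    dye="none",
                )
            )
            cols.append(value)
    return ExpressionMatrix(
        arrays.layer, arrays.feature_ids, samples, np.column_stack(cols)
    )
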