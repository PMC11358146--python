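"""Covariate-controlled correlations, FDR control and bootstrap mediation.

The statistical backbone of the analysis:

* :func:`partial_pearson` — Pearson correlation of two variables after
  residualising both on a covariate set (age, gender, music background in the
  canonical analysis), with a t-reference p-value on n - 2 - q degrees of
  freedom.
* :func:`fdr_bh` — Benjamini-Hochberg step-up false-discovery-rate control.
* :func:`mediate` — the simple mediation model IV -> M -> DV on z-scored
  variables: a (IV->M), b and c' (DV on M and IV jointly), total effect c,
  indirect effect ab = a*b with a percentile-bootstrap confidence interval
  over case resampling.  "Full mediation" is reported when the ab interval
  excludes zero, c is significant and c' is not.
* :func:`median_split` — low/high grouping at the sample median (high means
  score >= median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PartialCorrResult",
    "MediationResult",
    "partial_pearson",
    "fdr_bh",
    "mediate",
    "median_split",
]


@dataclass(frozen=True)
class PartialCorrResult:
    x_name: str
    y_name: str
    covariate_names: tuple[str, ...]
    n: int
    r: float
    p: float
    p_fdr: float | None = None


@dataclass(frozen=True)
class MediationResult:
    """Standardized mediation paths with a percentile-bootstrap CI on ab."""

    a: float
    b: float
    ab: float
    c_prime: float
    c_total: float
    p_a: float
    p_b: float
    p_c_prime: float
    p_c_total: float
    ci_ab: tuple[float, float]
    n: int
    n_boot: int
    ci_level: float
    seed: int | None
    full_mediation: bool


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (x - x.mean()) / sd


def partial_pearson(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrResult:
    """Partial Pearson correlation of ``x`` and ``y`` given ``covariates``.

    Both variables are residualised on the covariates plus an intercept by
    least squares; the correlation of the residuals is tested two-sided
    against a t distribution with ``n - 2 - q`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        if z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    q = z.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 observations (n={n}, q={q})")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    proj, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ proj
    if resid[:, 0].std() == 0 or resid[:, 1].std() == 0:
        raise ValueError("zero residual variance after covariate adjustment")
    r = float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])
    df = n - 2 - q
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(
        x_name=x_name,
        y_name=y_name,
        covariate_names=tuple(covariate_names),
        n=n,
        r=r,
        p=p,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejection mask, adjusted p-values) at level ``q``; adjusted
    p-values follow the standard monotone min-cummin construction.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _boot_paths(x, m, d, idx):
    """Standardized a, b, ab for each bootstrap resample (rows of idx)."""
    xb, mb, db = x[idx], m[idx], d[idx]
    n = idx.shape[1]

    def crosscorr(u, v):
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        num = np.einsum("bn,bn->b", uc, vc)
        den = np.sqrt(np.einsum("bn,bn->b", uc, uc) * np.einsum("bn,bn->b", vc, vc))
        return num, den

    nxm, dxm = crosscorr(xb, mb)
    nmd, dmd = crosscorr(mb, db)
    nxd, dxd = crosscorr(xb, db)
    bad = (dxm == 0) | (dmd == 0) | (dxd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_xm = np.where(bad, np.nan, nxm / dxm)
        r_md = np.where(bad, np.nan, nmd / dmd)
        r_xd = np.where(bad, np.nan, nxd / dxd)
        denom = 1.0 - r_xm**2
        collinear = denom < 1e-12
        a = r_xm
        b = np.where(collinear, r_md / np.where(r_xm == 0, 1.0, r_xm), (r_md - r_xd * r_xm) / denom)
    return a, b, a * b, bad


def mediate(
    iv,
    m,
    dv,
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int | None = None,
    alpha: float = 0.05,
    _boot_chunk: int = 512,
) -> MediationResult:
    """Simple mediation IV -> M -> DV with a percentile-bootstrap CI on ab.

    All three variables are z-scored; a is the slope of M on IV, b and c' come
    from the joint regression of DV on M and IV, and c from DV on IV, so the
    point estimates satisfy c = c' + a*b exactly.  The CI resamples cases with
    replacement ``n_boot`` times (paths re-standardised within each resample);
    degenerate resamples (zero variance) are redrawn, erroring if more than
    10% need redrawing.  If IV and M are (numerically) collinear the shared
    effect is attributed to the mediator: b = r(M, DV)/r(IV, M), c' = 0.
    """
    x = np.asarray(iv, dtype=float).ravel()
    med = np.asarray(m, dtype=float).ravel()
    d = np.asarray(dv, dtype=float).ravel()
    n = x.size
    if med.size != n or d.size != n:
        raise ValueError("iv, m and dv must have equal length")
    if n < 10:
        raise ValueError("mediation needs n >= 10")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    zx = _zscore(x, "iv")
    zm = _zscore(med, "m")
    zd = _zscore(d, "dv")

    r_xm = float(zx @ zm / (n - 1))
    r_md = float(zm @ zd / (n - 1))
    r_xd = float(zx @ zd / (n - 1))
    denom = 1.0 - r_xm**2
    a = r_xm
    c_total = r_xd
    if denom < 1e-12:  # M is an affine image of IV; credit the path to M
        b = r_md / r_xm
        c_prime = 0.0
        p_b = float("nan")
        p_c_prime = float("nan")
    else:
        b = (r_md - r_xd * r_xm) / denom
        c_prime = (r_xd - r_md * r_xm) / denom
        r2 = (r_md**2 + r_xd**2 - 2 * r_xm * r_md * r_xd) / denom
        r2 = min(r2, 1.0 - 1e-15)
        se = np.sqrt((1.0 - r2) / ((n - 3) * denom))
        p_b = float(2 * stats.t.sf(abs(b / se), n - 3))
        p_c_prime = float(2 * stats.t.sf(abs(c_prime / se), n - 3))

    def corr_p(r, df):
        r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r * np.sqrt(df / (1.0 - r**2))
        return float(2 * stats.t.sf(abs(t), df))

    p_a = corr_p(a, n - 2)
    p_c_total = corr_p(c_total, n - 2)

    rng = np.random.default_rng(seed)
    ab_samples = np.empty(n_boot)
    filled = 0
    redraws = 0
    while filled < n_boot:
        want = min(_boot_chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(want, n))
        _, _, ab_b, bad = _boot_paths(zx, zm, zd, idx)
        good = ~bad
        take = ab_b[good]
        redraws += int(bad.sum())
        if redraws > 0.1 * n_boot:
            raise ValueError("more than 10% of bootstrap resamples were degenerate")
        ab_samples[filled : filled + take.size] = take
        filled += take.size
    lo_q = (1.0 - ci_level) / 2.0
    ci = (
        float(np.quantile(ab_samples, lo_q)),
        float(np.quantile(ab_samples, 1.0 - lo_q)),
    )
    ab = a * b
    excludes_zero = ci[0] > 0 or ci[1] < 0
    full = bool(
        excludes_zero
        and p_c_total < alpha
        and (np.isnan(p_c_prime) or p_c_prime >= alpha)
    )
    return MediationResult(
        a=a,
        b=b,
        ab=ab,
        c_prime=c_prime,
        c_total=c_total,
        p_a=p_a,
        p_b=p_b,
        p_c_prime=p_c_prime,
        p_c_total=p_c_total,
        ci_ab=ci,
        n=n,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        full_mediation=full,
    )


def median_split(scores) -> np.ndarray:
    """Label each score ``low``/``high`` about the sample median (high: >= median)."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("median split needs at least 2 scores")
    med = np.median(s)
    return np.where(s >= med, "high", "low")
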