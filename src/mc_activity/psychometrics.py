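"""Psychometric validation battery for the MCSQ and MCS.

Implements the classical instrument-validation toolkit:

* factorability diagnostics -- Bartlett's test of sphericity and the
  Kaiser-Meyer-Olkin (KMO) measure of sampling adequacy;
* factor-count selection by parallel analysis;
* exploratory factor analysis with minimum-residual (minres) extraction and
  promax (oblique) rotation;
* internal consistency (Cronbach's alpha);
* test-retest reliability as ICC(2,k), the two-way random-effects,
  absolute-agreement, average-measures intraclass correlation, with the
  F-distribution confidence interval;
* responsiveness via paired Wilcoxon signed-rank tests with Bonferroni
  correction;
* convergent-validity correlation hypotheses (|r| >= 0.4 with the expected
  sign, Pearson or Spearman per variable-pair policy).

Extraction and rotation are implemented here (minres via bounded
quasi-Newton optimization of the uniquenesses, promax as a power-4 oblique
target rotation of the varimax solution); the test-suite cross-checks them
against statsmodels' factor-analysis machinery, and alpha/ICC against
pingouin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorModel",
    "ReliabilityResult",
    "ResponsivenessResult",
    "CorrelationHypothesis",
    "bartlett_sphericity",
    "kmo",
    "parallel_analysis",
    "efa",
    "varimax",
    "promax",
    "cronbach_alpha",
    "icc2k",
    "responsiveness_battery",
    "validity_correlations",
]


# ---------------------------------------------------------------------------
# Factorability
# ---------------------------------------------------------------------------

def bartlett_sphericity(correlation_matrix, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: H0 the correlation matrix is identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R),  df = p(p-1)/2.
    """
    r = np.asarray(correlation_matrix, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is singular or not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def kmo(correlation_matrix) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall KMO and per-item MSA.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.  Values >= 0.6 are conventionally deemed factorable.
    """
    r = np.asarray(correlation_matrix, dtype=float)
    p = r.shape[0]
    rinv = np.linalg.inv(r)
    d = 1.0 / np.sqrt(np.diag(rinv))
    partial = -rinv * np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = r[off] ** 2
    q2 = partial[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    msa = np.array(
        [
            (r[i, off[i]] ** 2).sum()
            / ((r[i, off[i]] ** 2).sum() + (partial[i, off[i]] ** 2).sum())
            for i in range(p)
        ]
    )
    return overall, msa


def parallel_analysis(
    data,
    n_reps: int = 500,
    quantile: float = 0.95,
    seed: int | None = None,
) -> int:
    """Suggested factor count by parallel analysis.

    Compares the eigenvalues of the observed correlation matrix against the
    chosen quantile of eigenvalues from column-permuted null data (which
    preserves the marginals while destroying all correlation).  The count is
    the leading run of observed eigenvalues exceeding their null quantile.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, p))
    for rep in range(n_reps):
        perm = np.column_stack([rng.permutation(x[:, j]) for j in range(p)])
        null[rep] = np.sort(np.linalg.eigvalsh(np.corrcoef(perm, rowvar=False)))[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    exceed = obs > thresh
    count = 0
    for flag in exceed:
        if not flag:
            break
        count += 1
    return count


# ---------------------------------------------------------------------------
# Exploratory factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    n_factors: int
    loadings: pd.DataFrame          # item x factor (rotated if requested)
    communalities: pd.Series
    uniquenesses: pd.Series
    eigenvalues: np.ndarray         # of the correlation matrix
    phi: np.ndarray                 # factor intercorrelations (identity if unrotated)
    rmsr: float                     # root-mean-square off-diagonal residual
    rotation: str
    heywood: bool = False


def _minres_loadings(r: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    """Loadings given uniquenesses: top-m eigenpairs of R - diag(psi)."""
    rr = r.copy()
    np.fill_diagonal(rr, 1.0 - psi)
    vals, vecs = np.linalg.eigh(rr)
    idx = np.argsort(vals)[::-1][:m]
    vals = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _minres_objective(psi: np.ndarray, r: np.ndarray, m: int) -> float:
    lam = _minres_loadings(r, psi, m)
    resid = r - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float((resid ** 2).sum()) / 2.0


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax rotation; returns (rotated, rotation matrix)."""
    lam = np.asarray(loadings, dtype=float).copy()
    p, m = lam.shape
    if m < 2:
        return lam, np.eye(m)
    norms = np.sqrt((lam ** 2).sum(axis=1)) if normalize else np.ones(p)
    norms[norms == 0] = 1.0
    lam = lam / norms[:, None]
    rot = np.eye(m)
    var = 0.0
    for _ in range(max_iter):
        z = lam @ rot
        b = lam.T @ (z ** 3 - z * (z ** 2).mean(axis=0))
        u, s, vt = np.linalg.svd(b)
        rot = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    lam = (lam @ rot) * norms[:, None]
    return lam, rot


def promax(loadings: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax followed by a power-``power`` target).

    Returns (pattern loadings, factor intercorrelation matrix phi).  Follows
    the classical construction: regress the varimax solution onto its
    sign-preserving |loading|^power target, rescale the transform so the
    implied factor covariance has unit diagonal.
    """
    x, _ = varimax(np.asarray(loadings, dtype=float))
    if x.shape[1] < 2:
        return x, np.eye(x.shape[1])
    q = x * np.abs(x) ** (power - 1)
    u = np.linalg.lstsq(x, q, rcond=None)[0]
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)
    z = x @ u
    phi = np.linalg.inv(u.T @ u)
    return z, phi


def _fix_sign_order(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic output convention: factors ordered by explained sum of
    squares (descending), each factor's loading sum made non-negative."""
    ss = (lam ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    lam = lam[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    lam = lam * signs
    phi = phi * np.outer(signs, signs)
    return lam, phi


def efa(
    data=None,
    n_factors: int = 1,
    rotation: str = "promax",
    *,
    corr=None,
    item_names: Sequence[str] | None = None,
    n_obs: int | None = None,
) -> FactorModel:
    """Exploratory factor analysis with minres extraction.

    ``data`` is an observations x items table (a correlation matrix may be
    supplied directly via ``corr``).  Extraction minimizes the sum of squared
    off-diagonal residuals of R - Lambda Lambda' over the uniquenesses
    (minimum-residual / minres).  ``rotation`` is ``"none"`` or ``"promax"``
    (power 4).  Heywood cases (communalities > 1) are clamped and flagged.
    """
    if corr is None:
        frame = pd.DataFrame(data)
        item_names = item_names or [str(c) for c in frame.columns]
        r = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
        n_obs = len(frame)
    else:
        r = np.asarray(corr, dtype=float)
        item_names = item_names or [f"item{i + 1}" for i in range(r.shape[0])]
    p = r.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be >= 1 and smaller than the number of items")
    if n_obs is not None and n_obs > p:
        _, _, bart_p = bartlett_sphericity(r, n_obs)
        overall_kmo, _ = kmo(r)
        if bart_p >= 0.05 or overall_kmo < 0.6:
            warnings.warn(
                f"data may not be factorable (Bartlett p={bart_p:.3g}, KMO={overall_kmo:.3f})"
            )
    eigenvalues = np.sort(np.linalg.eigvalsh(r))[::-1]

    # start at 1 - SMC (squared multiple correlations)
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    psi0 = np.clip(1.0 - smc, 0.005, 1.0)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(r, n_factors),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-10},
    )
    lam = _minres_loadings(r, res.x, n_factors)
    heywood = False
    commun = (lam ** 2).sum(axis=1)
    if (commun > 1.0 + 1e-8).any():
        heywood = True
        warnings.warn("Heywood case: communality > 1; clamping")
        scale = np.minimum(1.0, 1.0 / np.sqrt(np.maximum(commun, 1e-12)))
        lam = lam * scale[:, None]
        commun = (lam ** 2).sum(axis=1)

    resid = r - lam @ lam.T
    off = ~np.eye(p, dtype=bool)
    rmsr = float(np.sqrt((resid[off] ** 2).mean()))

    if rotation == "none":
        lam_out, phi = _fix_sign_order(lam, np.eye(n_factors))
    elif rotation == "promax":
        lam_out, phi = promax(lam)
        lam_out, phi = _fix_sign_order(lam_out, phi)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    factors = [f"F{i + 1}" for i in range(n_factors)]
    return FactorModel(
        n_factors=n_factors,
        loadings=pd.DataFrame(lam_out, index=list(item_names), columns=factors),
        communalities=pd.Series(commun, index=list(item_names)),
        uniquenesses=pd.Series(1.0 - commun, index=list(item_names)),
        eigenvalues=eigenvalues,
        phi=phi,
        rmsr=rmsr,
        rotation=rotation,
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    x = pd.DataFrame(item_matrix).dropna().to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha needs >= 2 items")
    if n < 3:
        raise ValueError("alpha needs >= 3 observations")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_occasions: int


def icc2k(matrix, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``matrix`` is subjects x occasions; rows with any missing value are
    dropped (listwise deletion).  The point estimate is
    (MSR - MSE) / (MSR + (MSC - MSE)/n) from the two-way ANOVA mean squares;
    the 95% CI uses the F-distribution method (single-measure bounds with
    Satterthwaite degrees of freedom, stepped up by Spearman-Brown).
    """
    x = pd.DataFrame(matrix).dropna().to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("ICC needs >= 2 occasions with complete data")
    if n < 5:
        raise ValueError("ICC needs >= 5 subjects with complete data")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc_k = (msr - mse) / (msr + (msc - mse) / n)

    # single-measure ICC(A,1) CI (McGraw & Wong), then Spearman-Brown step-up
    r1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * r1 / (n * (1.0 - r1)) if r1 < 1 else np.inf
    b = 1.0 + k * r1 * (n - 1) / (n * (1.0 - r1)) if r1 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:  # degenerate perfect agreement
        lo1 = hi1 = 1.0

    def step_up(r: float) -> float:
        return k * r / (1.0 + (k - 1) * r)

    return ReliabilityResult(
        icc=float(icc_k),
        ci_low=float(step_up(lo1)),
        ci_high=float(step_up(hi1)),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        k_occasions=k,
    )


# ---------------------------------------------------------------------------
# Responsiveness
# ---------------------------------------------------------------------------

@dataclass
class ResponsivenessResult:
    table: pd.DataFrame  # per item: statistic, p_raw, p_adjusted, direction, n_pairs, flag
    m_comparisons: int


def responsiveness_battery(
    baseline_items: pd.DataFrame,
    followup_items: pd.DataFrame,
    m_comparisons: int | None = None,
) -> ResponsivenessResult:
    """Paired Wilcoxon signed-rank test per item, baseline vs follow-up.

    Inputs are item tables indexed by patient id; only patients present at
    both timepoints enter.  The exact signed-rank null is used for <= 25
    informative pairs, the tie-corrected normal approximation above.
    Bonferroni adjustment multiplies by ``m_comparisons`` (default: the
    number of items tested).
    """
    base = pd.DataFrame(baseline_items)
    fup = pd.DataFrame(followup_items)
    common = base.index.intersection(fup.index)
    items = [c for c in base.columns if c in fup.columns]
    m = m_comparisons if m_comparisons is not None else len(items)
    rows = []
    for item in items:
        pair = pd.concat([base.loc[common, item], fup.loc[common, item]], axis=1).dropna()
        b, f = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        diff = f - b
        n_pairs = len(diff)
        n_nonzero = int((diff != 0).sum())
        if n_nonzero == 0:
            stat, p, flag = 0.0, 1.0, "no_change"
        else:
            method = "exact" if n_nonzero <= 25 and len(np.unique(np.abs(diff[diff != 0]))) == n_nonzero else "approx"
            res = stats.wilcoxon(b, f, zero_method="wilcox", method=method, correction=False)
            stat, p, flag = float(res.statistic), float(res.pvalue), ""
        direction = "decrease" if np.median(diff) < 0 else ("increase" if np.median(diff) > 0 else "none")
        rows.append(
            {
                "item": item,
                "statistic": stat,
                "p_raw": p,
                "p_adjusted": min(1.0, m * p),
                "direction": direction,
                "n_pairs": n_pairs,
                "flag": flag,
            }
        )
    return ResponsivenessResult(table=pd.DataFrame(rows).set_index("item"), m_comparisons=m)


# ---------------------------------------------------------------------------
# Convergent validity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationHypothesis:
    """One convergent-validity hypothesis: variables x and y should correlate
    with ``expected_sign`` at |r| >= ``threshold``; ``method`` is ``pearson``
    for interval pairs, ``spearman`` for ordinal ones."""

    x: str
    y: str
    expected_sign: int  # +1 or -1
    method: str = "pearson"
    threshold: float = 0.4


def validity_correlations(
    cohort: pd.DataFrame,
    hypotheses: Sequence[CorrelationHypothesis],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate correlation hypotheses on a cohort table.

    Returns a frame with the coefficient, raw and Bonferroni-adjusted p
    (m = number of hypotheses), and a ``met`` flag that is true when
    |r| >= threshold with the expected sign.  Constant columns yield an
    undefined correlation, flagged rather than raised.
    """
    m = len(hypotheses)
    rows = []
    for h in hypotheses:
        pair = cohort[[h.x, h.y]].dropna()
        x, y = pair[h.x].to_numpy(float), pair[h.y].to_numpy(float)
        if len(pair) < 10:
            raise ValueError(f"{h.x} vs {h.y}: fewer than 10 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {"x": h.x, "y": h.y, "method": h.method, "r": np.nan, "p_raw": np.nan,
                 "p_adjusted": np.nan, "n": len(pair), "met": False, "flag": "constant"}
            )
            continue
        if h.method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif h.method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown method {h.method!r}")
        met = bool(abs(r) >= h.threshold and np.sign(r) == h.expected_sign
                   and min(1.0, m * p) < alpha)
        rows.append(
            {"x": h.x, "y": h.y, "method": h.method, "r": float(r), "p_raw": float(p),
             "p_adjusted": min(1.0, m * float(p)), "n": len(pair), "met": met, "flag": ""}
        )
    return pd.DataFrame(rows)
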