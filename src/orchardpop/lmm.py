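"""Single-kinship-component linear mixed model association scan.

The model is y = W a + u + e with u ~ N(0, s2_g K) and e ~ N(0, s2_e I).
Following the EMMA / FaST-LMM approach, the eigendecomposition K = U S U'
rotates the model into independent observations with weights S_i + delta
(delta = s2_e / s2_g), so the REML criterion is a cheap one-dimensional
profile in delta, optimised on a log grid with Brent refinement.  The scan
reuses the null-model delta for every marker (the fast mode of FaST-LMM);
exact per-marker re-optimisation is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix
from .kinship import KinshipMatrix


@dataclass
class LmmFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    loglik: float  # REML log-likelihood at the optimum
    W: np.ndarray  # covariate matrix (with intercept), original basis


def _reml_loglik(delta: float, S: np.ndarray, yr: np.ndarray, Wr: np.ndarray) -> tuple:
    """Profiled REML log-likelihood of the rotated model at ``delta``.

    Returns (loglik, sigma_g2_hat).  Rotated responses ``yr = U'y`` and
    covariates ``Wr = U'W``; weights are S + delta.
    """
    n, q = Wr.shape
    D = S + delta
    Wd = Wr / D[:, None]
    WtDW = Wr.T @ Wd
    WtDy = Wd.T @ yr
    beta = np.linalg.solve(WtDW, WtDy)
    r = yr - Wr @ beta
    rss = float(np.sum(r * r / D))
    df = n - q
    sigma_g2 = rss / df
    sign, logdet_WtDW = np.linalg.slogdet(WtDW)
    _, logdet_WtW = np.linalg.slogdet(Wr.T @ Wr)
    ll = -0.5 * (
        df * (np.log(2 * np.pi * sigma_g2) + 1)
        + np.sum(np.log(D))
        + logdet_WtDW
        - logdet_WtW
    )
    return float(ll), sigma_g2


def fit_null(
    y: np.ndarray,
    kinship: KinshipMatrix,
    covariates: Optional[np.ndarray] = None,
    log_delta_bounds: tuple = (-5.0, 5.0),
    n_grid: int = 100,
) -> LmmFit:
    """REML fit of the null model (no marker term).

    ``delta`` is profiled on a log10 grid over ``log_delta_bounds`` and the
    best bracket refined by bounded Brent search.  K must be positive
    semidefinite (smallest eigenvalue above -1e-8 x trace); a singular
    covariate matrix or constant phenotype is rejected.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: variance components undefined")
    K = kinship.values
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular covariate matrix")
    S, U = np.linalg.eigh(K)
    if S.min() < -1e-8 * max(np.trace(K), 1.0):
        raise ValueError("kinship matrix is not positive semidefinite")
    S = np.clip(S, 0.0, None)
    yr = U.T @ y
    Wr = U.T @ W

    grid = np.logspace(log_delta_bounds[0], log_delta_bounds[1], n_grid)
    lls = np.array([_reml_loglik(d, S, yr, Wr)[0] for d in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik(10 ** ld, S, yr, Wr)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
    )
    delta = float(10 ** res.x)
    ll, sigma_g2 = _reml_loglik(delta, S, yr, Wr)
    return LmmFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_g2 * delta,
        delta=delta,
        eigenvalues=S,
        eigenvectors=U,
        loglik=ll,
        W=W,
    )


def reml_loglik_dense(
    y: np.ndarray,
    K: np.ndarray,
    W: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
) -> float:
    """Direct (dense) REML log-likelihood of y ~ N(W a, s2_g K + s2_e I).

    Textbook REML expression via explicit inversion — the slow counterpart
    used to validate the spectral path.
    """
    n, q = W.shape
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    WtViW = W.T @ Vi @ W
    beta = np.linalg.solve(WtViW, W.T @ Vi @ y)
    r = y - W @ beta
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_WtViW = np.linalg.slogdet(WtViW)
    _, logdet_WtW = np.linalg.slogdet(W.T @ W)
    ll = -0.5 * (
        (n - q) * np.log(2 * np.pi)
        + logdet_V
        + logdet_WtViW
        - logdet_WtW
        + float(r @ Vi @ r)
    )
    return float(ll)


def spectral_loglik(fit: LmmFit, y: np.ndarray, sigma_g2: float, delta: float) -> float:
    """REML log-likelihood at arbitrary (s2_g, delta) via the stored
    eigendecomposition; used for oracle comparisons against
    :func:`reml_loglik_dense`."""
    S, U, W = fit.eigenvalues, fit.eigenvectors, fit.W
    n, q = W.shape
    yr, Wr = U.T @ y, U.T @ W
    D = S + delta
    Wd = Wr / D[:, None]
    WtDW = Wr.T @ Wd
    beta = np.linalg.solve(WtDW, Wd.T @ yr)
    r = yr - Wr @ beta
    rss = float(np.sum(r * r / D))
    _, logdet_WtDW = np.linalg.slogdet(WtDW)
    _, logdet_WtW = np.linalg.slogdet(Wr.T @ Wr)
    ll = -0.5 * (
        (n - q) * np.log(2 * np.pi * sigma_g2)
        + np.sum(np.log(D))
        + logdet_WtDW
        - logdet_WtW
        + rss / sigma_g2
    )
    return float(ll)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def scan(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    kinship: KinshipMatrix,
    covariates: Optional[np.ndarray] = None,
    chrom: Optional[np.ndarray] = None,
    pos: Optional[np.ndarray] = None,
    fit: Optional[LmmFit] = None,
    per_marker_reml: bool = False,
) -> pd.DataFrame:
    """Wald-test association scan under the null-fit variance components.

    Each marker is tested by generalised least squares in the rotated
    basis with the null model's delta (per-marker REML re-optimisation
    behind ``per_marker_reml``).  Missing dosages are mean-imputed;
    monomorphic markers are skipped.  Returns a frame with chrom, pos,
    maf, beta, se, stat, p, pve and a ``lambda_gc`` attribute (genomic
    control factor, median chi2 / 0.4549).
    """
    y = np.asarray(y, dtype=float)
    if fit is None:
        fit = fit_null(y, kinship, covariates)
    S, U = fit.eigenvalues, fit.eigenvectors
    X = genotypes.dosages.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    X[nan_at] = np.take(col_mean, np.where(nan_at)[1])
    freqs = col_mean / 2.0
    poly = np.ptp(X, axis=0) > 0
    var_y = float(np.var(y))

    n = len(y)
    q = fit.W.shape[1]
    m = X.shape[1]
    chrom = np.asarray(chrom, dtype=object) if chrom is not None else np.array(
        ["NA"] * m, dtype=object
    )
    pos = np.asarray(pos) if pos is not None else np.arange(m)

    if per_marker_reml:
        rows = []
        for j in np.flatnonzero(poly):
            Wj = np.column_stack([fit.W, X[:, j]])
            yr, Wr = U.T @ y, U.T @ Wj
            grid = np.logspace(-5, 5, 50)
            lls = [_reml_loglik(d, S, yr, Wr)[0] for d in grid]
            dj = grid[int(np.argmax(lls))]
            rows.append((j, *_gls_marker(yr, U.T @ fit.W, (U.T @ X[:, j]), S, dj)))
        return _scan_frame(rows, chrom, pos, freqs, var_y, n, q)

    D = S + fit.delta
    sw = 1.0 / np.sqrt(D)
    yt = (U.T @ y) * sw
    Wt = (U.T @ fit.W) * sw[:, None]
    Xt = (U.T @ X) * sw[:, None]
    # residualise on covariates once
    Q, _ = np.linalg.qr(Wt)
    yres = yt - Q @ (Q.T @ yt)
    Xres = Xt - Q @ (Q.T @ Xt)

    xx = np.sum(Xres * Xres, axis=0)
    xy = Xres.T @ yres
    yy = float(yres @ yres)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        rss = yy - beta * xy
        df = n - q - 1
        sigma2 = rss / df
        se = np.sqrt(sigma2 / xx)
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)

    keep = poly & np.isfinite(tstat)
    result = pd.DataFrame(
        dict(
            chrom=chrom[keep],
            pos=pos[keep],
            maf=np.minimum(freqs[keep], 1 - freqs[keep]),
            beta=beta[keep],
            se=se[keep],
            stat=tstat[keep],
            p=np.clip(pvals[keep], np.finfo(float).tiny, 1.0),
            variant_index=np.flatnonzero(keep),
        )
    )
    result["pve"] = [
        pve(b, f, var_y) for b, f in zip(result["beta"], freqs[keep])
    ]
    chi2 = result["stat"].to_numpy() ** 2
    result.attrs["lambda_gc"] = float(
        np.median(chi2) / stats.chi2.ppf(0.5, 1)
    ) if len(chi2) else np.nan
    return result


def _gls_marker(yr, Wr, xr, S, delta):
    D = S + delta
    sw = 1.0 / np.sqrt(D)
    yt, Wt, xt = yr * sw, Wr * sw[:, None], xr * sw
    Q, _ = np.linalg.qr(Wt)
    yres = yt - Q @ (Q.T @ yt)
    xres = xt - Q @ (Q.T @ xt)
    xx = float(xres @ xres)
    beta = float(xres @ yres) / xx
    rss = float(yres @ yres) - beta * float(xres @ yres)
    df = len(yr) - Wr.shape[1] - 1
    se = np.sqrt(rss / df / xx)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta, se, t, p


def _scan_frame(rows, chrom, pos, freqs, var_y, n, q):
    idx = [r[0] for r in rows]
    df = pd.DataFrame(
        dict(
            chrom=chrom[idx],
            pos=pos[idx],
            maf=np.minimum(freqs[idx], 1 - freqs[idx]),
            beta=[r[1] for r in rows],
            se=[r[2] for r in rows],
            stat=[r[3] for r in rows],
            p=np.clip([r[4] for r in rows], np.finfo(float).tiny, 1.0),
            variant_index=idx,
        )
    )
    df["pve"] = [pve(b, f, var_y) for b, f in zip(df["beta"], freqs[idx])]
    chi2 = df["stat"].to_numpy() ** 2
    df.attrs["lambda_gc"] = float(np.median(chi2) / stats.chi2.ppf(0.5, 1)) \
        if len(chi2) else np.nan
    return df


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def significance_threshold(n_snps: int, mode: str = "paper") -> float:
    """Genome-wide p-value cutoff.

    ``paper`` mode returns 1/n (the convention of reporting the Bonferroni
    idea at significance level 1); ``bonferroni`` returns 0.05/n.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if mode == "paper":
        return 1.0 / n_snps
    if mode == "bonferroni":
        return 0.05 / n_snps
    raise ValueError(f"unknown threshold mode {mode!r}")


def pve(beta: float, allele_freq: float, var_y: float) -> float:
    """Phenotypic variance explained by one variant:
    beta^2 * 2 p (1 - p) / Var(y), clipped to [0, 1)."""
    if var_y <= 0:
        return 0.0
    v = beta ** 2 * 2 * allele_freq * (1 - allele_freq) / var_y
    return float(np.clip(v, 0.0, np.nextafter(1.0, 0.0)))


def peak_snps(results: pd.DataFrame, blocks) -> pd.DataFrame:
    """Peak (minimum-p) variant per LD block.

    ``blocks`` holds (chrom, start, end) intervals (half-open bp).  Ties on
    p are broken by larger |beta|, then by position.
    """
    rows = []
    for chrom, start, end in blocks:
        sub = results[
            (results["chrom"] == chrom)
            & (results["pos"] >= start)
            & (results["pos"] < end)
        ]
        if sub.empty:
            continue
        sub = sub.assign(absbeta=sub["beta"].abs()).sort_values(
            ["p", "absbeta", "pos"], ascending=[True, False, True]
        )
        rows.append(sub.iloc[0].drop(labels=["absbeta"]))
    return pd.DataFrame(rows).reset_index(drop=True)
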