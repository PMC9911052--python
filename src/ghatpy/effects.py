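"""Whole-genome marker-effect estimation.

Two estimators of per-marker allele-substitution effects are provided:

``fit_rrblup``
    Ridge-regression BLUP.  The mixed model ``y = Xb + Zu + e`` with
    ``u ~ N(0, I s2_u)`` and ``e ~ N(0, I s2_e)`` is fitted by REML using a
    single eigendecomposition of the (centered) genotype cross-product,
    reducing the variance-component search to a 1-D optimization over the
    ratio ``lambda = s2_e / s2_u``; the BLUP of ``u`` then gives the effects.

``fit_bayesc``
    A BayesC Gibbs sampler: a fixed fraction ``pi`` of markers has exactly
    zero effect a priori, the rest share one effect variance.  Effects are
    reported as posterior means together with posterior inclusion
    probabilities.

Both estimators center genotype columns (no variance standardization, so
effects stay in trait units per allele copy), absorb optional fixed-effect
covariates by least-squares projection, and mean-impute missing dosages.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize_scalar

from .datatypes import EffectEstimates, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["fit_rrblup", "fit_bayesc"]


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def _prepare(genotypes, phenotypes, trait, covariates, marker_ids):
    """Return (Z, y, X, marker_ids, counted_allele) ready for estimation."""
    if isinstance(genotypes, GenotypeMatrix):
        g = genotypes
        if not isinstance(phenotypes, pd.DataFrame):
            raise TypeError("phenotypes must be a DataFrame when genotypes "
                            "are a GenotypeMatrix")
        ph = phenotypes
        if trait is not None:
            ph = ph[ph["trait"] == trait]
        ph = ph.drop_duplicates(subset="sample")
        sample_pos = {s: i for i, s in enumerate(g.samples)}
        keep = ph["sample"].astype(str).map(sample_pos).dropna()
        if len(keep) == 0:
            raise ValueError("no phenotyped sample overlaps the genotypes")
        rows = keep.to_numpy(dtype=int)
        ph = ph.loc[keep.index]
        Z = g.dosages[rows].astype(np.float64)  # modest n in file-based runs
        y = ph["value"].to_numpy(dtype=float)
        X = np.ones((len(y), 1))
        if covariates:
            X = np.column_stack([X] + [ph[c].to_numpy(dtype=float)
                                       for c in covariates])
        mids = g.markers
        alleles = g.counted_allele
    else:
        Z = np.asarray(genotypes)
        # float32 input stays float32 (large design matrices); anything
        # else is promoted to float64 for the exact small-scale paths
        if Z.dtype != np.float32:
            Z = Z.astype(np.float64)
        y = np.asarray(phenotypes, dtype=float)
        if Z.shape[0] != len(y):
            raise ValueError("genotype rows and phenotype length differ")
        X = np.ones((len(y), 1))
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            X = np.column_stack([X, cov])
        mids = (np.asarray(marker_ids) if marker_ids is not None
                else np.asarray([f"m{j}" for j in range(Z.shape[1])]))
        alleles = None
    if len(y) < 2:
        raise ValueError("need at least 2 phenotyped, genotyped samples")
    # mean-impute missing dosages (on a copy, never the caller's array)
    if np.isnan(Z).any():
        Z = Z.copy()
        col_mean = np.nanmean(Z, axis=0)
        nan_r, nan_c = np.where(np.isnan(Z))
        Z[nan_r, nan_c] = col_mean[nan_c]
    return Z, y, X, mids, alleles


def _project_out(X, y, Z):
    """Residualize y and the columns of Z on the fixed-effect design.

    ``Z`` is assumed column-centered already, so an intercept-only design
    reduces to centering ``y``.
    """
    if X.shape[1] == 1:
        return y - y.mean(), Z, 1
    Q, _ = np.linalg.qr(X)
    yc = y - Q @ (Q.T @ y)
    Zc = Z - Q @ (Q.T @ Z)
    return yc, Zc, X.shape[1]


# ---------------------------------------------------------------------------
# RR-BLUP / REML
# ---------------------------------------------------------------------------

def _ridge_blup_cg(Zc, yc, lam, rtol=1e-4):
    """Ridge solution (Zc'Zc + lam I)^-1 Zc' yc by conjugate gradients.

    Never forms the Gram matrix; each iteration costs two matrix-vector
    products with ``Zc``.  The ridge system is well conditioned whenever
    ``lam`` is not tiny relative to the Gram spectrum, which holds for
    whole-genome regressions where each marker explains a small variance
    share.  The default tolerance keeps the solution error orders of
    magnitude below the estimation noise of the effects themselves.
    """
    from scipy.sparse.linalg import LinearOperator, cg

    m = Zc.shape[1]
    Z32 = Zc if Zc.dtype == np.float32 else Zc.astype(np.float32)

    def matvec(x):
        x32 = x.astype(np.float32)
        return (Z32.T @ (Z32 @ x32)).astype(np.float64) + lam * x

    op = LinearOperator((m, m), matvec=matvec, dtype=np.float64)
    w = (Z32.T @ yc.astype(np.float32)).astype(np.float64)
    u, info = cg(op, w, rtol=rtol, maxiter=1000)
    if info != 0:
        raise RuntimeError(f"ridge CG did not converge (info={info})")
    return u


def fit_rrblup(genotypes, phenotypes, trait: str | None = None,
               covariates=None, lam: float | None = None,
               marker_ids=None, reml_max_n: int | None = 800,
               subsample_seed: int = 0) -> EffectEstimates:
    """Ridge-regression BLUP marker effects with REML variance components.

    Parameters
    ----------
    genotypes
        ``GenotypeMatrix`` or an ``(n, m)`` dosage array.
    phenotypes
        Long-format DataFrame (columns ``sample``, ``trait``, ``value``,
        optional covariates) matched on sample id, or an ``(n,)`` vector
        aligned with the dosage rows.  Samples missing a phenotype are
        dropped; estimation on a phenotyped subset of the genotyped samples
        is the intended use for historical panels with modern phenotypes.
    trait
        Trait name to select from a long-format table.
    covariates
        Fixed-effect columns (names, or an array), absorbed by OLS
        projection alongside the intercept before marker estimation.
    lam
        Optional fixed variance ratio ``s2_e / s2_u``; skips REML.
    reml_max_n
        The REML eigendecomposition scales cubically with the number of
        records, while the BLUP itself can be solved matrix-free.  Above
        this many records the variance ratio (a population parameter, free
        of sample size) is estimated on a random subsample of rows and the
        effects are then solved on the full data by conjugate gradients.
        ``None`` forces the exact spectral path at any size.
    """
    Z, y, X, mids, alleles = _prepare(genotypes, phenotypes, trait,
                                      covariates, marker_ids)
    n, m = Z.shape
    if np.var(y) <= 0:
        warnings.warn("phenotype has zero variance; all effects set to 0")
        return EffectEstimates(marker=mids, alpha=np.zeros(m),
                               method="rrblup", counted_allele=alleles,
                               params={"s2_u": 0.0, "s2_e": 0.0,
                                       "lambda": np.inf})

    Z = Z - Z.mean(axis=0)   # column centering; keeps alpha in trait units
    yc, Zc, p = _project_out(X, y, Z)
    df = n - p
    if df < 2:
        raise ValueError("not enough residual degrees of freedom")

    big = reml_max_n is not None and n > reml_max_n
    if big:
        rows = np.random.default_rng(subsample_seed).choice(
            n, size=reml_max_n, replace=False)
        Zr, yr = Zc[rows], yc[rows]
        # re-center the subsample so its projected structure matches
        Zr = Zr - Zr.mean(axis=0)
        yr = yr - yr.mean()
    else:
        Zr, yr = Zc, yc
    n_r = len(yr)
    df_r = n_r - p

    K = (Zr.astype(np.float32) @ Zr.astype(np.float32).T).astype(np.float64)
    d_all, U_all = np.linalg.eigh(K)
    # keep the top n - p eigenpairs: the discarded directions span the
    # projected-out fixed-effect space where yc has no component
    d = np.clip(d_all[p:], 0.0, None)
    U = U_all[:, p:]
    eta = U.T @ yr
    ss_rest = max(float(yr @ yr - eta @ eta), 0.0)

    def quad(lam_):
        q = float(np.sum(eta**2 / (d + lam_)))
        if ss_rest > 0:
            q += ss_rest / lam_
        return q

    def neg_restricted_ll(log_lam):
        lam_ = 10.0 ** log_lam
        s2u = quad(lam_) / df_r
        return 0.5 * (df_r * np.log(s2u) + float(np.sum(np.log(d + lam_))))

    if lam is None:
        opt = minimize_scalar(neg_restricted_ll, bounds=(-8.0, 8.0),
                              method="bounded",
                              options={"xatol": 1e-10})
        lam_hat = float(10.0 ** opt.x)
    else:
        lam_hat = float(lam)
    s2u = quad(lam_hat) / df_r
    s2e = lam_hat * s2u

    if big:
        alpha = _ridge_blup_cg(Zc, yc, lam_hat)
    else:
        # BLUP: u = Zc' (K + lam I)^(-1) yc via the spectral factors
        v = U @ (eta / (d + lam_hat))
        resid = yc - U @ eta
        if ss_rest > 0:
            v = v + resid / lam_hat
        alpha = Zc.T @ v
    return EffectEstimates(marker=mids, alpha=alpha, method="rrblup",
                           counted_allele=alleles,
                           params={"s2_u": s2u, "s2_e": s2e,
                                   "lambda": lam_hat,
                                   "reml": lam is None, "n": n})


# ---------------------------------------------------------------------------
# BayesC Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bayesc_gibbs(Zt, y, pi, iters, burnin, nu_a, s2a_scale, nu_e,
                  s2e_scale, seed):   # pragma: no cover - jit
    m, n = Zt.shape
    np.random.seed(seed)
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = np.dot(Zt[j], Zt[j])
    b = np.zeros(m)
    incl = np.zeros(m, dtype=np.uint8)
    mu = np.mean(y)
    e = y - mu
    s2a = s2a_scale if s2a_scale > 0 else 0.01
    s2e = np.var(y) * 0.5 + 1e-12
    log_prior_odds = 0.0
    always_in = pi <= 0.0
    if not always_in:
        log_prior_odds = np.log(1.0 - pi) - np.log(pi)
    sum_b = np.zeros(m)
    sum_incl = np.zeros(m)
    n_keep = 0
    sum_s2a = 0.0
    sum_s2e = 0.0
    for it in range(iters):
        # intercept
        offset = np.mean(e) + np.random.normal() * np.sqrt(s2e / n)
        mu += offset
        e -= offset
        k_in = 0
        ssb = 0.0
        for j in range(m):
            if xtx[j] <= 0.0:
                continue
            b_old = b[j]
            r = np.dot(Zt[j], e) + xtx[j] * b_old
            c = xtx[j] + s2e / s2a
            if always_in:
                p_in = 1.0
            else:
                log_bf = (0.5 * np.log(s2e / (s2a * c))
                          + 0.5 * r * r / (s2e * c))
                t = log_prior_odds + log_bf
                if t > 35.0:
                    p_in = 1.0
                elif t < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-t))
            if np.random.random() < p_in:
                b_new = r / c + np.random.normal() * np.sqrt(s2e / c)
                incl[j] = 1
                k_in += 1
                ssb += b_new * b_new
            else:
                b_new = 0.0
                incl[j] = 0
            if b_new != b_old:
                diff = b_old - b_new
                for i in range(n):
                    e[i] += Zt[j, i] * diff
            b[j] = b_new
        # common effect variance (scaled-inverse-chi-square)
        chi = 2.0 * np.random.gamma(0.5 * (nu_a + k_in), 1.0)
        s2a = (ssb + nu_a * s2a_scale) / max(chi, 1e-12)
        # residual variance
        sse = np.dot(e, e)
        chi_e = 2.0 * np.random.gamma(0.5 * (nu_e + n), 1.0)
        s2e = (sse + nu_e * s2e_scale) / max(chi_e, 1e-12)
        if not np.isfinite(s2e) or not np.isfinite(s2a):
            return (sum_b, sum_incl, -1, mu, s2a, s2e, it)
        if it >= burnin:
            n_keep += 1
            sum_s2a += s2a
            sum_s2e += s2e
            for j in range(m):
                sum_b[j] += b[j]
                sum_incl[j] += incl[j]
    return (sum_b, sum_incl, n_keep, mu, sum_s2a / max(n_keep, 1),
            sum_s2e / max(n_keep, 1), iters)


def fit_bayesc(genotypes, phenotypes, trait: str | None = None,
               pi: float = 0.95, iters: int = 10000, burnin: int = 2000,
               seed: int = 0, covariates=None, marker_ids=None,
               nu: float = 4.0, h2_prior: float = 0.5) -> EffectEstimates:
    """BayesC posterior-mean marker effects.

    A fraction ``pi`` of markers is assumed to have exactly zero effect;
    included markers share one effect variance ``s2_alpha`` with a
    scaled-inverse-chi-square prior (``nu`` degrees of freedom, scale set so
    the prior genetic variance is ``h2_prior`` of the phenotypic variance).
    ``pi`` is fixed, not estimated.  ``pi = 1`` short-circuits to all-zero
    effects; ``pi = 0`` keeps every marker in the model.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    if not iters > burnin >= 0:
        raise ValueError("need iters > burnin >= 0")
    Z, y, X, mids, alleles = _prepare(genotypes, phenotypes, trait,
                                      covariates, marker_ids)
    n, m = Z.shape
    if pi >= 1.0:
        return EffectEstimates(marker=mids, alpha=np.zeros(m),
                               method="bayesc", counted_allele=alleles,
                               inclusion_prob=np.zeros(m),
                               params={"pi": 1.0, "iters": iters,
                                       "burnin": burnin, "seed": seed})
    Z = Z - Z.mean(axis=0)
    yc, Zc, _ = _project_out(X, y, Z)
    var_y = float(np.var(yc))
    if var_y <= 0:
        warnings.warn("phenotype has zero variance; all effects set to 0")
        return EffectEstimates(marker=mids, alpha=np.zeros(m),
                               method="bayesc", counted_allele=alleles,
                               inclusion_prob=np.zeros(m),
                               params={"pi": pi, "iters": iters,
                                       "burnin": burnin, "seed": seed})
    sum_var = float(np.sum(Zc.var(axis=0)))
    frac_in = max(1.0 - pi, 1.0 / m)
    s2a_scale = (h2_prior * var_y / max(frac_in * sum_var, 1e-12)
                 * (nu - 2.0) / nu)
    s2e_scale = (1.0 - h2_prior) * var_y * (nu - 2.0) / nu
    Zt = np.ascontiguousarray(Zc.T)
    (sum_b, sum_incl, n_keep, mu, s2a, s2e, it_done) = _bayesc_gibbs(
        Zt, yc.copy(), float(pi), int(iters), int(burnin), float(nu),
        float(s2a_scale), float(nu), float(s2e_scale), int(seed) % (2**31))
    if n_keep < 0:
        raise RuntimeError(
            f"BayesC variance update diverged at iteration {it_done}")
    alpha = sum_b / n_keep
    incl = sum_incl / n_keep
    return EffectEstimates(marker=mids, alpha=alpha, method="bayesc",
                           counted_allele=alleles, inclusion_prob=incl,
                           params={"pi": pi, "iters": iters,
                                   "burnin": burnin, "seed": seed,
                                   "s2_alpha": s2a, "s2_e": s2e, "nu": nu})
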