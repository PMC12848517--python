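"""Random-intercept linear mixed model for litter-structured volumetrics.

The model for one brain structure's relative volume is

    y = X beta + Z b + eps,    b ~ N(0, sigma_l^2 I_L),  eps ~ N(0, sigma_r^2 I_n)

with fixed effects X = [1, diet, sex, diet*sex] (diet coded CD=0 / HFHSS=1,
sex effect-coded F=-0.5 / M=+0.5, so the diet coefficient is the cross-sex
average diet effect) and Z the litter indicator matrix.  Estimation is REML
with the variance ratio lambda = sigma_l^2 / sigma_r^2 profiled out: for fixed
lambda the criterion reduces to a closed form in the rotated coordinates of
the eigendecomposition Z Z' = U diag(d) U', so each fit is a one-dimensional
bounded search over log(lambda) plus an explicit boundary check at lambda = 0.

Degrees of freedom for t-type contrasts use the Satterthwaite approximation:
df = 2 (c' C c)^2 / Var(c' C c), with C the fixed-effect covariance and the
denominator obtained by the delta method from the gradient of c' C(theta) c in
theta = (sigma_l^2, sigma_r^2) and the inverse of the observed REML
information (central finite differences of the criterion).

The eigendecomposition depends only on the design, so an
:class:`LmeWorkspace` built once can fit many simulated responses on the same
cohort cheaply; the power module relies on this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .types import CohortDesign, ContrastTest

logger = logging.getLogger(__name__)

FIXED_EFFECTS = ("intercept", "diet", "sex", "diet_sex")

#: Contrast selecting the paternal-diet main effect (cross-sex average).
DIET_CONTRAST = np.array([0.0, 1.0, 0.0, 0.0])
#: Contrast selecting the sex main effect.
SEX_CONTRAST = np.array([0.0, 0.0, 1.0, 0.0])
#: Contrast selecting the diet-by-sex interaction.
INTERACTION_CONTRAST = np.array([0.0, 0.0, 0.0, 1.0])

_LOGLAM_BOUNDS = (-12.0, 12.0)
_CRIT_TOL = 1e-10


class RankDeficientDesignError(ValueError):
    """The fixed-effect design matrix is not full column rank."""


def design_matrix(design: CohortDesign | pd.DataFrame):
    """Fixed-effect design matrix and litter coding for a cohort.

    Returns ``(X, litter_index, litter_ids)`` where ``litter_index`` maps each
    sample to 0..L-1 (litters sorted by id).
    """
    df = design.samples if isinstance(design, CohortDesign) else design
    diet = (df["diet"].to_numpy() == "HFHSS").astype(float)
    sex = np.where(df["sex"].to_numpy() == "M", 0.5, -0.5)
    X = np.column_stack([np.ones(len(df)), diet, sex, diet * sex])
    litter_index, litter_ids = pd.factorize(df["litter_id"], sort=True)
    return X, litter_index.astype(np.intp), list(litter_ids)


@dataclass
class LmeFit:
    """REML fit of the random-intercept model on one response vector."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_litter: float
    sigma2_resid: float
    n: int
    p: int
    converged: bool
    boundary: bool
    #: observed REML information for (sigma_l^2, sigma_r^2); None at boundary
    vc_information: np.ndarray | None
    reml_criterion: float
    _ws: "LmeWorkspace" = field(repr=False)

    @property
    def lam(self) -> float:
        return self.sigma2_litter / self.sigma2_resid

    def to_dict(self) -> dict:
        out = {f"beta_{name}": float(b) for name, b in zip(FIXED_EFFECTS, self.beta)}
        out.update(
            {f"se_{name}": float(s)
             for name, s in zip(FIXED_EFFECTS, np.sqrt(np.diag(self.cov_beta)))}
        )
        out.update(
            sigma2_litter=float(self.sigma2_litter),
            sigma2_resid=float(self.sigma2_resid),
            n=self.n, p=self.p,
            converged=self.converged, boundary=self.boundary,
        )
        return out


class LmeWorkspace:
    """Reusable REML machinery for a fixed cohort design.

    Precomputes the eigendecomposition of Z Z' and the rotated design matrix;
    :meth:`fit` then costs only a rotation of y plus a scalar search.
    """

    def __init__(self, design: CohortDesign):
        X, litter_index, litter_ids = design_matrix(design)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need n > {p} samples, got {n}")
        if np.linalg.matrix_rank(X) < p:
            raise RankDeficientDesignError(
                "design matrix is rank deficient (a diet or sex level is "
                "missing, or diet and sex are confounded)"
            )
        self.design = design
        self.X = X
        self.litter_index = litter_index
        self.litter_ids = litter_ids
        self.n = n
        self.p = p
        self.n_litters = len(litter_ids)
        Z = np.zeros((n, self.n_litters))
        Z[np.arange(n), litter_index] = 1.0
        d, U = np.linalg.eigh(Z @ Z.T)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.Xt = U.T @ X

    # -- profiled criterion ------------------------------------------------
    def _profile_state(self, yt: np.ndarray, lam: float):
        w = 1.0 + lam * self.d
        Xw = self.Xt / w[:, None]
        A = self.Xt.T @ Xw
        cho = cho_factor(A)
        beta = cho_solve(cho, Xw.T @ yt)
        r = yt - self.Xt @ beta
        # guard: exactly noiseless data would send log(rss) to -inf
        rss = max(float(np.dot(r * r, 1.0 / w)), np.finfo(float).tiny)
        logdet_A = 2.0 * float(np.log(np.diag(cho[0])).sum())
        np_ = self.n - self.p
        crit = np_ * math.log(rss / np_) + float(np.log(w).sum()) + logdet_A
        return crit, beta, rss, A

    def _neg2_reml(self, yt: np.ndarray, s2l: float, s2r: float) -> float:
        """-2 restricted log-likelihood (up to an additive constant)."""
        w = s2r + s2l * self.d
        Xw = self.Xt / w[:, None]
        A = self.Xt.T @ Xw
        cho = cho_factor(A)
        beta = cho_solve(cho, Xw.T @ yt)
        r = yt - self.Xt @ beta
        rss = max(float(np.dot(r * r, 1.0 / w)), np.finfo(float).tiny)
        logdet_A = 2.0 * float(np.log(np.diag(cho[0])).sum())
        return float(np.log(w).sum()) + logdet_A + rss

    def _observed_vc_information(self, yt, s2l, s2r) -> np.ndarray | None:
        scale = s2l + s2r
        h2 = 1e-5 * scale
        h1 = min(h2, 0.5 * s2l)
        if h1 <= 0:
            return None
        f = lambda a, b: self._neg2_reml(yt, a, b)
        f0 = f(s2l, s2r)
        H = np.empty((2, 2))
        H[0, 0] = (f(s2l + h1, s2r) - 2 * f0 + f(s2l - h1, s2r)) / h1**2
        H[1, 1] = (f(s2l, s2r + h2) - 2 * f0 + f(s2l, s2r - h2)) / h2**2
        H[0, 1] = H[1, 0] = (
            f(s2l + h1, s2r + h2) - f(s2l + h1, s2r - h2)
            - f(s2l - h1, s2r + h2) + f(s2l - h1, s2r - h2)
        ) / (4 * h1 * h2)
        return 0.5 * H

    def fit(self, y: np.ndarray) -> LmeFit:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"response length {y.shape} != design size {self.n}")
        yt = self.U.T @ y

        def crit(loglam: float) -> float:
            return self._profile_state(yt, math.exp(loglam))[0]

        res = optimize.minimize_scalar(
            crit, bounds=_LOGLAM_BOUNDS, method="bounded",
            options={"xatol": 1e-8},
        )
        crit0 = self._profile_state(yt, 0.0)[0]
        if crit0 <= res.fun + _CRIT_TOL:
            lam, boundary, best = 0.0, True, crit0
        else:
            lam, boundary, best = math.exp(res.x), False, float(res.fun)
        _, beta, rss, A = self._profile_state(yt, lam)
        s2r = rss / (self.n - self.p)
        s2l = lam * s2r
        cov_beta = s2r * np.linalg.inv(A)
        info = None if boundary else self._observed_vc_information(yt, s2l, s2r)
        return LmeFit(
            beta=beta, cov_beta=cov_beta,
            sigma2_litter=s2l, sigma2_resid=s2r,
            n=self.n, p=self.p,
            converged=bool(res.success) or boundary,
            boundary=boundary,
            vc_information=info,
            reml_criterion=best,
            _ws=self,
        )


def fit_lme(y, design: CohortDesign, workspace: LmeWorkspace | None = None) -> LmeFit:
    """Fit the litter random-intercept model to one response vector.

    ``y`` may be an array in the design's row order or a pandas Series indexed
    by sample_id.  Pass a prebuilt ``workspace`` to amortize the design setup
    over many fits on the same cohort.
    """
    ws = workspace if workspace is not None else LmeWorkspace(design)
    if isinstance(y, pd.Series):
        y = y.reindex(ws.design.sample_ids).to_numpy()
        if np.isnan(y).any():
            raise ValueError("response missing for some cohort samples")
    return ws.fit(np.asarray(y, dtype=float))


def satterthwaite_df(fit: LmeFit, contrast: np.ndarray) -> float:
    """Satterthwaite degrees of freedom for the contrast c'beta.

    At the boundary (sigma_l^2 = 0) this is exactly the residual df n - p;
    otherwise the delta-method value, clamped to (0, n - p].  A singular
    variance-component information falls back to n - p with a warning.
    """
    c = np.asarray(contrast, dtype=float)
    resid_df = float(fit.n - fit.p)
    if fit.boundary or fit.sigma2_litter <= 0 or fit.vc_information is None:
        return resid_df
    ws = fit._ws
    var_c = float(c @ fit.cov_beta @ c)
    u = ws.Xt @ (fit.cov_beta @ c)
    w = fit.sigma2_resid + fit.sigma2_litter * ws.d
    u2w2 = (u * u) / (w * w)
    g = np.array([float(ws.d @ u2w2), float(u2w2.sum())])
    try:
        cov_vc = np.linalg.inv(fit.vc_information)
    except np.linalg.LinAlgError:
        logger.warning("singular variance-component information; using residual df")
        return resid_df
    denom = float(g @ cov_vc @ g)
    if not np.isfinite(denom) or denom <= 0:
        logger.warning("non-positive Satterthwaite denominator; using residual df")
        return resid_df
    df = 2.0 * var_c**2 / denom
    return float(min(max(df, np.finfo(float).tiny), resid_df))


def test_contrast(fit: LmeFit, contrast: np.ndarray) -> ContrastTest:
    """Two-sided t-test of c'beta = 0 with Satterthwaite df."""
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    c = np.asarray(contrast, dtype=float)
    var_c = float(c @ fit.cov_beta @ c)
    if var_c <= 0:
        raise ValueError("contrast has zero standard error")
    se = math.sqrt(var_c)
    est = float(c @ fit.beta)
    t = est / se
    df = satterthwaite_df(fit, c)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ContrastTest(estimate=est, se=se, t=t, df=df, p=min(p, 1.0))


def welch_t_test(a, b) -> ContrastTest:
    """Welch unequal-variance two-sample t-test (two-sided).

    Degenerate inputs: if both samples are constant with equal means the test
    is a no-op (t = 0, p = 1); constant samples with different means have no
    noise scale and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    diff = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        if diff == 0:
            return ContrastTest(estimate=0.0, se=0.0, t=0.0,
                                df=float(na + nb - 2), p=1.0)
        raise ValueError("both samples constant with unequal means: no variance scale")
    se2 = va / na + vb / nb
    se = math.sqrt(se2)
    t = diff / se
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ContrastTest(estimate=diff, se=se, t=t, df=float(df), p=min(p, 1.0))
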