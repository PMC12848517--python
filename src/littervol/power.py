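"""Simulation-based minimum detectable volume change (MDVC).

For a structure with known simulation parameters and a fixed cohort design,
the power at an injected effect is the fraction of simulated replicates whose
litter-aware diet-contrast test falls below a strict significance threshold
(default p < 0.001).  Scanning an ascending effect grid gives a power curve;
the MDVC is the effect at which the curve first crosses the target power
(default 80%), found by linear interpolation between adjacent grid points.
An analytic noncentral-t oracle built from the true variance components
validates the simulation, and a cube-root conversion translates volumetric
change into linear-dimension change.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import seed_sequence
from .lme import DIET_CONTRAST, LmeWorkspace, test_contrast
from .types import (
    LEFT_CENSORED,
    RIGHT_CENSORED,
    CohortDesign,
    MdvcEstimate,
    PowerCurve,
    StructureParams,
)

logger = logging.getLogger(__name__)

#: Percent volume changes scanned by the power procedure.
DEFAULT_EFFECT_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.0, 11.0, 15.0, 20.0, 40.0)
DEFAULT_ALPHA = 0.001
DEFAULT_TARGET_POWER = 0.80
DEFAULT_N_ITER = 3000


def _group_means(params: StructureParams, ws: LmeWorkspace, effect_pct: float):
    """True per-sample mean vector with the effect applied to the HFHSS arm."""
    df = ws.design.samples
    is_m = (df["sex"] == "M").to_numpy()
    is_hf = (df["diet"] == "HFHSS").to_numpy()
    mu = np.where(is_m, params.mean_rel_m, params.mean_rel_f)
    return mu * (1.0 + effect_pct / 100.0 * is_hf)


def simulate_power(
    params: StructureParams,
    design: CohortDesign,
    effect_pct: float,
    n_iter: int,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    workspace: LmeWorkspace | None = None,
) -> float:
    """Rejection frequency of the diet contrast at one injected effect.

    Each replicate simulates both diet arms on the given design (CD at
    baseline, HFHSS mean multiplied by 1 + effect/100), fits the full LME
    (diet, sex, interaction, litter intercept) and tests the diet contrast.
    Replicate streams derive from (seed, structure_id, effect), so results
    are deterministic and independent across grid points.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    ws = workspace if workspace is not None else LmeWorkspace(design)
    mu = _group_means(params, ws, effect_pct)
    litter = ws.litter_index
    n, n_litters = ws.n, ws.n_litters
    children = seed_sequence(seed, "power", params.structure_id, effect_pct).spawn(n_iter)
    rejected = 0
    used = 0
    failed = 0
    for child in children:
        gen = np.random.default_rng(child)
        b = gen.normal(0.0, params.sd_litter, n_litters)
        y = mu + b[litter] + gen.normal(0.0, params.sd_resid, n)
        fit = ws.fit(y)
        if not fit.converged:
            failed += 1
            continue
        used += 1
        if test_contrast(fit, DIET_CONTRAST).p < alpha:
            rejected += 1
    if failed > 0.01 * n_iter:
        logger.warning(
            "%s at effect %.3g%%: %d/%d replicates did not converge",
            params.structure_id, effect_pct, failed, n_iter,
        )
    return rejected / max(used, 1)


def power_curve(
    params: StructureParams,
    design: CohortDesign,
    grid: Sequence[float] = DEFAULT_EFFECT_GRID,
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    workspace: LmeWorkspace | None = None,
) -> PowerCurve:
    """Simulated power at every effect of an ascending grid."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("effect grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("effect grid must be strictly ascending")
    ws = workspace if workspace is not None else LmeWorkspace(design)
    power = np.array(
        [
            simulate_power(params, design, float(e), n_iter, alpha=alpha,
                           seed=seed, workspace=ws)
            for e in grid
        ]
    )
    return PowerCurve(
        structure_id=params.structure_id,
        effects=grid, power=power,
        n_iter=n_iter, alpha=alpha, seed=seed,
    )


def estimate_mdvc(
    curve: PowerCurve, target_power: float = DEFAULT_TARGET_POWER
) -> MdvcEstimate:
    """Interpolate the effect at which power first reaches the target.

    Takes the FIRST adjacent grid pair (e_i, e_{i+1}) with
    power_i < target <= power_{i+1} and interpolates linearly; later dips of
    the (Monte-Carlo noisy) curve are ignored.  Power already at or above the
    target at the grid minimum is left-censored; a curve that never reaches
    the target is right-censored.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    eff, pw = curve.effects, curve.power
    if pw[0] >= target_power:
        return MdvcEstimate(curve.structure_id, float("nan"), LEFT_CENSORED,
                            target_power, curve.alpha)
    for i in range(len(eff) - 1):
        if pw[i] < target_power <= pw[i + 1]:
            frac = (target_power - pw[i]) / (pw[i + 1] - pw[i])
            mdvc = eff[i] + frac * (eff[i + 1] - eff[i])
            return MdvcEstimate(curve.structure_id, float(mdvc), None,
                                target_power, curve.alpha)
    return MdvcEstimate(curve.structure_id, float("nan"), RIGHT_CENSORED,
                        target_power, curve.alpha)


def _expected_vc_information(ws: LmeWorkspace, s2l: float, s2r: float) -> np.ndarray:
    """Expected REML information for (sigma_l^2, sigma_r^2) at true values.

    I_jk = 0.5 tr(P V_j P V_k) with P the REML projection V^-1 - V^-1 X C X' V^-1
    and V_1 = Z Z', V_2 = I, evaluated in the eigenbasis of Z Z'.
    """
    w = s2r + s2l * ws.d
    Xw = ws.Xt / w[:, None]
    C = np.linalg.inv(ws.Xt.T @ Xw)
    P = np.diag(1.0 / w) - Xw @ C @ Xw.T
    M = P * P
    d = ws.d
    return 0.5 * np.array(
        [[float(d @ M @ d), float((M @ d).sum())],
         [float((M @ d).sum()), float(M.sum())]]
    )


def analytic_power(
    params: StructureParams,
    design: CohortDesign,
    effect_pct: float,
    alpha: float = DEFAULT_ALPHA,
    workspace: LmeWorkspace | None = None,
) -> float:
    """Noncentral-t power of the diet contrast at known variance components.

    SE comes from c'(X'V^-1 X)^-1 c with V built from the true litter and
    residual variances; the noncentrality is the true diet coefficient
    (delta/100 times the cross-sex average mean) over that SE; degrees of
    freedom are the Satterthwaite value at the true components (residual df
    when sigma_l = 0).
    """
    ws = workspace if workspace is not None else LmeWorkspace(design)
    s2l = params.sd_litter**2
    s2r = params.sd_resid**2
    w = s2r + s2l * ws.d
    Xw = ws.Xt / w[:, None]
    C = np.linalg.inv(ws.Xt.T @ Xw)
    c = DIET_CONTRAST
    se = math.sqrt(float(c @ C @ c))
    true_effect = effect_pct / 100.0 * params.mean_rel
    ncp = true_effect / se
    resid_df = ws.n - ws.p
    if s2l == 0:
        df = float(resid_df)
    else:
        info = _expected_vc_information(ws, s2l, s2r)
        u = ws.Xt @ (C @ c)
        u2w2 = (u * u) / (w * w)
        g = np.array([float(ws.d @ u2w2), float(u2w2.sum())])
        denom = float(g @ np.linalg.inv(info) @ g)
        var_c = float(c @ C @ c)
        df = float(min(2.0 * var_c**2 / denom, resid_df)) if denom > 0 else float(resid_df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return _nct_two_tail(tcrit, df, ncp)


def _nct_two_tail(tcrit: float, df: float, ncp: float) -> float:
    """P(|T| > tcrit) for noncentral t, robust to far-tail NaN in scipy.

    A non-finite tail (scipy's nct underflows for moderate |ncp|) is replaced
    by its Gaussian approximation, which is itself vanishingly small there.
    """
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(upper):
        upper = stats.norm.sf(tcrit - ncp)
    if not np.isfinite(lower):
        lower = stats.norm.cdf(-tcrit - ncp)
    return float(min(upper + lower, 1.0))


def volume_to_linear_change(dv_pct: float) -> float:
    """Percent change in linear dimension equivalent to a % volume change.

    A structure scaling isotropically by a factor (1 + dv/100) in volume
    changes each linear dimension by its cube root.
    """
    if dv_pct <= -100:
        raise ValueError("volume change must exceed -100%")
    return 100.0 * ((1.0 + dv_pct / 100.0) ** (1.0 / 3.0) - 1.0)


def mdvc_map(
    params_list: Sequence[StructureParams],
    design: CohortDesign,
    grid: Sequence[float] = DEFAULT_EFFECT_GRID,
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    target_power: float = DEFAULT_TARGET_POWER,
    seed: int = 0,
    observed_pct_change: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[PowerCurve]]:
    """Per-structure MDVC table (plus raw curves) over a list of structures.

    When observed diet effects (% change per structure) are supplied, the
    table also reports 100 * |observed| / MDVC — how much of each structure's
    detection limit the observed effect attains.
    """
    ws = LmeWorkspace(design)
    rows = []
    curves: list[PowerCurve] = []
    for sp in params_list:
        curve = power_curve(sp, design, grid=grid, n_iter=n_iter, alpha=alpha,
                            seed=seed, workspace=ws)
        curves.append(curve)
        est = estimate_mdvc(curve, target_power=target_power)
        row = {
            "structure_id": sp.structure_id,
            "mdvc_pct": est.mdvc_pct,
            "censoring": est.censoring or "",
            "mdvc_linear_pct": (
                volume_to_linear_change(est.mdvc_pct) if not est.censored else float("nan")
            ),
        }
        if observed_pct_change is not None:
            obs = observed_pct_change.get(sp.structure_id)
            row["observed_pct_change"] = obs if obs is not None else float("nan")
            row["pct_of_mdvc"] = (
                100.0 * abs(obs) / est.mdvc_pct
                if obs is not None and not est.censored
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows), curves


def curves_to_frame(curves: Sequence[PowerCurve]) -> pd.DataFrame:
    """Long-format table of power-curve points for reporting."""
    rows = [
        {"structure_id": c.structure_id, "effect_pct": float(e),
         "power": float(p), "n_iter": c.n_iter, "alpha": c.alpha}
        for c in curves
        for e, p in zip(c.effects, c.power)
    ]
    return pd.DataFrame(rows)
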