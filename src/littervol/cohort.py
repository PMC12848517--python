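"""Synthetic cohort, structure-parameter, volume and weight generators.

These emulate the statistical structure of a two-group paternal-diet mouse
MRI study: litters sired by CD- or HFHSS-fed males (diet is therefore a
litter-level exposure), litters culled to at most six pups with a near-even
sex ratio, Gaussian litter random intercepts and residuals on the
relative-volume scale, and weekly sire weight trajectories.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._rng import rng, seed_sequence
from .types import (
    DIETS,
    CohortDesign,
    EffectSpec,
    StructureParams,
    validate_effect_spec,
    validate_weight_table,
)

logger = logging.getLogger(__name__)

#: Default litter-size distribution over 1..6: mass concentrated on 4-6 pups,
#: the typical C57BL/6J litter after culling to the six-pup cap.
DEFAULT_LITTER_SIZE_WEIGHTS = (0.02, 0.04, 0.09, 0.20, 0.35, 0.30)

#: Imaged offspring counts of the emulated study design: (F, M) per diet.
STUDY_GROUP_TARGETS = {"CD": {"F": 24, "M": 23}, "HFHSS": {"F": 26, "M": 25}}


def generate_cohort(
    n_litters_per_group: int,
    max_litter_size: int = 6,
    litter_size_weights=None,
    seed: int = 0,
) -> CohortDesign:
    """Draw a two-diet cohort with litter structure.

    Litter sizes are drawn from a categorical distribution over
    ``1..max_litter_size``; sexes alternate within a litter starting from a
    seeded coin flip, so each litter's sex split is even to within one pup.
    Deterministic given ``seed``.
    """
    if n_litters_per_group < 0:
        raise ValueError("n_litters_per_group must be >= 0")
    if max_litter_size < 1:
        raise ValueError("max_litter_size must be >= 1")
    if litter_size_weights is None:
        if max_litter_size == 6:
            weights = np.array(DEFAULT_LITTER_SIZE_WEIGHTS)
        else:
            weights = np.full(max_litter_size, 1.0 / max_litter_size)
    else:
        weights = np.asarray(litter_size_weights, dtype=float)
        if weights.shape != (max_litter_size,):
            raise ValueError(
                f"litter_size_weights must have length {max_litter_size}"
            )
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError("litter_size_weights must be a probability vector")
    gen = rng(seed, "cohort")
    rows = []
    for diet in DIETS:
        for i in range(n_litters_per_group):
            litter_id = f"{diet}_L{i + 1:02d}"
            size = int(gen.choice(max_litter_size, p=weights)) + 1
            first_is_male = bool(gen.integers(2))
            for j in range(size):
                sex = "M" if (j % 2 == 0) == first_is_male else "F"
                rows.append(
                    {
                        "sample_id": f"{litter_id}_P{j + 1}",
                        "sex": sex,
                        "diet": diet,
                        "litter_id": litter_id,
                    }
                )
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "diet", "litter_id"])
    design = CohortDesign(df)
    design.validate(max_litter_size=max_litter_size)
    return design


def study_cohort(
    seed: int = 0,
    n_litters_per_group: int = 20,
    group_targets: dict | None = None,
) -> CohortDesign:
    """Cohort matching the emulated study's imaged group sizes.

    Generates ``n_litters_per_group`` litters per diet and deterministically
    trims pups (largest litters first) until each diet x sex cell matches its
    target count (defaults: CD 23M/24F, HFHSS 25M/26F).
    """
    targets = group_targets or STUDY_GROUP_TARGETS
    base = generate_cohort(n_litters_per_group, seed=seed)
    df = base.samples.copy()
    for diet, by_sex in targets.items():
        for sex, want in by_sex.items():
            cell = df[(df["diet"] == diet) & (df["sex"] == sex)]
            if len(cell) < want:
                raise ValueError(
                    f"cannot reach {want} {sex} pups in {diet}: only {len(cell)} generated; "
                    "increase n_litters_per_group"
                )
            while len(cell) > want:
                sizes = df.groupby("litter_id").size()
                cand = cell.assign(litter_n=cell["litter_id"].map(sizes))
                cand = cand.sort_values(
                    ["litter_n", "litter_id", "sample_id"],
                    ascending=[False, True, True],
                )
                df = df.drop(index=cand.index[0])
                cell = df[(df["diet"] == diet) & (df["sex"] == sex)]
    return CohortDesign(df.reset_index(drop=True))


def generate_structure_params(n_structures: int, seed: int = 0) -> list[StructureParams]:
    """Draw plausible per-structure simulation parameters.

    Mean relative volumes are log-uniform over 0.01-5 % of total brain volume
    with mild sex dimorphism; litter and residual SDs are 1-15% and 3-15% of
    the structure mean respectively.  Deterministic given ``seed``.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    gen = rng(seed, "structure-params")
    base = 10.0 ** gen.uniform(math.log10(0.01), math.log10(5.0), n_structures)
    dimorphism = gen.uniform(0.95, 1.08, n_structures)
    mean_f = base
    mean_m = base * dimorphism
    mid = 0.5 * (mean_f + mean_m)
    sd_litter = mid * gen.uniform(0.01, 0.15, n_structures)
    sd_resid = mid * gen.uniform(0.03, 0.15, n_structures)
    return [
        StructureParams(
            structure_id=f"structure_{i:03d}",
            mean_rel_f=float(mean_f[i]),
            mean_rel_m=float(mean_m[i]),
            sd_litter=float(sd_litter[i]),
            sd_resid=float(sd_resid[i]),
        )
        for i in range(n_structures)
    ]


def simulate_relative_volumes(
    design: CohortDesign,
    params: list[StructureParams],
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a sample x structure relative-volume matrix.

    For structure s and sample i:

        y_is = mu_s(sex_i) * (1 + delta_s/100 * [diet_i = HFHSS]) + b_{litter(i),s} + eps_is

    with b ~ N(0, sd_litter_s^2) drawn once per litter per structure and
    eps ~ N(0, sd_resid_s^2) independent.  Each structure uses its own
    random stream derived from (seed, structure_id).  Structures are
    simulated independently; rows are NOT renormalized to sum to 100.
    """
    effects = validate_effect_spec(effects or {})
    known = {p.structure_id for p in params}
    unknown = set(effects) - known
    if unknown:
        raise ValueError(f"effects refer to unknown structure(s): {sorted(unknown)}")
    df = design.samples
    litter_index, litter_ids = pd.factorize(df["litter_id"], sort=True)
    is_m = (df["sex"] == "M").to_numpy()
    is_hf = (df["diet"] == "HFHSS").to_numpy()
    n = len(df)
    out = {}
    for sp in params:
        delta = effects.get(sp.structure_id, 0.0)
        gen = rng(seed, "volumes", sp.structure_id)
        b = gen.normal(0.0, sp.sd_litter, len(litter_ids))
        eps = gen.normal(0.0, sp.sd_resid, n)
        mu = np.where(is_m, sp.mean_rel_m, sp.mean_rel_f) * (
            1.0 + delta / 100.0 * is_hf
        )
        out[sp.structure_id] = mu + b[litter_index] + eps
    mat = pd.DataFrame(out, index=pd.Index(df["sample_id"], name="sample_id"))
    return mat


def simulate_weights(
    n_per_group: int = 20,
    n_weeks: int = 8,
    baseline: float = 22.0,
    weekly_gain=(0.625, 0.85),
    sd: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate weekly sire weights: linear growth plus per-record noise.

    ``weekly_gain`` is (CD, HFHSS) grams/week or a mapping; the defaults give
    the HFHSS group a 36% larger eight-week gain than CD.  Records cover
    weeks 0..n_weeks inclusive.  Deterministic given ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if isinstance(weekly_gain, dict):
        gains = {g: float(weekly_gain[g]) for g in DIETS}
    else:
        gains = dict(zip(DIETS, map(float, weekly_gain)))
    gen = rng(seed, "weights")
    rows = []
    for group in DIETS:
        for i in range(n_per_group):
            subject = f"{group}_S{i + 1:02d}"
            for week in range(n_weeks + 1):
                w = baseline + gains[group] * week + gen.normal(0.0, sd)
                rows.append(
                    {"subject_id": subject, "group": group,
                     "week": week, "weight_g": w}
                )
    return validate_weight_table(pd.DataFrame(rows))
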