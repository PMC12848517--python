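"""Domain containers shared across the package.

Tabular data (volume tables, relative-volume matrices, weight tables) is kept
in plain :class:`pandas.DataFrame` objects with validation helpers; small
structured records (cohort rosters, per-structure simulation parameters, test
results) are dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEXES = ("F", "M")
DIETS = ("CD", "HFHSS")

#: Columns of a cohort metadata table, in canonical order.
COHORT_COLUMNS = ("sample_id", "sex", "diet", "litter_id")

#: Columns of a weight table, in canonical order.
WEIGHT_COLUMNS = ("subject_id", "group", "week", "weight_g")


class CohortValidationError(ValueError):
    """A cohort roster violates a structural invariant."""


@dataclass
class CohortDesign:
    """Sample roster for a two-diet, litter-structured mouse cohort.

    Each row of ``samples`` describes one offspring: its id, sex (``F``/``M``),
    the paternal diet group (``CD``/``HFHSS``) and the litter it belongs to.
    Diet is a litter-level exposure: all pups of a litter share the sire, hence
    the diet label.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.samples).reset_index(drop=True)
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"metadata missing columns: {missing}")
        df = df.loc[:, list(COHORT_COLUMNS)].astype(
            {"sample_id": str, "sex": str, "diet": str, "litter_id": str}
        )
        object.__setattr__(self, "samples", df)
        self.validate()

    def validate(self, max_litter_size: int | None = None) -> None:
        df = self.samples
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate sample_id(s): {sorted(set(dup))}"
            )
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise CohortValidationError(f"unknown sex code(s): {sorted(bad_sex)}")
        bad_diet = set(df["diet"]) - set(DIETS)
        if bad_diet:
            raise CohortValidationError(f"unknown diet code(s): {sorted(bad_diet)}")
        diets_per_litter = df.groupby("litter_id")["diet"].nunique()
        mixed = diets_per_litter[diets_per_litter > 1]
        if len(mixed):
            raise CohortValidationError(
                "litter(s) span two diet groups (diet is a paternal, litter-level "
                f"exposure): {sorted(mixed.index)}"
            )
        if max_litter_size is not None:
            sizes = df.groupby("litter_id").size()
            over = sizes[sizes > max_litter_size]
            if len(over):
                raise CohortValidationError(
                    f"litter(s) exceed max size {max_litter_size}: {sorted(over.index)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def litter_ids(self) -> list[str]:
        return sorted(self.samples["litter_id"].unique())

    def litter_sizes(self) -> pd.Series:
        return self.samples.groupby("litter_id").size()

    def subset(self, sample_ids: Sequence[str]) -> "CohortDesign":
        """Roster restricted to ``sample_ids``, kept in the given order."""
        wanted = list(sample_ids)
        missing = set(wanted) - set(self.samples["sample_id"])
        if missing:
            raise KeyError(f"sample_id(s) not in cohort: {sorted(missing)}")
        indexed = self.samples.set_index("sample_id", drop=False)
        return CohortDesign(indexed.loc[wanted].reset_index(drop=True))

    def sex_balance_ok(self) -> bool:
        """True when every litter's sex split is even to within one pup."""
        if self.n_samples == 0:
            return True
        counts = self.samples.pivot_table(
            index="litter_id", columns="sex", values="sample_id",
            aggfunc="count", fill_value=0,
        )
        n_f = counts["F"] if "F" in counts.columns else pd.Series(0, index=counts.index)
        n_m = counts["M"] if "M" in counts.columns else pd.Series(0, index=counts.index)
        return bool((abs(n_f - n_m) <= 1).all())


@dataclass(frozen=True)
class StructureParams:
    """Per-structure simulation parameters on the relative-volume scale.

    Means are sex-specific structure volumes expressed as % of total brain
    volume; ``sd_litter`` and ``sd_resid`` are the litter random-intercept and
    residual standard deviations on the same scale.
    """

    structure_id: str
    mean_rel_f: float
    mean_rel_m: float
    sd_litter: float
    sd_resid: float

    def __post_init__(self) -> None:
        if not (self.mean_rel_f > 0 and self.mean_rel_m > 0):
            raise ValueError(f"{self.structure_id}: sex means must be > 0")
        if self.sd_litter < 0:
            raise ValueError(f"{self.structure_id}: sd_litter must be >= 0")
        if not self.sd_resid > 0:
            raise ValueError(f"{self.structure_id}: sd_resid must be > 0")

    @property
    def mean_rel(self) -> float:
        """Cross-sex average relative volume (% TBV)."""
        return 0.5 * (self.mean_rel_f + self.mean_rel_m)


#: Mapping structure_id -> percent multiplicative change applied to the
#: HFHSS group mean (0 = no change).  Entries must exceed -100.
EffectSpec = Mapping[str, float]


def validate_effect_spec(effects: EffectSpec) -> dict[str, float]:
    out = {}
    for sid, delta in dict(effects).items():
        delta = float(delta)
        if delta <= -100:
            raise ValueError(f"effect for {sid} must be > -100%, got {delta}")
        out[str(sid)] = delta
    return out


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a weight table and return it with canonical dtypes."""
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    df = weights.loc[:, list(WEIGHT_COLUMNS)].copy()
    df["week"] = df["week"].astype(int)
    df["weight_g"] = df["weight_g"].astype(float)
    if (df["week"] < 0).any():
        raise ValueError("weeks must be >= 0")
    if not (df["weight_g"] > 0).all():
        raise ValueError("weights must be positive")
    bad_group = set(df["group"]) - set(DIETS)
    if bad_group:
        raise ValueError(f"unknown group code(s): {sorted(bad_group)}")
    if df.duplicated(["subject_id", "week"]).any():
        raise ValueError("duplicate (subject_id, week) records")
    return df


@dataclass(frozen=True)
class ContrastTest:
    """A single t-type test: estimate, SE, t, degrees of freedom, two-sided p."""

    estimate: float
    se: float
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


@dataclass(frozen=True)
class PowerCurve:
    """Rejection frequency of the diet contrast across an effect-size grid."""

    structure_id: str
    effects: np.ndarray
    power: np.ndarray
    n_iter: int
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        eff = np.asarray(self.effects, dtype=float)
        pw = np.asarray(self.power, dtype=float)
        if eff.shape != pw.shape:
            raise ValueError("effects and power must have equal length")
        if len(eff) == 0:
            raise ValueError("empty effect grid")
        if np.any(np.diff(eff) <= 0):
            raise ValueError("effect grid must be strictly ascending")
        if np.any((pw < 0) | (pw > 1)):
            raise ValueError("power entries must lie in [0, 1]")
        object.__setattr__(self, "effects", eff)
        object.__setattr__(self, "power", pw)


LEFT_CENSORED = "left_censored_at_grid_min"
RIGHT_CENSORED = "right_censored_at_grid_max"


@dataclass(frozen=True)
class MdvcEstimate:
    """Minimum detectable volume change (%) at a target power, or censoring."""

    structure_id: str
    mdvc_pct: float  # NaN when censored
    censoring: str | None
    target_power: float
    alpha: float

    @property
    def censored(self) -> bool:
        return self.censoring is not None


@dataclass
class ScreenReport:
    """Structure-wise screen output.

    ``results`` has one row per converged structure with columns
    ``structure_id, pct_change, t, df, p, q`` sorted by ascending p
    (ties broken by structure_id).
    """

    results: pd.DataFrame
    fdr_level: float
    alpha_uncorrected: float
    n_discoveries: int
    n_uncorrected: int
    expected_chance: float
    n_tested: int
    excluded_structures: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "fdr_level": self.fdr_level,
            "n_discoveries": self.n_discoveries,
            "alpha_uncorrected": self.alpha_uncorrected,
            "n_uncorrected": self.n_uncorrected,
            "expected_chance": self.expected_chance,
            "excluded_structures": list(self.excluded_structures),
        }
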