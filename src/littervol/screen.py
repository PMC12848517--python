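"""Structure-wise screening: per-structure LME tests, FDR, weight comparisons.

One litter random-intercept model per structure, a Satterthwaite t-test of
the paternal-diet main effect, Benjamini-Hochberg adjustment across all
converged structures, and the expected-chance-findings arithmetic for the
uncorrected screen.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lme import DIET_CONTRAST, LmeWorkspace, test_contrast, welch_t_test
from .types import CohortDesign, ContrastTest, ScreenReport, validate_weight_table

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped to 1 and returned in the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expected_false_positives(m: int, alpha: float) -> float:
    """Expected count of uncorrected findings among m independent null tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return m * alpha


def analyze_structures(
    rel: pd.DataFrame,
    design: CohortDesign,
    fdr_level: float = 0.10,
    alpha_uncorrected: float = 0.05,
) -> ScreenReport:
    """Test every structure for a paternal-diet effect with litter-aware LMEs.

    Per structure: REML fit of relative volume on diet, sex, their interaction
    and a litter random intercept; two-sided Satterthwaite t-test of the diet
    main effect; percent change reported as 100 * (diet effect) / (model-implied
    CD mean averaged over sexes).  BH adjustment runs across all converged
    structures; non-converged ones are excluded and listed.
    """
    design = design.subset(list(rel.index))
    per_diet = design.samples.groupby("diet")["litter_id"].nunique()
    if len(per_diet) < 2 or (per_diet < 2).any():
        raise ValueError("need >= 2 litters in each diet group")
    ws = LmeWorkspace(design)
    rows = []
    excluded: list[str] = []
    for sid in rel.columns:
        fit = ws.fit(rel[sid].to_numpy(dtype=float))
        if not fit.converged:
            excluded.append(str(sid))
            continue
        ct = test_contrast(fit, DIET_CONTRAST)
        cd_mean = fit.beta[0]  # intercept = CD mean averaged over sexes
        rows.append(
            {
                "structure_id": str(sid),
                "pct_change": 100.0 * ct.estimate / cd_mean,
                "t": ct.t,
                "df": ct.df,
                "p": ct.p,
            }
        )
    if excluded:
        logger.warning("excluded %d non-converged structure(s): %s",
                       len(excluded), excluded)
    if not rows:
        raise ValueError("no structure converged; nothing to report")
    results = pd.DataFrame(rows)
    results["q"] = bh_adjust(results["p"].to_numpy())
    results = results.sort_values(["p", "structure_id"]).reset_index(drop=True)
    m = len(results)
    return ScreenReport(
        results=results,
        fdr_level=fdr_level,
        alpha_uncorrected=alpha_uncorrected,
        n_discoveries=int((results["q"] < fdr_level).sum()),
        n_uncorrected=int((results["p"] < alpha_uncorrected).sum()),
        expected_chance=expected_false_positives(m, alpha_uncorrected),
        n_tested=m,
        excluded_structures=excluded,
    )


def compare_weights(weights: pd.DataFrame, at_week="gain") -> ContrastTest:
    """Welch t-test of body weight (or weight gain) between diet groups.

    ``at_week="gain"`` compares per-subject gains, weight(final common week)
    minus weight(week 0); an integer compares absolute weights at that week.
    """
    weights = validate_weight_table(weights)
    wide = weights.pivot(index="subject_id", columns="week", values="weight_g")
    groups = weights.drop_duplicates("subject_id").set_index("subject_id")["group"]
    if groups.nunique() < 2:
        raise ValueError("both diet groups must be present")
    if at_week == "gain":
        if 0 not in wide.columns:
            raise ValueError("gain comparison requires week-0 records")
        final = max(wide.columns)
        values = wide[final] - wide[0]
        if values.isna().any():
            missing = sorted(values.index[values.isna()])
            raise ValueError(f"subjects missing week 0 or {final}: {missing}")
    else:
        week = int(at_week)
        if week not in wide.columns:
            raise ValueError(f"no records at week {week}")
        values = wide[week]
        if values.isna().any():
            missing = sorted(values.index[values.isna()])
            raise ValueError(f"subjects missing week {week}: {missing}")
    a = values[groups.reindex(values.index) == "CD"].to_numpy()
    b = values[groups.reindex(values.index) == "HFHSS"].to_numpy()
    return welch_t_test(b, a)  # estimate = HFHSS minus CD


def write_report(report: ScreenReport, tsv_path, json_path=None) -> None:
    """Write the per-structure TSV plus (optionally) a JSON summary."""
    report.results.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(report.summary(), fh, indent=2)
            fh.write("\n")
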