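"""Reading/writing volume, metadata and parameter tables; relative volumes.

All files are UTF-8 TSV with a header row.  The canonical volume dialect is
wide (first column ``sample_id``, one column per structure, volumes in mm^3);
a long dialect (``sample_id, structure_id, volume_mm3``) is accepted for
interchange.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lme import LmeWorkspace
from .types import CohortDesign, StructureParams

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("sample_id", "structure_id", "volume_mm3")
PARAM_COLUMNS = ("structure_id", "mean_rel_F", "mean_rel_M", "sd_litter", "sd_resid")


class TableFormatError(ValueError):
    """A table file violates the expected layout."""


def _validate_volume_frame(mat: pd.DataFrame, allow_missing: bool = True) -> pd.DataFrame:
    if mat.index.duplicated().any():
        dups = sorted(set(mat.index[mat.index.duplicated()]))
        raise TableFormatError(f"duplicated sample row(s): {dups}")
    if mat.columns.duplicated().any():
        dups = sorted(set(mat.columns[mat.columns.duplicated()]))
        raise TableFormatError(f"duplicated structure column(s): {dups}")
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"non-numeric volume entry: {exc}") from None
    nonpos = mat.le(0)
    if nonpos.any().any():
        row = mat.index[nonpos.any(axis=1)][0]
        raise TableFormatError(f"non-positive volume in sample {row!r}")
    if not allow_missing and mat.isna().any().any():
        row = mat.index[mat.isna().any(axis=1)][0]
        raise TableFormatError(f"missing volume in sample {row!r}")
    return mat.sort_index(axis=0).sort_index(axis=1)


def read_volume_table(path, dialect: str = "wide") -> pd.DataFrame:
    """Read an absolute-volume table (mm^3) as a sample x structure DataFrame.

    Rows and columns come back sorted by id.  Empty cells are treated as
    explicitly missing; non-positive or non-numeric volumes raise with the
    offending sample named.
    """
    if dialect == "wide":
        raw = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
        raw = raw.set_index(raw.columns[0])
        raw.index.name = "sample_id"
        return _validate_volume_frame(raw)
    if dialect == "long":
        raw = pd.read_csv(
            path, sep="\t", dtype={"sample_id": str, "structure_id": str},
            float_precision="round_trip",
        )
        missing = [c for c in LONG_COLUMNS if c not in raw.columns]
        if missing:
            raise TableFormatError(f"long volume table missing columns: {missing}")
        if raw.duplicated(["sample_id", "structure_id"]).any():
            bad = raw[raw.duplicated(["sample_id", "structure_id"])].iloc[0]
            raise TableFormatError(
                f"duplicated entry for sample {bad['sample_id']!r}, "
                f"structure {bad['structure_id']!r}"
            )
        mat = raw.pivot(index="sample_id", columns="structure_id", values="volume_mm3")
        mat.columns.name = None
        return _validate_volume_frame(mat)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


def write_volume_table(mat: pd.DataFrame, path, dialect: str = "wide") -> None:
    """Write a sample x structure table as TSV in the given dialect."""
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    if dialect == "wide":
        mat.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "long":
        long = (
            mat.rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="structure_id", value_name="volume_mm3")
            .dropna(subset=["volume_mm3"])
            .sort_values(["sample_id", "structure_id"])
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path) -> CohortDesign:
    """Read sample metadata (sample_id, sex, diet, litter_id) as a cohort."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CohortDesign(df)


def write_metadata(design: CohortDesign, path) -> None:
    design.samples.to_csv(path, sep="\t", index=False)


def check_sample_alignment(mat: pd.DataFrame, design: CohortDesign) -> None:
    """Raise if the volume matrix and metadata cover different samples."""
    vol_ids = set(mat.index)
    meta_ids = set(design.samples["sample_id"])
    if vol_ids != meta_ids:
        only_vol = sorted(vol_ids - meta_ids)
        only_meta = sorted(meta_ids - vol_ids)
        raise TableFormatError(
            "sample sets differ between volumes and metadata: "
            f"volumes-only={only_vol}, metadata-only={only_meta}"
        )


def compute_relative_volumes(vols: pd.DataFrame) -> pd.DataFrame:
    """Convert absolute volumes to % of total brain volume.

    Total brain volume for a sample is the sum of all its segmented structure
    volumes (this denominator choice changes every relative value, so it is
    stated here prominently).  Samples with any missing structure volume are
    dropped with a warning, since their total would be biased.
    """
    incomplete = vols.index[vols.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping %d sample(s) with missing structure volumes: %s",
            len(incomplete), list(incomplete),
        )
        vols = vols.drop(index=incomplete)
    totals = vols.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive total volume")
    return 100.0 * vols.div(totals, axis=0)


def extract_structure_params(
    rel: pd.DataFrame, design: CohortDesign, reference_diet: str = "CD"
) -> list[StructureParams]:
    """Estimate per-structure simulation parameters from a reference dataset.

    Fits the litter random-intercept model to each structure and returns the
    model-implied sex-specific means at the reference diet together with the
    estimated litter and residual SDs.  Structures whose fit does not converge
    are excluded with a warning.
    """
    design = design.subset(list(rel.index))
    groups = design.samples.groupby("diet")
    for diet, grp in groups:
        if grp["litter_id"].nunique() < 2:
            raise ValueError(f"need >= 2 litters in diet group {diet}")
        if len(grp) < 3:
            raise ValueError(f"need >= 3 samples in diet group {diet}")
    ws = LmeWorkspace(design)
    diet_code = 1.0 if reference_diet == "HFHSS" else 0.0
    out: list[StructureParams] = []
    for sid in rel.columns:
        fit = ws.fit(rel[sid].to_numpy(dtype=float))
        if not fit.converged:
            logger.warning("structure %s: LME did not converge; excluded", sid)
            continue
        b = fit.beta
        # model-implied means at the reference diet: intercept +- sex effect
        mean_f = b[0] + diet_code * b[1] - 0.5 * (b[2] + diet_code * b[3])
        mean_m = b[0] + diet_code * b[1] + 0.5 * (b[2] + diet_code * b[3])
        out.append(
            StructureParams(
                structure_id=str(sid),
                mean_rel_f=float(mean_f),
                mean_rel_m=float(mean_m),
                sd_litter=float(np.sqrt(max(fit.sigma2_litter, 0.0))),
                sd_resid=float(np.sqrt(fit.sigma2_resid)),
            )
        )
    return out


def write_structure_params(params: list[StructureParams], path) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": p.structure_id,
                "mean_rel_F": p.mean_rel_f,
                "mean_rel_M": p.mean_rel_m,
                "sd_litter": p.sd_litter,
                "sd_resid": p.sd_resid,
            }
            for p in params
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_structure_params(path) -> list[StructureParams]:
    df = pd.read_csv(path, sep="\t", dtype={"structure_id": str},
                     float_precision="round_trip")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"parameter table missing columns: {missing}")
    return [
        StructureParams(
            structure_id=row["structure_id"],
            mean_rel_f=float(row["mean_rel_F"]),
            mean_rel_m=float(row["mean_rel_M"]),
            sd_litter=float(row["sd_litter"]),
            sd_resid=float(row["sd_resid"]),
        )
        for _, row in df.iterrows()
    ]


def write_weight_table(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weight_table(path) -> pd.DataFrame:
    from .types import validate_weight_table

    return validate_weight_table(
        pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                    float_precision="round_trip")
    )
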