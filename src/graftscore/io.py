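"""File formats: label volumes (NIfTI/NRRD), landmark JSON, score CSVs.

All CSV outputs written by this package carry a schema-version comment on
the first line (``# schema=graftscore.<name>.v1``); readers reject unknown
versions.  The published study tables ship as checksum-pinned fixtures.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import LabeledVolume, ToothLandmarks

SCORES_SCHEMA = "graftscore.scores.v1"
MEASUREMENTS_SCHEMA = "graftscore.measurements.v1"
ASSESSMENTS_SCHEMA = "graftscore.assessments.v1"

_FIXTURE_SHA256 = {
    "table2_site_scores.csv": "534b17bf24ac5dd3c0faaeec495ce17a8d1d5b02e6363d925094aca7a5d990ec",
    "table3_total_scores.csv": "7dede0c1da87260ca8ea16dd532633ae94fdad35291bd09419795076bbb84738",
}


class FormatError(ValueError):
    """Unsupported or inconsistent on-disk data."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture failed its checksum."""


# ---------------------------------------------------------------- volumes

def write_volume(volume: LabeledVolume, path: str | Path) -> Path:
    """Write a label volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = Path(path)
    data = np.asarray(volume.voxels, dtype=np.int16)
    if path.suffix == ".nrrd":
        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
        img.SetSpacing((volume.spacing_mm,) * 3)
        img.SetDirection(tuple(volume.orientation.flatten()))
        sitk.WriteImage(img, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = volume.orientation * volume.spacing_mm
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path: str | Path) -> LabeledVolume:
    """Read a NIfTI or NRRD label volume.

    Rejects non-integer voxel data and anisotropic spacing (beyond 1e-6).
    """
    path = Path(path)
    if path.suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = np.asarray(img.GetSpacing())
        orientation = np.asarray(img.GetDirection()).reshape(3, 3)
    elif path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        orientation = affine[:3, :3] / spacing
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(
            f"label volumes must hold integer data, got dtype {data.dtype}"
        )
    if np.ptp(spacing) > 1e-6 * spacing.mean():
        raise FormatError(f"anisotropic spacing {spacing} is not supported")
    return LabeledVolume(
        np.ascontiguousarray(data), float(spacing.mean()), orientation
    )


# -------------------------------------------------------------- landmarks

def write_landmarks(landmarks: dict[str, ToothLandmarks], path: str | Path) -> Path:
    """Landmark JSON, world millimetres: {tooth: {cej_mm, apex_mm, axis}}."""
    path = Path(path)
    payload = {
        "units": "mm",
        "frame": "world (labiolingual, mesiodistal, apicocoronal; origin at volume corner)",
        "teeth": {name: lm.to_dict() for name, lm in landmarks.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_landmarks(path: str | Path) -> dict[str, ToothLandmarks]:
    payload = json.loads(Path(path).read_text())
    if payload.get("units") != "mm":
        raise FormatError("landmark files must declare units 'mm'")
    return {
        name: ToothLandmarks.from_dict(d) for name, d in payload["teeth"].items()
    }


# ------------------------------------------------------------ score tables

SCORE_COLUMNS = ["patient_id", "side", "level_mm", "score", "rater", "series", "flags"]


def validate_score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score-table schema and invariants."""
    missing = [c for c in SCORE_COLUMNS if c not in df.columns and c != "flags"]
    if missing:
        raise FormatError(f"score table missing columns: {missing}")
    if "flags" not in df.columns:
        df = df.assign(flags="")
    df = df.assign(flags=df["flags"].fillna("").astype(str))
    if not df["score"].isin([0, 1, 2, 3]).all():
        raise FormatError("scores must lie in 0..3")
    if not df["level_mm"].isin([3, 5, 7, 9]).all():
        raise FormatError("level_mm must be one of 3, 5, 7, 9")
    if not df["side"].isin(["cleft", "noncleft"]).all():
        raise FormatError("side must be 'cleft' or 'noncleft'")
    key = ["patient_id", "side", "level_mm", "rater", "series"]
    if df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)].head(4)
        raise FormatError(f"duplicate score rows for key {key}:\n{dupes}")
    return df


def write_scores(df: pd.DataFrame, path: str | Path, schema: str = SCORES_SCHEMA) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema={schema}\n")
        df.to_csv(fh, index=False)
    return path


def read_scores(path: str | Path, schema: str = SCORES_SCHEMA) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# schema="):
            raise FormatError(f"{path.name}: missing schema header line")
        found = first.removeprefix("# schema=")
        if found != schema:
            raise FormatError(
                f"{path.name}: unknown schema '{found}' (expected '{schema}')"
            )
        df = pd.read_csv(fh)
    if schema == SCORES_SCHEMA:
        df = validate_score_table(df)
    return df


# ---------------------------------------------------------------- fixtures

def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("graftscore.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureIntegrityError(
            f"fixture {name} is corrupted (sha256 {digest} != pinned)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_published_tables() -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Published per-level site-score marginals and total-score counts.

    Returns ``(site_scores, total_scores, n_patients)`` where
    ``site_scores`` has columns (side, level_mm, score, count) and
    ``total_scores`` has (side, total, count); both sides have 21 patients.
    """
    sites = _load_fixture("table2_site_scores.csv")
    totals = _load_fixture("table3_total_scores.csv")
    n = int(totals.groupby("side")["count"].sum().iloc[0])
    return sites, totals, n


def site_counts_to_scores(site_counts: pd.DataFrame, rater: str = "published") -> pd.DataFrame:
    """Expand (side, level_mm, score, count) marginals into a long score table.

    Patient identities are synthetic (marginals carry no pairing), one row
    per site; useful for summary statistics, not for paired tests.
    """
    rows = []
    for side, group in site_counts.groupby("side"):
        for level, lvl_group in group.groupby("level_mm"):
            pid = 0
            for _, row in lvl_group.sort_values("score").iterrows():
                for _ in range(int(row["count"])):
                    pid += 1
                    rows.append(
                        {"patient_id": f"M{pid:03d}", "side": side,
                         "level_mm": int(level), "score": int(row["score"]),
                         "rater": rater, "series": 1, "flags": ""}
                    )
    return validate_score_table(pd.DataFrame(rows))
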