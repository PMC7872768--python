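"""Reading and writing of subject tables, reports, and optional NIfTI ROI extraction.

The pipeline operates on two tabular inputs:

* a **regional volume table** — one row per subject, one column per atlas
  region (90 AAL-style cortical/subcortical regions by default), entries are
  grey-matter volumes in arbitrary volumetric units;
* a **cohort table** — per-subject demographics (age, gender), a two-level
  group label (patient vs. control), and any number of named clinical score
  columns.

Column order of the volume table defines node index order for every
downstream network: node ``i`` is column ``i``. ROI labels are used in all
reported output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ParseError",
    "ValidationError",
    "RegionalVolumeTable",
    "CohortTable",
    "read_volume_table",
    "write_volume_table",
    "read_clinical_table",
    "write_clinical_table",
    "extract_roi_volumes",
    "write_report",
    "DEFAULT_GENDER_MAP",
]

#: Gender is carried as a numeric 0/1 design column; text labels in input
#: files are coerced through this mapping (overridable per call).
DEFAULT_GENDER_MAP: Mapping[str, int] = {"M": 1, "F": 0, "male": 1, "female": 0}


class FormatError(ValueError):
    """A file's structure (headers, duplicated columns) is invalid."""


class ParseError(ValueError):
    """A cell could not be parsed; message carries row/column coordinates."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RegionalVolumeTable:
    """Subjects x ROI grey-matter volumes.

    Attributes
    ----------
    subject_ids : list of str
        Opaque subject identifiers, unique, in file/row order.
    roi_labels : list of str
        Region names, unique; their order defines node index order.
    volumes : ndarray, shape (n_subjects, n_roi)
        Finite grey-matter volumes (arbitrary volumetric units).
    """

    subject_ids: list[str]
    roi_labels: list[str]
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.roi_labels = [str(r) for r in self.roi_labels]
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject ids")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("duplicate ROI labels")
        if self.volumes.ndim != 2:
            raise ValidationError("volumes must be a 2-D matrix")
        if self.volumes.shape != (len(self.subject_ids), len(self.roi_labels)):
            raise ValidationError(
                f"volume matrix shape {self.volumes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.roi_labels)} ROIs"
            )
        if not np.all(np.isfinite(self.volumes)):
            bad = np.argwhere(~np.isfinite(self.volumes))[0]
            raise ValidationError(
                f"non-finite volume at subject {self.subject_ids[bad[0]]}, "
                f"ROI {self.roi_labels[bad[1]]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.volumes, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.roi_labels,
        )


@dataclasses.dataclass
class CohortTable:
    """Per-subject demographics, two-level group label and clinical scores.

    ``data`` holds one row per subject with at least the columns
    ``subject_id``, ``group``, ``age`` and ``gender`` (numeric 0/1); every
    other column is carried along as a named clinical variable and may
    contain missing values for subjects it does not apply to.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "gender")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        df = self.data.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject ids in cohort table")
        levels = df["group"].unique()
        if len(levels) > 2:
            raise ValidationError(f"group must have at most two levels, got {list(levels)}")
        if df["age"].isna().any():
            raise ValidationError("missing age values")
        if not (df["age"] > 0).all():
            raise ValidationError("age must be positive")
        self.data = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def group_levels(self) -> list:
        return sorted(self.data["group"].unique().tolist(), key=str)

    @property
    def clinical_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def subjects_in_group(self, level) -> np.ndarray:
        """Boolean mask over rows for one group level."""
        return (self.data["group"] == level).to_numpy()

    def aligned_to(self, volumes: RegionalVolumeTable) -> "CohortTable":
        """Reorder rows to match a volume table's subject order (one-to-one)."""
        ours = set(self.subject_ids)
        theirs = set(volumes.subject_ids)
        if ours != theirs:
            raise ValidationError(
                "cohort and volume tables do not describe the same subjects "
                f"(cohort-only: {sorted(ours - theirs)[:3]}, "
                f"volume-only: {sorted(theirs - ours)[:3]})"
            )
        df = self.data.set_index("subject_id").loc[volumes.subject_ids].reset_index()
        return CohortTable(df)


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_volume_table(path: str | Path, delimiter: str | None = None) -> RegionalVolumeTable:
    """Read a subjects x ROI volume table from delimited text.

    The first column holds subject ids; every remaining header names an ROI.
    The delimiter is auto-detected (comma vs. tab) unless given.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a subject id column plus ROI columns")
    header = list(df.columns)
    if any(h.startswith("Unnamed") or h.strip() == "" for h in header):
        raise FormatError(f"{path}: missing column header")
    if len(set(header)) != len(header) or any(h.endswith(".1") and h[:-2] in header for h in header):
        raise FormatError(f"{path}: duplicated column header")
    subject_ids = df.iloc[:, 0].tolist()
    roi_labels = header[1:]
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {r + 2} (subject {subject_ids[r]}), "
            f"column {roi_labels[c]!r}: {raw.iat[r, c]!r}"
        )
    return RegionalVolumeTable(subject_ids, roi_labels, numeric.to_numpy(dtype=float))


def write_volume_table(table: RegionalVolumeTable, path: str | Path, delimiter: str = "\t") -> None:
    table.to_dataframe().to_csv(path, sep=delimiter)


def read_clinical_table(
    path: str | Path,
    delimiter: str | None = None,
    gender_map: Mapping[str, int] = DEFAULT_GENDER_MAP,
) -> CohortTable:
    """Read a per-subject demographic/clinical table.

    Requires ``subject_id`` (or first column), ``group``, ``age`` and
    ``gender`` columns; extra clinical columns are kept by name. Textual
    gender labels are coerced to 0/1 through ``gender_map``.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0)
    if "subject_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "subject_id"})
    for col in ("group", "age", "gender"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing from header")
    if df["gender"].dtype == object:
        mapped = df["gender"].map(lambda g: gender_map.get(str(g).strip(), None))
        if mapped.isna().any():
            bad = df["gender"][mapped.isna()].iloc[0]
            raise ParseError(f"{path}: gender label {bad!r} not in mapping {dict(gender_map)}")
        df["gender"] = mapped.astype(int)
    return CohortTable(df)


def write_clinical_table(cohort: CohortTable, path: str | Path, delimiter: str = "\t") -> None:
    cohort.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Optional NIfTI ROI extraction
# ---------------------------------------------------------------------------


def extract_roi_volumes(
    gm_maps: Sequence,
    atlas,
    stat: str = "sum",
    subject_ids: Sequence[str] | None = None,
) -> RegionalVolumeTable:
    """Aggregate voxel values of grey-matter maps within integer atlas labels.

    Parameters
    ----------
    gm_maps : sequence of NIfTI images or paths
        One 3-D grey-matter map per subject, all on the atlas grid.
    atlas : NIfTI image or path
        3-D integer label volume; positive labels define ROIs, ascending
        label order defines column order.
    stat : {"sum", "mean"}
        ``sum`` integrates voxel values and scales by voxel volume from the
        image affine (so a probability/density map yields volumetric units);
        ``mean`` averages voxel values within the label.
    """
    import nibabel as nib

    if stat not in ("sum", "mean"):
        raise ValueError(f"stat must be 'sum' or 'mean', got {stat!r}")
    atlas_img = nib.load(str(atlas)) if not hasattr(atlas, "get_fdata") else atlas
    labels_vol = np.asarray(atlas_img.get_fdata())
    if not np.allclose(labels_vol, np.round(labels_vol)):
        raise ValidationError("atlas volume must contain integer labels")
    labels_vol = labels_vol.astype(int)
    labels = np.unique(labels_vol)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValidationError("atlas contains no positive labels")

    rows = []
    for k, m in enumerate(gm_maps):
        img = nib.load(str(m)) if not hasattr(m, "get_fdata") else m
        data = np.asarray(img.get_fdata())
        if data.shape != labels_vol.shape:
            raise ValidationError(
                f"map {k} grid {data.shape} does not match atlas grid {labels_vol.shape}"
            )
        voxel_volume = float(abs(np.linalg.det(np.asarray(img.affine)[:3, :3])))
        row = np.empty(labels.size)
        for c, lab in enumerate(labels):
            mask = labels_vol == lab
            n_vox = int(mask.sum())
            if n_vox == 0:  # unreachable for labels from np.unique; kept for API parity
                row[c] = 0.0
                continue
            vals = data[mask]
            row[c] = vals.sum() * voxel_volume if stat == "sum" else vals.mean()
        rows.append(row)

    ids = list(subject_ids) if subject_ids is not None else [f"sub-{k:03d}" for k in range(len(rows))]
    roi_labels = [f"roi-{int(lab)}" for lab in labels]
    return RegionalVolumeTable(ids, roi_labels, np.vstack(rows) if rows else np.empty((0, labels.size)))


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write a pipeline result bundle to ``out_dir``.

    DataFrame values are written as TSV (one file per key), everything else
    is pooled into ``report.json`` with sorted keys for byte-stable reruns.
    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalar_results = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            p = out_dir / f"{key}.tsv"
            value.to_csv(p, sep="\t", index=False)
            written.append(p)
        else:
            scalar_results[key] = _jsonable(value)
    p = out_dir / "report.json"
    with open(p, "w") as fh:
        json.dump(scalar_results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written


def read_report(out_dir: str | Path) -> dict:
    """Re-load a bundle written by :func:`write_report` (lossless round-trip)."""
    out_dir = Path(out_dir)
    with open(out_dir / "report.json") as fh:
        results = json.load(fh)
    for p in sorted(out_dir.glob("*.tsv")):
        results[p.stem] = pd.read_csv(p, sep="\t")
    return results
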