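"""Regional volumetry: grey-matter-masked volumes, ICV normalization, cohort I/O.

A cohort is a table with one row per subject: identifying metadata
(``subject_id``, ``group``, ``side``, ``age``, ``sex``, ``icv_cm3``) followed
by the 83 regional volumes in catalog order. Volumes are stored in mm^3;
after :func:`normalize_by_icv` they are dimensionless volume/ICV ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import StructureCatalog, default_catalog
from .images import LabelVolume

__all__ = [
    "METADATA_COLUMNS",
    "SubjectRecord",
    "CohortTable",
    "regional_volumes",
    "normalize_by_icv",
    "read_cohort",
    "write_cohort",
]

METADATA_COLUMNS = ("subject_id", "group", "side", "age", "sex", "icv_cm3")

#: grey-matter probability above which a voxel counts toward a masked region
GM_THRESHOLD = 0.5


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    side: str  # "L" | "R" | "none"
    age: float
    sex: str  # "F" | "M"
    icv: float  # cm^3
    volumes: dict[str, float]  # structure name -> mm^3 (or ratio if normalized)

    def __post_init__(self) -> None:
        if self.icv <= 0:
            raise ValueError(f"subject {self.subject_id}: ICV must be positive")


@dataclass
class CohortTable:
    """Ordered table of subjects with regional volumes.

    ``data`` holds the metadata columns, the structure columns (in catalog
    order) and any extra columns carried along as opaque metadata. Only
    catalog names enter the analysis.
    """

    data: pd.DataFrame
    normalized: bool = False
    catalog: StructureCatalog = field(default_factory=default_catalog)

    def __post_init__(self) -> None:
        missing_meta = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing_meta:
            raise ValueError(f"cohort table missing metadata columns: {missing_meta}")
        missing = [n for n in self.catalog.names if n not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing structure columns: {missing}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate subject_id values: {dupes}")
        if (self.data["icv_cm3"] <= 0).any():
            bad = self.data.loc[self.data["icv_cm3"] <= 0, "subject_id"].tolist()
            raise ValueError(f"non-positive ICV for subjects: {bad}")
        # canonical column order: metadata, structures, extras
        extras = [
            c for c in self.data.columns
            if c not in METADATA_COLUMNS and c not in set(self.catalog.names)
        ]
        self.data = self.data[
            list(METADATA_COLUMNS) + list(self.catalog.names) + extras
        ].reset_index(drop=True)

    # --- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def structures(self) -> tuple[str, ...]:
        return self.catalog.names

    @property
    def extra_columns(self) -> list[str]:
        return [
            c for c in self.data.columns
            if c not in METADATA_COLUMNS and c not in set(self.catalog.names)
        ]

    def volume_matrix(self) -> np.ndarray:
        """N x 83 array of volumes (or ratios) in catalog column order."""
        return self.data[list(self.catalog.names)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def subset(self, mask) -> "CohortTable":
        """Row subset (boolean mask or positional indices), preserving order."""
        mask = np.asarray(mask)
        sub = self.data[mask] if mask.dtype == bool else self.data.iloc[mask]
        return replace(self, data=sub.reset_index(drop=True))

    def select_groups(self, groups) -> "CohortTable":
        return self.subset(self.data["group"].isin(list(groups)).to_numpy())

    def records(self) -> list[SubjectRecord]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    side=str(row["side"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    icv=float(row["icv_cm3"]),
                    volumes={n: float(row[n]) for n in self.catalog.names},
                )
            )
        return out


# --- operations ------------------------------------------------------------


def regional_volumes(
    labels: LabelVolume,
    gm_probability: np.ndarray,
    catalog: StructureCatalog | None = None,
) -> dict[str, float]:
    """Per-region volumes in mm^3 from a label image and a GM probability map.

    Non-exempt regions are restricted to voxels whose grey-matter probability
    strictly exceeds 50%; exempt regions (ventricles, corpus callosum, deep
    grey nuclei, brainstem) are counted in full.

    Label codes absent from the catalog are ignored; catalog regions absent
    from the image get volume 0.
    """
    catalog = catalog or default_catalog()
    gm = np.asarray(gm_probability, dtype=float)
    if gm.shape != labels.grid.shape:
        raise ValueError(
            f"grid mismatch: labels {labels.grid.shape} vs GM map {gm.shape}"
        )
    if gm.min() < 0 or gm.max() > 1:
        raise ValueError("gm_probability values must lie in [0, 1]")

    vv = labels.voxel_volume
    gm_mask = gm > GM_THRESHOLD
    known = set(catalog.names)
    out: dict[str, float] = {name: 0.0 for name in catalog.names}
    for code, name in labels.codes.items():
        if name not in known:
            continue  # unknown label codes ignored
        region = labels.grid == code
        if name in catalog.gm_exempt:
            count = int(region.sum())
        else:
            count = int((region & gm_mask).sum())
        out[name] = count * vv
    return out


def normalize_by_icv(cohort: CohortTable) -> CohortTable:
    """Replace each volume (mm^3) by the dimensionless ratio volume / ICV.

    ICV is stored in cm^3 and converted to mm^3 so units cancel. Refuses to
    normalize twice.
    """
    if cohort.normalized:
        raise ValueError("cohort is already ICV-normalized")
    bad = cohort.data.loc[cohort.data["icv_cm3"] <= 0, "subject_id"].tolist()
    if bad:
        raise ValueError(f"non-positive ICV for subjects: {bad}")
    data = cohort.data.copy()
    icv_mm3 = data["icv_cm3"].to_numpy(dtype=float) * 1000.0
    cols = list(cohort.catalog.names)
    data[cols] = data[cols].to_numpy(dtype=float) / icv_mm3[:, None]
    return replace(cohort, data=data, normalized=True)


# --- I/O --------------------------------------------------------------------

_HEADER_PREFIX = "# tlemorph-cohort"


def write_cohort(cohort: CohortTable, path) -> None:
    """Write as CSV with a comment header carrying the normalized flag."""
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX} normalized={str(cohort.normalized).lower()}\n")
        cohort.data.to_csv(fh, index=False)


def read_cohort(path, catalog: StructureCatalog | None = None) -> CohortTable:
    """Read a cohort CSV; errors name any missing structure columns."""
    catalog = catalog or default_catalog()
    normalized = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_HEADER_PREFIX):
            normalized = "normalized=true" in first
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [n for n in catalog.names if n not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing structure columns: {missing}")
    return CohortTable(data=df, normalized=normalized, catalog=catalog)
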