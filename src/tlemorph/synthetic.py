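"""Synthetic cohorts with the statistical structure the analysis assumes.

No patient scans accompany this package, so the generator produces regional
volume tables directly, under a simple generative model:

* intracranial volume (ICV) is drawn per subject from a group-specific
  normal distribution truncated at zero;
* each regional volume is proportional to ICV (a fixed per-structure base
  fraction), reduced by a group-specific fractional atrophy effect on
  affected structures, and perturbed by lognormal multiplicative noise whose
  coefficient of variation is ``noise_cv``.

Proportionality to ICV reproduces the positive volume-ICV correlation seen
in real cohorts; lateralized effect maps are defined for left-focus groups
and mirrored across the midline for right-focus groups.

The module also builds toy label-image pairs for exercising the fusion and
overlap machinery without registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import StructureCatalog, default_catalog
from .images import LabelVolume
from .volumetry import CohortTable

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "generate_cohort",
    "generate_label_pair",
    "default_base_fractions",
    "default_groups",
    "default_cohort_config",
    "CONTROL",
    "TLE_HA_L",
    "TLE_HA_R",
    "TLE_N_L",
    "TLE_N_R",
]

CONTROL = "control"
TLE_HA_L = "TLE-HA_L"
TLE_HA_R = "TLE-HA_R"
TLE_N_L = "TLE-N_L"
TLE_N_R = "TLE-N_R"

GROUP_NAMES = (CONTROL, TLE_HA_L, TLE_HA_R, TLE_N_L, TLE_N_R)


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group of the synthetic cohort.

    ``effects`` maps structure names to fractional volume reductions in
    [0, 1); a value of 0.30 on the hippocampus means the group's hippocampal
    volumes are on average 30% smaller than ICV-proportionality predicts.
    """

    name: str
    n: int
    icv_mean: float  # cm^3
    icv_sd: float  # cm^3
    effects: dict[str, float] = field(default_factory=dict)
    age_median: float = 35.0
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.5  # fraction female

    def validate(self, catalog: StructureCatalog) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.name}: need n >= 2, got {self.n}")
        if self.icv_sd <= 0:
            raise ValueError(f"group {self.name}: icv_sd must be positive")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError(f"group {self.name}: sex_ratio must be in [0, 1]")
        known = set(catalog.names)
        for s, e in self.effects.items():
            if s not in known:
                raise ValueError(f"group {self.name}: unknown structure {s!r} in effects")
            if not 0 <= e < 1:
                raise ValueError(f"group {self.name}: effect for {s} must be in [0, 1)")

    @property
    def side(self) -> str:
        if self.name.endswith("_L"):
            return "L"
        if self.name.endswith("_R"):
            return "R"
        return "none"


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    base_fractions: dict[str, float]
    noise_cv: float = 0.08
    seed: int = 0
    #: optional fractional volume change per year of age relative to age 40
    age_slope_per_year: float = 0.0

    def validate(self, catalog: StructureCatalog) -> None:
        if not self.groups:
            raise ValueError("cohort config needs at least one group")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        missing = [n for n in catalog.names if n not in self.base_fractions]
        if missing:
            raise ValueError(f"base_fractions missing structures: {missing[:5]}...")
        bad = [n for n in catalog.names if self.base_fractions[n] <= 0]
        if bad:
            raise ValueError(f"base_fractions must be positive; offending: {bad[:5]}")
        for g in self.groups:
            g.validate(catalog)


# --- defaults ----------------------------------------------------------------

#: Approximate structure volume as a fraction of ICV, per bilateral stem or
#: midline structure. Values are plausible adult magnitudes (hippocampus
#: ~3 cm^3 against ~1450 cm^3 ICV etc.); absolute levels are inconsequential
#: for the analysis, which operates on ICV ratios and z-scores.
_BASE_FRACTION_BY_STEM: dict[str, float] = {
    "Hippocampus": 0.0022,
    "Amygdala": 0.0012,
    "Ant_temporal_lobe_medial": 0.0040,
    "Ant_temporal_lobe_lateral": 0.0050,
    "Parahippocampal_gyrus": 0.0030,
    "Sup_temporal_gyrus_post": 0.0070,
    "Sup_temporal_gyrus_ant": 0.0030,
    "Mid_inf_temporal_gyrus": 0.0150,
    "Fusiform_gyrus": 0.0060,
    "Post_temporal_lobe": 0.0150,
    "Cerebellum": 0.0370,
    "Brainstem": 0.0160,
    "Insula": 0.0070,
    "Ant_cingulate_gyrus": 0.0060,
    "Post_cingulate_gyrus": 0.0060,
    "Mid_frontal_gyrus": 0.0180,
    "Precentral_gyrus": 0.0120,
    "Straight_gyrus": 0.0015,
    "Ant_orbital_gyrus": 0.0015,
    "Inf_frontal_gyrus": 0.0080,
    "Sup_frontal_gyrus": 0.0180,
    "Med_orbital_gyrus": 0.0020,
    "Lat_orbital_gyrus": 0.0015,
    "Post_orbital_gyrus": 0.0020,
    "Subgenual_frontal_cortex": 0.0006,
    "Subcallosal_area": 0.0005,
    "Presubgenual_frontal_cortex": 0.0004,
    "Postcentral_gyrus": 0.0090,
    "Sup_parietal_gyrus": 0.0110,
    "Inf_lat_parietal_lobe": 0.0150,
    "Lingual_gyrus": 0.0060,
    "Cuneus": 0.0040,
    "Lat_occipital_lobe": 0.0120,
    "Caudate_nucleus": 0.0028,
    "Nucleus_accumbens": 0.0004,
    "Putamen": 0.0035,
    "Thalamus": 0.0050,
    "Pallidum": 0.0012,
    "Substantia_nigra": 0.0004,
    "Corpus_callosum": 0.0100,
    "Lat_ventricle": 0.0050,
    "Lat_ventricle_temporal_horn": 0.0008,
    "Third_ventricle": 0.0008,
}


def default_base_fractions(catalog: StructureCatalog | None = None) -> dict[str, float]:
    catalog = catalog or default_catalog()
    out: dict[str, float] = {}
    for name in catalog.names:
        stem = name[:-2] if name.endswith(("_L", "_R")) else name
        out[name] = _BASE_FRACTION_BY_STEM[stem]
    return out


def _graded(names: list[str], hi: float, lo: float) -> dict[str, float]:
    grades = np.linspace(hi, lo, len(names))
    return {n: float(g) for n, g in zip(names, grades)}


def _tle_ha_left_effects() -> dict[str, float]:
    # ipsilateral atrophy, strongest in the hippocampus, graded down the
    # remaining affected structures; the anterior temporal lobe contributes
    # both its lateral and medial parts at a shared grade
    eff = {"Hippocampus_L": 0.30}
    ranked = [
        "Amygdala_L",
        "Ant_orbital_gyrus_L",
        ("Ant_temporal_lobe_lateral_L", "Ant_temporal_lobe_medial_L"),
        "Fusiform_gyrus_L",
        "Thalamus_L",
        "Cerebellum_L",
        "Parahippocampal_gyrus_L",
        "Med_orbital_gyrus_L",
    ]
    grades = np.linspace(0.15, 0.05, len(ranked))
    for entry, g in zip(ranked, grades):
        for name in (entry if isinstance(entry, tuple) else (entry,)):
            eff[name] = float(g)
    return eff


def _tle_n_left_effects() -> dict[str, float]:
    # subtler, orbitofronto-temporal pattern, partly contralateral
    ranked = [
        "Substantia_nigra_L",
        "Ant_orbital_gyrus_L",
        "Straight_gyrus_R",
        "Med_orbital_gyrus_L",
        "Subgenual_frontal_cortex_L",
        "Lingual_gyrus_R",
        "Ant_temporal_lobe_lateral_L",
        "Subcallosal_area_R",
        "Amygdala_L",
        "Cerebellum_L",
    ]
    return _graded(ranked, 0.10, 0.03)


def default_groups(catalog: StructureCatalog | None = None) -> tuple[GroupSpec, ...]:
    """Study-size groups: 28 controls, 60 TLE-HA (33 L / 27 R), 20 TLE-N (11 L / 9 R)."""
    catalog = catalog or default_catalog()
    ha_l = _tle_ha_left_effects()
    ha_r = catalog.mirror_effects(ha_l)
    n_l = _tle_n_left_effects()
    n_r = catalog.mirror_effects(n_l)
    return (
        GroupSpec(CONTROL, 28, 1483.0, 160.0, {}, 31.0, (19.0, 55.0), 14 / 28),
        GroupSpec(TLE_HA_L, 33, 1387.0, 128.0, ha_l, 39.0, (19.0, 66.0), 29 / 60),
        GroupSpec(TLE_HA_R, 27, 1387.0, 128.0, ha_r, 39.0, (19.0, 66.0), 29 / 60),
        GroupSpec(TLE_N_L, 11, 1423.0, 150.0, n_l, 38.0, (23.0, 53.0), 9 / 20),
        GroupSpec(TLE_N_R, 9, 1423.0, 150.0, n_r, 38.0, (23.0, 53.0), 9 / 20),
    )


def default_cohort_config(seed: int = 0, noise_cv: float = 0.08) -> CohortConfig:
    catalog = default_catalog()
    return CohortConfig(
        groups=default_groups(catalog),
        base_fractions=default_base_fractions(catalog),
        noise_cv=noise_cv,
        seed=seed,
    )


# --- generation --------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws resampled until positive (truncation at 0)."""
    out = rng.normal(mean, sd, size=n)
    while (out <= 0).any():
        bad = out <= 0
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def _ages(rng: np.random.Generator, spec: GroupSpec) -> np.ndarray:
    lo, hi = spec.age_range
    sd = max((hi - lo) / 4.0, 1.0)
    out = rng.normal(spec.age_median, sd, size=spec.n)
    while ((out < lo) | (out > hi)).any():
        bad = (out < lo) | (out > hi)
        out[bad] = rng.normal(spec.age_median, sd, size=int(bad.sum()))
    return np.round(out).astype(float)


def generate_cohort(
    config: CohortConfig, catalog: StructureCatalog | None = None
) -> CohortTable:
    """Draw a cohort table from the generative model, deterministic given seed."""
    catalog = catalog or default_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    # multiplicative lognormal noise with CV == noise_cv
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    base = np.array([config.base_fractions[n] for n in catalog.names])
    effects_rows = []
    rows = []
    for spec in config.groups:
        icv = _truncated_normal(rng, spec.icv_mean, spec.icv_sd, spec.n)
        ages = _ages(rng, spec)
        n_female = int(round(spec.n * spec.sex_ratio))
        sexes = np.array(["F"] * n_female + ["M"] * (spec.n - n_female))
        rng.shuffle(sexes)
        reduction = np.array(
            [1.0 - spec.effects.get(n, 0.0) for n in catalog.names]
        )
        for i in range(spec.n):
            if sigma > 0:
                noise = np.exp(rng.normal(0.0, sigma, size=len(catalog)))
            else:
                noise = np.ones(len(catalog))
            age_factor = 1.0 + config.age_slope_per_year * (ages[i] - 40.0)
            vols = base * (icv[i] * 1000.0) * reduction * noise * age_factor
            rows.append(
                {
                    "subject_id": f"{spec.name}_{i:03d}",
                    "group": spec.name,
                    "side": spec.side,
                    "age": ages[i],
                    "sex": sexes[i],
                    "icv_cm3": icv[i],
                    **dict(zip(catalog.names, vols)),
                }
            )
        effects_rows.append(spec)
    df = pd.DataFrame(rows)
    return CohortTable(data=df, normalized=False, catalog=catalog)


def generate_label_pair(
    shape: tuple[int, int, int],
    n_regions: int,
    flip_fraction: float,
    seed: int = 0,
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[LabelVolume, LabelVolume]:
    """A block-partition label image and a noise-degraded copy.

    The first volume splits the grid into ``n_regions`` contiguous slabs
    labelled 1..n_regions; the second reassigns a ``flip_fraction`` of voxels
    to a uniformly random *other* label. With a single region there is no
    other label and the copy is identical.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must be in [0, 1]")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("shape must be three positive integers")
    if shape[0] < n_regions:
        raise ValueError(
            f"grid of shape {shape} cannot host {n_regions} slab regions"
        )
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, shape[0], n_regions + 1).round().astype(int)
    grid = np.zeros(shape, dtype=np.int16)
    for r in range(n_regions):
        grid[edges[r] : edges[r + 1]] = r + 1
    codes = {r + 1: f"Region_{r + 1:02d}" for r in range(n_regions)}
    a = LabelVolume(grid=grid, voxel_dims=voxel_dims, codes=codes)

    flipped = grid.copy()
    if n_regions > 1 and flip_fraction > 0:
        n_vox = grid.size
        n_flip = int(round(flip_fraction * n_vox))
        idx = rng.choice(n_vox, size=n_flip, replace=False)
        flat = flipped.ravel()
        # shift by a random offset in 1..n_regions-1, modulo the label cycle
        offsets = rng.integers(1, n_regions, size=n_flip)
        flat[idx] = (flat[idx] - 1 + offsets) % n_regions + 1
    b = LabelVolume(grid=flipped, voxel_dims=voxel_dims, codes=dict(codes))
    return a, b
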