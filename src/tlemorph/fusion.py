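"""Vote-rule label fusion and region overlap evaluation.

Multi-atlas segmentation yields one candidate label image per atlas for each
target brain; :func:`vote_fuse` combines them by per-voxel majority vote.
:func:`dice_overlap` and :func:`overlap_comparison` quantify region-wise
agreement between segmentations, e.g. to compare two fusion pipelines against
a common reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .images import LabelVolume

__all__ = ["vote_fuse", "dice_overlap", "overlap_comparison", "OverlapComparison"]


def _check_same_grid(vols: Sequence[LabelVolume]) -> None:
    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"grid mismatch: {first.grid.shape}/{first.voxel_dims} vs "
                f"{v.grid.shape}/{v.voxel_dims}"
            )


def vote_fuse(candidates: Sequence[LabelVolume]) -> LabelVolume:
    """Per-voxel modal label across candidates; lowest label code wins ties.

    The tie rule makes the result deterministic and independent of candidate
    order. Code maps of the candidates are merged (first definition wins).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("vote_fuse needs at least one candidate segmentation")
    _check_same_grid(candidates)
    stack = np.stack([c.grid for c in candidates], axis=0)
    # scipy's mode returns the smallest modal value on ties
    fused = stats.mode(stack, axis=0, keepdims=False).mode.astype(stack.dtype)
    codes: dict[int, str] = {}
    for c in candidates:
        for k, v in c.codes.items():
            codes.setdefault(k, v)
    return LabelVolume(grid=fused, voxel_dims=candidates[0].voxel_dims, codes=codes)


def _region_mask(vol: LabelVolume, region: str) -> np.ndarray | None:
    code = vol.label_for(region)
    if code is None:
        return None
    return vol.grid == code


def dice_overlap(
    a: LabelVolume, b: LabelVolume, region: str, metric: str = "dice"
) -> float:
    """Overlap of one named region between two segmentations.

    Dice = 2|A n B| / (|A| + |B|); Jaccard = |A n B| / |A u B|. Both are 1.0
    when the region is empty in both images, and invariant to voxel size. The
    region must appear in the code map of at least one input; in an input
    whose code map lacks it, the region is the empty set.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"grid mismatch: {a.grid.shape} vs {b.grid.shape}")
    ma, mb = _region_mask(a, region), _region_mask(b, region)
    if ma is None and mb is None:
        raise KeyError(f"region {region!r} unknown to both inputs")
    if ma is None:
        ma = np.zeros_like(mb)
    if mb is None:
        mb = np.zeros_like(ma)
    na, nb = int(ma.sum()), int(mb.sum())
    inter = int((ma & mb).sum())
    if metric == "dice":
        return 1.0 if na + nb == 0 else 2.0 * inter / (na + nb)
    if metric == "jaccard":
        union = na + nb - inter
        return 1.0 if union == 0 else inter / union
    raise ValueError(f"unknown overlap metric {metric!r}")


@dataclass(frozen=True)
class OverlapComparison:
    """Per-region paired differences of mean overlap (set A minus set B)."""

    regions: tuple[str, ...]
    differences: np.ndarray  # one value per region
    mean: float
    sd: float


def overlap_comparison(
    set_a: Sequence[LabelVolume],
    set_b: Sequence[LabelVolume],
    reference: LabelVolume,
    regions: Sequence[str] | None = None,
    metric: str = "dice",
) -> OverlapComparison:
    """Compare two segmentation sets against one reference, region by region.

    For each region the statistic is the difference of the mean overlap of
    set A with the reference minus that of set B. The summary is mean +/- SD
    over regions (population SD; 0 for a single region).
    """
    set_a, set_b = list(set_a), list(set_b)
    if len(set_a) != len(set_b):
        raise ValueError(
            f"set length mismatch: {len(set_a)} vs {len(set_b)} segmentations"
        )
    if not set_a:
        raise ValueError("need at least one segmentation per set")
    if regions is None:
        regions = [reference.codes[k] for k in sorted(reference.codes)]
    diffs = []
    for region in regions:
        da = np.mean([dice_overlap(v, reference, region, metric) for v in set_a])
        db = np.mean([dice_overlap(v, reference, region, metric) for v in set_b])
        diffs.append(da - db)
    arr = np.asarray(diffs, dtype=float)
    return OverlapComparison(
        regions=tuple(regions),
        differences=arr,
        mean=float(arr.mean()),
        sd=float(arr.std()),
    )
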