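"""Bullseye parcellation of cerebral white matter.

The parcellation intersects two voxelwise coordinate maps:

* a *concentric* map — the normalized ventricle-to-cortex distance
  ``d_vent / (d_vent + d_cortex)`` cut into four equidistant layers
  ``[0, 0.25) [0.25, 0.5) [0.5, 0.75) [0.75, 1]`` numbered 1..4 from the
  ventricles outwards, and
* a *lobar* map — nine regions (frontal/parietal/temporal/occipital per
  hemisphere plus one bilateral basal-ganglia region) coded 1..9,

yielding 36 parcels coded ``region * 10 + layer`` (11..94).  Every voxel of
the white-matter + basal-ganglia domain receives exactly one parcel code, so
the nonzero voxel count of the parcellation equals the domain voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, ScalarVolume, check_same_grid

__all__ = [
    "REGION_NAMES",
    "PARCEL_CODES",
    "N_LAYERS",
    "BullseyeMap",
    "distance_map",
    "normalized_distance",
    "assign_layers",
    "build_bullseye",
    "parcel_code",
    "parcel_decode",
    "parcel_name",
    "parcellate",
]

#: Fixed region order; determines CSV column order downstream.
REGION_NAMES: dict[int, str] = {
    1: "frontal-L",
    2: "frontal-R",
    3: "parietal-L",
    4: "parietal-R",
    5: "temporal-L",
    6: "temporal-R",
    7: "occipital-L",
    8: "occipital-R",
    9: "basal-ganglia",
}

N_LAYERS = 4

LAYER_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)


def parcel_code(region: int, layer: int) -> int:
    """Encode (region 1..9, layer 1..4) as the two-digit parcel code."""
    if not 1 <= region <= 9:
        raise ValueError(f"region must be in 1..9, got {region}")
    if not 1 <= layer <= N_LAYERS:
        raise ValueError(f"layer must be in 1..{N_LAYERS}, got {layer}")
    return region * 10 + layer


def parcel_decode(code: int) -> tuple[int, int]:
    """Inverse of :func:`parcel_code`."""
    region, layer = divmod(int(code), 10)
    if not (1 <= region <= 9 and 1 <= layer <= N_LAYERS):
        raise ValueError(f"invalid parcel code {code}")
    return region, layer


#: All 36 parcel codes in region-major order (11..14, 21..24, ..., 91..94).
PARCEL_CODES: tuple[int, ...] = tuple(
    parcel_code(r, l) for r in REGION_NAMES for l in range(1, N_LAYERS + 1)
)


def parcel_name(code: int) -> str:
    region, layer = parcel_decode(code)
    return f"{REGION_NAMES[region]}-layer{layer}"


@dataclass
class BullseyeMap:
    """36-parcel label volume plus the code table describing each parcel."""

    values: LabelVolume
    code_table: dict[int, tuple[str, str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.code_table:
            self.code_table = {
                code: (
                    REGION_NAMES[parcel_decode(code)[0]],
                    _hemisphere(parcel_decode(code)[0]),
                    parcel_decode(code)[1],
                )
                for code in PARCEL_CODES
            }

    @property
    def spacing(self):
        return self.values.spacing

    def codes_present(self) -> np.ndarray:
        codes = np.unique(self.values.data)
        return codes[codes != 0]


def _hemisphere(region: int) -> str:
    if region == 9:
        return "both"
    return "left" if region % 2 == 1 else "right"


def distance_map(mask: LabelVolume, spacing=None) -> ScalarVolume:
    """Exact Euclidean distance (mm) from every voxel to the nearest mask voxel.

    Honors anisotropic spacing via the EDT sampling argument.  Zero on mask
    voxels by construction.
    """
    if spacing is None:
        spacing = mask.spacing
    m = mask.as_bool()
    if not m.any():
        raise ValueError("distance_map: mask is empty, distance undefined")
    dist = ndimage.distance_transform_edt(~m, sampling=spacing)
    return ScalarVolume(dist, spacing, affine=mask.affine)


def normalized_distance(
    dist_vent: ScalarVolume, dist_cortex: ScalarVolume, domain: LabelVolume
) -> ScalarVolume:
    """Normalized ventricle-to-cortex distance on the domain, NaN elsewhere.

    ``value_i = dv_i / (dv_i + dc_i)`` — 0 at the ventricle surface, 1 at the
    cortex surface.
    """
    check_same_grid(dist_vent, dist_cortex, domain)
    dom = domain.as_bool()
    dv = dist_vent.data
    dc = dist_cortex.data
    total = dv + dc
    bad = dom & (total <= 0)
    if bad.any():
        raise ValueError(
            f"normalized_distance: {int(bad.sum())} domain voxel(s) have zero "
            "distance to both ventricles and cortex (inconsistent masks)"
        )
    out = np.full(dv.shape, np.nan)
    out[dom] = dv[dom] / total[dom]
    return ScalarVolume(out, domain.spacing, affine=domain.affine)


def assign_layers(norm: ScalarVolume) -> LabelVolume:
    """Cut the normalized distance into 4 equidistant layers.

    Layer 1 ↔ [0, 0.25), 2 ↔ [0.25, 0.5), 3 ↔ [0.5, 0.75), 4 ↔ [0.75, 1]
    (upper bound closed).  Voxels outside the domain (NaN) get 0.
    """
    values = norm.data
    dom = ~np.isnan(values)
    v = values[dom]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError(
            f"assign_layers: values outside [0, 1] (min={v.min()}, max={v.max()})"
        )
    layers = np.zeros(values.shape, dtype=np.int32)
    # floor(v * 4) + 1, with v == 1 folded into layer 4
    layers[dom] = np.minimum((v * N_LAYERS).astype(np.int32) + 1, N_LAYERS)
    return LabelVolume(layers, norm.spacing, affine=norm.affine)


def _fill_lobar_gaps(lobar: LabelVolume, domain_mask: np.ndarray) -> np.ndarray:
    """Assign unlabeled domain voxels to the nearest labeled region (mm).

    Ties are broken deterministically toward the lowest region code by taking
    the argmin over per-region distance maps in code order.
    """
    labels = lobar.data.copy()
    missing = domain_mask & (labels == 0)
    if not missing.any():
        return labels
    dists = np.empty((len(REGION_NAMES),) + labels.shape)
    for i, region in enumerate(sorted(REGION_NAMES)):
        region_mask = labels == region
        if region_mask.any():
            dists[i] = ndimage.distance_transform_edt(~region_mask, sampling=lobar.spacing)
        else:
            dists[i] = np.inf
    nearest = np.argmin(dists[:, missing], axis=0)  # argmin → first (lowest) code on ties
    labels[missing] = np.asarray(sorted(REGION_NAMES))[nearest]
    return labels


def build_bullseye(
    layers: LabelVolume, lobar: LabelVolume, domain: LabelVolume
) -> BullseyeMap:
    """Intersect the concentric layer map with the lobar map on the domain.

    Every domain voxel gets ``code = lobar * 10 + layer``; conservation of the
    domain voxel count is enforced.
    """
    check_same_grid(layers, lobar, domain)
    dom = domain.as_bool()
    lobar_filled = _fill_lobar_gaps(lobar, dom)
    lay = layers.data
    missing_layer = dom & (lay == 0)
    missing_lobar = dom & (lobar_filled == 0)
    n_bad = int((missing_layer | missing_lobar).sum())
    if n_bad:
        raise ValueError(
            f"build_bullseye: {n_bad} domain voxel(s) lack a layer or lobar label"
        )
    codes = np.zeros(lay.shape, dtype=np.int32)
    codes[dom] = lobar_filled[dom] * 10 + lay[dom]
    out = LabelVolume(codes, domain.spacing, affine=domain.affine)
    assert out.count() == int(dom.sum()), "voxel conservation violated"
    return BullseyeMap(out)


def parcellate(
    ventricle_mask: LabelVolume,
    cortex_mask: LabelVolume,
    wm_mask: LabelVolume,
    lobar_labels: LabelVolume,
    *,
    max_overlap_fraction: float = 0.001,
) -> BullseyeMap:
    """End-to-end bullseye parcellation from the four input volumes.

    The parcellation domain is every voxel carrying a lobar label (white
    matter and basal ganglia), minus any voxels inside the ventricle or
    cortex masks.  If such overlap removes more than ``max_overlap_fraction``
    of the domain the inputs are considered inconsistent and an error is
    raised.
    """
    check_same_grid(ventricle_mask, cortex_mask, wm_mask, lobar_labels)
    dom = (wm_mask.as_bool()) | (lobar_labels.data > 0)
    overlap = dom & (ventricle_mask.as_bool() | cortex_mask.as_bool())
    if dom.sum() and overlap.sum() / dom.sum() > max_overlap_fraction:
        raise ValueError(
            f"parcellate: {int(overlap.sum())} domain voxels overlap the "
            f"ventricle/cortex masks (> {max_overlap_fraction:.2%} of domain)"
        )
    dom &= ~overlap
    domain = LabelVolume(dom.astype(np.int32), wm_mask.spacing, affine=wm_mask.affine)
    dv = distance_map(ventricle_mask)
    dc = distance_map(cortex_mask)
    norm = normalized_distance(dv, dc, domain)
    layers = assign_layers(norm)
    return build_bullseye(layers, lobar_labels, domain)
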