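"""Per-parcel WMH volumetry, head-size adjustment, BPF, and summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import PARCEL_CODES, REGION_NAMES, BullseyeMap, parcel_decode
from .volumes import LabelVolume, check_same_grid

__all__ = [
    "ParcelVolumeTable",
    "parcel_volumes",
    "adjust_etiv",
    "compute_bpf",
    "log_transform",
    "summarize_distribution",
    "table_from_cohort",
]

PARCEL_COLUMNS = [f"p{code}" for code in PARCEL_CODES]


@dataclass
class ParcelVolumeTable:
    """Subjects x 36 parcel WMH volumes (mm^3) with eTIV bookkeeping.

    ``data`` holds one row per subject with columns ``subject_id``, ``etiv``,
    ``p11`` .. ``p94`` and optionally ``unassigned_mm3``.  The ``adjusted``
    and ``logged`` flags record which transforms have been applied, with the
    eTIV sample mean and the log offset retained so both are recheckable and
    invertible.
    """

    data: pd.DataFrame
    adjusted: bool = False
    logged: bool = False
    log_offset: float | None = None
    etiv_mean: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ["subject_id", "etiv", *PARCEL_COLUMNS] if c not in self.data.columns]
        if missing:
            raise ValueError(f"parcel table missing columns: {missing}")
        if (self.data["etiv"] <= 0).any():
            raise ValueError("eTIV must be positive for every subject")
        if not self.logged and (self.data[PARCEL_COLUMNS] < 0).to_numpy().any():
            raise ValueError("parcel volumes must be non-negative")

    @property
    def volumes(self) -> pd.DataFrame:
        return self.data[PARCEL_COLUMNS]

    def copy(self) -> "ParcelVolumeTable":
        return ParcelVolumeTable(
            self.data.copy(), self.adjusted, self.logged, self.log_offset,
            self.etiv_mean, dict(self.meta),
        )


def parcel_volumes(
    parcels: BullseyeMap, wmh: LabelVolume, spacing=None
) -> tuple[dict[int, float], float]:
    """WMH volume (mm^3) per bullseye parcel.

    Returns ``(volumes, unassigned)`` where ``unassigned`` is the volume of
    lesion voxels outside the parcellated domain — reported, never dropped.
    """
    check_same_grid(parcels.values, wmh)
    spacing = spacing or parcels.spacing
    vox = float(np.prod(spacing))
    lesion = wmh.as_bool()
    codes = parcels.values.data[lesion]
    counts = {code: 0 for code in PARCEL_CODES}
    uniq, cnt = np.unique(codes, return_counts=True)
    unassigned = 0.0
    for code, c in zip(uniq.tolist(), cnt.tolist()):
        if code == 0:
            unassigned = c * vox
        elif code in counts:
            counts[code] = c
        else:
            raise ValueError(f"unexpected parcel code {code} in bullseye map")
    return {code: c * vox for code, c in counts.items()}, unassigned


def adjust_etiv(table: ParcelVolumeTable) -> ParcelVolumeTable:
    """Head-size adjustment: value_ij <- value_ij * eTIV_mean / eTIV_i.

    The eTIV mean is the arithmetic mean over the full loaded sample and is
    stored on the returned table so the adjustment can be verified.
    """
    if table.adjusted:
        raise ValueError("table is already eTIV-adjusted")
    if table.logged:
        raise ValueError("adjust before log-transforming, not after")
    out = table.copy()
    etiv = out.data["etiv"].to_numpy(float)
    etiv_mean = float(etiv.mean())
    out.data[PARCEL_COLUMNS] = out.data[PARCEL_COLUMNS].to_numpy(float) * (
        etiv_mean / etiv
    )[:, None]
    out.adjusted = True
    out.etiv_mean = etiv_mean
    return out


def compute_bpf(supratentorial_mm3: float, etiv_mm3: float) -> float:
    """Brain parenchymal fraction: supratentorial volume / eTIV x 100 (%)."""
    if etiv_mm3 <= 0:
        raise ValueError(f"eTIV must be positive, got {etiv_mm3}")
    if supratentorial_mm3 < 0:
        raise ValueError(f"supratentorial volume must be >= 0, got {supratentorial_mm3}")
    return supratentorial_mm3 / etiv_mm3 * 100.0


def log_transform(table: ParcelVolumeTable, offset: float = 1.0) -> ParcelVolumeTable:
    """Natural-log transform ln(volume + offset); offset recorded for inversion."""
    if table.logged:
        raise ValueError("table is already log-transformed")
    vols = table.data[PARCEL_COLUMNS].to_numpy(float)
    if (vols < 0).any():
        raise ValueError("negative volumes cannot be log-transformed")
    out = table.copy()
    out.data[PARCEL_COLUMNS] = np.log(vols + offset)
    out.logged = True
    out.log_offset = float(offset)
    return out


def summarize_distribution(table: ParcelVolumeTable) -> dict[str, pd.DataFrame]:
    """Descriptive summaries: per-lobe layer proportions, per-parcel medians
    and skewness (on raw, non-log volumes)."""
    if table.logged:
        raise ValueError("summaries require raw (non-log) volumes")
    vols = table.data[PARCEL_COLUMNS].to_numpy(float)
    totals = vols.sum(axis=0)  # per parcel, over subjects

    rows = []
    for region, name in REGION_NAMES.items():
        layer_tot = np.array([
            totals[PARCEL_CODES.index(region * 10 + layer)] for layer in range(1, 5)
        ])
        s = layer_tot.sum()
        props = layer_tot / s if s > 0 else np.zeros(4)
        rows.append({"region": name, **{f"layer{l}": props[l - 1] for l in range(1, 5)}})
    proportions = pd.DataFrame(rows)

    med = np.median(vols, axis=0)
    n = vols.shape[0]
    centered = vols - vols.mean(axis=0)
    sd = vols.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(sd > 0, (centered**3).mean(axis=0) / sd**3, 0.0)
    per_parcel = pd.DataFrame({
        "parcel": PARCEL_COLUMNS,
        "code": list(PARCEL_CODES),
        "region": [REGION_NAMES[parcel_decode(c)[0]] for c in PARCEL_CODES],
        "layer": [parcel_decode(c)[1] for c in PARCEL_CODES],
        "median_mm3": med,
        "skewness": skew,
    })
    return {"layer_proportions": proportions, "per_parcel": per_parcel}


def table_from_cohort(cohort_table: pd.DataFrame) -> ParcelVolumeTable:
    """Build a ParcelVolumeTable from a simulated cohort data frame."""
    cols = ["subject_id", "etiv", *PARCEL_COLUMNS]
    return ParcelVolumeTable(cohort_table[cols].copy())


def warn_if_unassigned(unassigned_mm3: float, total_mm3: float, threshold: float = 0.05) -> None:
    if total_mm3 > 0 and unassigned_mm3 / total_mm3 > threshold:
        warnings.warn(
            f"{unassigned_mm3:.0f} mm^3 of WMH ({unassigned_mm3 / total_mm3:.1%}) "
            "falls outside the parcellated domain",
            stacklevel=2,
        )
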