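"""Spine and dendrite morphometry from serial-section reconstructions.

All quantities follow the standard volume-EM bookkeeping: a structure is
reconstructed as a stack of planar contours at a fixed section thickness
(40 nm in the FIB/SEM datasets this package emulates), so volumes are
summed contour areas times thickness and PSD areas are summed PSD trace
lengths times thickness (or a single en-face area).  Dendrite-level
summaries (spine density, PSD-area density, neck-length density, total
PSD-to-neck ratio) are per-micrometre aggregates over the spines of a
reconstructed segment.

Units: lengths in micrometres (um), areas in um^2, volumes in um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContourStack",
    "SpineRecord",
    "DendriteRecord",
    "AmbiguousStackError",
    "head_volume",
    "psd_area",
    "dendrite_diameter",
    "spine_density",
    "psd_area_density",
    "neck_length_density",
    "psd_neck_ratio",
    "dendrite_psd_neck_ratio",
    "fold_range",
    "cv",
    "axon_coupled_fraction",
    "er_hotspot_fraction",
    "surface_area_fractions",
    "dendrites_from_tables",
    "summarize_dendrites",
    "summarize_region",
]


class AmbiguousStackError(ValueError):
    """Raised when a contour stack carries both PSD representations."""


@dataclass(frozen=True)
class ContourStack:
    """Per-section reconstruction of one spine head and its PSD.

    ``areas`` are plasma-membrane contour areas (um^2) per section;
    ``psd_trace_lengths`` are PSD trace lengths (um) per section for a
    cross-sectioned synapse; ``en_face_area`` (um^2) replaces them when
    the synapse was cut en face and the PSD is measured in one section.
    """

    areas: np.ndarray
    thickness: float
    psd_trace_lengths: np.ndarray | None = None
    en_face_area: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        if self.psd_trace_lengths is not None:
            object.__setattr__(
                self,
                "psd_trace_lengths",
                np.asarray(self.psd_trace_lengths, dtype=float),
            )
        if self.thickness <= 0:
            raise ValueError(f"section thickness must be > 0, got {self.thickness}")
        if np.any(self.areas < 0):
            raise ValueError("contour areas must be non-negative")


@dataclass(frozen=True)
class SpineRecord:
    """One reconstructed spine. ``psd_area`` is NaN when the neck left the
    imaged volume and the PSD could not be measured (tracked for QC)."""

    head_volume: float
    neck_length: float
    neck_diameter: float
    psd_area: float
    position: float = 0.0
    perforated: bool = False
    branched: bool = False
    er: bool = False
    filopodium: bool = False
    stubby: bool = False
    axon_id: str | int | None = None
    dendrite_id: str | int | None = None

    def __post_init__(self) -> None:
        for name in ("head_volume", "neck_length", "neck_diameter", "position"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.filopodium and not (np.isnan(self.psd_area) or self.psd_area == 0):
            raise ValueError("filopodia lack synaptic contacts: psd_area must be 0")


@dataclass
class DendriteRecord:
    """A reconstructed dendritic segment with its spines ordered by position."""

    dendrite_id: str | int
    length: float
    diameter: float
    region: str = ""
    section_widths: Sequence[float] | None = None
    spines: list[SpineRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"dendrite length must be > 0, got {self.length}")
        if self.diameter <= 0:
            raise ValueError(f"dendrite diameter must be > 0, got {self.diameter}")
        self.spines = sorted(self.spines, key=lambda s: s.position)

    @property
    def synaptic_spines(self) -> list[SpineRecord]:
        """Spines that bear synapses (filopodia excluded)."""
        return [s for s in self.spines if not s.filopodium]


# ---------------------------------------------------------------------------
# contour-stack measurements


def head_volume(stack: ContourStack) -> float:
    """Spine head volume: total cross-sectional contour area x thickness."""
    if stack.areas.size == 0:
        raise ValueError("cannot compute head volume of an empty contour stack")
    return float(np.sum(stack.areas) * stack.thickness)


def psd_area(stack: ContourStack) -> float:
    """PSD area from a contour stack.

    Cross-sectioned synapse: summed PSD trace length x thickness.
    En-face synapse: the area measured in the single section, verbatim.
    """
    has_traces = stack.psd_trace_lengths is not None and stack.psd_trace_lengths.size > 0
    has_en_face = stack.en_face_area is not None
    if has_traces and has_en_face:
        raise AmbiguousStackError(
            "stack has both PSD trace lengths and an en-face area; provide one"
        )
    if has_en_face:
        return float(stack.en_face_area)
    if has_traces:
        return float(np.sum(stack.psd_trace_lengths) * stack.thickness)
    raise ValueError("stack has neither PSD trace lengths nor an en-face area")


def dendrite_diameter(section_widths: Sequence[float]) -> float:
    """Mean of the per-section widest-transect widths (um)."""
    widths = np.asarray(section_widths, dtype=float)
    if widths.size == 0:
        raise ValueError("need at least one section width")
    return float(widths.mean())


# ---------------------------------------------------------------------------
# dendrite-level aggregates


def spine_density(dendrite: DendriteRecord) -> float:
    """Spines per um of dendrite; filopodia are not counted as spines."""
    if dendrite.length <= 0:
        raise ValueError("dendrite length must be > 0")
    return len(dendrite.synaptic_spines) / dendrite.length


def _psd_values(dendrite: DendriteRecord) -> tuple[np.ndarray, int]:
    """Measured PSD areas and the QC count of spines with missing PSD."""
    vals = np.array([s.psd_area for s in dendrite.synaptic_spines], dtype=float)
    missing = int(np.isnan(vals).sum())
    return vals[~np.isnan(vals)], missing


def qc_missing_psd(dendrite: DendriteRecord) -> int:
    """Number of synaptic spines whose PSD left the field of view."""
    return _psd_values(dendrite)[1]


def psd_area_density(dendrite: DendriteRecord) -> float:
    """Summed PSD area of the dendrite's spines per um of dendrite.

    Spines with unmeasurable PSD (neck left the field of view) are
    excluded here; their count is available via :func:`qc_missing_psd`.
    """
    if dendrite.length <= 0:
        raise ValueError("dendrite length must be > 0")
    vals, _ = _psd_values(dendrite)
    return float(vals.sum()) / dendrite.length


def neck_length_density(dendrite: DendriteRecord) -> float:
    """Summed spine neck length per um of dendrite (um/um)."""
    if dendrite.length <= 0:
        raise ValueError("dendrite length must be > 0")
    total = sum(s.neck_length for s in dendrite.synaptic_spines)
    return total / dendrite.length


def psd_neck_ratio(spine: SpineRecord) -> float:
    """Per-spine PSD area / neck length (um). Undefined for zero necks."""
    if spine.neck_length <= 0:
        raise ValueError(
            "psd_neck_ratio undefined for zero neck length (stubby spine); "
            "exclude stubby spines from ratio statistics"
        )
    return spine.psd_area / spine.neck_length


def dendrite_psd_neck_ratio(dendrite: DendriteRecord) -> float:
    """Dendrite-level ratio of total PSD area to total neck length.

    This is sum(PSD)/sum(neck), not the mean of per-spine ratios. Stubby
    spines (no measurable neck) and spines with missing PSD are excluded.
    """
    psd_sum = 0.0
    neck_sum = 0.0
    for s in dendrite.synaptic_spines:
        if s.stubby or s.neck_length <= 0 or np.isnan(s.psd_area):
            continue
        psd_sum += s.psd_area
        neck_sum += s.neck_length
    if neck_sum <= 0:
        raise ValueError("total neck length must be > 0 for the dendrite ratio")
    return psd_sum / neck_sum


# ---------------------------------------------------------------------------
# distribution descriptors


def fold_range(values: Iterable[float]) -> float:
    """max/min fold difference between the largest and smallest value."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("fold_range needs at least two values")
    if np.any(arr <= 0):
        raise ValueError("fold_range requires strictly positive values")
    return float(arr.max() / arr.min())


def cv(values: Iterable[float]) -> float:
    """Coefficient of variation, SD/mean (population SD, ddof=0)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("cv needs at least two values")
    if np.any(arr <= 0):
        raise ValueError("cv requires strictly positive values")
    return float(arr.std(ddof=0) / arr.mean())


# ---------------------------------------------------------------------------
# spatial organisation


def axon_coupled_fraction(
    spines: pd.DataFrame,
) -> tuple[float, tuple[int, int] | None]:
    """Fraction of spines sharing a (dendrite, axon) pair with another spine.

    Axon-coupled spines reside on the same dendritic segment and receive
    input from the same axon.  Returns ``(fraction, (min, max))`` where the
    range is the multiplicity of spines per coupled axon (None when no
    coupling exists).  An empty table yields ``(0.0, None)``.
    """
    if len(spines) == 0:
        return 0.0, None
    counts = spines.groupby(["dendrite_id", "axon_id"], sort=False).size()
    coupled = counts[counts >= 2]
    if coupled.empty:
        return 0.0, None
    frac = float(coupled.sum()) / float(len(spines))
    return frac, (int(coupled.min()), int(coupled.max()))


def er_hotspot_fraction(dendrite: DendriteRecord) -> float:
    """Among ER-containing spines, the fraction whose immediate positional
    neighbour (previous or next spine along the dendrite) also contains ER.

    Adjacency is ordinal over all spines in positional order. Returns NaN
    for dendrites with fewer than two spines (undefined), and NaN when the
    dendrite has no ER-positive spines.
    """
    flags = [bool(s.er) for s in dendrite.spines]
    if len(flags) < 2:
        return math.nan
    n_er = sum(flags)
    if n_er == 0:
        return math.nan
    hits = 0
    for i, f in enumerate(flags):
        if not f:
            continue
        prev_er = i > 0 and flags[i - 1]
        next_er = i + 1 < len(flags) and flags[i + 1]
        if prev_er or next_er:
            hits += 1
    return hits / n_er


def surface_area_fractions(
    head_sa: float, psd_sa: float, neck_sa: float, shaft_sa: float
) -> tuple[float, float, float, float]:
    """Fractions of total surface area in head, PSD, neck, and shaft."""
    parts = np.array([head_sa, psd_sa, neck_sa, shaft_sa], dtype=float)
    if np.any(parts < 0):
        raise ValueError("surface areas must be non-negative")
    total = parts.sum()
    if total <= 0:
        raise ValueError("total surface area must be > 0")
    out = parts / total
    return float(out[0]), float(out[1]), float(out[2]), float(out[3])


# ---------------------------------------------------------------------------
# table interface (CSV schemas shared with spinelab.synthetic)

_SPINE_BOOL_COLS = ("perforated", "branched", "er")


def dendrites_from_tables(
    spines: pd.DataFrame, dendrites: pd.DataFrame
) -> list[DendriteRecord]:
    """Build DendriteRecord objects from the spine/dendrite CSV tables."""
    records: list[DendriteRecord] = []
    grouped = spines.groupby("dendrite_id", sort=False)
    for _, drow in dendrites.iterrows():
        did = drow["dendrite_id"]
        try:
            grp = grouped.get_group(did)
        except KeyError:
            grp = spines.iloc[0:0]
        spine_list = [
            SpineRecord(
                head_volume=row["head_volume_um3"],
                neck_length=row["neck_length_um"],
                neck_diameter=row["neck_diameter_um"],
                psd_area=row["psd_area_um2"],
                position=row["position_um"],
                perforated=bool(row.get("perforated", False)),
                branched=bool(row.get("branched", False)),
                er=bool(row.get("er", False)),
                axon_id=row.get("axon_id"),
                dendrite_id=did,
            )
            for _, row in grp.iterrows()
        ]
        records.append(
            DendriteRecord(
                dendrite_id=did,
                length=drow["length_um"],
                diameter=drow["diameter_um"],
                region=str(drow.get("region", "")),
                spines=spine_list,
            )
        )
    return records


def summarize_dendrites(
    spines: pd.DataFrame, dendrites: pd.DataFrame
) -> pd.DataFrame:
    """Per-dendrite summary table: density, PSD-area density, neck-length
    density, total PSD/neck ratio, ER hotspot fraction, and QC counts."""
    rows = []
    for d in dendrites_from_tables(spines, dendrites):
        try:
            ratio = dendrite_psd_neck_ratio(d)
        except ValueError:
            ratio = math.nan
        rows.append(
            {
                "dendrite_id": d.dendrite_id,
                "region": d.region,
                "length_um": d.length,
                "diameter_um": d.diameter,
                "n_spines": len(d.synaptic_spines),
                "spine_density": spine_density(d),
                "psd_area_density": psd_area_density(d),
                "neck_length_density": neck_length_density(d),
                "total_ratio": ratio,
                "er_hotspot_fraction": er_hotspot_fraction(d),
                "qc_missing_psd": qc_missing_psd(d),
            }
        )
    return pd.DataFrame(rows)


def summarize_region(spines: pd.DataFrame, dendrites: pd.DataFrame) -> pd.DataFrame:
    """Region-level summary mirroring the per-region morphometry tables:
    mean +/- SD of spine density and spine dimensions, fold ranges, CVs,
    the PSD/neck ratio, and the axon-coupled spine fraction."""
    per_dend = summarize_dendrites(spines, dendrites)
    rows = []
    for region, dgrp in per_dend.groupby("region", sort=False):
        dend_ids = set(dgrp["dendrite_id"])
        sgrp = spines[spines["dendrite_id"].isin(dend_ids)]
        hv = sgrp["head_volume_um3"].to_numpy(dtype=float)
        nl = sgrp["neck_length_um"].to_numpy(dtype=float)
        coupled_frac, coupled_range = axon_coupled_fraction(sgrp)
        with np.errstate(divide="ignore", invalid="ignore"):
            spine_ratio = sgrp["psd_area_um2"] / sgrp["neck_length_um"]
        rows.append(
            {
                "region": region,
                "n_spines": len(sgrp),
                "n_dendrites": len(dgrp),
                "spine_density_mean": dgrp["spine_density"].mean(),
                "spine_density_sd": dgrp["spine_density"].std(ddof=1),
                "head_volume_mean": hv.mean(),
                "head_volume_sd": hv.std(ddof=1),
                "head_volume_fold": fold_range(hv) if len(hv) >= 2 else math.nan,
                "head_volume_cv": cv(hv) if len(hv) >= 2 else math.nan,
                "neck_length_mean": nl.mean(),
                "neck_length_sd": nl.std(ddof=1),
                "neck_length_fold": fold_range(nl) if len(nl) >= 2 else math.nan,
                "neck_diameter_mean": sgrp["neck_diameter_um"].mean(),
                "neck_diameter_sd": sgrp["neck_diameter_um"].std(ddof=1),
                "psd_neck_ratio_mean": float(np.nanmean(spine_ratio)),
                "psd_neck_ratio_sd": float(np.nanstd(spine_ratio, ddof=1)),
                "dendrite_diameter_mean": dgrp["diameter_um"].mean(),
                "dendrite_diameter_sd": dgrp["diameter_um"].std(ddof=1),
                "psd_area_density_mean": dgrp["psd_area_density"].mean(),
                "psd_area_density_sd": dgrp["psd_area_density"].std(ddof=1),
                "neck_length_density_mean": dgrp["neck_length_density"].mean(),
                "neck_length_density_sd": dgrp["neck_length_density"].std(ddof=1),
                "total_ratio_mean": dgrp["total_ratio"].mean(),
                "total_ratio_sd": dgrp["total_ratio"].std(ddof=1),
                "axon_coupled_fraction": coupled_frac,
                "axon_coupled_min": coupled_range[0] if coupled_range else 0,
                "axon_coupled_max": coupled_range[1] if coupled_range else 0,
                "er_fraction": float(sgrp["er"].mean()) if len(sgrp) else math.nan,
            }
        )
    return pd.DataFrame(rows)
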