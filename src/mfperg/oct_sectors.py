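"""ETDRS-grid and peripapillary sector summarization of OCT thickness data.

Macular layer maps are averaged within the three ETDRS rings (1 mm foveal
disc, 1-3 mm parafoveal and 3-6 mm perifoveal annuli, centered on the
fovea); the ganglion cell + inner plexiform complex (GCIPL) is derived
pointwise as GCL + IPL.  Peripapillary nerve-fiber profiles (768 samples on
the 3.5 mm disc circle) are averaged within Spectralis-style sectors:
temporal (90° about the temporal meridian), superior, nasal, inferior, and
the 30° papillomacular bundle inside the temporal sector; G is the mean of
all samples (uniform angular sampling makes this circumference-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_SECTORS,
    ETDRS_RADII_MM,
    LayerThicknessData,
    _region_masks_macula,
    _sector_mask,
)

MACULAR_REGIONS = ("center", "parafoveal", "perifoveal")


@dataclass
class EtdrsSummary:
    """Mean thickness (µm) per layer and ETDRS region."""

    table: pd.DataFrame   # tidy: layer, region, mean_um

    def value(self, layer: str, region: str) -> float:
        sel = self.table[(self.table.layer == layer) & (self.table.region == region)]
        if len(sel) != 1:
            raise KeyError(f"no summary for {layer}/{region}")
        return float(sel.mean_um.iloc[0])


@dataclass
class SectorSummary:
    """Peripapillary RNFL sector means (µm)."""

    g: float
    t: float
    pmb: float
    s: float
    i: float
    n: float

    @property
    def nt_ratio(self) -> float:
        return self.n / self.t

    def as_dict(self) -> dict[str, float]:
        return {"G": self.g, "T": self.t, "PMB": self.pmb, "S": self.s,
                "I": self.i, "N": self.n, "NT_ratio": self.nt_ratio}


def summarize_etdrs(
    data: LayerThicknessData,
    fovea_center_deg: tuple[float, float] | None = None,
    degrees_per_mm: float | None = None,
) -> EtdrsSummary:
    """Average every layer map (and derived GCIPL) over the ETDRS regions."""
    center = fovea_center_deg if fovea_center_deg is not None else data.fovea_center_deg
    dpm = degrees_per_mm if degrees_per_mm is not None else data.degrees_per_mm
    outer_deg = ETDRS_RADII_MM[-1] * dpm
    if (center[0] - outer_deg < data.x_deg.min() or
            center[0] + outer_deg > data.x_deg.max() or
            center[1] - outer_deg < data.y_deg.min() or
            center[1] + outer_deg > data.y_deg.max()):
        raise ValueError("6 mm ETDRS circle exceeds the map extent")
    masks, _ = _region_masks_macula(data.x_deg, data.y_deg, center, dpm)

    layers = dict(data.maps)
    if "GCL" in layers and "IPL" in layers and "GCIPL" not in layers:
        layers["GCIPL"] = data.gcipl()
    rows = [
        {"layer": layer, "region": region, "mean_um": float(m[mask].mean())}
        for layer, m in layers.items()
        for region, mask in masks.items()
    ]
    return EtdrsSummary(table=pd.DataFrame(rows))


def summarize_prnfl(
    profile: np.ndarray,
    angles_deg: np.ndarray | None = None,
    sectors: Mapping[str, tuple[float, float]] | None = None,
) -> SectorSummary:
    """Sector means of a peripapillary circle profile.

    The T/S/N/I spans must partition the circle (G is the mean over all
    samples either way, but an overlapping or non-covering configuration is
    a configuration error and is rejected).
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if angles_deg is None:
        angles_deg = (np.arange(n) * 360.0 / n + 180.0) % 360.0 - 180.0
    sectors = dict(DEFAULT_SECTORS if sectors is None else sectors)

    main = ("T", "S", "N", "I")
    cover = np.zeros(n, dtype=int)
    masks = {}
    for name in (*main, "PMB"):
        masks[name] = _sector_mask(np.asarray(angles_deg), sectors[name])
        if name in main:
            cover += masks[name]
    if not np.all(cover == 1):
        raise ValueError("T/S/N/I sectors must cover the circle without overlap")
    if not np.all(masks["T"][masks["PMB"]]):
        raise ValueError("PMB span must lie inside the temporal sector")

    return SectorSummary(
        g=float(profile.mean()),
        t=float(profile[masks["T"]].mean()),
        pmb=float(profile[masks["PMB"]].mean()),
        s=float(profile[masks["S"]].mean()),
        i=float(profile[masks["I"]].mean()),
        n=float(profile[masks["N"]].mean()),
    )


def mirror_profile(profile: np.ndarray) -> np.ndarray:
    """Reverse the angular direction of a circle profile (angle -> -angle,
    swapping superior and inferior) for imports stored in screen rather
    than eye-relative coordinates.  An involution."""
    profile = np.asarray(profile)
    return np.concatenate([profile[:1], profile[:0:-1]])
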