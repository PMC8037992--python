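"""Loading and indexing of the group-level calibration tables.

Three CSVs ship with the package: mfPERG amplitude/peak-time summaries per
ring and component, OCT layer-thickness summaries per region, and cohort
demographics.  They parameterize the synthetic generators and feed the
summary-statistics reconstruction of the printed omnibus tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

GROUPS = ("Control", "NON", "HON")
COMPONENTS = ("N1", "P1", "N2")
MACULAR_REGIONS = ("center", "parafoveal", "perifoveal")
DISC_SECTORS = ("G", "PMB", "T")
MACULAR_LAYERS = ("Total", "mRNFL", "GCL", "IPL", "INL", "ONL", "ORL")


def _read(name: str, path: str | Path | None) -> pd.DataFrame:
    if path is not None:
        return pd.read_csv(path, comment="#")
    with resources.as_file(resources.files("mfperg.data").joinpath(name)) as p:
        return pd.read_csv(p, comment="#")


def load_mfperg_calibration(path: str | Path | None = None) -> pd.DataFrame:
    """mfPERG calibration table (group, ring, component, amp/time summaries)."""
    df = _read("mfperg_calibration.csv", path)
    required = {"group", "ring", "component", "amp_mean_uV", "amp_sd_uV",
                "time_median_ms", "time_range_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration file missing columns {sorted(missing)}")
    return df


def load_oct_calibration(path: str | Path | None = None) -> pd.DataFrame:
    """OCT calibration table (group, layer, region, mean/SD in µm)."""
    df = _read("oct_calibration.csv", path)
    required = {"group", "layer", "region", "mean_um", "sd_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration file missing columns {sorted(missing)}")
    return df


def load_cohort_demographics(path: str | Path | None = None) -> pd.DataFrame:
    return _read("cohort_demographics.csv", path)


def mfperg_cell(df: pd.DataFrame, group: str, ring: int, component: str) -> pd.Series:
    """Single calibration cell; raises naming the cell if absent."""
    sel = df[(df.group == group) & (df.ring == ring) & (df.component == component)]
    if len(sel) != 1:
        raise KeyError(
            f"calibration cell (group={group}, ring={ring}, component={component}) "
            f"{'missing' if len(sel) == 0 else 'duplicated'}"
        )
    return sel.iloc[0]


def oct_cell(df: pd.DataFrame, group: str, layer: str, region: str) -> pd.Series:
    sel = df[(df.group == group) & (df.layer == layer) & (df.region == region)]
    if len(sel) != 1:
        raise KeyError(
            f"calibration cell (group={group}, layer={layer}, region={region}) "
            f"{'missing' if len(sel) == 0 else 'duplicated'}"
        )
    return sel.iloc[0]
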