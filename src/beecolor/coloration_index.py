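"""Coloration index: area under the coloration profile.

The index is the trapezoidal area under the curve of gray value (y) against
position along the abdomen (x), with the position axis taken as the vector
index at unit spacing.  For a length-L profile with mean value m the index is
close to m * (L - 1), so at L = 1998 a typical dark cuticle (mean gray around
0.22) scores in the 430-460 range.  Higher index = lighter abdomen.

The index is computed on the length-equalized profile, never on the native
width, so abdomen pixel length does not confound brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_extraction import FixedProfile

__all__ = [
    "IndexValue",
    "coloration_index",
    "index_table",
    "summarize_groups",
    "group_label",
    "validate_metadata",
    "COLONIES",
    "TEMPERATURES",
]

COLONIES = ("gray", "yellow")
TEMPERATURES = (30, 34)


@dataclass(frozen=True)
class IndexValue:
    specimen_id: str
    index: float


def coloration_index(p: FixedProfile | np.ndarray) -> float:
    """Trapezoidal area under the profile with unit spacing on the x-axis."""
    v = p.values if isinstance(p, FixedProfile) else np.asarray(p, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("coloration index requires a 1-D profile of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("profile contains missing values")
    return float(np.trapezoid(v))


def index_table(profiles: list[FixedProfile]) -> pd.DataFrame:
    """Compute indices for many profiles; columns specimen_id, index."""
    return pd.DataFrame(
        {
            "specimen_id": [p.specimen_id for p in profiles],
            "index": [coloration_index(p) for p in profiles],
        }
    )


def group_label(colony: str, temperature: int) -> str:
    return f"{int(temperature)}{colony}"


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the specimen metadata table (specimen_id, colony, temperature)."""
    required = {"specimen_id", "colony", "temperature"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    meta = meta.copy()
    meta["colony"] = meta["colony"].astype(str)
    meta["temperature"] = meta["temperature"].astype(int)
    bad_colony = set(meta["colony"]) - set(COLONIES)
    if bad_colony:
        raise ValueError(f"unknown colony value(s): {sorted(bad_colony)}")
    bad_temp = set(meta["temperature"]) - set(TEMPERATURES)
    if bad_temp:
        raise ValueError(f"unknown temperature value(s): {sorted(bad_temp)}")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValueError(f"duplicate specimen_id in metadata: {dup!r}")
    return meta


def summarize_groups(indices: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary of indices: group, n, mean, sd, min, max, se.

    One row per colony x temperature combination present in the metadata.
    SD uses the n-1 denominator; SE = SD / sqrt(n).
    """
    meta = validate_metadata(meta)
    merged = indices.merge(meta, on="specimen_id", how="left", validate="1:1")
    orphans = merged.loc[merged["colony"].isna(), "specimen_id"].tolist()
    if orphans:
        raise ValueError(f"specimen(s) without metadata: {orphans[:5]}")
    rows = []
    for (temp, colony), sub in merged.groupby(["temperature", "colony"]):
        x = sub["index"].to_numpy(dtype=float)
        n = x.size
        rows.append(
            {
                "group": group_label(colony, temp),
                "n": n,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if n > 1 else 0.0,
                "min": float(x.min()),
                "max": float(x.max()),
                "se": float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values("group", ignore_index=True)
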