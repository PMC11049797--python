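"""CSV schemas for profile and index tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profile_extraction import FixedProfile

__all__ = [
    "write_profiles",
    "read_profiles",
    "profiles_to_matrix",
]


def write_profiles(profiles: list[FixedProfile], path: str | Path) -> Path:
    """Write profiles as one row per specimen: specimen_id, v0001 ... vNNNN."""
    if not profiles:
        raise ValueError("no profiles to write")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mixed lengths: {sorted(lengths)}")
    L = lengths.pop()
    width = max(4, len(str(L)))
    cols = [f"v{i + 1:0{width}d}" for i in range(L)]
    df = pd.DataFrame([p.values for p in profiles], columns=cols)
    df.insert(0, "specimen_id", [p.specimen_id for p in profiles])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> list[FixedProfile]:
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise ValueError(f"profile table {path} lacks a specimen_id column")
    vcols = [c for c in df.columns if c != "specimen_id"]
    if not vcols:
        raise ValueError(f"profile table {path} has no value columns")
    X = df[vcols].to_numpy(dtype=float)
    return [
        FixedProfile(values=row, specimen_id=str(sid))
        for sid, row in zip(df["specimen_id"], X)
    ]


def profiles_to_matrix(profiles: list[FixedProfile]) -> tuple[list[str], np.ndarray]:
    """Stack profiles into (ids, n x L matrix), preserving order."""
    return [p.specimen_id for p in profiles], np.vstack([p.values for p in profiles])
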