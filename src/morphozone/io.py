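"""Readers and writers for landmark files, symmetry schemes and covariates.

Two landmark dialects are supported:

* TPS with ``LM3`` records — one record per configuration::

      LM3=4
      0.1 0.2 0.3
      ...
      ID=spec01_left

  The ID suffixes ``_left`` / ``_right`` mark sides for matching symmetry;
  an unsuffixed ID is a whole (object-symmetric) configuration.

* long-format CSV with columns
  ``specimen_id, side, landmark_index, x, y, z``.

Symmetry schemes are YAML mappings with keys ``mode``, ``paired`` (list of
``[left, right]`` index pairs), ``midline`` (list of indices) and optional
``symmetry_plane_axis``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import LandmarkConfig, SymmetryScheme

__all__ = [
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_scheme_yaml",
    "write_scheme_yaml",
    "read_covariates_csv",
]

_SIDE_SUFFIXES = {"_left": "left", "_right": "right"}


def _split_id(raw_id: str) -> tuple[str, str]:
    for suffix, side in _SIDE_SUFFIXES.items():
        if raw_id.endswith(suffix):
            return raw_id[: -len(suffix)], side
    return raw_id, "whole"


def read_tps(path: str | Path) -> list[LandmarkConfig]:
    """Parse a TPS file of LM3 records into landmark configurations."""
    configs: list[LandmarkConfig] = []
    coords: list[list[float]] = []
    expected = 0
    raw_id: str | None = None
    record_open = False

    def flush(line_no: int) -> None:
        nonlocal coords, expected, raw_id, record_open
        if not record_open:
            return
        if len(coords) != expected:
            raise ValueError(
                f"{path}: record ending near line {line_no} has {len(coords)} "
                f"landmarks, expected {expected}"
            )
        sid, side = _split_id(raw_id if raw_id is not None else f"spec{len(configs)}")
        configs.append(LandmarkConfig(sid, np.array(coords), side))
        coords, expected, raw_id, record_open = [], 0, None, False

    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush(line_no)
                expected = int(line.split("=", 1)[1])
                record_open = True
            elif upper.startswith("ID="):
                raw_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=", "LM=")):
                continue  # tolerated but unused metadata
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{line_no}: expected 3 coordinates")
                coords.append([float(p) for p in parts])
    flush(-1)
    if not configs:
        raise ValueError(f"{path}: no LM3 records found")
    return configs


def write_tps(configs: Iterable[LandmarkConfig], path: str | Path) -> None:
    """Write configurations as LM3 TPS records (side encoded in the ID)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM3={cfg.n_landmarks}\n")
            for row in cfg.coords:
                fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
            suffix = "" if cfg.side == "whole" else f"_{cfg.side}"
            fh.write(f"ID={cfg.specimen_id}{suffix}\n")


def read_landmarks_csv(path: str | Path) -> list[LandmarkConfig]:
    """Read the long-format landmark CSV dialect."""
    df = pd.read_csv(path)
    required = {"specimen_id", "side", "landmark_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    configs = []
    for (sid, side), sub in df.groupby(["specimen_id", "side"], sort=False):
        sub = sub.sort_values("landmark_index")
        idx = sub["landmark_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"{path}: specimen {sid!r} side {side!r} has non-contiguous "
                "landmark indices"
            )
        configs.append(
            LandmarkConfig(str(sid), sub[["x", "y", "z"]].to_numpy(float), str(side))
        )
    return configs


def write_landmarks_csv(configs: Iterable[LandmarkConfig], path: str | Path) -> None:
    """Write configurations in the long-format landmark CSV dialect."""
    rows = []
    for cfg in configs:
        for i, (x, y, z) in enumerate(cfg.coords):
            rows.append(
                {
                    "specimen_id": cfg.specimen_id,
                    "side": cfg.side,
                    "landmark_index": i,
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scheme_yaml(path: str | Path) -> SymmetryScheme:
    """Load a symmetry scheme from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SymmetryScheme(
        mode=data["mode"],
        paired=tuple(tuple(p) for p in data["paired"]),
        midline=tuple(data.get("midline", ())),
        symmetry_plane_axis=int(data.get("symmetry_plane_axis", 0)),
    )


def write_scheme_yaml(scheme: SymmetryScheme, path: str | Path) -> None:
    """Save a symmetry scheme to YAML."""
    data = {
        "mode": scheme.mode,
        "paired": [list(p) for p in scheme.paired],
        "midline": list(scheme.midline),
        "symmetry_plane_axis": scheme.symmetry_plane_axis,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    """Read the specimen covariate table (id, admixture %, family, sex, age)."""
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns or "pct_dom" not in df.columns:
        raise ValueError(f"{path}: covariates need specimen_id and pct_dom columns")
    df["specimen_id"] = df["specimen_id"].astype(str)
    return df
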