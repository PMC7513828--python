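"""Table and config I/O, run manifests, logging setup.

All interchange is tidy UTF-8 CSV with a header row.  Cell tables follow
the segmented-fluorescence schema (``cell_id, embryo_id, litter_id, z,
nanog_raw, gata6_raw, gfp_raw, ti_flag`` plus optional ``identity``); track
tables follow ``cell_id, frame, gfp`` plus optional ``smoothed_gfp, event,
identity_at_frame``.  Unknown columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .circuit import CircuitParams
from .mechanics import EmbryoState, GrowthConfig, MechanicsParams

__all__ = [
    "CELL_COLUMNS",
    "TRACK_COLUMNS",
    "SchemaError",
    "read_cell_table",
    "read_track_table",
    "write_table",
    "embryo_to_frame",
    "load_growth_config",
    "dump_growth_config",
    "RunManifest",
    "write_manifest",
    "setup_logging",
]

log = logging.getLogger("icmfate")

CELL_COLUMNS = ("cell_id", "embryo_id", "litter_id", "z",
                "nanog_raw", "gata6_raw", "gfp_raw", "ti_flag")
TRACK_COLUMNS = ("cell_id", "frame", "gfp")

_INTENSITY_COLUMNS = ("nanog_raw", "gata6_raw", "gfp_raw", "gfp")


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


def _validate(df: pd.DataFrame, required: tuple[str, ...], what: str) -> pd.DataFrame:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")
    for col in _INTENSITY_COLUMNS:
        if col in df.columns and (df[col].astype(float) < 0).any():
            raise SchemaError(f"negative intensities in column {col!r}")
    return df


def read_cell_table(path) -> pd.DataFrame:
    """Load and schema-validate a segmented-fluorescence cell table."""
    return _validate(pd.read_csv(path), CELL_COLUMNS, f"cell table {path}")


def read_track_table(path) -> pd.DataFrame:
    """Load and schema-validate a time-lapse GFP track table."""
    return _validate(pd.read_csv(path), TRACK_COLUMNS, f"track table {path}")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def embryo_to_frame(e: EmbryoState) -> pd.DataFrame:
    """Snapshot of an embryo state as a tidy table (one row per cell)."""
    return pd.DataFrame({
        "cell_id": e.ids, "t": e.t,
        "x": e.positions[:, 0], "y": e.positions[:, 1], "z": e.positions[:, 2],
        "x_level": e.x, "status": e.status.astype(str), "alive": e.alive,
    })


# ---------------------------------------------------------------------------
# Config files (flat YAML key: value with dotted nesting)

def load_growth_config(path) -> GrowthConfig:
    """Build a :class:`GrowthConfig` from a YAML mapping.

    Top-level keys set GrowthConfig fields; ``circuit:`` and ``mechanics:``
    sub-mappings set the nested parameter sets.  Missing keys keep defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return growth_config_from_dict(raw)


def growth_config_from_dict(raw: dict) -> GrowthConfig:
    raw = dict(raw)
    circuit = CircuitParams(**raw.pop("circuit", {}))
    mechanics = MechanicsParams(**raw.pop("mechanics", {}))
    known = {f.name for f in fields(GrowthConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return GrowthConfig(circuit=circuit, mechanics=mechanics, **raw)


def dump_growth_config(cfg: GrowthConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# Run manifests

@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    command: str
    seed: Optional[int]
    config_hash: str
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    outputs: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


def _config_hash(obj: Any) -> str:
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, command: str, seed: Optional[int], config: Any,
                   outputs: list, parameters: Optional[dict] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = RunManifest(command=command, seed=seed, config_hash=_config_hash(config),
                      outputs=[str(o) for o in outputs],
                      parameters=parameters or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(man), indent=2))
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
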