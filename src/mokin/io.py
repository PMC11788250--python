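"""File formats and study configuration.

TAC files are plain CSV with header ``frame_start_s,frame_duration_s``
followed by one column per organ plus ``idif``, activities in kBq/mL
decay-corrected to injection time, one file per subject.  A reader for
PMOD-style ``.tac`` exports (tab-separated, two header lines) is also
provided.  Study configuration lives in a small versioned YAML schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .organs import ORGAN_IDS
from .schedule import FrameSchedule
from .synthetic import DEFAULT_NOISE_SC

__all__ = [
    "read_tacs",
    "write_tacs",
    "read_pmod_tac",
    "StudyConfig",
    "load_config",
    "save_config",
    "config_hash",
]

REQUIRED_COLUMNS = ("frame_start_s", "frame_duration_s", *ORGAN_IDS, "idif")


def read_tacs(path: str | Path) -> pd.DataFrame:
    """Read one subject's framed TACs; validates columns and frame layout."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough with context
        raise ValueError(f"{path}: cannot parse TAC file: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[list(REQUIRED_COLUMNS)].isna()
    if bad.to_numpy().any():
        line = int(bad.any(axis=1).idxmax()) + 2  # 1-based + header line
        raise ValueError(f"{path}: malformed value at line {line}")
    FrameSchedule(
        df["frame_start_s"].to_numpy(dtype=float),
        df["frame_duration_s"].to_numpy(dtype=float),
    )
    return df


def write_tacs(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


def read_pmod_tac(path: str | Path, time_unit: str = "seconds") -> pd.DataFrame:
    """Read a PMOD-style ``.tac`` export (tab-separated, two header lines).

    Line 1 names the columns (``start end region1 region2 ...``), line 2
    carries units; frame times are converted to the package's
    ``frame_start_s/frame_duration_s`` convention.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split("\t")
        fh.readline()  # units line
        body = pd.read_csv(fh, sep="\t", names=header, comment="#")
    factor = {"seconds": 1.0, "minutes": 60.0}[time_unit]
    start = body[header[0]].to_numpy(dtype=float) * factor
    end = body[header[1]].to_numpy(dtype=float) * factor
    out = pd.DataFrame(
        {"frame_start_s": start, "frame_duration_s": end - start}
    )
    for col in header[2:]:
        out[col] = body[col].to_numpy(dtype=float)
    return out


# ----------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Validated knobs for an end-to-end study run."""

    schema_version: int = 1
    seed: int = 0
    n_subjects: int = 6
    n_starts: int = 200
    scales: tuple[str, ...] = ("short", "long")
    noise_sc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SC)
    )
    gamma_mode: str = "divide"
    idif_n_terms: int = 3
    free_heart_k2: bool = False
    bounds: dict[str, tuple[float, float]] | None = None
    max_nfev: int = 150

    def __post_init__(self) -> None:
        if self.schema_version != 1:
            raise ValueError(f"unknown config schema {self.schema_version}")
        if self.n_subjects < 1 or self.n_starts < 1:
            raise ValueError("n_subjects and n_starts must be >= 1")
        for s in self.scales:
            if s not in ("short", "long"):
                raise ValueError(f"unknown scale {s!r}")
        if self.gamma_mode not in ("divide", "multiply"):
            raise ValueError("gamma_mode must be 'divide' or 'multiply'")
        if not 2 <= self.idif_n_terms <= 4:
            raise ValueError("idif_n_terms must be 2-4")
        missing = [k for k in (*ORGAN_IDS, "idif") if k not in self.noise_sc]
        if missing:
            raise ValueError(f"noise_sc missing entries for {missing}")


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scales" in raw:
        raw["scales"] = tuple(raw["scales"])
    if "bounds" in raw and raw["bounds"] is not None:
        raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
    return StudyConfig(**raw)


def save_config(config: StudyConfig, path: str | Path) -> None:
    data = asdict(config)
    data["scales"] = list(config.scales)
    if data["bounds"]:
        data["bounds"] = {k: list(v) for k, v in data["bounds"].items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: StudyConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
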