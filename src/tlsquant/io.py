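"""CSV schemas and config loading.

All tabular inputs are plain UTF-8 CSV with a mandatory header row and
decimal points; concentrations are in nM and times in s (no unit
inference anywhere).

Schemas
-------
titration:    ``ligand_total_nM, signal[, replicate]`` (long form) or
              ``ligand_total_nM, signal_mean[, signal_sd]``
competition:  ``competitor_total_nM, signal[, replicate]``
ladder:       ``time_s, position, concentration_nM`` with an optional
              companion background file of identical schema
config:       YAML or JSON, keyed per analysis (e.g. ``lt_nM,
              partner_nM, kd_nM`` for the Ki context).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .binding import TitrationCurve
from .competition import CompetitionCurve
from .processivity import BandLadder

__all__ = [
    "SchemaError",
    "read_titration_csv",
    "read_competition_csv",
    "read_ladder_csv",
    "write_titration_csv",
    "write_competition_csv",
    "write_ladder_csv",
    "load_config",
    "file_digest",
]


class SchemaError(ValueError):
    """An input file violates its documented schema."""


def _read_table(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    if path.stat().st_size == 0:
        raise SchemaError(f"{what} file is empty: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"could not parse {what} file {path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"{what} file {path} contains a header but no rows")
    return df


def read_titration_csv(path, substrate_total: float) -> TitrationCurve:
    """Read a titration table (long or averaged form)."""
    df = _read_table(path, "titration")
    try:
        return TitrationCurve.from_dataframe(df, substrate_total)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def read_competition_csv(path) -> CompetitionCurve:
    df = _read_table(path, "competition")
    try:
        return CompetitionCurve.from_dataframe(df)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def read_ladder_csv(path, background_path=None,
                    full_length_position: int | None = None) -> BandLadder:
    df = _read_table(path, "ladder")
    bg = _read_table(background_path, "background") if background_path else None
    try:
        return BandLadder(df, full_length_position=full_length_position,
                          background=bg)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def write_titration_csv(curve: TitrationCurve, path) -> None:
    df = pd.DataFrame({
        "ligand_total_nM": curve.ligand_total,
        "signal_mean": curve.signal,
    })
    if curve.replicate_sd is not None:
        df["signal_sd"] = curve.replicate_sd
    df.to_csv(path, index=False)


def write_competition_csv(curve: CompetitionCurve, path) -> None:
    df = pd.DataFrame({
        "competitor_total_nM": curve.competitor_total,
        "signal": curve.signal,
    })
    df.to_csv(path, index=False)


def write_ladder_csv(ladder: BandLadder, path, background_path=None) -> None:
    ladder.data.to_csv(path, index=False)
    if background_path is not None and ladder.background is not None:
        ladder.background.to_csv(background_path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def file_digest(path) -> str:
    """sha256 hex digest of a file, for report provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
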