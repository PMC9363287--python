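"""Cohort CSV readers/writers, configuration loading and run manifests.

Cohort files are RFC-4180 CSV with the canonical header, decimal points,
empty fields for missing values and UTF-8 encoding.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import COHORT_COLUMNS, GeneratorConfig
from .errors import ConfigError, DataError

log = logging.getLogger("semcohort")

_NUMERIC_COLUMNS = tuple(c for c in COHORT_COLUMNS
                         if c not in ("subject_id", "arm"))


def write_cohort(table: pd.DataFrame, path, include_hidden: bool = False
                 ) -> None:
    """Write a cohort table with the canonical column order; hidden
    generator-state columns (leading underscore) are dropped unless
    requested."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort table lacks columns: {missing}")
    cols = list(COHORT_COLUMNS)
    if include_hidden:
        cols += [c for c in table.columns if c.startswith("_")]
    table[cols].to_csv(path, index=False, float_format="%.12g",
                       lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name unknown/missing
    columns and non-numeric cells."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(table.columns)
    missing = [c for c in COHORT_COLUMNS if c not in cols]
    unknown = [c for c in cols
               if c not in COHORT_COLUMNS and not c.startswith("_")]
    if missing or unknown:
        raise DataError(f"bad cohort header: missing {missing}, "
                        f"unknown {unknown}")
    out = {}
    out["subject_id"] = table["subject_id"]
    out["arm"] = table["arm"]
    for col in cols:
        if col in ("subject_id", "arm"):
            continue
        raw = table[col].replace("", None)
        try:
            out[col] = pd.to_numeric(raw)
        except (ValueError, TypeError):
            bad = next(i for i, v in raw.items()
                       if v is not None and not _is_number(v))
            raise DataError(f"non-numeric value {raw[bad]!r} in column "
                            f"{col!r}, row {bad}") from None
    frame = pd.DataFrame(out)[cols]
    frame["cv_death_5y"] = frame["cv_death_5y"].astype("Int64")
    log.info("read cohort %s: n=%d rows, %d missing cells", path,
             len(frame), int(frame.isna().sum().sum()))
    return frame


def _is_number(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def load_config(path) -> GeneratorConfig:
    """Load a YAML generator configuration; unknown keys are rejected
    and missing keys fall back to the documented defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    return GeneratorConfig.from_dict(raw)


def save_config(config: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(),
                                         sort_keys=True),
                          encoding="utf-8")


@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every CLI output."""

    seed: int | None
    config_hash: str | None
    stages: list[str]
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(
            _dt.timezone.utc).isoformat(timespec="seconds"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True) + "\n",
                              encoding="utf-8")


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
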