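"""Plain-text serialization: cohort CSV, specs/truth/report JSON, records TSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

RESERVED_COLUMNS = (
    "participant_id", "family_id", "site_id", "subsample",
    "age", "sex", "sex_male", "race_black", "race_white", "hispanic", "sgm",
    "income_ordinal", "parent_education", "adversity", "nonsocial_screentime",
    "outcome_continuous", "outcome_binary",
)


def exposure_columns(df: pd.DataFrame) -> list[str]:
    """Exposure columns by convention: everything outside the reserved set."""
    return [c for c in df.columns if c not in RESERVED_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    """UTF-8 comma-delimited table; missing values as empty fields."""
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_JsonEncoder) + "\n",
                          encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_records_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_records_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
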