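"""Survey table I/O, validation, and the cause-group scheme.

Visit reasons in aging/adult-health surveys are recorded as one of a short
list of raw codes (18 here).  Analysis collapses them into seven cause
groups informed by burden-of-disease classifications: NCDs, CDs (which
include maternal and child health), injuries, pain, surgery, other, and
unidentified.  The raw-code-to-group mapping is survey-specific and is
therefore shipped as an editable two-column CSV, not hard-coded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from checause.errors import CodebookError, IntegrityError, SchemaError

log = logging.getLogger(__name__)


class CauseGroup(str, Enum):
    """The seven analysis cause groups.

    Declaration order is canonical and is used for deterministic
    tie-breaking wherever a modal class must be chosen.
    """

    NCD = "NCD"
    CD = "CD"  # includes maternal and child health
    INJURY = "INJURY"
    PAIN = "PAIN"
    SURGERY = "SURGERY"
    OTHER = "OTHER"
    UNIDENTIFIED = "UNIDENTIFIED"


CAUSE_ORDER: tuple[str, ...] = tuple(g.value for g in CauseGroup)

#: categories a CHE case can be attributed to
DISEASE_CATEGORIES: tuple[str, ...] = ("NCD", "CD", "INJURY")

CARE_LEVELS: tuple[str, ...] = ("outpatient", "inpatient")


@dataclass(frozen=True)
class ReasonCodebook:
    """Total mapping from raw visit-reason codes to cause groups."""

    mapping: Mapping[str, CauseGroup]
    version: str = "default"

    def __post_init__(self):
        groups = set(self.mapping.values())
        for required in (CauseGroup.NCD, CauseGroup.CD, CauseGroup.INJURY):
            if required not in groups:
                raise SchemaError(
                    f"codebook must map at least one code to {required.value}"
                )

    @classmethod
    def default(cls) -> "ReasonCodebook":
        """Ship-with default 18-reason codebook (best-effort mapping)."""
        with resources.files("checause.data").joinpath(
            "reason_codebook.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df, version="builtin-18")

    @classmethod
    def from_csv(cls, path: str | Path, version: str | None = None) -> "ReasonCodebook":
        df = pd.read_csv(path)
        return cls.from_frame(df, version=version or str(path))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, version: str = "frame") -> "ReasonCodebook":
        if not {"code", "group"} <= set(df.columns):
            raise SchemaError("codebook needs columns 'code' and 'group'")
        try:
            mapping = {
                str(r.code): CauseGroup(r.group) for r in df.itertuples(index=False)
            }
        except ValueError as exc:
            raise SchemaError(f"unknown cause group in codebook: {exc}") from exc
        return cls(mapping=mapping, version=version)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.mapping)


def map_reason_to_group(raw_code: str, codebook: ReasonCodebook) -> CauseGroup:
    """Map one raw reason code to its cause group.

    Raises :class:`CodebookError` listing the valid codes when the code is
    absent — unmapped reasons must be surfaced, never silently bucketed.
    """
    try:
        return codebook.mapping[raw_code]
    except KeyError:
        raise CodebookError(
            f"reason code {raw_code!r} not in codebook "
            f"(valid codes: {sorted(codebook.mapping)})"
        ) from None


def map_reasons(codes: pd.Series, codebook: ReasonCodebook) -> pd.Series:
    """Vectorized reason→group mapping; missing inputs stay missing."""
    present = codes.dropna()
    unknown = set(present.unique()) - set(codebook.mapping)
    if unknown:
        raise CodebookError(
            f"reason codes {sorted(unknown)} not in codebook "
            f"(valid codes: {sorted(codebook.mapping)})"
        )
    out = codes.map({k: v.value for k, v in codebook.mapping.items()})
    return out


@dataclass
class SurveyDesign:
    """Complex-survey design: per-household stratum, PSU and weight."""

    frame: pd.DataFrame = field(repr=False)  # household_id, stratum, psu, weight

    def __post_init__(self):
        required = {"household_id", "stratum", "psu", "weight"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"design frame missing columns {sorted(missing)}")
        if self.frame["household_id"].duplicated().any():
            raise SchemaError("design frame has duplicate household ids")
        if (self.frame["weight"] <= 0).any():
            raise SchemaError("survey weights must be strictly positive")

    @classmethod
    def from_households(cls, households: pd.DataFrame) -> "SurveyDesign":
        return cls(households[["household_id", "stratum", "psu", "weight"]].copy())

    def weights_for(self, household_ids: pd.Series) -> pd.Series:
        w = self.frame.set_index("household_id")["weight"]
        return household_ids.map(w)


# ---------------------------------------------------------------------------
# schema definition and validated reading
# ---------------------------------------------------------------------------

HOUSEHOLD_COLUMNS = {
    "household_id": "int64",
    "country": "str",
    "stratum": "int64",
    "psu": "int64",
    "weight": "float64",
    "hh_type": "str",
    "size": "int64",
    "expenditure": "float64",
    "food_expenditure": "float64",
    "asset_index": "float64",
    "wealth_q": "int64",
}

RESPONDENT_COLUMNS = {
    "respondent_id": "int64",
    "household_id": "int64",
    "country": "str",
    "age": "int64",
    "female": "int64",
    "urban": "int64",
    "education": "int64",
    "wealth_q": "int64",
    "n_visits_outpatient": "int64",
    "n_visits_inpatient": "int64",
}

VISIT_COLUMNS = {
    "visit_id": "int64",
    "respondent_id": "int64",
    "household_id": "int64",
    "country": "str",
    "care_level": "str",
    "rank": "int64",
    "reason_code": "str?",  # ? = nullable
    "cause_group": "str?",
    "private_facility": "float64?",
    "oop_cost": "float64?",
}


def schema_dict() -> dict:
    """Machine-readable schema: column name, type, nullability, units."""
    def spec(cols, units=None):
        units = units or {}
        return [
            {
                "name": c,
                "type": t.rstrip("?"),
                "nullable": t.endswith("?"),
                "units": units.get(c, ""),
            }
            for c, t in cols.items()
        ]

    money = "nominal currency units"
    return {
        "missingness": "missing cells are empty/NA, never sentinel numbers",
        "households": spec(
            HOUSEHOLD_COLUMNS,
            {"expenditure": money, "food_expenditure": money, "weight": "persons"},
        ),
        "respondents": spec(RESPONDENT_COLUMNS, {"age": "years"}),
        "visits": spec(VISIT_COLUMNS, {"oop_cost": money}),
    }


def _check_columns(df: pd.DataFrame, cols: dict, name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"table '{name}' missing columns {sorted(missing)}")


def validate_tables(
    households: pd.DataFrame, respondents: pd.DataFrame, visits: pd.DataFrame
) -> None:
    """Validate schema, value ranges, and referential integrity."""
    _check_columns(households, HOUSEHOLD_COLUMNS, "households")
    _check_columns(respondents, RESPONDENT_COLUMNS, "respondents")
    _check_columns(visits, VISIT_COLUMNS, "visits")

    if (households["weight"] <= 0).any():
        bad = households.index[households["weight"] <= 0][0]
        raise SchemaError(f"households row {bad}: nonpositive weight")
    if (households["size"] < 1).any():
        raise SchemaError("households: size must be >= 1")

    oop = visits["oop_cost"]
    if (oop.dropna() < 0).any():
        row = visits.index[oop < 0][0]
        raise SchemaError(f"visits row {row}: negative oop_cost")
    if (visits["rank"] < 1).any():
        raise SchemaError("visits: rank must be >= 1")
    bad_level = ~visits["care_level"].isin(CARE_LEVELS)
    if bad_level.any():
        raise SchemaError(
            f"visits: unknown care_level {visits.loc[bad_level, 'care_level'].iloc[0]!r}"
        )

    hh_ids = set(households["household_id"])
    orphan_resp = ~respondents["household_id"].isin(hh_ids)
    if orphan_resp.any():
        rid = respondents.loc[orphan_resp, "respondent_id"].iloc[0]
        raise IntegrityError(f"respondent {rid} references unknown household")
    resp_ids = set(respondents["respondent_id"])
    orphan_vis = ~visits["respondent_id"].isin(resp_ids)
    if orphan_vis.any():
        vid = visits.loc[orphan_vis, "visit_id"].iloc[0]
        raise IntegrityError(f"visit {vid} references unknown respondent")


def write_survey(
    out_dir: str | Path,
    households: pd.DataFrame,
    respondents: pd.DataFrame,
    visits: pd.DataFrame,
    fmt: str = "both",
) -> Path:
    """Write the three flat tables as CSV and/or parquet plus a schema file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {"households": households, "respondents": respondents, "visits": visits}
    for name, df in tables.items():
        if fmt in ("csv", "both"):
            df.to_csv(out / f"{name}.csv", index=False)
        if fmt in ("parquet", "both"):
            df.to_parquet(out / f"{name}.parquet", index=False)
    (out / "schema.json").write_text(json.dumps(schema_dict(), indent=2))
    return out


def read_survey(
    in_dir: str | Path, fmt: str = "csv"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SurveyDesign]:
    """Read, type and validate the three tables; return them plus the design."""
    ind = Path(in_dir)
    frames = {}
    for name in ("households", "respondents", "visits"):
        path = ind / f"{name}.{ 'parquet' if fmt == 'parquet' else 'csv'}"
        if not path.exists():
            raise SchemaError(f"missing input file {path}")
        if fmt == "parquet":
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
        frames[name] = df
    households, respondents, visits = (
        frames["households"],
        frames["respondents"],
        frames["visits"],
    )
    # normalize dtypes for nullable columns read back from CSV
    for col in ("oop_cost", "private_facility"):
        if col in visits:
            visits[col] = pd.to_numeric(visits[col], errors="coerce")
    validate_tables(households, respondents, visits)
    log.info(
        "read survey: %d households, %d respondents, %d visits",
        len(households),
        len(respondents),
        len(visits),
    )
    return households, respondents, visits, SurveyDesign.from_households(households)
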