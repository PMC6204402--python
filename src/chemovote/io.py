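"""CSV dialects and config serialization.

Two table formats are defined and round-tripped exactly:

* **Assay CSV** (long format), header ``strain,lot,lab,analyte,value`` —
  one row per lot × analyte. An *empty* value field means the lab did not
  test that analyte on that lot; ``0`` / ``0.0`` is a measured zero. The
  two are never conflated.
* **Survey CSV**, header ``respondent_id,likert_rating,most_effective,
  least_effective,side_effects,symptoms`` — one row per respondent;
  multi-select fields are semicolon-delimited, a blank rating means the
  item was skipped.

Parsing goes through pandas with ``keep_default_na=False`` so empty fields
survive as empty strings rather than NaN.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from . import panel as _panel
from .models import (
    AssociationResult,
    LotAssay,
    SurveyResponse,
    TerpenePartition,
    VoteTally,
    WeightedProfile,
)

PathLike = Union[str, Path]

ASSAY_COLUMNS = ["strain", "lot", "lab", "analyte", "value"]
SURVEY_COLUMNS = [
    "respondent_id",
    "likert_rating",
    "most_effective",
    "least_effective",
    "side_effects",
    "symptoms",
]


class ParseError(ValueError):
    """A table failed validation; the message carries the offending line."""


def _require_header(df: pd.DataFrame, expected: list[str], path: PathLike) -> None:
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: expected header {','.join(expected)!r},"
            f" got {','.join(df.columns)!r}"
        )


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------


def read_assay_table(path: PathLike) -> list[LotAssay]:
    """Read a long-format assay CSV into per-lot assay records.

    Strain and lot labels are trimmed; analyte names are canonicalized
    against the panel. Duplicate (strain, lot, analyte) cells, negative
    values, unknown analytes and conflicting lab labels are parse errors
    reported with their line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_header(df, ASSAY_COLUMNS, path)
    cells: dict[tuple[str, str], dict[str, Optional[float]]] = {}
    labs: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based, after header
        strain = row.strain.strip()
        lot = row.lot.strip()
        if not strain or not lot:
            raise ParseError(f"{path}:{line}: empty strain or lot label")
        try:
            analyte = _panel.canonical_analyte(row.analyte)
        except _panel.UnknownAnalyteError as exc:
            raise ParseError(f"{path}:{line}: {exc.args[0]}") from None
        raw = row.value.strip()
        if raw == "":
            value: Optional[float] = None
        else:
            try:
                value = float(raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{line}: unparseable value {raw!r}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}:{line}: negative concentration {value}")
        key = (strain, lot)
        if key not in cells:
            cells[key] = {}
            labs[key] = row.lab.strip()
            order.append(key)
        elif labs[key] != row.lab.strip():
            raise ParseError(
                f"{path}:{line}: conflicting lab for lot {lot!r}:"
                f" {labs[key]!r} vs {row.lab.strip()!r}"
            )
        if analyte in cells[key]:
            raise ParseError(
                f"{path}:{line}: duplicate cell ({strain!r}, {lot!r}, {analyte!r})"
            )
        cells[key][analyte] = value
    return [
        LotAssay(strain=s, lot=t, lab=labs[(s, t)], concentrations=cells[(s, t)])
        for s, t in order
    ]


def write_assay_table(assays: Iterable[LotAssay], path: PathLike) -> None:
    rows = []
    for a in assays:
        for analyte in sorted(a.concentrations, key=_panel.panel_sort_key):
            value = a.concentrations[analyte]
            rows.append(
                {
                    "strain": a.strain,
                    "lot": a.lot,
                    "lab": a.lab,
                    "analyte": analyte,
                    "value": "" if value is None else repr(float(value)),
                }
            )
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------


def _parse_multiselect(raw: str) -> frozenset[str]:
    return frozenset(s.strip() for s in raw.split(";") if s.strip())


def read_survey_table(path: PathLike) -> list[SurveyResponse]:
    """Read a survey CSV; one response per row, duplicate ids rejected."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_header(df, SURVEY_COLUMNS, path)
    seen: set[str] = set()
    responses: list[SurveyResponse] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        rid = row.respondent_id.strip()
        if not rid:
            raise ParseError(f"{path}:{line}: empty respondent_id")
        if rid in seen:
            raise ParseError(f"{path}:{line}: duplicate respondent_id {rid!r}")
        seen.add(rid)
        raw_rating = row.likert_rating.strip()
        if raw_rating == "":
            rating: Optional[int] = None
        else:
            try:
                rating = int(raw_rating)
            except ValueError:
                raise ParseError(
                    f"{path}:{line}: unparseable likert_rating {raw_rating!r}"
                ) from None
            if not 0 <= rating <= 10:
                raise ParseError(
                    f"{path}:{line}: likert_rating {rating} out of 0..10"
                )
        responses.append(
            SurveyResponse(
                respondent_id=rid,
                likert_rating=rating,
                most_effective=_parse_multiselect(row.most_effective),
                least_effective=_parse_multiselect(row.least_effective),
                side_effects=_parse_multiselect(row.side_effects),
                symptoms=_parse_multiselect(row.symptoms),
            )
        )
    return responses


def write_survey_table(responses: Iterable[SurveyResponse], path: PathLike) -> None:
    def join(values: frozenset[str]) -> str:
        return ";".join(sorted(values))

    rows = [
        {
            "respondent_id": r.respondent_id,
            "likert_rating": "" if r.likert_rating is None else str(r.likert_rating),
            "most_effective": join(r.most_effective),
            "least_effective": join(r.least_effective),
            "side_effects": join(r.side_effects),
            "symptoms": join(r.symptoms),
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_tally_csv(tally: VoteTally, path: PathLike) -> None:
    rows = [
        {"strain": s, "votes": v}
        for s, v in sorted(tally.votes.items(), key=lambda sv: (-sv[1], sv[0]))
    ]
    pd.DataFrame(rows, columns=["strain", "votes"]).to_csv(path, index=False)


def write_profile_csv(profile: WeightedProfile, path: PathLike) -> None:
    rows = [
        {
            "group": profile.group,
            "analyte": analyte,
            "weighted_mean": st.weighted_mean,
            "weighted_sd": st.weighted_sd,
            "weighted_se": st.weighted_se,
            "n_measurements": st.n_measurements,
        }
        for analyte, st in profile.stats.items()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "group",
            "analyte",
            "weighted_mean",
            "weighted_sd",
            "weighted_se",
            "n_measurements",
        ],
    ).to_csv(path, index=False)


_ASSOC_COLUMNS = [
    "analyte",
    "wa_me",
    "wa_le",
    "cc",
    "se_cc",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "flag",
    "status",
]


def association_frame(
    table: Sequence[AssociationResult], decimals: Optional[int] = None
) -> pd.DataFrame:
    """Association table as a DataFrame; ``decimals`` gives the fixed-point
    report rendering (3 mirrors the published table), ``None`` keeps full
    precision for machine use."""
    rows = []
    for r in table:
        row = {
            "analyte": r.analyte,
            "wa_me": r.wa_me,
            "wa_le": r.wa_le,
            "cc": r.cc,
            "se_cc": r.se_cc,
            "t_stat": r.t_stat,
            "df": r.df,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "flag": r.flag,
            "status": r.status,
        }
        if decimals is not None:
            for key in ("wa_me", "wa_le", "cc", "se_cc", "t_stat", "df", "p_value", "q_value"):
                value = row[key]
                row[key] = "" if value is None or value != value else f"{value:.{decimals}f}"
        rows.append(row)
    return pd.DataFrame(rows, columns=_ASSOC_COLUMNS)


def write_association_csv(
    table: Sequence[AssociationResult],
    path: PathLike,
    decimals: Optional[int] = None,
) -> None:
    association_frame(table, decimals=decimals).to_csv(path, index=False)


def write_partition_csv(partition: TerpenePartition, path: PathLike) -> None:
    rows = [
        {"analyte": a, "class": "major"}
        for a in sorted(partition.major, key=_panel.panel_sort_key)
    ] + [
        {"analyte": a, "class": "minor"}
        for a in sorted(partition.minor, key=_panel.panel_sort_key)
    ]
    pd.DataFrame(rows, columns=["analyte", "class"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configs and manifests
# ---------------------------------------------------------------------------


def load_structured(path: PathLike) -> dict:
    """Load a YAML or JSON mapping (YAML is a superset, so one loader)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return data


def dump_json(data: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
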