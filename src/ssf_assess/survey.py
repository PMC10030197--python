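"""Domain model and I/O for gillnet fisher recall surveys.

A recall survey interviews each fisher once and asks about "typical trips"
during up to three career periods: the first three years fishing, the last
three years, and (for careers longer than a decade) a mid-career year.  Each
fisher reports multispecies catch per trip (kg), effort (hours fishing,
excluding travel), gear (gillnet length in m, mesh size in cm between
opposing knots), and — for the five most caught species — per-species catch,
rank by weight contribution, and average length-at-catch (cm).

This module defines the record types, the convention that maps recall
periods to calendar years, schema validation, and plain-CSV serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "FisherRecord",
    "PeriodObservation",
    "SpeciesObservation",
    "SpeciesInfo",
    "SurveyData",
    "Violation",
    "assign_period_years",
    "validate_survey",
    "read_survey",
    "write_survey",
    "SurveySchemaError",
]

PERIOD_TAGS = ("first", "mid", "last")

#: Default survey year: fishers still active are assigned this stop year.
DEFAULT_SURVEY_YEAR = 2020


class SurveySchemaError(ValueError):
    """A survey CSV does not match the expected schema."""


@dataclass(frozen=True)
class FisherRecord:
    """One interviewed fisher's career span within one fishery."""

    fisher_id: str
    fishery_id: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(
                f"fisher {self.fisher_id!r}: end_year {self.end_year} precedes "
                f"start_year {self.start_year}"
            )

    @property
    def career_length(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass(frozen=True)
class PeriodObservation:
    """A fisher's recalled typical trip during one career period.

    ``year_assigned`` follows the midpoint convention of
    :func:`assign_period_years`.
    """

    fisher_id: str
    period_tag: str
    year_assigned: int
    catch_kg: float
    fishing_time_hr: float
    gillnet_length_m: float
    mesh_size_cm: float

    def __post_init__(self) -> None:
        if self.period_tag not in PERIOD_TAGS:
            raise ValueError(f"unknown period_tag {self.period_tag!r}")


@dataclass(frozen=True)
class SpeciesObservation:
    """Per-species recalled catch within one fisher x period."""

    fisher_id: str
    period_tag: str
    species_id: str
    catch_kg: float
    rank: int
    length_at_catch_cm: float


@dataclass(frozen=True)
class SpeciesInfo:
    """Life-history traits for one species.

    Optional fields are ``None`` when unknown; ``lm_external_cm`` and
    ``lopt_external_cm`` hold externally sourced length-at-maturity /
    optimal length that take precedence over the empirical chain.
    """

    species_id: str
    scientific_name: str = ""
    common_name: str = ""
    lmax_cm: Optional[float] = None
    growth_k: Optional[float] = None
    natural_mortality_m: Optional[float] = None
    age_at_maturity_yr: Optional[float] = None
    lm_external_cm: Optional[float] = None
    lopt_external_cm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("lmax_cm", "growth_k", "natural_mortality_m",
                     "age_at_maturity_yr", "lm_external_cm", "lopt_external_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"species {self.species_id!r}: {name} must be > 0")


@dataclass
class SurveyData:
    """A complete survey dataset: fishers, period and species observations."""

    fishers: list[FisherRecord]
    period_obs: list[PeriodObservation]
    species_obs: list[SpeciesObservation]
    species_table: list[SpeciesInfo] = field(default_factory=list)

    def fisher_map(self) -> dict[str, FisherRecord]:
        return {f.fisher_id: f for f in self.fishers}


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def assign_period_years(
    start_year: int, end_year: int, *, fisher_id: str = "?"
) -> tuple[int, Optional[int], int]:
    """Map a career span to the calendar years of the recall periods.

    The first/last recall periods are the first and last three-year windows
    of the career, represented by their midpoint years (``start+1`` and
    ``end-1``).  A mid-career period exists only for careers longer than
    10 years and is the career midpoint, rounding half up.  Careers shorter
    than three years collapse both windows to the career midpoint.

    Returns ``(first, mid, last)`` with ``mid`` ``None`` when absent.
    """
    if end_year < start_year:
        raise ValueError(
            f"fisher {fisher_id!r}: reversed career years ({start_year}, {end_year})"
        )
    career = end_year - start_year + 1
    midpoint = _round_half_up((start_year + end_year) / 2)
    if career < 3:
        return midpoint, None, midpoint
    first = start_year + 1
    last = end_year - 1
    mid = midpoint if career > 10 else None
    return first, mid, last


@dataclass(frozen=True)
class Violation:
    """One validation failure, located as precisely as the data allows."""

    kind: str
    message: str
    fisher_id: str = ""
    period_tag: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "/".join(p for p in (self.fisher_id, self.period_tag) if p)
        return f"[{self.kind}] {loc}: {self.message}" if loc else f"[{self.kind}] {self.message}"


def validate_survey(
    fishers: Sequence[FisherRecord],
    period_obs: Sequence[PeriodObservation],
    species_obs: Sequence[SpeciesObservation],
    species_table: Sequence[SpeciesInfo] = (),
) -> list[Violation]:
    """Check a survey dataset for structural violations.

    Returns an empty list on clean data.  Checks: unknown fishers/species,
    year assignments outside the career, mid periods on short careers,
    nonpositive measurements, and duplicate or out-of-range species ranks.
    """
    out: list[Violation] = []
    fmap = {f.fisher_id: f for f in fishers}
    known_species = {s.species_id for s in species_table}

    for f in fishers:
        if f.end_year < f.start_year:  # unreachable via constructor, kept for raw rows
            out.append(Violation("reversed_years", f"end {f.end_year} < start {f.start_year}", f.fisher_id))

    for p in period_obs:
        rec = fmap.get(p.fisher_id)
        if rec is None:
            out.append(Violation("unknown_fisher", "period for unlisted fisher", p.fisher_id, p.period_tag))
            continue
        if not (rec.start_year <= p.year_assigned <= rec.end_year):
            out.append(Violation(
                "year_out_of_career",
                f"year_assigned {p.year_assigned} outside [{rec.start_year}, {rec.end_year}]",
                p.fisher_id, p.period_tag))
        if p.period_tag == "mid" and rec.career_length <= 10:
            out.append(Violation("spurious_mid", f"mid period on a {rec.career_length}-year career",
                                 p.fisher_id, p.period_tag))
        if p.catch_kg < 0:
            out.append(Violation("negative_catch", f"catch_kg = {p.catch_kg}", p.fisher_id, p.period_tag))
        for name in ("fishing_time_hr", "gillnet_length_m", "mesh_size_cm"):
            if not getattr(p, name) > 0:
                out.append(Violation("nonpositive_measurement", f"{name} = {getattr(p, name)}",
                                     p.fisher_id, p.period_tag))

    groups: dict[tuple[str, str], list[SpeciesObservation]] = {}
    for s in species_obs:
        groups.setdefault((s.fisher_id, s.period_tag), []).append(s)
        if s.fisher_id not in fmap:
            out.append(Violation("unknown_fisher", "species row for unlisted fisher", s.fisher_id, s.period_tag))
        if known_species and s.species_id not in known_species:
            out.append(Violation("unknown_species", f"species_id {s.species_id!r} not in species table",
                                 s.fisher_id, s.period_tag))
        if s.catch_kg < 0:
            out.append(Violation("negative_catch", f"species catch_kg = {s.catch_kg}", s.fisher_id, s.period_tag))
        if not s.length_at_catch_cm > 0:
            out.append(Violation("nonpositive_measurement",
                                 f"length_at_catch_cm = {s.length_at_catch_cm}", s.fisher_id, s.period_tag))
        if not 1 <= s.rank <= 5:
            out.append(Violation("rank_out_of_range", f"rank = {s.rank}", s.fisher_id, s.period_tag))

    for (fid, tag), rows in groups.items():
        ranks = [r.rank for r in rows]
        if len(set(ranks)) != len(ranks):
            dup = sorted({r for r in ranks if ranks.count(r) > 1})
            out.append(Violation("duplicate_rank", f"duplicate rank(s) {dup}", fid, tag))
        if len(rows) > 5:
            out.append(Violation("too_many_species", f"{len(rows)} species reported (max 5)", fid, tag))
    return out


# ---------------------------------------------------------------------------
# CSV serialization

_FISHER_COLS = ["fisher_id", "fishery_id", "start_year", "end_year"]
_PERIOD_COLS = ["fisher_id", "period_tag", "year_assigned", "catch_kg",
                "fishing_time_hr", "gillnet_length_m", "mesh_size_cm"]
_SPECIES_OBS_COLS = ["fisher_id", "period_tag", "species_id", "catch_kg",
                     "rank", "length_at_catch_cm"]
_SPECIES_COLS = ["species_id", "scientific_name", "common_name", "lmax_cm",
                 "growth_k", "natural_mortality_m", "age_at_maturity_yr",
                 "lm_external_cm", "lopt_external_cm"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path,
                     optional: Iterable[str] = ()) -> None:
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise SurveySchemaError(f"{path.name}: missing required column(s) {missing}")


def read_survey(path: str | Path) -> SurveyData:
    """Read a survey directory of fishers/periods/species_obs/species CSVs.

    ``year_assigned`` is recomputed from the career span when absent from
    periods.csv; a supplied value is kept and later checked by
    :func:`validate_survey`.  Blank cells mean missing.
    """
    d = Path(path)
    fdf = pd.read_csv(d / "fishers.csv")
    _require_columns(fdf, _FISHER_COLS, d / "fishers.csv")
    fishers = [FisherRecord(str(r.fisher_id), str(r.fishery_id), int(r.start_year), int(r.end_year))
               for r in fdf.itertuples()]
    fmap = {f.fisher_id: f for f in fishers}

    pdf = pd.read_csv(d / "periods.csv")
    _require_columns(pdf, _PERIOD_COLS, d / "periods.csv", optional=["year_assigned"])
    period_obs = []
    for i, r in enumerate(pdf.itertuples()):
        fid = str(r.fisher_id)
        if "year_assigned" in pdf.columns and not pd.isna(r.year_assigned):
            year = int(r.year_assigned)
        else:
            rec = fmap.get(fid)
            if rec is None:
                raise SurveySchemaError(f"periods.csv row {i}: unknown fisher {fid!r}")
            first, mid, last = assign_period_years(rec.start_year, rec.end_year, fisher_id=fid)
            tagmap = {"first": first, "mid": mid, "last": last}
            year = tagmap[str(r.period_tag)]
            if year is None:
                raise SurveySchemaError(
                    f"periods.csv row {i}: mid period on short career for fisher {fid!r}")
        try:
            period_obs.append(PeriodObservation(
                fid, str(r.period_tag), year, float(r.catch_kg),
                float(r.fishing_time_hr), float(r.gillnet_length_m), float(r.mesh_size_cm)))
        except (TypeError, ValueError) as e:
            raise SurveySchemaError(f"periods.csv row {i}: {e}") from e

    sdf = pd.read_csv(d / "species_obs.csv")
    _require_columns(sdf, _SPECIES_OBS_COLS, d / "species_obs.csv")
    species_obs = []
    for i, r in enumerate(sdf.itertuples()):
        try:
            species_obs.append(SpeciesObservation(
                str(r.fisher_id), str(r.period_tag), str(r.species_id),
                float(r.catch_kg), int(r.rank), float(r.length_at_catch_cm)))
        except (TypeError, ValueError) as e:
            raise SurveySchemaError(f"species_obs.csv row {i}: {e}") from e

    species_table: list[SpeciesInfo] = []
    sp_path = d / "species.csv"
    if sp_path.exists():
        tdf = pd.read_csv(sp_path)
        _require_columns(tdf, ["species_id"], sp_path)
        for r in tdf.itertuples():
            kw = {}
            for col in _SPECIES_COLS[3:]:
                v = getattr(r, col, None)
                kw[col] = None if v is None or pd.isna(v) else float(v)
            species_table.append(SpeciesInfo(
                str(r.species_id),
                "" if pd.isna(getattr(r, "scientific_name", "")) else str(getattr(r, "scientific_name", "")),
                "" if pd.isna(getattr(r, "common_name", "")) else str(getattr(r, "common_name", "")),
                **kw))
    return SurveyData(fishers, period_obs, species_obs, species_table)


def write_survey(data: SurveyData, path: str | Path) -> None:
    """Write a survey dataset as the four plain CSVs under ``path``."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{c: getattr(f, c) for c in _FISHER_COLS} for f in data.fishers],
                 columns=_FISHER_COLS).to_csv(d / "fishers.csv", index=False)
    pd.DataFrame([{c: getattr(p, c) for c in _PERIOD_COLS} for p in data.period_obs],
                 columns=_PERIOD_COLS).to_csv(d / "periods.csv", index=False)
    pd.DataFrame([{c: getattr(s, c) for c in _SPECIES_OBS_COLS} for s in data.species_obs],
                 columns=_SPECIES_OBS_COLS).to_csv(d / "species_obs.csv", index=False)
    rows = []
    for s in data.species_table:
        rows.append({c: ("" if getattr(s, c) is None else getattr(s, c)) for c in _SPECIES_COLS})
    pd.DataFrame(rows, columns=_SPECIES_COLS).to_csv(d / "species.csv", index=False)


def periods_frame(data: SurveyData) -> pd.DataFrame:
    """Period observations joined with career metadata, one row per fisher x period."""
    fmap = data.fisher_map()
    rows = []
    for p in data.period_obs:
        rec = fmap[p.fisher_id]
        rows.append({
            "fisher_id": p.fisher_id, "fishery_id": rec.fishery_id,
            "period_tag": p.period_tag, "year_assigned": p.year_assigned,
            "catch_kg": p.catch_kg, "fishing_time_hr": p.fishing_time_hr,
            "gillnet_length_m": p.gillnet_length_m, "mesh_size_cm": p.mesh_size_cm,
        })
    return pd.DataFrame(rows)


def species_frame(data: SurveyData) -> pd.DataFrame:
    """Species observations joined with fishery id and assigned year."""
    fmap = data.fisher_map()
    years = {(p.fisher_id, p.period_tag): p.year_assigned for p in data.period_obs}
    rows = []
    for s in data.species_obs:
        rec = fmap[s.fisher_id]
        rows.append({
            "fisher_id": s.fisher_id, "fishery_id": rec.fishery_id,
            "period_tag": s.period_tag,
            "year_assigned": years.get((s.fisher_id, s.period_tag)),
            "species_id": s.species_id, "catch_kg": s.catch_kg,
            "rank": s.rank, "length_at_catch_cm": s.length_at_catch_cm,
        })
    return pd.DataFrame(rows)
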