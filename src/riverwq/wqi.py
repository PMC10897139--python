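"""Water Quality Index engine.

The index is the weighted mean

    WQI = sum_i(C_i * P_i) / sum_i(P_i)

where each of twelve physicochemical/microbiological parameters receives a
normalization score ``C_i`` in {0, 10, ..., 100} from a banded lookup table
and an integer relative weight ``P_i``. The band table follows the
Pesce–Wunderlin convention for river monitoring: nine parameters are
"smaller is better" (strict upper bounds per band), dissolved oxygen is
"larger is better", and temperature and pH are scored on nested/overlapping
intervals resolved by first match scanning from the best band (100) down.

Boundary semantics are taken literally from the printed comparators: a value
equal to a strict threshold fails that band and falls to the next one (e.g.
turbidity 5 scores 90, dissolved oxygen 7.0 scores 80). The second-worst band
of the "smaller is better" rows is an inclusive upper bound, making the bands
jointly exhaustive together with the residual 0 band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Literal

import yaml

log = logging.getLogger(__name__)


def _load_yaml_text_or_path(text_or_path):
    """Accept either YAML text or a path to a YAML file."""
    import os

    try:
        is_file = os.path.exists(str(text_or_path)) and "\n" not in str(text_or_path)
    except (OSError, ValueError):
        is_file = False
    if is_file:
        with open(text_or_path) as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(text_or_path)

#: canonical ids of the twelve index parameters, with units
PARAMETER_UNITS: dict[str, str] = {
    "conductivity": "uS/cm",
    "dissolved_oxygen": "mg/L",
    "turbidity": "NTU",
    "nitrite": "mg/L",
    "nitrate": "mg/L",
    "ammonium": "mg/L",
    "hardness": "mg/L",
    "chloride": "mg/L",
    "sulfate": "mg/L",
    "total_coliforms": "MPN/100 mL",
    "temperature": "degC",
    "ph": "unitless",
}
PARAMETER_IDS: tuple[str, ...] = tuple(PARAMETER_UNITS)

#: extra variables carried through to the association stage (not in the index)
ASSOCIATION_PARAMETERS: tuple[str, ...] = (
    "color",
    "total_phosphorus",
    "total_alkalinity",
    "total_evaporation_residue",
)

WEIGHTS: dict[str, int] = {
    "conductivity": 2,
    "dissolved_oxygen": 4,
    "turbidity": 2,
    "nitrite": 2,
    "nitrate": 2,
    "ammonium": 3,
    "hardness": 1,
    "chloride": 1,
    "sulfate": 2,
    "total_coliforms": 3,
    "temperature": 1,
    "ph": 1,
}

CI_LEVELS: tuple[int, ...] = tuple(range(100, -1, -10))

# "smaller is better" rows: nine strict upper bounds (C_i = 100..20) and one
# inclusive upper bound (C_i = 10); the residual "> last" band scores 0.
_UPPER_BOUND_ROWS: dict[str, list[float]] = {
    "conductivity": [750, 1000, 1250, 1500, 2000, 2500, 3000, 5000, 8000, 12000],
    "turbidity": [5, 10, 15, 20, 25, 30, 40, 60, 80, 100],
    "nitrite": [0.005, 0.01, 0.03, 0.05, 0.10, 0.15, 0.20, 0.25, 0.50, 1.00],
    "nitrate": [0.5, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 50.0, 100.0],
    "ammonium": [0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.75, 1.00, 1.25],
    "hardness": [25, 100, 200, 300, 400, 500, 600, 800, 1000, 1500],
    "chloride": [25, 50, 100, 150, 200, 300, 500, 700, 1000, 1500],
    "sulfate": [25, 50, 75, 100, 150, 250, 400, 600, 1000, 1500],
    "total_coliforms": [50, 500, 1000, 2000, 3000, 4000, 5000, 7000, 10000, 14000],
}

# dissolved oxygen: larger is better; >= 7.5 is 100, the 10 band is >= 1.0,
# below 1.0 scores 0.
_DO_ROW: list[tuple[float, bool]] = [
    (7.5, True),
    (7.0, False),
    (6.5, False),
    (6.0, False),
    (5.0, False),
    (4.0, False),
    (3.5, False),
    (3.0, False),
    (2.0, False),
    (1.0, True),
]

# temperature bands are widening nested closed intervals [low, high];
# outside the widest one ( > 45 or < -6 ) scores 0.
_TEMPERATURE_ROW: list[tuple[float, float]] = [
    (16, 21), (15, 22), (14, 24), (12, 26), (10, 28),
    (5, 30), (0, 32), (-2, 36), (-4, 40), (-6, 45),
]

# pH bands are overlapping closed intervals resolved by first match from the
# top; the worst non-zero band spans the full usual pH scale.
_PH_ROW: list[tuple[float, float]] = [
    (7, 8), (7, 8.5), (7, 9), (6.5, 7), (6, 9.5),
    (5, 10), (4, 11), (3, 12), (2, 13), (1, 14),
]


@dataclass(frozen=True)
class BandPredicate:
    """One cell of the normalization table.

    kind:
      * ``upper_bound`` — value < high (or <= high when inclusive)
      * ``lower_bound`` — value > low (or >= low when inclusive)
      * ``interval``    — low <= value <= high (closed)
      * ``residual``    — catch-all for the 0 band
    """

    kind: Literal["upper_bound", "lower_bound", "interval", "residual"]
    low: float | None = None
    high: float | None = None
    inclusive: bool = False

    def matches(self, value: float) -> bool:
        if self.kind == "upper_bound":
            return value <= self.high if self.inclusive else value < self.high
        if self.kind == "lower_bound":
            return value >= self.low if self.inclusive else value > self.low
        if self.kind == "interval":
            return self.low <= value <= self.high
        return True  # residual

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.low is not None:
            d["low"] = self.low
        if self.high is not None:
            d["high"] = self.high
        if self.kind in ("upper_bound", "lower_bound"):
            d["inclusive"] = self.inclusive
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BandPredicate":
        return cls(
            kind=d["kind"],
            low=d.get("low"),
            high=d.get("high"),
            inclusive=d.get("inclusive", False),
        )


@dataclass(frozen=True)
class ParameterDef:
    """A parameter row: unit, weight and the eleven (C_i, predicate) bands."""

    id: str
    unit: str
    weight: int
    bands: tuple[tuple[int, BandPredicate], ...]

    def __post_init__(self):
        if tuple(ci for ci, _ in self.bands) != CI_LEVELS:
            raise ValueError(f"{self.id}: bands must run 100 down to 0 by 10s")


class NormalizationTable:
    """The full 12-parameter band table."""

    def __init__(self, parameters: dict[str, ParameterDef]):
        if set(parameters) != set(PARAMETER_IDS):
            missing = set(PARAMETER_IDS) ^ set(parameters)
            raise ValueError(f"table must define exactly the 12 parameters; off by {sorted(missing)}")
        self.parameters = dict(parameters)

    def weight(self, param_id: str) -> int:
        return self[param_id].weight

    def __getitem__(self, param_id: str) -> ParameterDef:
        try:
            return self.parameters[param_id]
        except KeyError:
            raise KeyError(f"unknown water-quality parameter: {param_id!r}") from None

    def normalize(self, param_id: str, value: float) -> int:
        """Score ``value`` to its C_i: the first band matched scanning 100 -> 0."""
        pdef = self[param_id]
        if not math.isfinite(value):
            raise ValueError(f"{param_id}: value must be finite, got {value!r}")
        for ci, band in pdef.bands:
            if band.matches(value):
                return ci
        raise AssertionError(f"{param_id}: bands failed to cover {value!r}")  # pragma: no cover

    # -- audit round-trip -------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            pid: {
                "unit": p.unit,
                "weight": p.weight,
                "bands": [{"ci": ci, **band.to_dict()} for ci, band in p.bands],
            }
            for pid, p in self.parameters.items()
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "NormalizationTable":
        doc = _load_yaml_text_or_path(text_or_path)
        params = {}
        for pid, row in doc.items():
            bands = tuple(
                (b["ci"], BandPredicate.from_dict(b)) for b in row["bands"]
            )
            params[pid] = ParameterDef(pid, row["unit"], row["weight"], bands)
        return cls(params)


def build_normalization_table() -> NormalizationTable:
    """Construct the canonical 12-parameter normalization table."""
    params: dict[str, ParameterDef] = {}
    for pid, thresholds in _UPPER_BOUND_ROWS.items():
        bands = [
            (ci, BandPredicate("upper_bound", high=t, inclusive=(i == 9)))
            for i, (ci, t) in enumerate(zip(CI_LEVELS[:-1], thresholds))
        ]
        bands.append((0, BandPredicate("residual")))
        params[pid] = ParameterDef(pid, PARAMETER_UNITS[pid], WEIGHTS[pid], tuple(bands))

    do_bands = [
        (ci, BandPredicate("lower_bound", low=lo, inclusive=inc))
        for ci, (lo, inc) in zip(CI_LEVELS[:-1], _DO_ROW)
    ]
    do_bands.append((0, BandPredicate("residual")))
    params["dissolved_oxygen"] = ParameterDef(
        "dissolved_oxygen", "mg/L", WEIGHTS["dissolved_oxygen"], tuple(do_bands)
    )

    for pid, row in (("temperature", _TEMPERATURE_ROW), ("ph", _PH_ROW)):
        bands = [
            (ci, BandPredicate("interval", low=lo, high=hi))
            for ci, (lo, hi) in zip(CI_LEVELS[:-1], row)
        ]
        bands.append((0, BandPredicate("residual")))
        params[pid] = ParameterDef(pid, PARAMETER_UNITS[pid], WEIGHTS[pid], tuple(bands))

    return NormalizationTable(params)


def normalize_parameter(table: NormalizationTable, param_id: str, value: float) -> int:
    """Functional alias for :meth:`NormalizationTable.normalize`."""
    return table.normalize(param_id, value)


# ---------------------------------------------------------------------------
# records, seasons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonCalendar:
    """Maps sample dates to the regional wet/dry split.

    Default: summer (warm, rainy) = December–April; winter (cold, dry) =
    May–November.
    """

    summer_months: frozenset[int] = frozenset({12, 1, 2, 3, 4})

    def season_for(self, d: _date) -> str:
        return "summer" if d.month in self.summer_months else "winter"


@dataclass
class WaterQualityRecord:
    """One site x date measurement vector."""

    site_id: str
    date: _date
    season: str
    values: dict[str, float]

    def __post_init__(self):
        if self.season not in ("summer", "winter"):
            raise ValueError(f"season must be 'summer' or 'winter', got {self.season!r}")
        ph = self.values.get("ph")
        if ph is not None and not (0 <= ph <= 14):
            raise ValueError(f"{self.site_id} {self.date}: pH {ph} outside [0, 14]")
        for pid, v in self.values.items():
            if pid != "temperature" and v < 0:
                raise ValueError(f"{self.site_id} {self.date}: {pid} negative ({v})")


@dataclass
class WQIResult:
    site_id: str
    scope: str  # overall | summer | winter
    wqi: float
    breakdown: list[dict]  # per parameter: value, ci, weight
    n_records: int
    missing: list[str]


def compute_wqi(
    record: WaterQualityRecord,
    table: NormalizationTable,
    missing_policy: Literal["strict", "renormalize"] = "strict",
) -> WQIResult:
    """Score one record: WQI = sum(C_i * P_i) / sum(P_i) over used parameters.

    ``strict`` (default) raises on any missing index parameter;
    ``renormalize`` drops the missing ones and shrinks the weight sum.
    """
    present = [p for p in PARAMETER_IDS if p in record.values]
    missing = [p for p in PARAMETER_IDS if p not in record.values]
    if not present:
        raise ValueError(f"{record.site_id} {record.date}: no index parameters present")
    if missing and missing_policy == "strict":
        raise ValueError(
            f"{record.site_id} {record.date}: missing parameters {missing} "
            "(use missing_policy='renormalize' to drop them)"
        )
    breakdown = []
    num = 0
    den = 0
    for pid in present:
        value = record.values[pid]
        ci = table.normalize(pid, value)
        w = table.weight(pid)
        num += ci * w
        den += w
        breakdown.append({"parameter": pid, "value": value, "ci": ci, "weight": w})
    return WQIResult(
        site_id=record.site_id,
        scope="record",
        wqi=num / den,
        breakdown=breakdown,
        n_records=1,
        missing=missing,
    )


def aggregate_seasonal(
    records: list[WaterQualityRecord],
    table: NormalizationTable,
    missing_policy: Literal["strict", "renormalize"] = "strict",
) -> dict[str, WQIResult]:
    """Per-site seasonal aggregation: index each record, then average.

    Returns up to three scopes — ``overall``, ``summer``, ``winter`` — for the
    single site the records belong to. Scopes without records are absent from
    the result (never reported as zero).
    """
    if not records:
        raise ValueError("aggregate_seasonal needs at least one record")
    site_ids = {r.site_id for r in records}
    if len(site_ids) != 1:
        raise ValueError(f"records span multiple sites: {sorted(site_ids)}")
    site_id = records[0].site_id

    per_record = [(r, compute_wqi(r, table, missing_policy)) for r in records]
    out: dict[str, WQIResult] = {}
    for scope in ("overall", "summer", "winter"):
        sub = [res for r, res in per_record if scope == "overall" or r.season == scope]
        if not sub:
            continue
        missing = sorted({m for res in sub for m in res.missing})
        out[scope] = WQIResult(
            site_id=site_id,
            scope=scope,
            wqi=sum(res.wqi for res in sub) / len(sub),
            breakdown=[],
            n_records=len(sub),
            missing=missing,
        )
    return out


# ---------------------------------------------------------------------------
# guideline exceedances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Guideline:
    """A regulatory limit and the direction in which it is violated.

    kind ``max``: values above ``high`` violate. kind ``min``: values below
    ``low`` violate. kind ``range``: the pair (low, high) brackets the safe
    window for an increasing-toxicity analyte; only values above ``high``
    are flagged (a concentration below the window is not a health breach).
    """

    parameter: str
    kind: Literal["max", "min", "range"]
    low: float | None = None
    high: float | None = None
    source: str = ""

    def violated_by(self, value: float) -> bool:
        if self.kind == "max":
            return value > self.high
        if self.kind == "min":
            return value < self.low
        return value > self.high


class GuidelineSet:
    def __init__(self, guidelines: list[Guideline]):
        self.by_parameter = {g.parameter: g for g in guidelines}

    def __iter__(self):
        return iter(self.by_parameter.values())

    def __len__(self):
        return len(self.by_parameter)

    def to_yaml(self, path=None) -> str:
        doc = [
            {k: v for k, v in vars(g).items() if v not in (None, "")}
            for g in self
        ]
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "GuidelineSet":
        doc = _load_yaml_text_or_path(text_or_path)
        return cls([Guideline(**d) for d in doc])


def default_guidelines() -> GuidelineSet:
    """The three limits shipped by default (configuration supplies the rest)."""
    return GuidelineSet(
        [
            Guideline("nitrite", "max", high=0.2, source="WHO drinking-water guideline"),
            Guideline("dissolved_oxygen", "min", low=4.0, source="aquatic-life guideline"),
            Guideline("ammonium", "range", low=0.05, high=0.47,
                      source="national aquatic-life safe window"),
        ]
    )


@dataclass(frozen=True)
class Violation:
    parameter: str
    value: float
    guideline: Guideline


def flag_exceedances(record: WaterQualityRecord, guidelines: GuidelineSet) -> list[Violation]:
    """List every parameter of ``record`` breaching its guideline."""
    violations = []
    for g in guidelines:
        if g.parameter not in record.values:
            log.info(
                "guideline for %s skipped: parameter absent from record %s %s",
                g.parameter, record.site_id, record.date,
            )
            continue
        value = record.values[g.parameter]
        if g.violated_by(value):
            violations.append(Violation(g.parameter, value, g))
    return violations
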