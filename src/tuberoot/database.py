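"""Per-variety parameter databases and field-measurement tables.

A :class:`ParameterDatabase` maps organ class -> parameter name ->
:class:`~tuberoot.distributions.DistributionSpec` for one potato variety.
The organ classes and their required parameters mirror the characterization
table of the tuber-root model: roots (seminal root, creeping root, creeping
stem) carry initial angles, radii, length, depth, total deflection, count and
— for stem-borne roots — the rooting distance to the seed potato; the
underground (main) stem carries bottom/top radius and height; tubers carry
the three ellipsoid dimensions and a count; the seed potato carries its
dimensions and burial depth.

Field measurements travel as a long-format table (``MeasurementTable``), one
row per (plant, organ instance, parameter) with explicit units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import (
    DistributionSpec,
    ValidationError,
    fit_distribution,
    sample_nonnegative,
    sample_parameter,
)

__all__ = [
    "ORGAN_CLASSES",
    "REQUIRED_PARAMETERS",
    "VARIETY_CODES",
    "ParameterDatabase",
    "build_database",
    "load_database",
    "save_database",
    "load_measurements",
    "save_measurements",
]

ROOT_CLASSES = ("seminal_root", "creeping_root", "creeping_stem")

_ROOT_PARAMS = (
    "axial_angle_deg",
    "radial_angle_deg",
    "initial_radius_mm",
    "tip_radius_mm",
    "length_mm",
    "depth_mm",
    "total_deflection_deg",
    "count",
)

#: parameter set required for each organ class (long-format names; units are
#: part of the name so a table row is self-describing)
REQUIRED_PARAMETERS: dict[str, tuple[str, ...]] = {
    "seed_potato": ("length_mm", "width_mm", "height_mm", "burial_depth_mm"),
    "underground_stem": ("bottom_radius_mm", "top_radius_mm", "height_mm"),
    "seminal_root": _ROOT_PARAMS,
    "creeping_root": _ROOT_PARAMS + ("distance_to_seed_mm",),
    "creeping_stem": _ROOT_PARAMS + ("distance_to_seed_mm",),
    "tuber": ("length_mm", "width_mm", "height_mm", "count"),
}

ORGAN_CLASSES = tuple(REQUIRED_PARAMETERS)

#: variety codes as used in the build flow charts
VARIETY_CODES = {1: "Zaodabai", 2: "Helanshiwu", 3: "Fujin"}
VARIETY_NAMES = {v.lower(): k for k, v in VARIETY_CODES.items()}

#: angles may take any sign; everything else is physically nonnegative
_SIGNED_PARAMS = {"axial_angle_deg", "radial_angle_deg", "total_deflection_deg"}

#: instance counts per plant are derived from distinct instance ids, one spec
#: per multi-instance organ class
_COUNTED_CLASSES = ("seminal_root", "creeping_root", "creeping_stem", "tuber")

_UNITS = {"deg": "deg", "mm": "mm", "count": "count"}


def parameter_units(parameter: str) -> str:
    if parameter.endswith("_deg"):
        return "deg"
    if parameter.endswith("_mm"):
        return "mm"
    if parameter == "count":
        return "count"
    raise ValidationError(f"unknown parameter {parameter!r}")


@dataclass
class ParameterDatabase:
    """variety -> organ class -> parameter -> DistributionSpec."""

    variety: str
    organs: dict[str, dict[str, DistributionSpec]] = field(default_factory=dict)

    def spec(self, organ: str, parameter: str) -> DistributionSpec:
        try:
            return self.organs[organ][parameter]
        except KeyError:
            raise ValidationError(
                f"database for {self.variety!r} is missing spec "
                f"organs.{organ}.{parameter}"
            ) from None

    def sample(
        self, organ: str, parameter: str, rng: np.random.Generator
    ) -> float:
        """Draw one value; nonnegative parameters reject/clamp negatives."""
        spec = self.spec(organ, parameter)
        if parameter in _SIGNED_PARAMS:
            return sample_parameter(spec, rng)
        return sample_nonnegative(spec, rng)

    def sample_count(
        self, organ: str, rng: np.random.Generator
    ) -> int:
        """Organ count: sampled then rounded to the nearest nonnegative int."""
        return max(0, round(self.sample(organ, "count", rng)))

    def missing(self) -> list[tuple[str, str]]:
        """Required (organ, parameter) pairs not present in the database."""
        out = []
        for organ, params in REQUIRED_PARAMETERS.items():
            for p in params:
                if p not in self.organs.get(organ, {}):
                    out.append((organ, p))
        return out

    def validate_complete(self) -> None:
        gaps = self.missing()
        if gaps:
            organ, p = gaps[0]
            raise ValidationError(
                f"database for {self.variety!r} is incomplete: missing "
                f"organs.{organ}.{p} (and {len(gaps) - 1} more)"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variety": self.variety,
            "organs": {
                organ: {p: s.to_dict() for p, s in params.items()}
                for organ, params in self.organs.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterDatabase":
        if not isinstance(d, dict) or "variety" not in d:
            raise ValidationError("variety: missing required field")
        organs_doc = d.get("organs")
        if not isinstance(organs_doc, dict):
            raise ValidationError("organs: missing or not an object")
        organs: dict[str, dict[str, DistributionSpec]] = {}
        for organ, params in organs_doc.items():
            if organ not in ORGAN_CLASSES:
                raise ValidationError(
                    f"organs.{organ}: unknown organ class {organ!r} "
                    f"(expected one of {', '.join(ORGAN_CLASSES)})"
                )
            organs[organ] = {}
            for p, spec_doc in params.items():
                parameter_units(p)  # rejects unknown parameter names
                organs[organ][p] = DistributionSpec.from_dict(
                    spec_doc, path=f"organs.{organ}.{p}"
                )
        return cls(variety=str(d["variety"]), organs=organs)


def resolve_variety(code_or_name: int | str) -> tuple[int, str]:
    """Accept a numeric code (1/2/3) or a variety name; return both."""
    if isinstance(code_or_name, str) and not code_or_name.isdigit():
        key = code_or_name.lower()
        if key not in VARIETY_NAMES:
            raise ValidationError(f"unknown variety {code_or_name!r}")
        return VARIETY_NAMES[key], VARIETY_CODES[VARIETY_NAMES[key]]
    code = int(code_or_name)
    if code not in VARIETY_CODES:
        raise ValidationError(
            f"unknown variety code {code} (expected 1, 2 or 3)"
        )
    return code, VARIETY_CODES[code]


# ---------------------------------------------------------------------------
# measurement tables


MEASUREMENT_COLUMNS = [
    "plant_id", "organ_class", "instance_id", "parameter", "value", "units"
]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(
            f"measurement table missing columns: {', '.join(missing)}"
        )
    vals = pd.to_numeric(table["value"], errors="coerce")
    if vals.isna().any() or not np.isfinite(vals).all():
        bad = table.loc[~np.isfinite(pd.to_numeric(table['value'],
                                                   errors='coerce'))]
        raise ValidationError(
            f"non-finite measurement values in {len(bad)} rows"
        )
    return table


def load_measurements(path: str | Path) -> pd.DataFrame:
    return _check_table(pd.read_csv(path))


def save_measurements(table: pd.DataFrame, path: str | Path) -> None:
    _check_table(table)
    table.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def build_database(
    table: pd.DataFrame, alpha: float = 0.05, variety: str | None = None
) -> ParameterDatabase:
    """Fit one DistributionSpec per measured (organ, parameter).

    Scalar parameters are fitted by :func:`fit_distribution`; per-plant organ
    counts (roots, stems, tubers) are derived from the number of distinct
    instance ids each plant carries and fitted the same way.  Organ classes
    present in the table must carry their full parameter set; classes absent
    altogether are simply left out (the result then fails
    ``validate_complete`` until supplied).
    """
    _check_table(table)
    if len(table) == 0:
        raise ValidationError("empty measurement table")
    if variety is None:
        variety = "unknown"

    organs: dict[str, dict[str, DistributionSpec]] = {}
    for organ, grp in table.groupby("organ_class"):
        if organ not in ORGAN_CLASSES:
            raise ValidationError(f"unknown organ class {organ!r} in table")
        organs[organ] = {}
        for parameter in REQUIRED_PARAMETERS[organ]:
            if parameter == "count":
                continue
            rows = grp[grp["parameter"] == parameter]
            if len(rows) < 8:
                raise ValidationError(
                    f"missing or underpowered (organ, parameter) pair "
                    f"({organ}, {parameter}): {len(rows)} values, need >= 8"
                )
            organs[organ][parameter] = fit_distribution(
                rows["value"].to_numpy(float), alpha=alpha
            )
        if organ in _COUNTED_CLASSES:
            per_plant = (
                grp.groupby("plant_id")["instance_id"].nunique().to_numpy(float)
            )
            organs[organ]["count"] = fit_distribution(
                per_plant, alpha=alpha, discrete=True
            )
    return ParameterDatabase(variety=variety, organs=organs)


def save_database(db: ParameterDatabase, path: str | Path) -> None:
    Path(path).write_text(json.dumps(db.to_dict(), indent=2) + "\n")


def load_database(path: str | Path) -> ParameterDatabase:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: not valid JSON ({e})") from None
    return ParameterDatabase.from_dict(doc)
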