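"""Data model and I/O for drug panels, endpoint series, and chip QC.

The panel describes each benchmark drug by its clinical exposure (total plasma
C_max), protein-binding fractions in plasma and in the 2% FBS chip medium, and
its Garside DILI severity rank (1 = severe clinical DILI ... 5 = no DILI).
Endpoint series hold replicate measurements over a dose grid expressed as
multiples of the unbound human C_max (0 = vehicle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ENDPOINTS = ("albumin", "ALT", "morphology_score")
DAYS = (1, 3, 7)

PANEL_COLUMNS = [
    "drug",
    "cmax_total_ng_ml",
    "fu_plasma",
    "fu_media",
    "garside_rank",
    "matched_pair",
    "donors",
]
SERIES_COLUMNS = ["drug", "donor", "endpoint", "day", "dose_multiple", "replicate", "value"]

#: protein-content ratio of 2% FBS culture medium to human plasma, used when a
#: measured media unbound fraction is not supplied
DEFAULT_MEDIA_PROTEIN_RATIO = 0.02

#: perfusion rates (uL/h) accepted by default for effluent production-rate QC
DEFAULT_FLOW_RATES = (30.0, 150.0)


class SchemaError(ValueError):
    """A delimited-text input is missing required structure (e.g. a column)."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugRecord:
    """One benchmark drug: identity, exposure, binding, severity rank.

    ``cmax_total`` is total plasma concentration at C_max in ng/mL; ``fu_plasma``
    and ``fu_media`` are unbound fractions in (0, 1]. Binding and exposure may be
    ``None`` when only rank-level information is available (the bundled panel);
    operations that need them raise :class:`ValidationError`.
    """

    name: str
    garside_rank: int
    cmax_total: float | None = None
    fu_plasma: float | None = None
    fu_media: float | None = None
    matched_pair: str | None = None
    donors_tested: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("drug name must be non-empty")
        if self.garside_rank not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"{self.name}: garside_rank must be in 1..5, got {self.garside_rank!r}"
            )
        for attr in ("cmax_total",):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValidationError(f"{self.name}: {attr} must be > 0, got {v}")
        for attr in ("fu_plasma", "fu_media"):
            v = getattr(self, attr)
            if v is not None and not (0 < v <= 1):
                raise ValidationError(f"{self.name}: {attr} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class DoseResponseSeries:
    """Replicate endpoint measurements over an ascending dose grid.

    ``doses`` are multiples of unbound C_max (dimensionless, >= 0; 0 = vehicle);
    ``values[i]`` holds the replicate measurements at ``doses[i]``.
    """

    drug: str
    donor: str
    endpoint: str
    day: int
    doses: tuple[float, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.day not in DAYS:
            raise ValidationError(f"day must be one of {DAYS}, got {self.day}")
        if len(self.doses) != len(self.values):
            raise ValidationError("doses and values must align")
        if any(d < 0 for d in self.doses):
            raise ValidationError("doses must be >= 0")
        if list(self.doses) != sorted(self.doses):
            raise ValidationError("doses must be sorted ascending")
        if 0.0 not in self.doses:
            raise ValidationError("a vehicle (dose 0) group is required")
        if any(len(v) == 0 for v in self.values):
            raise ValidationError("every dose needs at least one replicate")
        if self.endpoint == "morphology_score":
            flat = [x for v in self.values for x in v]
            if any(not (0 <= x <= 4) for x in flat):
                raise ValidationError("morphology scores must lie in [0, 4]")

    @property
    def vehicle_values(self) -> tuple[float, ...]:
        return self.values[self.doses.index(0.0)]

    @property
    def nonzero_doses(self) -> tuple[float, ...]:
        return tuple(d for d in self.doses if d > 0)

    @property
    def max_tested(self) -> float:
        return max(self.doses)


@dataclass(frozen=True)
class ProductionRate:
    """Effluent analyte production, ug per 1e6 hepatocytes per day."""

    analyte: str
    donor: str
    day: int
    rate: float

    def __post_init__(self) -> None:
        if self.analyte not in ("albumin", "urea"):
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.rate < 0:
            raise ValidationError("production rate must be >= 0")


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _opt_float(raw: str | float | None) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    return float(s) if s else None


def load_panel(path: str | Path) -> list[DrugRecord]:
    """Read a drug-panel CSV into validated :class:`DrugRecord` objects.

    Duplicate drug names are rejected; ranks outside 1..5 raise
    :class:`ValidationError`; a missing column raises :class:`SchemaError`
    naming the column.
    """
    df = _read_csv(path, ["drug", "garside_rank"])
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = str(row["drug"]).strip()
        if name in seen:
            raise ValidationError(f"duplicate drug name {name!r}")
        seen.add(name)
        try:
            rank = int(str(row["garside_rank"]).strip())
        except ValueError as exc:
            raise ValidationError(f"{name}: unparseable garside_rank {row['garside_rank']!r}") from exc
        donors_raw = row.get("donors")
        donors: frozenset[str] = frozenset()
        if isinstance(donors_raw, str) and donors_raw.strip():
            donors = frozenset(p.strip() for p in donors_raw.split(";") if p.strip())
        pair = row.get("matched_pair")
        pair = str(pair).strip() if isinstance(pair, str) and str(pair).strip() else None
        records.append(
            DrugRecord(
                name=name,
                garside_rank=rank,
                cmax_total=_opt_float(row.get("cmax_total_ng_ml")),
                fu_plasma=_opt_float(row.get("fu_plasma")),
                fu_media=_opt_float(row.get("fu_media")),
                matched_pair=pair,
                donors_tested=donors,
            )
        )
    return records


def write_panel(records: Iterable[DrugRecord], path: str | Path) -> None:
    """Write records back to the panel CSV schema (round-trips ``load_panel``)."""
    rows = []
    for r in records:
        rows.append(
            {
                "drug": r.name,
                "cmax_total_ng_ml": r.cmax_total,
                "fu_plasma": r.fu_plasma,
                "fu_media": r.fu_media,
                "garside_rank": r.garside_rank,
                "matched_pair": r.matched_pair,
                "donors": ";".join(sorted(r.donors_tested)),
            }
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def load_series(path: str | Path) -> list[DoseResponseSeries]:
    """Read long-format endpoint series CSV into grouped series objects."""
    df = _read_csv(path, SERIES_COLUMNS)
    df = df.astype({"day": int, "dose_multiple": float, "value": float})
    out: list[DoseResponseSeries] = []
    for (drug, donor, endpoint, day), g in df.groupby(
        ["drug", "donor", "endpoint", "day"], sort=True
    ):
        doses = sorted(g["dose_multiple"].unique())
        values = tuple(
            tuple(g.loc[g["dose_multiple"] == d, "value"].tolist()) for d in doses
        )
        out.append(
            DoseResponseSeries(
                drug=str(drug),
                donor=str(donor),
                endpoint=str(endpoint),
                day=int(day),
                doses=tuple(float(d) for d in doses),
                values=values,
            )
        )
    return out


def write_series(series: Iterable[DoseResponseSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for dose, reps in zip(s.doses, s.values):
            for i, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "drug": s.drug,
                        "donor": s.donor,
                        "endpoint": s.endpoint,
                        "day": s.day,
                        "dose_multiple": dose,
                        "replicate": i,
                        "value": v,
                    }
                )
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def table1_panel_path() -> Path:
    """Path of the bundled 27-drug benchmark panel fixture."""
    return Path(str(resources.files("chipdili").joinpath("data/table1_panel.csv")))


def table4_mos_path() -> Path:
    """Path of the bundled published MOS table fixture."""
    return Path(str(resources.files("chipdili").joinpath("data/table4_mos.csv")))


# ---------------------------------------------------------------------------
# exposure arithmetic and QC
# ---------------------------------------------------------------------------


def unbound_cmax(drug: DrugRecord) -> float:
    """Unbound plasma C_max in ng/mL: ``cmax_total * fu_plasma``."""
    if drug.cmax_total is None or drug.fu_plasma is None:
        raise ValidationError(f"{drug.name}: cmax_total and fu_plasma are required")
    return drug.cmax_total * drug.fu_plasma


def fu_media_from_plasma(
    fu_plasma: float, protein_ratio: float = DEFAULT_MEDIA_PROTEIN_RATIO
) -> float:
    """Extrapolate the unbound fraction in culture medium from plasma binding.

    Protein-dilution scaling: binding sites scale with protein content, so
    ``fu_media = 1 / (1 + R * (1 - fu_plasma) / fu_plasma)`` with ``R`` the
    medium-to-plasma protein-content ratio (default 0.02 for 2% FBS medium).
    Measured per-drug values should be preferred when available.
    """
    if not (0 < fu_plasma <= 1):
        raise ValidationError(f"fu_plasma must be in (0, 1], got {fu_plasma}")
    if protein_ratio < 0:
        raise ValidationError("protein_ratio must be >= 0")
    return 1.0 / (1.0 + protein_ratio * (1.0 - fu_plasma) / fu_plasma)


def with_media_fraction(
    drug: DrugRecord, protein_ratio: float = DEFAULT_MEDIA_PROTEIN_RATIO
) -> DrugRecord:
    """Fill ``fu_media`` by extrapolation when absent; explicit values win."""
    if drug.fu_media is not None:
        return drug
    if drug.fu_plasma is None:
        raise ValidationError(f"{drug.name}: fu_plasma needed to extrapolate fu_media")
    return replace(drug, fu_media=fu_media_from_plasma(drug.fu_plasma, protein_ratio))


def production_rate(
    effluent_conc: float,
    flow: float,
    hepatocyte_count: float,
    *,
    analyte: str = "albumin",
    donor: str = "d1",
    day: int = 1,
    allowed_flows: Sequence[float] | None = DEFAULT_FLOW_RATES,
) -> ProductionRate:
    """Convert effluent concentration to ug per 1e6 hepatocytes per day.

    ``effluent_conc`` in ug/mL, ``flow`` in uL/h, ``hepatocyte_count`` in cells:
    ``rate = conc * flow * 24 / 1000 / (count / 1e6)``.
    """
    if hepatocyte_count <= 0:
        raise ValidationError("hepatocyte_count must be > 0")
    if effluent_conc < 0:
        raise ValidationError("effluent concentration must be >= 0")
    if allowed_flows is not None and flow not in allowed_flows:
        raise ValidationError(f"flow {flow} uL/h not in allowed set {tuple(allowed_flows)}")
    rate = effluent_conc * flow * 24.0 / 1000.0 / (hepatocyte_count / 1e6)
    return ProductionRate(analyte=analyte, donor=donor, day=day, rate=rate)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample (n-1) standard deviation divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("coefficient of variation needs n >= 2")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return float(arr.std(ddof=1) / mean)
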