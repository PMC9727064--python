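"""Margin-of-safety (MOS)-like scoring with censoring semantics.

A drug's minimum toxic concentration (in multiples of unbound C_max) is the
lowest level flagged by any primary endpoint; donors are combined by taking
the minimum over observed values, or the widest censored bound when nothing
was observed. Two bases are supported:

* uncorrected - free assay concentration over TOTAL plasma C_max
  (``multiple * fu_plasma``), the published convention for hepatic spheroids;
* corrected  - free assay concentration over UNBOUND plasma C_max
  (the multiple itself), which accounts for protein binding.

For every drug ``corrected = uncorrected / fu_plasma`` with identical bound
flags. A censored value renders as ">x": no toxicity observed up to x.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dose_response import EndpointCall
from .panel_io import DrugRecord, ValidationError, _read_csv, table4_mos_path

__all__ = [
    "MOSValue",
    "parse_mos",
    "format_mos",
    "min_toxic_multiple",
    "combine_donors",
    "mos_uncorrected",
    "mos_corrected",
    "load_mos_table",
    "mos_table_to_frame",
]

SCOPES = ("donor1", "donor2", "donor3", "combined", "spheroid")
BASES = ("uncorrected", "corrected")


@dataclass(frozen=True)
class MOSValue:
    """A margin-of-safety number or a censored lower bound.

    ``is_bound`` True renders as ">value": no toxicity observed at any tested
    concentration, with ``value`` the largest multiple tested. Values of 0 are
    admitted for observed entries (toxicity at every tested dose).
    """

    drug: str
    donor_scope: str
    value: float
    is_bound: bool
    basis: str

    def __post_init__(self) -> None:
        if self.donor_scope not in SCOPES:
            raise ValidationError(f"unknown donor scope {self.donor_scope!r}")
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.value < 0 or (self.is_bound and not self.value > 0):
            raise ValidationError(f"{self.drug}: invalid MOS value {self.value}")


def parse_mos(text: str, *, drug: str, donor_scope: str, basis: str = "uncorrected") -> MOSValue:
    """Parse a printed MOS cell such as ``1.8`` or ``>33.7``."""
    s = str(text).strip().replace(" ", "").replace(",", "")
    bound = s.startswith(">")
    return MOSValue(
        drug=drug, donor_scope=donor_scope,
        value=float(s[1:] if bound else s), is_bound=bound, basis=basis,
    )


def format_mos(mos: MOSValue, sig: int = 3) -> str:
    """Report-layer rendering at <= ``sig`` significant figures (">x" bounds)."""
    v = float(f"{mos.value:.{sig}g}")
    text = f"{v:g}"
    return f">{text}" if mos.is_bound else text


def min_toxic_multiple(calls: Sequence[EndpointCall]) -> tuple[float, bool]:
    """Lowest concentration flagged by any endpoint for one drug/donor.

    Observed calls dominate censored bounds; if every endpoint is a bound the
    result is the largest bound (the widest interval with no finding), still
    censored.
    """
    if not calls:
        raise ValidationError("need at least one endpoint call")
    observed = [c.min_toxic_multiple for c in calls if not c.is_bound]
    if observed:
        return min(observed), False
    return max(c.min_toxic_multiple for c in calls), True


def combine_donors(per_donor: Sequence[MOSValue]) -> MOSValue:
    """Combine per-donor MOS values: minimum observed, else maximum bound.

    All inputs must share a basis; the result is scope ``combined`` and is
    invariant to donor ordering.
    """
    if not per_donor:
        raise ValidationError("need at least one donor value")
    bases = {m.basis for m in per_donor}
    if len(bases) > 1:
        raise ValidationError(f"mixed bases {sorted(bases)} cannot be combined")
    drug = per_donor[0].drug
    observed = [m for m in per_donor if not m.is_bound]
    if observed:
        best = min(observed, key=lambda m: m.value)
        return replace(best, donor_scope="combined")
    best = max(per_donor, key=lambda m: m.value)
    return replace(best, donor_scope="combined", drug=drug)


def _require_fu(drug: DrugRecord) -> float:
    if drug.fu_plasma is None:
        raise ValidationError(f"{drug.name}: fu_plasma required for MOS scoring")
    if drug.fu_plasma == 0:
        raise ValidationError(f"{drug.name}: fu_plasma must be nonzero")
    return drug.fu_plasma


def mos_uncorrected(
    drug: DrugRecord, min_toxic: float, is_bound: bool, donor_scope: str = "donor1"
) -> MOSValue:
    """Free assay concentration over total plasma C_max.

    With the minimum toxic level expressed as a multiple m of unbound C_max,
    the free assay concentration is ``m * cmax_total * fu_plasma`` and the
    uncorrected MOS is ``m * fu_plasma``.
    """
    fu = _require_fu(drug)
    return MOSValue(
        drug=drug.name, donor_scope=donor_scope,
        value=min_toxic * fu, is_bound=is_bound, basis="uncorrected",
    )


def mos_corrected(
    drug: DrugRecord, min_toxic: float, is_bound: bool, donor_scope: str = "donor1"
) -> MOSValue:
    """Free assay concentration over unbound plasma C_max (protein-binding
    corrected); equals ``mos_uncorrected / fu_plasma`` exactly."""
    _require_fu(drug)
    return MOSValue(
        drug=drug.name, donor_scope=donor_scope,
        value=float(min_toxic), is_bound=is_bound, basis="corrected",
    )


_TABLE_SCOPES = {
    "mos_donor1": "donor1",
    "mos_donor2": "donor2",
    "mos_both": "combined",
    "mos_spheroid": "spheroid",
}


def load_mos_table(
    path: str | Path | None = None, basis: str = "uncorrected"
) -> dict[str, dict[str, MOSValue]]:
    """Read a published-format MOS table (the bundled fixture by default).

    Returns ``{drug: {scope: MOSValue}}`` with scopes among donor1, donor2,
    combined, spheroid; empty cells (drug not tested) are omitted.
    """
    path = table4_mos_path() if path is None else path
    df = _read_csv(path, ["drug", "mos_donor1"])
    out: dict[str, dict[str, MOSValue]] = {}
    for _, row in df.iterrows():
        drug = str(row["drug"]).strip()
        cells: dict[str, MOSValue] = {}
        for col, scope in _TABLE_SCOPES.items():
            raw = row.get(col)
            if isinstance(raw, str) and raw.strip():
                cells[scope] = parse_mos(raw, drug=drug, donor_scope=scope, basis=basis)
        out[drug] = cells
    return out


def mos_table_to_frame(table: Iterable[MOSValue]) -> pd.DataFrame:
    """Long-format report frame with columns drug, scope, basis, mos, bound."""
    return pd.DataFrame(
        [
            {
                "drug": m.drug,
                "scope": m.donor_scope,
                "basis": m.basis,
                "mos": m.value,
                "bound": m.is_bound,
            }
            for m in table
        ],
        columns=["drug", "scope", "basis", "mos", "bound"],
    )
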