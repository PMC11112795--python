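"""Demethylation (5-azacytidine) response on MassArray-style CpG-unit panels.

A panel row holds one CpG unit's methylation fraction in untreated tumor
cells, after demethylating treatment, and optionally in a normal-cell
reference.  The headline readout is the relative decrease

    (level_untreated - level_treated) / level_untreated * 100  [percent]

and the unit on which it is maximal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._utils import round_half_away
from .errors import ParameterError, UndefinedRatioError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["unit_id", "level_untreated", "level_treated", "level_reference"]


@dataclass
class DemethPanel:
    """Rows of per-CpG-unit methylation fractions; unit ids unique."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        if "level_reference" not in df.columns:
            df["level_reference"] = None
        df = pd.DataFrame(df, columns=PANEL_COLUMNS)
        if len(df):
            if df["unit_id"].duplicated().any():
                raise ParameterError("duplicate unit_id in panel")
            for col in ("level_untreated", "level_treated"):
                v = df[col].astype(float)
                if ((v < 0) | (v > 1)).any():
                    raise ParameterError(f"{col} outside [0, 1]")
            ref = df["level_reference"].dropna().astype(float)
            if ((ref < 0) | (ref > 1)).any():
                raise ParameterError("level_reference outside [0, 1]")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.rows["unit_id"]]


@dataclass(frozen=True)
class ResponseRecord:
    """One unit's treatment response.

    ``rel_decrease`` is in percent and sign-preserving: negative means the
    unit gained methylation under treatment.
    """

    unit_id: str
    abs_delta: float
    rel_decrease: float


def relative_decrease(before: float, after: float) -> float:
    """Relative methylation decrease in percent: (before - after)/before*100.

    Unrounded; report writers round to 1 decimal.  ``before`` must be > 0.
    """
    for name, x in (("before", before), ("after", after)):
        if not 0.0 <= x <= 1.0:
            raise ParameterError(f"{name} level must be in [0, 1], got {x}")
    if before == 0:
        raise UndefinedRatioError("relative decrease undefined at before = 0")
    return (before - after) / before * 100.0


def panel_response(
    panel: DemethPanel, loci_subset: list[str] | None = None
) -> tuple[list[ResponseRecord], ResponseRecord | None]:
    """Per-unit responses and the unit of maximal relative decrease.

    ``loci_subset`` restricts the computation to named units (it must be a
    subset of the panel).  Units with an untreated level of 0 are excluded
    and logged.  The argmax breaks ties lexicographically by unit id; it is
    None for an empty selection.
    """
    units = panel.unit_ids
    if loci_subset is not None:
        unknown = set(loci_subset) - set(units)
        if unknown:
            raise ParameterError(f"units not in panel: {sorted(unknown)}")
        chosen = [u for u in units if u in set(loci_subset)]
    else:
        chosen = units
    records = []
    df = panel.rows.set_index("unit_id")
    for unit in chosen:
        before = float(df.loc[unit, "level_untreated"])
        after = float(df.loc[unit, "level_treated"])
        if before == 0:
            logger.info("unit %s has untreated level 0; excluded", unit)
            continue
        records.append(
            ResponseRecord(unit, before - after, relative_decrease(before, after))
        )
    if not records:
        return [], None
    best = min(records, key=lambda r: (-r.rel_decrease, r.unit_id))
    return records, best


# ---------------------------------------------------------------------------
# I/O


def read_panel(path) -> DemethPanel:
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    return DemethPanel(df)


def write_panel(panel: DemethPanel, path) -> None:
    panel.rows.to_csv(path, sep="\t", index=False)


def write_response(records: list[ResponseRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "abs_delta": round_half_away(r.abs_delta, 3),
                "rel_decrease_pct": round_half_away(r.rel_decrease, 1),
            }
            for r in records
        ],
        columns=["unit_id", "abs_delta", "rel_decrease_pct"],
    ).to_csv(path, sep="\t", index=False)
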