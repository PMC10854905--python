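"""Optic-nerve subarachnoid-space width and trans-lamina cribrosa pressure.

The subarachnoid space around the orbital optic nerve is a non-invasive
MRI surrogate for retrobulbar cerebrospinal fluid pressure (CSFP).  On
oblique-coronal T2 sections taken 3, 9 and 15 mm behind the globe, the
optic nerve diameter (OND) and optic nerve sheath diameter (ONSD) are
each measured horizontally and vertically; the space width is

    ONSASW = ONSD/2 - OND/2

with the two axes averaged.  The trans-lamina cribrosa pressure
difference is TLCPD = IOP - CSFP (mmHg); CSFP must be supplied — no
estimation formula is applied.

All lengths are millimetres, pressures mmHg; no unit inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ONSASMeasurement",
    "PressureInputs",
    "compute_onsasw",
    "compute_tlcpd",
    "load_mri_measurements",
    "VALID_DISTANCES_MM",
    "MRI_CSV_COLUMNS",
]

log = logging.getLogger(__name__)

VALID_DISTANCES_MM = (3.0, 9.0, 15.0)

MRI_CSV_COLUMNS = [
    "subject_id",
    "eye",
    "distance_mm",
    "ond_h_mm",
    "ond_v_mm",
    "onsd_h_mm",
    "onsd_v_mm",
]


@dataclass(frozen=True)
class ONSASMeasurement:
    """One optic-nerve/sheath measurement at a retrobulbar station."""

    subject_id: str
    eye: str  # OD | OS
    distance_mm: float
    ond_h_mm: float
    ond_v_mm: float
    onsd_h_mm: float
    onsd_v_mm: float

    def validate(self) -> None:
        if self.distance_mm not in VALID_DISTANCES_MM:
            raise ValueError(
                f"distance_mm must be one of {VALID_DISTANCES_MM} "
                f"(retrobulbar measurement stations), got {self.distance_mm}"
            )
        for axis in ("h", "v"):
            ond = getattr(self, f"ond_{axis}_mm")
            onsd = getattr(self, f"onsd_{axis}_mm")
            if ond < 0 or onsd < 0:
                raise ValueError(f"negative diameter on axis {axis}")
            if onsd < ond:
                raise ValueError(
                    f"sheath narrower than nerve on axis {axis}: "
                    f"ONSD {onsd} < OND {ond}"
                )


@dataclass(frozen=True)
class PressureInputs:
    iop_mmhg: float
    csfp_mmhg: float

    def validate(self) -> None:
        if self.iop_mmhg < 0 or self.csfp_mmhg < 0:
            raise ValueError("pressures must be non-negative")


def compute_onsasw(m: ONSASMeasurement) -> float:
    """Subarachnoid-space width: half-ONSD minus half-OND, axes averaged.

    By linearity this equals the mean of the per-axis half-differences, so
    it does not matter whether axes are averaged before or after the
    subtraction.
    """
    m.validate()
    ond = 0.5 * (m.ond_h_mm + m.ond_v_mm)
    onsd = 0.5 * (m.onsd_h_mm + m.onsd_v_mm)
    return (onsd - ond) / 2.0


def compute_tlcpd(p: PressureInputs) -> float:
    """Trans-lamina cribrosa pressure difference, IOP - CSFP (mmHg).

    May be negative (CSFP exceeding IOP); callers should surface the sign.
    """
    p.validate()
    return p.iop_mmhg - p.csfp_mmhg


def load_mri_measurements(path) -> list[ONSASMeasurement]:
    """Read validated ONSAS measurements from a CSV file.

    Expects the columns in :data:`MRI_CSV_COLUMNS`.  Rows violating an
    invariant raise with the offending row number; an empty file returns
    an empty list with a logged warning.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        log.warning("MRI measurement file %s is empty", path)
        return []
    missing = [c for c in MRI_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    out = []
    for i, row in df.iterrows():
        try:
            numeric = {c: float(row[c]) for c in MRI_CSV_COLUMNS[2:]}
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i + 1}: non-numeric cell ({exc})") from exc
        m = ONSASMeasurement(
            subject_id=str(row["subject_id"]),
            eye=str(row["eye"]),
            distance_mm=numeric["distance_mm"],
            ond_h_mm=numeric["ond_h_mm"],
            ond_v_mm=numeric["ond_v_mm"],
            onsd_h_mm=numeric["onsd_h_mm"],
            onsd_v_mm=numeric["onsd_v_mm"],
        )
        try:
            m.validate()
        except ValueError as exc:
            raise ValueError(f"row {i + 1}: {exc}") from exc
        out.append(m)
    return out


def onsasw_table(measurements: list[ONSASMeasurement]) -> pd.DataFrame:
    """Tabulate ONSASW per subject/eye/station."""
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "eye": m.eye,
                "distance_mm": m.distance_mm,
                "onsasw_mm": compute_onsasw(m),
            }
            for m in measurements
        ],
        columns=["subject_id", "eye", "distance_mm", "onsasw_mm"],
    )
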