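"""Suspect library model, retention-index calibration and threshold sets.

A suspect library row carries the compound identity (CAS / InChIKey /
formula), a reference retention time and a reference collision cross
section, each tagged with its provenance. Provenance matters because the
matching thresholds are calibrated per source: literature CCS values are
reproducible to about +/-2% across instruments, whereas machine-learned CCS
predictions for halogenated hydrophobic contaminants carry a systematic
bias and a much wider spread, so they get wider bands. Likewise, retention
times converted from literature retention indices are tighter than
predicted ones.

Retention indices normalise elution position to a homologous reference
series. Because alkanes evade APCI ionisation, the library uses the Fiehn
scale (fatty acid methyl ester references); Kovats indices from n-alkane
based libraries are first mapped onto the Fiehn scale with a linear fit
over compounds indexed on both scales, then converted to retention time by
piecewise-linear interpolation over a user-supplied anchor table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    AdductKind,
    FormulaError,
    MolecularFormula,
    adduct_mz,
    parse_formula,
)

__all__ = [
    "CalibrationError",
    "LibraryFormatError",
    "DegenerateCalibrationWarning",
    "RT_SOURCES",
    "CCS_SOURCES",
    "SuspectEntry",
    "RICalibration",
    "KovatsFiehnMap",
    "ThresholdSet",
    "kovats_to_fiehn",
    "ri_to_rt",
    "calibrate_rt_thresholds",
    "default_thresholds",
    "read_suspect_library",
    "write_suspect_library",
]

logger = logging.getLogger(__name__)

RT_SOURCES = ("measured", "literature_converted", "predicted")
CCS_SOURCES = ("literature", "predicted")

#: Columns of the delimited-text suspect library interchange format.
LIBRARY_COLUMNS = (
    "suspect_id", "cas", "inchikey", "formula", "rt_minutes",
    "ri_kovats", "ri_fiehn", "rt_source", "ccs_a2", "ccs_source",
)


class CalibrationError(ValueError):
    """Raised for unusable retention-index calibration data."""


class LibraryFormatError(ValueError):
    """Raised when a library file is missing mandatory structure."""


class DegenerateCalibrationWarning(UserWarning):
    """Emitted when calibrated thresholds collapse to a point (zero spread)."""


@dataclass
class SuspectEntry:
    """One suspect-library compound with sourced RT/CCS reference values."""

    suspect_id: str
    formula: MolecularFormula
    adducts: list[tuple[AdductKind, float]]
    rt_reference: float
    rt_source: str
    ccs_reference: float
    ccs_source: str
    cas: str | None = None
    inchikey: str | None = None

    def __post_init__(self) -> None:
        if not self.adducts:
            raise ValueError(f"suspect {self.suspect_id}: at least one adduct required")
        for kind, mz in self.adducts:
            expected = adduct_mz(self.formula, kind)
            if abs(mz - expected) > 1e-4:
                raise ValueError(
                    f"suspect {self.suspect_id}: {kind.value} m/z {mz:.5f} inconsistent "
                    f"with formula ({expected:.5f})"
                )
        if self.rt_reference <= 0:
            raise ValueError(f"suspect {self.suspect_id}: rt_reference must be > 0")
        if self.ccs_reference <= 0:
            raise ValueError(f"suspect {self.suspect_id}: ccs_reference must be > 0")
        if self.rt_source not in RT_SOURCES:
            raise ValueError(f"suspect {self.suspect_id}: unknown rt_source {self.rt_source!r}")
        if self.ccs_source not in CCS_SOURCES:
            raise ValueError(f"suspect {self.suspect_id}: unknown ccs_source {self.ccs_source!r}")


def make_suspect_entry(
    suspect_id: str,
    formula: MolecularFormula | str,
    rt_reference: float,
    rt_source: str,
    ccs_reference: float,
    ccs_source: str,
    adduct_kinds: Sequence[AdductKind] = (AdductKind.RADICAL_CATION, AdductKind.PROTONATED),
    cas: str | None = None,
    inchikey: str | None = None,
) -> SuspectEntry:
    """Convenience constructor that computes theoretical adduct m/z values."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    adducts = [(kind, adduct_mz(formula, kind)) for kind in adduct_kinds]
    return SuspectEntry(
        suspect_id=suspect_id, formula=formula, adducts=adducts,
        rt_reference=rt_reference, rt_source=rt_source,
        ccs_reference=ccs_reference, ccs_source=ccs_source,
        cas=cas, inchikey=inchikey,
    )


@dataclass(frozen=True)
class RICalibration:
    """Anchor table mapping a retention-index scale to retention time.

    Anchors must be strictly increasing in both coordinates; retention-index
    to retention-time conversion interpolates linearly between bracketing
    anchors and extrapolates from the terminal segment outside the range.
    """

    anchors: tuple[tuple[float, float], ...]
    index_scale: str = "fiehn"

    def __post_init__(self) -> None:
        if self.index_scale not in ("kovats", "fiehn"):
            raise CalibrationError(f"unknown index scale {self.index_scale!r}")
        if len(self.anchors) < 2:
            raise CalibrationError("at least 2 calibration anchors required")
        ris = [ri for ri, _ in self.anchors]
        rts = [rt for _, rt in self.anchors]
        if any(b <= a for a, b in zip(ris, ris[1:])) or any(b <= a for a, b in zip(rts, rts[1:])):
            raise CalibrationError("calibration anchors must be strictly increasing in RI and RT")


@dataclass(frozen=True)
class KovatsFiehnMap:
    """Linear map between the Kovats (n-alkane) and Fiehn (FAME) index scales.

    Both scales are near-affine functions of elution temperature over the
    relevant range, so a single least-squares line over compounds indexed on
    both scales is used rather than a segmented fit.
    """

    slope: float
    intercept: float

    @classmethod
    def fit(cls, pairs: Iterable[tuple[float, float]]) -> "KovatsFiehnMap":
        """Least-squares fit from (kovats, fiehn) pairs of shared compounds."""
        pairs = list(pairs)
        if len(pairs) < 2:
            raise CalibrationError("at least 2 shared (kovats, fiehn) pairs required")
        x = np.asarray([p[0] for p in pairs], dtype=float)
        y = np.asarray([p[1] for p in pairs], dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        return cls(slope=float(slope), intercept=float(intercept))

    def apply(self, ri_kovats: float) -> float:
        return self.slope * ri_kovats + self.intercept

    def inverse(self) -> "KovatsFiehnMap":
        if self.slope == 0:
            raise CalibrationError("degenerate map cannot be inverted")
        return KovatsFiehnMap(slope=1.0 / self.slope, intercept=-self.intercept / self.slope)


def kovats_to_fiehn(ri_kovats: float, mapping: KovatsFiehnMap) -> float:
    """Convert a Kovats retention index to the Fiehn scale."""
    return mapping.apply(ri_kovats)


def ri_to_rt(ri: float, cal: RICalibration) -> tuple[float, bool]:
    """Convert a Fiehn retention index to retention time in minutes.

    Returns ``(rt_minutes, extrapolated)``; the flag is True when *ri* lies
    outside the anchor range and the terminal segment was extended linearly.
    """
    if cal.index_scale != "fiehn":
        raise CalibrationError("ri_to_rt requires a Fiehn-scale calibration")
    ris = np.asarray([a[0] for a in cal.anchors], dtype=float)
    rts = np.asarray([a[1] for a in cal.anchors], dtype=float)
    extrapolated = bool(ri < ris[0] or ri > ris[-1])
    if extrapolated:
        if ri < ris[0]:
            i0, i1 = 0, 1
        else:
            i0, i1 = -2, -1
        slope = (rts[i1] - rts[i0]) / (ris[i1] - ris[i0])
        return float(rts[i0] + slope * (ri - ris[i0])), True
    return float(np.interp(ri, ris, rts)), False


def calibrate_rt_thresholds(
    deltas: Sequence[float],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Calibrate RT matching intervals from observed measured-minus-reference residuals.

    Returns ``(high, low)`` intervals where high = [mu - sd, mu + sd] and
    low = [mu - 2 sd, mu + 2 sd], using the sample mean and standard
    deviation of *deltas*. The intervals are deliberately asymmetric about
    zero: a systematic bias in the reference values (mu != 0) is preserved
    rather than symmetrised away.
    """
    values = np.asarray(list(deltas), dtype=float)
    if values.size < 3:
        raise CalibrationError("at least 3 residuals required to calibrate RT thresholds")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "all residuals identical; calibrated intervals collapse to a point",
            DegenerateCalibrationWarning,
            stacklevel=2,
        )
    high = (mu - sd, mu + sd)
    low = (mu - 2.0 * sd, mu + 2.0 * sd)
    return high, low


@dataclass(frozen=True)
class ThresholdSet:
    """High/low confidence matching thresholds per dimension and reference source.

    CCS thresholds are symmetric percentage bounds (CT_high, CT_low); RT
    thresholds are explicit (possibly asymmetric) minute intervals keyed by
    RT source, each a ``(high_interval, low_interval)`` pair with the high
    interval strictly inside the low one.
    """

    ccs_literature: tuple[float, float] = (2.0, 3.0)
    ccs_predicted: tuple[float, float] = (5.0, 7.0)
    rt_intervals: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, (high, low) in (("ccs_literature", self.ccs_literature),
                                  ("ccs_predicted", self.ccs_predicted)):
            if not 0 < high < low:
                raise ValueError(f"{name}: need 0 < CT_high < CT_low, got {high}, {low}")
        for source, (high, low) in self.rt_intervals.items():
            if not (low[0] < high[0] < high[1] < low[1]):
                raise ValueError(
                    f"rt_intervals[{source!r}]: high interval {high} must lie strictly "
                    f"inside low interval {low}"
                )

    def ccs_bounds(self, ccs_source: str) -> tuple[float, float]:
        if ccs_source == "literature":
            return self.ccs_literature
        if ccs_source == "predicted":
            return self.ccs_predicted
        raise KeyError(f"unknown ccs_source {ccs_source!r}")

    def rt_bounds(self, rt_source: str) -> tuple[tuple[float, float], tuple[float, float]]:
        try:
            return self.rt_intervals[rt_source]
        except KeyError:
            raise KeyError(f"no RT thresholds configured for rt_source {rt_source!r}") from None


# Calibration summaries of measured-minus-reference RT residuals (minutes):
# literature-converted references mu=0.15, sd=0.69 (n=36); model-predicted
# references mu=0.086, sd=1.13 (n=102).
_RT_LITERATURE_MU_SD = (0.15, 0.69)
_RT_PREDICTED_MU_SD = (0.086, 1.13)


def _mu_sd_intervals(mu: float, sd: float) -> tuple[tuple[float, float], tuple[float, float]]:
    return (mu - sd, mu + sd), (mu - 2 * sd, mu + 2 * sd)


def default_thresholds() -> ThresholdSet:
    """Threshold set calibrated for this workflow's reference sources.

    CCS: +/-2% / +/-3% against literature values (interlaboratory
    reproducibility), +/-5% / +/-7% against model predictions (kept just
    inside the observed isomer CCS spread to avoid isomer-level
    misidentification). RT: mean +/- SD and mean +/- 2 SD of the
    per-source residual distributions; retention times measured in-house
    share the literature-converted intervals.
    """
    lit = _mu_sd_intervals(*_RT_LITERATURE_MU_SD)
    pred = _mu_sd_intervals(*_RT_PREDICTED_MU_SD)
    return ThresholdSet(
        ccs_literature=(2.0, 3.0),
        ccs_predicted=(5.0, 7.0),
        rt_intervals={
            "measured": lit,
            "literature_converted": lit,
            "predicted": pred,
        },
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python", dtype=str,
                           skip_blank_lines=True)
    return pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)


def _cell(row: pd.Series, column: str) -> str | None:
    value = row.get(column)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value).strip()
    return value or None


def read_suspect_library(
    path,
    ri_cal: RICalibration | None = None,
    kovats_map: KovatsFiehnMap | None = None,
    sep: str | None = None,
) -> list[SuspectEntry]:
    """Read a delimited-text suspect library into validated entries.

    Mandatory columns: ``suspect_id``, ``formula``, ``ccs_a2``,
    ``ccs_source`` and at least one of ``rt_minutes`` / ``ri_fiehn`` /
    ``ri_kovats``. Retention-index columns are converted to RT via *ri_cal*
    (and *kovats_map* for the Kovats scale) when ``rt_minutes`` is absent,
    in which case ``rt_source`` becomes ``literature_converted``. Rows that
    fail validation are logged with the row number and skipped; duplicate
    InChIKeys keep the first occurrence.
    """
    frame = _read_table(path, sep)
    mandatory = {"suspect_id", "formula", "ccs_a2", "ccs_source"}
    missing = mandatory - set(frame.columns)
    if missing:
        raise LibraryFormatError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    rt_columns = {"rt_minutes", "ri_kovats", "ri_fiehn"} & set(frame.columns)
    if not rt_columns:
        raise LibraryFormatError(
            "missing mandatory column(s): one of rt_minutes, ri_kovats, ri_fiehn"
        )

    entries: list[SuspectEntry] = []
    seen_inchikeys: set[str] = set()
    for index, row in frame.iterrows():
        row_no = index + 2  # header is line 1
        try:
            entry = _parse_library_row(row, ri_cal, kovats_map)
        except (FormulaError, CalibrationError, ValueError) as exc:
            logger.warning("library row %d skipped: %s", row_no, exc)
            continue
        if entry.inchikey and entry.inchikey in seen_inchikeys:
            logger.warning(
                "library row %d: duplicate InChIKey %s; keeping first occurrence",
                row_no, entry.inchikey,
            )
            continue
        if entry.inchikey:
            seen_inchikeys.add(entry.inchikey)
        entries.append(entry)
    return entries


def _parse_library_row(
    row: pd.Series,
    ri_cal: RICalibration | None,
    kovats_map: KovatsFiehnMap | None,
) -> SuspectEntry:
    suspect_id = _cell(row, "suspect_id")
    formula_text = _cell(row, "formula")
    if not suspect_id or not formula_text:
        raise ValueError("suspect_id and formula must be non-empty")
    formula = parse_formula(formula_text)

    rt_minutes = _cell(row, "rt_minutes")
    rt_source = _cell(row, "rt_source")
    if rt_minutes is not None:
        rt_reference = float(rt_minutes)
        rt_source = rt_source or "measured"
    else:
        ri_fiehn = _cell(row, "ri_fiehn")
        ri_kovats = _cell(row, "ri_kovats")
        if ri_fiehn is None and ri_kovats is not None:
            if kovats_map is None:
                raise CalibrationError("ri_kovats given but no Kovats->Fiehn map supplied")
            ri_fiehn = kovats_to_fiehn(float(ri_kovats), kovats_map)
        if ri_fiehn is None:
            raise ValueError("no retention information (rt_minutes / ri_fiehn / ri_kovats)")
        if ri_cal is None:
            raise CalibrationError("retention index given but no RI calibration supplied")
        rt_reference, _ = ri_to_rt(float(ri_fiehn), ri_cal)
        rt_source = rt_source or "literature_converted"

    ccs_reference = float(_cell(row, "ccs_a2"))
    ccs_source = _cell(row, "ccs_source")
    return make_suspect_entry(
        suspect_id=suspect_id,
        formula=formula,
        rt_reference=rt_reference,
        rt_source=rt_source,
        ccs_reference=ccs_reference,
        ccs_source=ccs_source,
        cas=_cell(row, "cas"),
        inchikey=_cell(row, "inchikey"),
    )


def write_suspect_library(entries: Sequence[SuspectEntry], path, sep: str = ",") -> None:
    """Write entries in the interchange format read by :func:`read_suspect_library`."""
    rows = [
        {
            "suspect_id": e.suspect_id,
            "cas": e.cas or "",
            "inchikey": e.inchikey or "",
            "formula": e.formula.hill_notation(),
            "rt_minutes": repr(float(e.rt_reference)),
            "ri_kovats": "",
            "ri_fiehn": "",
            "rt_source": e.rt_source,
            "ccs_a2": repr(float(e.ccs_reference)),
            "ccs_source": e.ccs_source,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS)).to_csv(path, sep=sep, index=False)
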