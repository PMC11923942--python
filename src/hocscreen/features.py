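"""Measured-feature data model and text I/O.

Covers the downstream half of the data flow: deconvoluted feature tables
(one row per aligned peak with m/z, RT, CCS, intensity, isotope envelope
and optional fragment list), NIST MSP spectral records, the block-text
input files consumed by an external fragmentation scorer, and the
similarity-score tables that scorer produces.

Fragmentation-spectrum similarity is an external dependency by design:
this package exports per-candidate scorer inputs and imports the resulting
scores, but never invokes or reimplements the scorer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import AdductKind
from .library import SuspectEntry

__all__ = [
    "FeatureFormatError",
    "MspFormatError",
    "ExportError",
    "MeasuredFeature",
    "MS2Score",
    "MspRecord",
    "read_feature_table",
    "write_feature_table",
    "read_msp",
    "write_msp",
    "export_fragmentation_input",
    "read_ms2_scores",
    "write_ms2_scores",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "feature_id", "mz", "rt_minutes", "ccs_a2", "intensity",
    "isotope_envelope", "ms2_fragments",
)


class FeatureFormatError(ValueError):
    """Raised when a feature or score table is structurally unusable."""


class MspFormatError(ValueError):
    """Raised for malformed NIST MSP records."""


class ExportError(ValueError):
    """Raised when a fragmentation-scorer export cannot be produced."""


@dataclass
class MeasuredFeature:
    """One deconvoluted, aligned peak from the instrument pipeline.

    ``mz`` is the m/z of the most abundant isotopologue (the envelope base
    peak), matching the convention used for theoretical adduct masses.
    """

    feature_id: str
    mz: float
    rt_measured: float
    ccs_measured: float
    intensity: float
    isotope_envelope: list[tuple[float, float]] = field(default_factory=list)
    ms2_fragments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("mz", "rt_measured", "ccs_measured", "intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"feature {self.feature_id}: {name} must be > 0")
        if self.isotope_envelope and not any(
            abs(ri - 100.0) < 1e-6 for _, ri in self.isotope_envelope
        ):
            raise ValueError(
                f"feature {self.feature_id}: isotope envelope must contain the base peak at 100%"
            )


@dataclass(frozen=True)
class MS2Score:
    """Fragmentation-spectrum similarity between a feature and a suspect, in [0, 1]."""

    feature_id: str
    suspect_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"MS2 score for ({self.feature_id}, {self.suspect_id}) "
                f"outside [0, 1]: {self.score}"
            )


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def _encode_pairs(pairs: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{a!r}:{b!r}" for a, b in pairs)


def _decode_pairs(text: str | None) -> list[tuple[float, float]]:
    if text is None or not str(text).strip() or (isinstance(text, float) and np.isnan(text)):
        return []
    pairs = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        a, _, b = chunk.partition(":")
        pairs.append((float(a), float(b)))
    return pairs


def read_feature_table(path, sep: str | None = None) -> list[MeasuredFeature]:
    """Read a delimited feature table; invalid rows are logged and skipped.

    Isotope envelopes and fragment lists are encoded as semicolon-joined
    ``mz:intensity`` pairs; an empty cell means no envelope / no fragments.
    """
    try:
        if sep is None:
            frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            frame = pd.read_csv(path, sep=sep, dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        return []
    missing = {"feature_id", "mz", "rt_minutes", "ccs_a2", "intensity"} - set(frame.columns)
    if missing:
        raise FeatureFormatError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    features: list[MeasuredFeature] = []
    for index, row in frame.iterrows():
        row_no = index + 2
        try:
            features.append(
                MeasuredFeature(
                    feature_id=str(row["feature_id"]).strip(),
                    mz=float(row["mz"]),
                    rt_measured=float(row["rt_minutes"]),
                    ccs_measured=float(row["ccs_a2"]),
                    intensity=float(row["intensity"]),
                    isotope_envelope=_decode_pairs(row.get("isotope_envelope")),
                    ms2_fragments=_decode_pairs(row.get("ms2_fragments")),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("feature row %d skipped: %s", row_no, exc)
    return features


def write_feature_table(features: Sequence[MeasuredFeature], path, sep: str = ",") -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "mz": repr(float(f.mz)),
            "rt_minutes": repr(float(f.rt_measured)),
            "ccs_a2": repr(float(f.ccs_measured)),
            "intensity": repr(float(f.intensity)),
            "isotope_envelope": _encode_pairs(f.isotope_envelope),
            "ms2_fragments": _encode_pairs(f.ms2_fragments),
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# NIST MSP
# ---------------------------------------------------------------------------

@dataclass
class MspRecord:
    """One MSP spectral record: name, precursor m/z and the peak list.

    MSP has no single normative dialect; unknown header keys are preserved
    in ``metadata`` on read and re-emitted on write, but otherwise ignored.
    """

    name: str
    precursor_mz: float | None
    peaks: list[tuple[float, float]]
    metadata: dict[str, str] = field(default_factory=dict)


def read_msp(path) -> list[MspRecord]:
    """Parse NIST MSP records; ``Num Peaks`` must match the actual peak count."""
    records: list[MspRecord] = []
    name: str | None = None
    metadata: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    declared: int | None = None

    def flush() -> None:
        nonlocal name, metadata, peaks, declared
        if name is None and not metadata and not peaks:
            return
        if name is None:
            raise MspFormatError("MSP record without a Name header")
        if declared is not None and len(peaks) != declared:
            raise MspFormatError(
                f"record {name!r}: Num Peaks declares {declared} but {len(peaks)} parsed"
            )
        precursor = None
        for key in ("precursormz", "precursor_mz", "mw"):
            if key in metadata:
                precursor = float(metadata[key])
                break
        records.append(MspRecord(name=name, precursor_mz=precursor,
                                 peaks=list(peaks), metadata=dict(metadata)))
        name, metadata, peaks, declared = None, {}, [], None

    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key_norm = key.strip().lower().replace(" ", "")
                value = value.strip()
                if key_norm == "name":
                    if name is not None:
                        flush()
                    name = value
                elif key_norm == "numpeaks":
                    declared = int(value)
                else:
                    metadata[key_norm] = value
            else:
                parts = line.replace("\t", " ").split()
                if len(parts) < 2:
                    raise MspFormatError(f"record {name!r}: malformed peak line {line!r}")
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return records


def write_msp(records: Sequence[MspRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(f"Name: {record.name}\n")
            if record.precursor_mz is not None:
                handle.write(f"PrecursorMZ: {record.precursor_mz!r}\n")
            for key, value in record.metadata.items():
                if key in ("precursormz", "precursor_mz"):
                    continue
                handle.write(f"{key}: {value}\n")
            handle.write(f"Num Peaks: {len(record.peaks)}\n")
            for mz, intensity in record.peaks:
                handle.write(f"{mz!r} {intensity!r}\n")
            handle.write("\n")


# ---------------------------------------------------------------------------
# Fragmentation-scorer export / score import
# ---------------------------------------------------------------------------

def export_fragmentation_input(
    feature: MeasuredFeature,
    suspect: SuspectEntry,
    adduct: AdductKind,
    path,
) -> None:
    """Write one per-candidate input file for the external fragmentation scorer.

    The file is block-structured plain text declaring the candidate's
    compound name, formula, ionization, parent ion m/z and InChIKey,
    followed by the measured fragment peak list. Because the candidate is
    already known from the full-scan/RT/CCS match, declaring formula and
    adduct pins the scorer to that candidate rather than an open search.
    """
    if not feature.ms2_fragments:
        raise ExportError(
            f"feature {feature.feature_id}: no MS2 fragments; nothing to export"
        )
    lines = [
        f">compound {suspect.suspect_id}",
        f">formula {suspect.formula.hill_notation()}",
        f">ionization {adduct.sirius_ionization}",
        f">parentmass {feature.mz!r}",
    ]
    if suspect.inchikey:
        lines.append(f"#inchikey {suspect.inchikey}")
    lines.append(">ms2")
    for mz, intensity in feature.ms2_fragments:
        lines.append(f"{mz!r} {intensity!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ms2_scores(path, sep: str | None = None) -> list[MS2Score]:
    """Read (feature_id, suspect_id, score) rows; out-of-range scores are
    rejected (logged and skipped), never clamped."""
    try:
        if sep is None:
            frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            frame = pd.read_csv(path, sep=sep, dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        return []
    missing = {"feature_id", "suspect_id", "score"} - set(frame.columns)
    if missing:
        raise FeatureFormatError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    scores: list[MS2Score] = []
    for index, row in frame.iterrows():
        try:
            scores.append(
                MS2Score(
                    feature_id=str(row["feature_id"]).strip(),
                    suspect_id=str(row["suspect_id"]).strip(),
                    score=float(row["score"]),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("score row %d rejected: %s", index + 2, exc)
    return scores


def write_ms2_scores(scores: Sequence[MS2Score], path, sep: str = ",") -> None:
    rows = [
        {"feature_id": s.feature_id, "suspect_id": s.suspect_id, "score": repr(float(s.score))}
        for s in scores
    ]
    pd.DataFrame(rows, columns=["feature_id", "suspect_id", "score"]).to_csv(
        path, sep=sep, index=False
    )
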