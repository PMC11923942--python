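"""Multidimensional candidate gating, scoring, fusion and retention.

This is the core of the workflow. A (feature, suspect) pairing must first
survive two mandatory full-scan gates:

* exact mass: < 5 ppm for ions above 200 Da, < 2 mDa below (the two rules
  coincide at 200 Da, where the ppm rule -- the stricter of the two -- is
  applied);
* isotope pattern: at least one non-base isotopologue observed, and the
  geometric mean of the relative intensity deviations of matched
  isotopologues strictly below 5%.

Surviving candidates are scored continuously in the retention-time and
collision-cross-section dimensions. Each dimension has a high-confidence
threshold CT_high (deviations inside score 1) and a low-confidence
threshold CT_low (deviations outside score 0 and exclude the candidate);
between the two the score decays linearly toward the low boundary on the
same side as the deviation. The shape of the decay is pluggable via
``score_shape``.

Dimension scores are fused as a weighted sum

    S = W_RT * S_RT + W_CCS * S_CCS + W_MS2 * S_MS2

with defaults W = (0.2, 0.4, 0.4) -- retention time is down-weighted
because it depends on chromatographic conditions. A missing MS2 score
contributes 0 *without* renormalising the weights: with the default 0.60
cutoff this deliberately forces perfect RT and CCS agreement whenever
fragmentation evidence is unavailable. Finally only candidates at or above
the cutoff are retained, and per suspect only the highest-scoring retained
candidate survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem import AdductKind, IsotopePattern, isotope_pattern
from .features import MeasuredFeature, MS2Score
from .library import SuspectEntry, ThresholdSet, default_thresholds

__all__ = [
    "ConfigurationError",
    "ScoringConfig",
    "CandidateMatch",
    "StageCounts",
    "ScreeningResult",
    "MassGateResult",
    "IsotopeGateResult",
    "mass_gate",
    "isotope_gate",
    "delta_rt",
    "delta_ccs",
    "continuous_score",
    "fuse_scores",
    "screen",
    "rank_candidates",
    "write_results",
    "read_results",
    "write_summary",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for inconsistent scoring configuration."""


#: Shape of the score decay between CT_high (1) and CT_low (0); takes the
#: fractional position in [0, 1] from the high boundary toward the low
#: boundary and returns the score.
ScoreShape = Callable[[float], float]


def linear_decay(t: float) -> float:
    return 1.0 - t


@dataclass
class ScoringConfig:
    """All tunables of the screening workflow.

    Weights must sum to 1 and the cutoff lies in (0, 1]. The defaults
    reproduce the published operating point: weights (0.2, 0.4, 0.4),
    cutoff 0.60, 5 ppm / 2 mDa mass rule switching at 200 Da, 5% isotope
    deviation ceiling, at least one isotope ion, and at least two
    monoisotopic fragments before an MS2 score is considered estimable.
    """

    weights: tuple[float, float, float] = (0.2, 0.4, 0.4)
    cutoff: float = 0.60
    thresholds: ThresholdSet = field(default_factory=default_thresholds)
    mass_tol_ppm: float = 5.0
    mass_tol_mda: float = 2.0
    mass_rule_boundary: float = 200.0
    isotope_max_gm_deviation: float = 5.0
    min_isotope_ions: int = 1
    min_ms2_fragments_for_scoring: int = 2
    score_shape: ScoreShape = linear_decay

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1, got {self.weights}")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("weights must be non-negative")
        if not 0.0 < self.cutoff <= 1.0:
            raise ConfigurationError(f"cutoff must lie in (0, 1], got {self.cutoff}")
        for name in ("mass_tol_ppm", "mass_tol_mda", "mass_rule_boundary",
                     "isotope_max_gm_deviation"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.min_isotope_ions < 0 or self.min_ms2_fragments_for_scoring < 0:
            raise ConfigurationError("minimum counts must be >= 0")

    # -- round-trippable key-value representation -------------------------

    def to_dict(self) -> dict:
        t = self.thresholds
        return {
            "weights": {"rt": self.weights[0], "ccs": self.weights[1], "ms2": self.weights[2]},
            "cutoff": self.cutoff,
            "mass_tol_ppm": self.mass_tol_ppm,
            "mass_tol_mda": self.mass_tol_mda,
            "mass_rule_boundary": self.mass_rule_boundary,
            "isotope_max_gm_deviation": self.isotope_max_gm_deviation,
            "min_isotope_ions": self.min_isotope_ions,
            "min_ms2_fragments_for_scoring": self.min_ms2_fragments_for_scoring,
            "thresholds": {
                "ccs_literature": list(t.ccs_literature),
                "ccs_predicted": list(t.ccs_predicted),
                "rt_intervals": {
                    source: {"high": list(high), "low": list(low)}
                    for source, (high, low) in t.rt_intervals.items()
                },
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScoringConfig":
        data = dict(data)
        weights = data.pop("weights", None)
        kwargs: dict = {}
        if weights is not None:
            kwargs["weights"] = (float(weights["rt"]), float(weights["ccs"]),
                                 float(weights["ms2"]))
        thresholds = data.pop("thresholds", None)
        if thresholds is not None:
            kwargs["thresholds"] = ThresholdSet(
                ccs_literature=tuple(thresholds["ccs_literature"]),
                ccs_predicted=tuple(thresholds["ccs_predicted"]),
                rt_intervals={
                    source: (tuple(iv["high"]), tuple(iv["low"]))
                    for source, iv in thresholds.get("rt_intervals", {}).items()
                },
            )
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle))


class MassGateResult(NamedTuple):
    passed: bool
    error_ppm: float
    error_mda: float


class IsotopeGateResult(NamedTuple):
    passed: bool
    gm_deviation: float | None
    n_matched: int
    bypassed: bool


def mass_gate(feature_mz: float, theoretical_mz: float, cfg: ScoringConfig) -> MassGateResult:
    """Exact-mass gate with the ppm rule at/above the boundary, mDa below."""
    if feature_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be > 0")
    delta = feature_mz - theoretical_mz
    error_ppm = delta / theoretical_mz * 1e6
    error_mda = delta * 1e3
    if theoretical_mz >= cfg.mass_rule_boundary:
        passed = abs(error_ppm) < cfg.mass_tol_ppm
    else:
        passed = abs(error_mda) < cfg.mass_tol_mda
    return MassGateResult(passed, error_ppm, error_mda)


def _mz_tolerance(mz: float, cfg: ScoringConfig) -> float:
    if mz >= cfg.mass_rule_boundary:
        return mz * cfg.mass_tol_ppm * 1e-6
    return cfg.mass_tol_mda * 1e-3


def isotope_gate(
    envelope: Sequence[tuple[float, float]],
    theory: IsotopePattern,
    cfg: ScoringConfig,
) -> IsotopeGateResult:
    """Isotope-pattern gate on a measured envelope against a theoretical pattern.

    Every non-base theoretical isotopologue is paired with the nearest
    measured envelope peak within the active mass tolerance; at least
    ``min_isotope_ions`` non-base matches are required, and the geometric
    mean over matched isotopologues of
    ``|measured - theoretical| / theoretical * 100`` must be strictly below
    ``isotope_max_gm_deviation``. A single-peak theoretical pattern
    (monoisotopic compound) passes vacuously with the ``bypassed`` flag set.
    """
    if theory.is_single_peak:
        logger.debug("isotope gate bypassed: single-isotope compound")
        return IsotopeGateResult(True, None, 0, True)

    base_mz = theory.base_peak_mz
    theory_peaks = [(mz, ri) for mz, ri in theory.peaks if abs(ri - 100.0) > 1e-9]
    measured = [(mz, ri) for mz, ri in envelope if abs(ri - 100.0) > 1e-6 or
                abs(mz - base_mz) > _mz_tolerance(base_mz, cfg)]

    deviations: list[float] = []
    for theo_mz, theo_ri in theory_peaks:
        tol = _mz_tolerance(theo_mz, cfg)
        candidates = [(abs(m - theo_mz), m, ri) for m, ri in measured if abs(m - theo_mz) <= tol]
        if not candidates:
            continue
        _, _, meas_ri = min(candidates)
        deviations.append(abs(meas_ri - theo_ri) / theo_ri * 100.0)

    if len(deviations) < max(cfg.min_isotope_ions, 1):
        return IsotopeGateResult(False, None, len(deviations), False)
    # Geometric mean; exact-zero deviations are floored to keep the mean finite.
    gm = float(np.exp(np.mean(np.log(np.maximum(deviations, 1e-12)))))
    return IsotopeGateResult(gm < cfg.isotope_max_gm_deviation, gm, len(deviations), False)


def delta_rt(rt_measured: float, rt_reference: float) -> float:
    """Signed retention-time difference, measured minus reference, in minutes."""
    if rt_measured <= 0 or rt_reference <= 0:
        raise ValueError("retention times must be > 0")
    return rt_measured - rt_reference


def delta_ccs(ccs_measured: float, ccs_reference: float) -> float:
    """Relative collision-cross-section difference in percent of the reference."""
    if ccs_measured <= 0 or ccs_reference <= 0:
        raise ValueError("CCS values must be > 0")
    return (ccs_measured - ccs_reference) / ccs_reference * 100.0


Interval = tuple[float, float]


def _as_interval(bound: float | Interval) -> Interval:
    if isinstance(bound, (int, float)):
        if bound <= 0:
            raise ConfigurationError("a symmetric bound must be > 0")
        return (-float(bound), float(bound))
    lo, hi = bound
    if not lo < hi:
        raise ConfigurationError(f"interval {bound} must be increasing")
    return (float(lo), float(hi))


def continuous_score(
    delta: float,
    high: float | Interval,
    low: float | Interval,
    shape: ScoreShape = linear_decay,
) -> float:
    """Continuous 0..1 score of a deviation against high/low confidence thresholds.

    *high* and *low* are either symmetric percentage/minute bounds
    (``2`` means the interval [-2, 2]) or explicit asymmetric intervals.
    Deviations inside the high interval score exactly 1; at or beyond the
    low interval they score exactly 0 (the candidate is excluded); in
    between, *shape* maps the fractional position between the two
    boundaries on the deviation's side to a score (default: linear decay).
    """
    (h_lo, h_hi), (l_lo, l_hi) = _as_interval(high), _as_interval(low)
    if not (l_lo < h_lo and h_hi < l_hi):
        raise ConfigurationError(
            f"high interval ({h_lo}, {h_hi}) must lie strictly inside low ({l_lo}, {l_hi})"
        )
    if h_lo <= delta <= h_hi:
        return 1.0
    if delta >= l_hi or delta <= l_lo:
        return 0.0
    if delta > h_hi:
        t = (delta - h_hi) / (l_hi - h_hi)
    else:
        t = (h_lo - delta) / (h_lo - l_lo)
    return float(min(1.0, max(0.0, shape(t))))


def fuse_scores(
    score_rt: float,
    score_ccs: float,
    score_ms2: float | None,
    cfg: ScoringConfig,
) -> float:
    """Weighted multidimensional score; an absent MS2 score contributes 0.

    Weights are intentionally not renormalised when MS2 is missing: with
    the default weights and cutoff, a candidate lacking fragmentation
    evidence is retained only on perfect RT and CCS agreement.
    """
    for name, s in (("score_rt", score_rt), ("score_ccs", score_ccs), ("score_ms2", score_ms2)):
        if s is not None and not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {s}")
    w_rt, w_ccs, w_ms2 = cfg.weights
    return w_rt * score_rt + w_ccs * score_ccs + w_ms2 * (score_ms2 or 0.0)


@dataclass
class CandidateMatch:
    """One (feature, suspect) pairing that survived the full-scan gates."""

    feature_id: str
    suspect_id: str
    matched_adduct: AdductKind
    mass_error_ppm: float
    mass_error_mda: float
    isotope_gm_deviation: float | None
    isotope_bypassed: bool
    delta_rt: float
    delta_ccs: float
    score_rt: float
    score_ccs: float
    score_ms2: float | None
    multidimensional_score: float
    retained: bool
    best: bool = False
    rt_in_low: bool = True
    ccs_in_low: bool = True


class StageCounts(NamedTuple):
    """Candidate counts at the four workflow stages (non-increasing)."""

    n_ms1_rt: int
    n_ms1_rt_ccs: int
    n_above_cutoff: int
    n_best_retained: int


@dataclass
class ScreeningResult:
    candidates: list[CandidateMatch]
    stage_counts: StageCounts

    @property
    def best_candidates(self) -> list[CandidateMatch]:
        """Highest-scoring retained candidate per suspect."""
        return [c for c in self.candidates if c.best]


def _candidate_sort_key(candidate: CandidateMatch) -> tuple:
    return (
        -candidate.multidimensional_score,
        abs(candidate.delta_ccs),
        abs(candidate.mass_error_ppm),
        candidate.suspect_id,
        candidate.feature_id,
    )


def screen(
    features: Sequence[MeasuredFeature],
    library: Sequence[SuspectEntry],
    ms2_scores: Sequence[MS2Score] = (),
    cfg: ScoringConfig | None = None,
) -> ScreeningResult:
    """Run the full screening workflow over a feature table and suspect library.

    For every (feature, suspect) pair the best-matching adduct is gated on
    exact mass and isotope pattern, then scored in RT and CCS against the
    source-specific thresholds; an MS2 similarity score is attached when one
    is supplied for the pair and the feature carries at least
    ``min_ms2_fragments_for_scoring`` fragments. Candidates at or above the
    cutoff are marked retained and the highest-scoring retained candidate
    per suspect is flagged ``best``. Stage counts tally candidates at the
    four workflow stages: full-scan + RT match, + CCS match, score above
    cutoff, and best-per-suspect.
    """
    cfg = cfg or ScoringConfig()
    if not features or not library:
        logger.warning("empty %s; screening result is empty",
                       "feature list" if not features else "library")
        return ScreeningResult([], StageCounts(0, 0, 0, 0))

    score_lookup = {(s.feature_id, s.suspect_id): s.score for s in ms2_scores}

    # Theoretical envelopes per (formula, adduct); the base-peak m/z of the
    # envelope (the most abundant isotopologue) is the mass-gate reference,
    # matching the base-peak convention of measured feature m/z.
    pattern_cache: dict[tuple[str, AdductKind], IsotopePattern] = {}

    def theory(entry: SuspectEntry, kind: AdductKind) -> IsotopePattern:
        key = (entry.formula.hill_notation(), kind)
        if key not in pattern_cache:
            pattern_cache[key] = isotope_pattern(entry.formula, kind)
        return pattern_cache[key]

    # Pre-filter on m/z: sorted array of theoretical base-peak m/z values.
    index: list[tuple[float, int, AdductKind]] = []
    for i, entry in enumerate(library):
        for kind, _ in entry.adducts:
            index.append((theory(entry, kind).base_peak_mz, i, kind))
    index.sort()
    mz_array = np.asarray([item[0] for item in index])

    candidates: list[CandidateMatch] = []
    for feature in features:
        window = max(feature.mz * cfg.mass_tol_ppm * 1e-6, cfg.mass_tol_mda * 1e-3)
        lo = int(np.searchsorted(mz_array, feature.mz - window - 1e-9))
        hi = int(np.searchsorted(mz_array, feature.mz + window + 1e-9))
        hits: dict[int, tuple[MassGateResult, AdductKind]] = {}
        for theo_mz, i, kind in index[lo:hi]:
            gate = mass_gate(feature.mz, theo_mz, cfg)
            if not gate.passed:
                continue
            current = hits.get(i)
            if current is None or abs(gate.error_ppm) < abs(current[0].error_ppm):
                hits[i] = (gate, kind)

        for i, (gate, kind) in hits.items():
            entry = library[i]
            iso = isotope_gate(feature.isotope_envelope, theory(entry, kind), cfg)
            if not iso.passed:
                continue
            candidates.append(
                _score_candidate(feature, entry, kind, gate, iso, score_lookup, cfg)
            )

    # Best retained candidate per suspect.
    retained = [c for c in candidates if c.retained]
    retained.sort(key=_candidate_sort_key)
    seen: set[str] = set()
    for candidate in retained:
        if candidate.suspect_id not in seen:
            candidate.best = True
            seen.add(candidate.suspect_id)

    stage_counts = StageCounts(
        n_ms1_rt=sum(1 for c in candidates if c.rt_in_low),
        n_ms1_rt_ccs=sum(1 for c in candidates if c.rt_in_low and c.ccs_in_low),
        n_above_cutoff=sum(1 for c in candidates if c.retained),
        n_best_retained=sum(1 for c in candidates if c.best),
    )
    return ScreeningResult(candidates, stage_counts)


def _score_candidate(
    feature: MeasuredFeature,
    entry: SuspectEntry,
    kind: AdductKind,
    gate: MassGateResult,
    iso: IsotopeGateResult,
    score_lookup: dict[tuple[str, str], float],
    cfg: ScoringConfig,
) -> CandidateMatch:
    d_rt = delta_rt(feature.rt_measured, entry.rt_reference)
    d_ccs = delta_ccs(feature.ccs_measured, entry.ccs_reference)

    rt_high, rt_low = cfg.thresholds.rt_bounds(entry.rt_source)
    ccs_high, ccs_low = cfg.thresholds.ccs_bounds(entry.ccs_source)

    rt_in_low = rt_low[0] < d_rt < rt_low[1]
    ccs_in_low = -ccs_low < d_ccs < ccs_low

    score_rt = continuous_score(d_rt, rt_high, rt_low, cfg.score_shape) if rt_in_low else 0.0
    score_ccs = continuous_score(d_ccs, ccs_high, ccs_low, cfg.score_shape) if ccs_in_low else 0.0

    score_ms2 = None
    if len(feature.ms2_fragments) >= cfg.min_ms2_fragments_for_scoring:
        score_ms2 = score_lookup.get((feature.feature_id, entry.suspect_id))

    fused = fuse_scores(score_rt, score_ccs, score_ms2, cfg)
    retained = rt_in_low and ccs_in_low and fused >= cfg.cutoff
    return CandidateMatch(
        feature_id=feature.feature_id,
        suspect_id=entry.suspect_id,
        matched_adduct=kind,
        mass_error_ppm=gate.error_ppm,
        mass_error_mda=gate.error_mda,
        isotope_gm_deviation=iso.gm_deviation,
        isotope_bypassed=iso.bypassed,
        delta_rt=d_rt,
        delta_ccs=d_ccs,
        score_rt=score_rt,
        score_ccs=score_ccs,
        score_ms2=score_ms2,
        multidimensional_score=fused,
        retained=retained,
        rt_in_low=rt_in_low,
        ccs_in_low=ccs_in_low,
    )


def rank_candidates(result: ScreeningResult) -> list[CandidateMatch]:
    """Candidates ordered by descending multidimensional score.

    Ties break deterministically by smaller absolute CCS deviation, then
    smaller absolute ppm mass error, then lexicographic suspect id.
    """
    return sorted(result.candidates, key=_candidate_sort_key)


# ---------------------------------------------------------------------------
# Result I/O
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "feature_id", "suspect_id", "adduct", "mass_error_ppm", "mass_error_mda",
    "isotope_gm_deviation", "isotope_bypassed", "delta_rt", "delta_ccs",
    "score_rt", "score_ccs", "score_ms2", "multidimensional_score",
    "retained", "best", "rt_in_low", "ccs_in_low",
)


def write_results(result: ScreeningResult, path, sep: str = ",") -> None:
    rows = [
        {
            "feature_id": c.feature_id,
            "suspect_id": c.suspect_id,
            "adduct": c.matched_adduct.value,
            "mass_error_ppm": repr(float(c.mass_error_ppm)),
            "mass_error_mda": repr(float(c.mass_error_mda)),
            "isotope_gm_deviation": "" if c.isotope_gm_deviation is None
            else repr(float(c.isotope_gm_deviation)),
            "isotope_bypassed": str(c.isotope_bypassed),
            "delta_rt": repr(float(c.delta_rt)),
            "delta_ccs": repr(float(c.delta_ccs)),
            "score_rt": repr(float(c.score_rt)),
            "score_ccs": repr(float(c.score_ccs)),
            "score_ms2": "" if c.score_ms2 is None else repr(c.score_ms2),
            "multidimensional_score": repr(float(c.multidimensional_score)),
            "retained": str(c.retained),
            "best": str(c.best),
            "rt_in_low": str(c.rt_in_low),
            "ccs_in_low": str(c.ccs_in_low),
        }
        for c in rank_candidates(result)
    ]
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, sep=sep, index=False)


def read_results(path, sep: str = ",") -> ScreeningResult:
    """Read a candidate table written by :func:`write_results`.

    Stage counts are recomputed from the per-candidate flags.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    adduct_by_value = {kind.value: kind for kind in AdductKind}
    candidates = []
    for _, row in frame.iterrows():
        candidates.append(
            CandidateMatch(
                feature_id=row["feature_id"],
                suspect_id=row["suspect_id"],
                matched_adduct=adduct_by_value[row["adduct"]],
                mass_error_ppm=float(row["mass_error_ppm"]),
                mass_error_mda=float(row["mass_error_mda"]),
                isotope_gm_deviation=float(row["isotope_gm_deviation"])
                if row["isotope_gm_deviation"] else None,
                isotope_bypassed=row["isotope_bypassed"] == "True",
                delta_rt=float(row["delta_rt"]),
                delta_ccs=float(row["delta_ccs"]),
                score_rt=float(row["score_rt"]),
                score_ccs=float(row["score_ccs"]),
                score_ms2=float(row["score_ms2"]) if row["score_ms2"] else None,
                multidimensional_score=float(row["multidimensional_score"]),
                retained=row["retained"] == "True",
                best=row["best"] == "True",
                rt_in_low=row["rt_in_low"] == "True",
                ccs_in_low=row["ccs_in_low"] == "True",
            )
        )
    stage_counts = StageCounts(
        n_ms1_rt=sum(1 for c in candidates if c.rt_in_low),
        n_ms1_rt_ccs=sum(1 for c in candidates if c.rt_in_low and c.ccs_in_low),
        n_above_cutoff=sum(1 for c in candidates if c.retained),
        n_best_retained=sum(1 for c in candidates if c.best),
    )
    return ScreeningResult(candidates, stage_counts)


def write_summary(result: ScreeningResult, path, sep: str = ",") -> None:
    """Write the four stage counts as a small two-column summary table."""
    frame = pd.DataFrame(
        {
            "stage": ["ms1_rt", "ms1_rt_ccs", "above_cutoff", "best_retained"],
            "n_hits": list(result.stage_counts),
        }
    )
    frame.to_csv(path, sep=sep, index=False)
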