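"""Shared fixtures: a tiny suspect library and features that match it exactly."""

import itertools
import math

import pytest
from pyteomics.mass import nist_mass

import hocscreen as h


def brute_force_pattern(element_counts, adduct=h.AdductKind.RADICAL_CATION):
    """Independent oracle: exhaustive enumeration of all isotopologue assignments.

    Every atom independently takes one of its element's naturally occurring
    isotopes; assignments are aggregated into mass-number bins with
    intensity-weighted centroid masses, exactly the aggregation the
    convolution implementation claims to perform.
    """
    atom_choices = []
    for element, count in element_counts.items():
        isotopes = [
            (number, mass, abundance)
            for number, (mass, abundance) in nist_mass[element].items()
            if number != 0 and abundance > 0.0
        ]
        atom_choices.extend([isotopes] * count)
    bins = {}
    for assignment in itertools.product(*atom_choices):
        p = math.prod(ab for _, _, ab in assignment)
        key = sum(number for number, _, _ in assignment)
        mass = sum(m for _, m, _ in assignment)
        p0, s0 = bins.get(key, (0.0, 0.0))
        bins[key] = (p0 + p, s0 + p * mass)
    p_max = max(p for p, _ in bins.values())
    return {
        key: (s / p + adduct.mass_shift, p / p_max * 100.0)
        for key, (p, s) in bins.items()
        if p > 0.0
    }


def assert_pattern_matches_oracle(pattern, oracle, ri_tol=1e-6, mz_tol=1e-6):
    """Compare a computed pattern with the enumeration oracle.

    Peaks are paired by nearest m/z (bins are ~1 Da apart, so a 0.4 Da
    window is unambiguous); intensities must agree within *ri_tol* percent,
    with absent peaks treated as zero. Centroid m/z is compared only for
    observable peaks, whose centroids are not dominated by pruning noise.
    """
    oracle_peaks = sorted(oracle.values())
    pattern_peaks = list(pattern.peaks)
    for oracle_mz, oracle_ri in oracle_peaks:
        near = [(abs(mz - oracle_mz), mz, ri) for mz, ri in pattern_peaks
                if abs(mz - oracle_mz) < 0.4]
        if near:
            _, pattern_mz, pattern_ri = min(near)
        else:
            pattern_mz, pattern_ri = None, 0.0
        assert abs(pattern_ri - oracle_ri) <= ri_tol, (
            f"intensity mismatch at m/z {oracle_mz}: {pattern_ri} vs {oracle_ri}"
        )
        if pattern_mz is not None and oracle_ri > 1e-3:
            assert abs(pattern_mz - oracle_mz) <= mz_tol
    for mz, ri in pattern_peaks:
        assert any(abs(mz - omz) < 0.4 for omz, _ in oracle_peaks) or ri <= ri_tol, (
            f"unexpected peak at m/z {mz} ({ri}%)"
        )


@pytest.fixture
def config():
    return h.ScoringConfig()


def exact_feature(entry, adduct=h.AdductKind.RADICAL_CATION, feature_id=None, **overrides):
    """A measured feature reproducing *entry* with zero measurement error."""
    pattern = h.isotope_pattern(entry.formula, adduct)
    fields = dict(
        feature_id=feature_id or f"feat_{entry.suspect_id}",
        mz=pattern.base_peak_mz,
        rt_measured=entry.rt_reference,
        ccs_measured=entry.ccs_reference,
        intensity=1e5,
        isotope_envelope=list(pattern.peaks),
        ms2_fragments=[(77.0386, 1200.0), (102.0464, 800.0)],
    )
    fields.update(overrides)
    return h.MeasuredFeature(**fields)


@pytest.fixture
def tiny_library():
    """Three chemically distinct suspects with literature references."""
    return [
        h.make_suspect_entry("naphthalene", "C10H8", rt_reference=8.2,
                             rt_source="literature_converted", ccs_reference=124.5,
                             ccs_source="literature", inchikey="UFWIBTONFRDIAS-UHFFFAOYSA-N"),
        h.make_suspect_entry("hexachlorobenzene", "C6Cl6", rt_reference=14.6,
                             rt_source="literature_converted", ccs_reference=146.8,
                             ccs_source="literature", inchikey="CKAPSXZOOQJIBF-UHFFFAOYSA-N"),
        h.make_suspect_entry("bde47", "C12H6Br4O", rt_reference=27.9,
                             rt_source="predicted", ccs_reference=170.1,
                             ccs_source="predicted", inchikey="HJSPWKGEPDZNLK-UHFFFAOYSA-N"),
    ]
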