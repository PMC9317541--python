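"""Radiative-transfer core: leaf model, canopy model, and their composition."""

from __future__ import annotations

import numpy as np
import pytest

from reference_rtm import ref_prosail, ref_prospect, ref_tav

from wheatlai import (
    CanopyParams,
    LeafParams,
    ViewGeometry,
    foursail,
    prospect_d,
    simulate_canopy_reflectance,
)
from wheatlai.prospect import tav
from wheatlai.sail import compute_skyl

SET1_MIDPOINT = dict(Ns=1.75, Cab=45.0, Car=10.0, Cant=0.0, Cbrown=0.0,
                     Cw=0.0255, Cm=0.0105)


def _leaf(**over):
    p = {**SET1_MIDPOINT, **over}
    return LeafParams(**p)


# A panel spanning the Table-2 style parameter ranges (leaf x canopy x geometry).
REFERENCE_PANEL = [
    # Ns,  Cab, Car, Cw,    Cm,    LAI, ALA, hspot, SZA, VZA, RAA
    (1.0,   0.0,  0.0, 0.001, 0.001, 0.5, 20.0, 0.01, 20.0, 0.0,   0.0),
    (1.0,  90.0, 20.0, 0.050, 0.020, 8.0, 70.0, 0.50, 70.0, 0.0, -90.0),
    (2.5,   0.0, 20.0, 0.050, 0.001, 0.1, 70.0, 0.50, 20.0, 0.0,  90.0),
    (2.5,  90.0,  0.0, 0.001, 0.020, 8.0, 20.0, 0.01, 70.0, 0.0, -45.0),
    (1.75, 45.0, 10.0, 0.0255, 0.0105, 4.0, 45.0, 0.25, 45.0, 0.0, 0.0),
    (1.2,  10.0,  3.0, 0.005, 0.002, 1.0, 30.0, 0.10, 25.0, 0.0,  30.0),
    (1.2,  80.0, 18.0, 0.040, 0.018, 6.0, 60.0, 0.40, 65.0, 0.0, -60.0),
    (2.2,  20.0, 15.0, 0.010, 0.015, 2.0, 25.0, 0.05, 35.0, 0.0,  45.0),
    (2.2,  70.0,  5.0, 0.030, 0.004, 7.0, 65.0, 0.30, 55.0, 0.0, -30.0),
    (1.5,  30.0,  8.0, 0.015, 0.006, 3.0, 40.0, 0.20, 30.0, 0.0,  60.0),
    (1.5,  60.0, 12.0, 0.020, 0.012, 5.0, 50.0, 0.15, 60.0, 0.0, -15.0),
    (1.9,  40.0,  6.0, 0.045, 0.008, 0.2, 57.3, 0.45, 40.0, 0.0,  15.0),
    (1.9,  55.0, 16.0, 0.025, 0.016, 4.5, 35.0, 0.35, 50.0, 0.0, -75.0),
    (1.1,  25.0,  2.0, 0.035, 0.003, 2.5, 55.0, 0.25, 22.0, 0.0,  75.0),
    (2.4,  85.0, 19.0, 0.048, 0.019, 7.5, 68.0, 0.48, 68.0, 0.0,  -5.0),
    (1.3,   5.0,  1.0, 0.002, 0.0015, 0.8, 22.0, 0.02, 45.0, 0.0,  5.0),
    (1.6,  35.0,  9.0, 0.018, 0.007, 3.5, 48.0, 0.18, 38.0, 0.0,  40.0),
    (2.0,  50.0, 11.0, 0.028, 0.009, 5.5, 52.0, 0.28, 42.0, 0.0, -40.0),
    (1.4,  15.0,  4.0, 0.008, 0.005, 1.5, 28.0, 0.08, 28.0, 0.0,  20.0),
    (2.3,  65.0, 14.0, 0.038, 0.014, 6.5, 62.0, 0.38, 58.0, 0.0, -20.0),
    # off-nadir and hotspot-aligned cases
    (1.6,  35.0,  9.0, 0.020, 0.008, 2.7, 48.0, 0.20, 38.0, 25.0, 40.0),
    (1.6,  35.0,  9.0, 0.020, 0.008, 2.7, 48.0, 0.30, 38.0, 38.0, 20.0),
    (1.75, 45.0, 10.0, 0.0255, 0.0105, 3.0, 45.0, 0.40, 40.0, 40.0, 0.0),
    (1.75, 45.0, 10.0, 0.0255, 0.0105, 3.0, 45.0, 0.0, 40.0, 10.0, 120.0),
]


class TestProspect:
    def test_validation_errors_name_the_field(self):
        with pytest.raises(ValueError, match="Ns"):
            LeafParams(Ns=0.5, Cab=40, Car=8, Cw=0.01, Cm=0.005)
        with pytest.raises(ValueError, match="Cab"):
            LeafParams(Ns=1.5, Cab=-1, Car=8, Cw=0.01, Cm=0.005)

    def test_energy_conservation_across_panel(self):
        for row in REFERENCE_PANEL[:8]:
            lo = prospect_d(_leaf(Ns=row[0], Cab=row[1], Car=row[2], Cw=row[3], Cm=row[4]))
            assert np.all(lo.reflectance >= 0)
            assert np.all(lo.transmittance >= 0)
            assert np.all(lo.reflectance + lo.transmittance <= 1.0 + 1e-12)

    def test_chlorophyll_absorption_darkens_red(self):
        r670 = [
            prospect_d(_leaf(Cab=cab)).reflectance[670 - 400]
            for cab in (20.0, 40.0, 60.0)
        ]
        assert r670[0] > r670[1] > r670[2]

    def test_matches_scalar_reference_transcription(self):
        lo = prospect_d(_leaf(Ns=1.5, Cab=40, Car=8, Cw=0.01, Cm=0.005))
        rr, rt = ref_prospect(1.5, 40, 8, 0, 0, 0.01, 0.005)
        assert np.max(np.abs(lo.reflectance - np.array(rr))) <= 1e-4
        assert np.max(np.abs(lo.transmittance - np.array(rt))) <= 1e-4

    def test_tav_matches_scalar_reference(self):
        for n in (1.3, 1.45, 1.6):
            for theta in (40.0, 90.0):
                assert tav(theta, np.array([n]))[0] == pytest.approx(
                    ref_tav(theta, n), abs=1e-10
                )

    def test_deterministic(self):
        a = prospect_d(_leaf())
        b = prospect_d(_leaf())
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.transmittance, b.transmittance)


class TestSkyl:
    def test_matches_driver_formula(self):
        for sza in (0.0, 30.0):
            sh = np.sin(np.deg2rad(90.0 - sza))
            expected = np.clip(0.847 - 1.61 * sh + 1.04 * sh * sh, 0, 1)
            assert compute_skyl(sza) == pytest.approx(expected, abs=1e-6)

    def test_clamped_to_unit_interval(self):
        for sza in np.linspace(0, 89.9, 50):
            assert 0.0 <= compute_skyl(float(sza)) <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            compute_skyl(90.0)
        with pytest.raises(ValueError):
            compute_skyl(-1.0)


class TestFoursail:
    def test_bare_soil_limit(self, dry_soil):
        lo = prospect_d(_leaf())
        out = foursail(
            lo, CanopyParams(LAI=0.0, ALA=45, hspot=0.25),
            ViewGeometry(SZA=40), dry_soil,
        )
        assert np.max(np.abs(out - dry_soil)) <= 1e-9

    def test_reflectance_bounds(self, dry_soil):
        for row in REFERENCE_PANEL:
            lo = prospect_d(_leaf(Ns=row[0], Cab=row[1], Car=row[2], Cw=row[3], Cm=row[4]))
            out = foursail(
                lo, CanopyParams(LAI=row[5], ALA=row[6], hspot=row[7]),
                ViewGeometry(SZA=row[8], VZA=row[9], RAA=row[10]), dry_soil,
            )
            assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_grid_mismatch_raises(self, dry_soil):
        lo = prospect_d(_leaf())
        with pytest.raises(ValueError, match="grid"):
            foursail(lo, CanopyParams(LAI=2, ALA=45, hspot=0.2),
                     ViewGeometry(SZA=40), dry_soil[:-1])


class TestReferenceEquivalence:
    @pytest.mark.parametrize("row", REFERENCE_PANEL,
                             ids=[f"combo{i}" for i in range(len(REFERENCE_PANEL))])
    def test_panel_matches_scalar_reference(self, row, dry_soil):
        """Vectorised model vs independent scalar transcription, <= 1e-4."""
        ns, cab, car, cw, cm, lai, ala, hspot, sza, vza, raa = row
        skyl = compute_skyl(sza)
        lo = prospect_d(_leaf(Ns=ns, Cab=cab, Car=car, Cw=cw, Cm=cm))
        mine = foursail(
            lo, CanopyParams(LAI=lai, ALA=ala, hspot=hspot),
            ViewGeometry(SZA=sza, VZA=vza, RAA=raa, skyl=skyl), dry_soil,
        )
        ref = ref_prosail(ns, cab, car, 0.0, 0.0, cw, cm, lai, ala, hspot,
                          sza, vza, raa, list(dry_soil), skyl)
        assert np.max(np.abs(mine - np.array(ref))) <= 1e-4


class TestSimulateCanopyReflectance:
    def test_hspot_zeroed_off_alignment(self, dry_soil):
        canopy_a = CanopyParams(LAI=3.0, ALA=45, hspot=0.3)
        canopy_b = CanopyParams(LAI=3.0, ALA=45, hspot=0.0)
        geom = ViewGeometry(SZA=40, VZA=0)
        a = simulate_canopy_reflectance(_leaf(), canopy_a, geom, dry_soil)
        b = simulate_canopy_reflectance(_leaf(), canopy_b, geom, dry_soil)
        assert np.array_equal(a, b)

    def test_hspot_active_on_alignment(self, dry_soil):
        geom = ViewGeometry(SZA=40, VZA=40, RAA=30)
        big = simulate_canopy_reflectance(
            _leaf(), CanopyParams(LAI=3.0, ALA=45, hspot=0.4), geom, dry_soil)
        small = simulate_canopy_reflectance(
            _leaf(), CanopyParams(LAI=3.0, ALA=45, hspot=0.01), geom, dry_soil)
        nir = 840 - 400
        assert big[nir] > small[nir]

    def test_bare_soil_limit(self, dry_soil):
        out = simulate_canopy_reflectance(
            _leaf(), CanopyParams(LAI=0, ALA=45, hspot=0.2),
            ViewGeometry(SZA=35), dry_soil,
        )
        assert np.max(np.abs(out - dry_soil)) <= 1e-9

    def test_composition_matches_scalar_reference(self, dry_soil):
        out = simulate_canopy_reflectance(
            _leaf(), CanopyParams(LAI=4.0, ALA=45, hspot=0.25),
            ViewGeometry(SZA=45, VZA=0, RAA=0), dry_soil,
        )
        ref = ref_prosail(
            1.75, 45.0, 10.0, 0.0, 0.0, 0.0255, 0.0105, 4.0, 45.0, 0.0,
            45.0, 0.0, 0.0, list(dry_soil), compute_skyl(45.0),
        )
        assert np.max(np.abs(out - np.array(ref))) <= 1e-4
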