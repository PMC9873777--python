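"""Soil characterization arithmetic and plant-available-water accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorgsim.errors import InputError, InvalidSampleError
from sorgsim import soil as s


class TestSampleArithmetic:
    @pytest.mark.parametrize(
        "wet,dry,expected",
        [(120, 100, 20.0), (100, 100, 0.0), (137.5, 110, 25.0)],
    )
    def test_gravimetric_water_pct(self, wet, dry, expected):
        assert s.gravimetric_water_pct(wet, dry) == pytest.approx(expected)

    def test_gravimetric_rejects_bad_samples(self):
        with pytest.raises(InvalidSampleError):
            s.gravimetric_water_pct(100, 0)
        with pytest.raises(InvalidSampleError):
            s.gravimetric_water_pct(90, 100)

    @pytest.mark.parametrize(
        "dry,vol,expected", [(150, 100, 1.5), (122, 100, 1.22), (100, 100, 1.0)]
    )
    def test_bulk_density(self, dry, vol, expected):
        assert s.bulk_density(dry, vol) == pytest.approx(expected)

    def test_bulk_density_warns_outside_plausible_range(self):
        with pytest.warns(UserWarning):
            s.bulk_density(250, 100)
        with pytest.raises(InvalidSampleError):
            s.bulk_density(150, 0)

    @pytest.mark.parametrize(
        "grav,bd,expected", [(20, 1.2, 24.0), (0, 1.5, 0.0), (25, 1.13, 28.25)]
    )
    def test_volumetric_pct(self, grav, bd, expected):
        assert s.volumetric_pct(grav, bd) == pytest.approx(expected)

    @given(
        dry=st.floats(50, 500),
        extra=st.floats(0, 200),
        vol=st.floats(50, 400),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_against_arithmetic_oracle(self, dry, extra, vol):
        # volumetric(gravimetric(w,d), bd(d,v)) == ((w-d)/d) * (d/v) * 100
        import warnings

        wet = dry + extra
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # implausible-BD advisories
            got = s.volumetric_pct(
                s.gravimetric_water_pct(wet, dry), s.bulk_density(dry, vol)
            )
        assert got == pytest.approx((wet - dry) / dry * (dry / vol) * 100, rel=1e-12)


class TestLayerAndProfile:
    def test_layer_paw_matches_printed_values(self):
        melkassa_15_30 = s.SoilLayer(15, 30, 1.2, dul=0.26, cll=0.12, sw=0.23)
        assert s.layer_paw(melkassa_15_30) == pytest.approx(21.0)
        miesso_0_15 = s.SoilLayer(0, 15, 1.13, dul=0.39, cll=0.08, sw=0.36)
        assert s.layer_paw(miesso_0_15) == pytest.approx(46.5)

    def test_layer_paw_zero_when_dul_equals_cll(self):
        layer = s.SoilLayer(0, 20, 1.2, dul=0.25, cll=0.25, sw=0.25)
        assert s.layer_paw(layer) == 0.0

    def test_profile_pawc_additivity(self):
        layers = [
            s.SoilLayer(0, 15, 1.2, dul=0.26, cll=0.12, sw=0.2),
            s.SoilLayer(15, 30, 1.2, dul=0.26, cll=0.12, sw=0.2),
        ]
        assert s.profile_pawc(s.SoilProfile(layers)) == pytest.approx(42.0)

    def test_miesso_profile_totals(self, miesso_profile):
        assert s.profile_pawc(miesso_profile) == pytest.approx(504.0)
        assert s.profile_available_sw(miesso_profile) == pytest.approx(185.0, abs=1.0)

    def test_available_sw_boundary_identities(self, melkassa_profile):
        at_cll = melkassa_profile.copy()
        for l in at_cll.layers:
            l.sw = l.cll
        assert s.profile_available_sw(at_cll) == 0.0
        at_dul = melkassa_profile.copy()
        for l in at_dul.layers:
            l.sw = l.dul
        assert s.profile_available_sw(at_dul) == pytest.approx(
            s.profile_pawc(melkassa_profile)
        )

    def test_profile_requires_contiguous_layers(self):
        with pytest.raises(InputError):
            s.SoilProfile(
                [
                    s.SoilLayer(0, 15, 1.2, dul=0.3, cll=0.1),
                    s.SoilLayer(20, 30, 1.2, dul=0.3, cll=0.1),
                ]
            )
        with pytest.raises(InputError):
            s.SoilProfile([])

    def test_sw_clamped_to_physical_band(self):
        soggy = s.SoilLayer(0, 15, 1.2, dul=0.30, cll=0.10, sw=0.9)
        assert soggy.sw == pytest.approx(soggy.saturation)
        parched = s.SoilLayer(0, 15, 1.2, dul=0.30, cll=0.10, sw=0.0)
        assert parched.sw == pytest.approx(0.5 * 0.10)


@st.composite
def random_profiles(draw):
    n = draw(st.integers(1, 6))
    layers = []
    top = 0.0
    for _ in range(n):
        thick = draw(st.floats(5, 40))
        cll = draw(st.floats(0.05, 0.25))
        dul = cll + draw(st.floats(0.01, 0.3))
        layers.append(
            s.SoilLayer(top, top + thick, 1.2, dul=min(dul, 0.6), cll=cll, sw=dul)
        )
        top += thick
    return s.SoilProfile(layers)


class TestProfileProperties:
    @given(random_profiles())
    @settings(max_examples=100, deadline=None)
    def test_saturated_asw_equals_pawc(self, profile):
        for l in profile.layers:
            l.sw = l.dul
        assert s.profile_available_sw(profile) == pytest.approx(
            s.profile_pawc(profile), abs=1e-9
        )

    @given(random_profiles(), st.floats(0.1, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_pawc_invariant_under_layer_split(self, profile, frac):
        import dataclasses

        target = profile.layers[0]
        mid = target.top_depth + frac * (target.bottom_depth - target.top_depth)
        split = [
            dataclasses.replace(target, bottom_depth=mid),
            dataclasses.replace(target, top_depth=mid),
        ] + [dataclasses.replace(l) for l in profile.layers[1:]]
        assert s.profile_pawc(s.SoilProfile(split)) == pytest.approx(
            s.profile_pawc(profile), abs=1e-9
        )

    def test_layer_paw_monotone_in_dul_and_cll(self):
        base = s.SoilLayer(0, 15, 1.2, dul=0.30, cll=0.10)
        wider = s.SoilLayer(0, 15, 1.2, dul=0.32, cll=0.10)
        narrower = s.SoilLayer(0, 15, 1.2, dul=0.30, cll=0.12)
        assert s.layer_paw(wider) > s.layer_paw(base) > s.layer_paw(narrower) >= 0


class TestIO:
    def test_csv_round_trip(self, tmp_path, miesso_profile):
        path = tmp_path / "profile.csv"
        s.write_profile(miesso_profile, path)
        back = s.read_profile(path)
        assert s.profile_pawc(back) == pytest.approx(s.profile_pawc(miesso_profile))
        assert [l.sw for l in back.layers] == pytest.approx(
            [l.sw for l in miesso_profile.layers]
        )

    def test_unknown_fixture_rejected(self):
        with pytest.raises(InputError):
            s.load_fixture("atlantis")

    def test_generic_profile_matches_requested_pawc(self):
        prof = s.generic_profile(100.0, 132.0)
        assert s.profile_pawc(prof) == pytest.approx(132.0)
        assert prof.depth_cm == pytest.approx(100.0)
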