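"""Field estimators, magnification curves, isolines, numerical inverse."""
import numpy as np
import pytest

from foveamap import (AreaLabel, CorticalPoint, GridSpec, ModelParams,
                      VisualAreaMap, area_ratio, areal_magnification_curve,
                      extract_isolines, local_anisotropy_field,
                      meridional_anisotropy_field, numeric_inverse)
from foveamap.mapping import conformal_derivative_abs, local_jacobian, VisualPoint

SMALL_GRID = GridSpec(ecc_min=0.2, ecc_max=12.0, n_ecc=24, n_polar=91)


class TestLocalAnisotropy:
    def test_conformal_wedge_is_locally_isotropic_in_v1(self, conformal_wedge):
        df = local_anisotropy_field(conformal_wedge, SMALL_GRID)
        v1 = df[(df.area == "V1") & df.ok]
        np.testing.assert_allclose(v1.local_anisotropy, 1.0, atol=1e-2)

    def test_log_polar_wedge_v3_value(self, conformal_wedge):
        """Angular compression alpha3=0.4 shows up as anisotropy 2.5."""
        df = local_anisotropy_field(conformal_wedge, SMALL_GRID)
        v3 = df[df.area.isin(["V3v", "V3d"]) & df.ok]
        np.testing.assert_allclose(v3.local_anisotropy, 2.5, rtol=0.02)

    def test_banding_restores_foveal_isotropy(self, banded_model,
                                              sheared_wedge):
        """The banding moves central V2/V3 local anisotropy toward 1
        relative to the non-banded sheared wedge."""
        grid = GridSpec(ecc_min=0.05, ecc_max=0.5, n_ecc=10, n_polar=91)
        bb = local_anisotropy_field(banded_model, grid)
        nb = local_anisotropy_field(sheared_wedge, grid)
        for areas in (["V2v", "V2d"], ["V3v", "V3d"]):
            dev_b = np.abs(np.log(
                bb[bb.area.isin(areas) & bb.ok].local_anisotropy)).median()
            dev_n = np.abs(np.log(
                nb[nb.area.isin(areas) & nb.ok].local_anisotropy)).median()
            assert dev_b < dev_n

    def test_banded_v3_near_isotropic_centrally(self, banded_model):
        """Median V3 local anisotropy sits in [0.8, 1.25] around E ~ 0.25
        (the non-banded value there is 1/alpha3 = 2.5)."""
        grid = GridSpec(ecc_min=0.15, ecc_max=0.3, n_ecc=6, n_polar=91)
        df = local_anisotropy_field(banded_model, grid)
        v3 = df[df.area.isin(["V3v", "V3d"]) & df.ok]
        assert 0.8 <= v3.local_anisotropy.median() <= 1.25


class TestMeridionalAnisotropy:
    def test_sheared_v1_flat(self, sheared_wedge):
        df = meridional_anisotropy_field(sheared_wedge, SMALL_GRID)
        v1 = df[(df.area == "V1") & df.ok]
        np.testing.assert_allclose(v1.meridional_anisotropy, 1.0, atol=0.05)

    def test_sheared_v3_equals_alpha3(self, sheared_wedge):
        df = meridional_anisotropy_field(sheared_wedge, SMALL_GRID)
        v3 = df[df.area.isin(["V3v", "V3d"]) & df.ok]
        np.testing.assert_allclose(v3.meridional_anisotropy, 0.4, rtol=0.05)

    def test_log_polar_wedge_reaches_sevenfold(self, conformal_wedge):
        grid = GridSpec(ecc_min=0.1, ecc_max=12.0, n_ecc=64, n_polar=181)
        df = meridional_anisotropy_field(conformal_wedge, grid)
        sel = df[df.area.isin(["V3v", "V3d"]) & df.ok
                 & df.ecc_deg.between(0.4, 2.5)]
        assert sel.meridional_anisotropy.max() >= 7.0

    def test_estimators_are_distinct_for_conformal_maps(self, conformal_wedge):
        """Conformal wedge: local anisotropy is 1 everywhere, yet V1's
        meridional anisotropy deviates from 1 near E ~ a (ballooning)."""
        grid = GridSpec(ecc_min=0.8, ecc_max=1.4, n_ecc=5, n_polar=91)
        loc = local_anisotropy_field(conformal_wedge, grid)
        mer = meridional_anisotropy_field(conformal_wedge, grid)
        v1_loc = loc[(loc.area == "V1") & loc.ok]
        v1_mer = mer[(mer.area == "V1") & mer.ok]
        np.testing.assert_allclose(v1_loc.local_anisotropy, 1.0, atol=1e-2)
        assert v1_mer.meridional_anisotropy.max() > 1.5

    def test_fields_mirror_symmetric(self, sheared_wedge):
        df = meridional_anisotropy_field(sheared_wedge, SMALL_GRID)
        up = df[df.area == "V3v"].sort_values(["ecc_deg", "polar_rad"])
        dn = df[df.area == "V3d"].sort_values(
            ["ecc_deg", "polar_rad"], ascending=[True, False])
        np.testing.assert_allclose(up.meridional_anisotropy.to_numpy(),
                                   dn.meridional_anisotropy.to_numpy(),
                                   rtol=1e-8)


class TestMagnification:
    def test_matches_closed_form_on_horizontal_meridian(self,
                                                        conformal_wedge,
                                                        sheared_wedge):
        """Closed-form |f'| oracle at E=10 (valid on the HM): a narrow
        conformal band around the HM and the full sheared band (whose
        magnification is polar-invariant) both reproduce it."""
        from foveamap.cartography import _band_surface
        p = conformal_wedge.params
        ref = p.k * abs(1.0 / (10 + p.a) - 1.0 / (10 + p.b))
        E1, E2 = 10.0 * 0.99, 10.0 * 1.01
        th = np.linspace(-0.05, 0.05, 21)
        a_c = _band_surface(conformal_wedge, AreaLabel.V1, E1, E2, th)
        a_v = (th[-1] - th[0]) * (E2 ** 2 - E1 ** 2) / 2
        assert np.sqrt(a_c / a_v) == pytest.approx(ref, rel=0.02)
        got = areal_magnification_curve(sheared_wedge, "V1",
                                        [10.0])["M_mm_per_deg"].iloc[0]
        assert got == pytest.approx(ref, rel=0.02)

    def test_doubling_k_doubles_magnification(self, sheared_wedge):
        eccs = [0.5, 2.0, 8.0]
        m1 = areal_magnification_curve(sheared_wedge, "V2", eccs)
        m2 = areal_magnification_curve(sheared_wedge.with_(k=40.0), "V2", eccs)
        np.testing.assert_allclose(m2.M_mm_per_deg, 2 * m1.M_mm_per_deg,
                                   rtol=1e-9)

    def test_banding_boosts_foveal_extrastriate_magnification(
            self, banded_model, sheared_wedge):
        """The banded model predicts extra foveal surface for V2/V3."""
        eccs = [0.05]
        for grp in ("V2", "V3"):
            mb = areal_magnification_curve(banded_model, grp, eccs)
            mn = areal_magnification_curve(sheared_wedge, grp, eccs)
            assert np.all(mb.M_mm_per_deg.to_numpy()
                          > mn.M_mm_per_deg.to_numpy())

    def test_banded_foveal_v2_exceeds_v1(self, banded_model):
        eccs = [0.05, 0.1]
        m1 = areal_magnification_curve(banded_model, "V1", eccs)
        m2 = areal_magnification_curve(banded_model, "V2", eccs)
        assert np.all(m2.M_mm_per_deg.to_numpy() > m1.M_mm_per_deg.to_numpy())

    def test_rejects_degenerate_band(self, sheared_wedge):
        with pytest.raises(ValueError):
            areal_magnification_curve(sheared_wedge, "V1", [0.0])


class TestAreaRatio:
    def test_sheared_wedge_v3_to_v1(self, sheared_wedge):
        assert sheared_wedge.area_ratio("V3", "V1", (0.5, 12.0)) == \
            pytest.approx(0.4, rel=0.02)

    def test_identity_ratio(self, sheared_wedge):
        assert sheared_wedge.area_ratio("V1", "V1", (0.5, 12.0)) == \
            pytest.approx(1.0, rel=1e-12)

    def test_log_polar_foveal_ballooning_inflates_v3(self, conformal_wedge):
        """Conformal wedge V3 exceeds the alpha3 share near the fovea."""
        assert conformal_wedge.area_ratio("V3", "V1", (0.5, 2.0)) > 0.4


class TestEqConsistency:
    def test_finite_square_matches_jacobian_determinant(self, sheared_wedge):
        """The square estimator converges to |det J| as delta -> 0."""
        from foveamap.cartography import _square_measures
        p = sheared_wedge.params
        for E, th, area in ((1.0, 0.3, AreaLabel.V1), (4.0, 0.8, AreaLabel.V3v)):
            from foveamap.wedge import pacman_angle
            tp = float(pacman_angle(th, area, p))
            J = local_jacobian(None, VisualPoint(E, tp), p)
            dth = abs(float(pacman_angle(1.0, area, p))
                      - float(pacman_angle(0.0, area, p)))
            det_ref = J.areal * dth  # angular compression of the area
            errs = []
            for frac in (0.02, 0.01):
                _, _, Ma, ok, _ = _square_measures(
                    sheared_wedge, np.array([E]), np.array([th]), area, frac)
                assert ok.all()
                errs.append(abs(Ma[0] - det_ref) / det_ref)
            assert errs[-1] < 0.01
            assert errs[1] < errs[0]


class TestIsolines:
    def test_v1_horizontal_meridian_on_x_axis(self, sheared_wedge):
        lines = extract_isolines(sheared_wedge, levels=[1.0, 8.0])
        hm = [l for l in lines if l["kind"] == "meridian"
              and l["area"] == "V1" and l["name"] == "HM"]
        assert len(hm) == 1
        np.testing.assert_allclose(hm[0]["xy"][:, 1], 0.0, atol=1e-12)

    def test_isoecc_contours_meet_at_shared_borders(self, sheared_wedge):
        """Contours continue seamlessly across the V1/V2/V3 borders."""
        lines = extract_isolines(sheared_wedge, levels=[4.0])
        iso = {l["area"]: l["xy"] for l in lines if l["kind"] == "isoecc"}
        # V2v's polar samples run from the V2/V3 border (theta=0) to the
        # V1/V2 border (theta=pi/2)
        d12 = np.min(np.linalg.norm(iso["V2v"] - iso["V1"][-1], axis=1))
        d23 = np.min(np.linalg.norm(iso["V3v"] - iso["V2v"][0], axis=1))
        assert d12 < 1e-9 and d23 < 1e-9

    def test_banded_foveal_isoline_geometry(self, banded_model):
        lines = extract_isolines(banded_model, levels=[0.0])
        length = {}
        for l in (l for l in lines if l["kind"] == "isoecc"):
            xy = l["xy"]
            length[l["area"]] = np.sum(
                np.linalg.norm(np.diff(xy, axis=0), axis=1))
        assert length["V1"] == pytest.approx(0.0, abs=1e-9)
        assert length["V2v"] > 1.0 and length["V3v"] > 1.0


class TestNumericInverse:
    def test_round_trip_random_points(self, sheared_wedge, rng):
        for area in AreaLabel:
            for _ in range(4):
                E = float(np.exp(rng.uniform(np.log(0.3), np.log(15))))
                lo, hi = ((0, np.pi / 2)
                          if area in (AreaLabel.V2v, AreaLabel.V3v)
                          else (-np.pi / 2, 0)
                          if area in (AreaLabel.V2d, AreaLabel.V3d)
                          else (-np.pi / 2, np.pi / 2))
                th = float(rng.uniform(lo + 0.05, hi - 0.05))
                w = complex(sheared_wedge.project(E, th, area))
                got = numeric_inverse(sheared_wedge, w)
                assert got is not None
                pt, lab = got
                assert lab == area
                assert pt.eccentricity == pytest.approx(E, abs=1e-6)
                assert pt.polar_angle == pytest.approx(th, abs=1e-6)

    def test_border_point_classified_to_lower_area(self, sheared_wedge):
        w = complex(sheared_wedge.project(3.0, np.pi / 2, "V2v"))
        got = numeric_inverse(sheared_wedge, w)
        assert got is not None and got[1] == AreaLabel.V1

    def test_far_off_map_point_unmapped(self, sheared_wedge):
        """A point beyond the foveal anchor lies outside every area."""
        assert numeric_inverse(sheared_wedge, CorticalPoint(-30.0, 0.0)) is None
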