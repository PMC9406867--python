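import numpy as np
import pytest
from scipy import ndimage

from implantheat.errors import ValidationError
from implantheat.fixtures import make_implant
from implantheat.gc import (
    ImplantModel,
    QMatrix,
    assemble_q,
    average_power,
    coil_field_coefficients,
    solve_unit_current,
    worst_case_epi,
)
from implantheat.sequence import (
    Axis,
    GradientEvent,
    GradientSpectrum,
    SequenceModel,
)
from implantheat.voxel import VoxelField

from conftest import SPHERE_RADIUS


def _identity_coeffs():
    return coil_field_coefficients((0, 0, 0), model="user_supplied", user_B=np.eye(3))


class TestUnitCurrentSolve:
    def test_sphere_analytic_current(self, sphere_implant, sphere_unit_solutions):
        """Axial field on a sphere: |J| = pi*sigma*rho, azimuthal, no potential."""
        imp = sphere_implant
        sol = sphere_unit_solutions[Axis.Z]
        interior = ndimage.binary_erosion(imp.mask_bool, iterations=2)
        x, y, _ = imp.mask.meshgrid()
        rho = np.hypot(x - imp.barycentre[0], y - imp.barycentre[1])
        jmag = np.linalg.norm(np.asarray(sol.j_field.values), axis=-1)
        scale = imp.conductivity * np.pi * SPHERE_RADIUS
        assert np.abs(jmag[interior] - imp.conductivity * np.pi * rho[interior]).max() < 0.08 * scale
        # azimuthal: no z component
        jz = np.asarray(sol.j_field.values)[..., 2]
        assert np.abs(jz[interior]).max() < 0.03 * scale

    def test_rotation_symmetry(self):
        imp = make_implant("cylinder", {"radius": 0.004, "length": 0.02}, spacing=1e-3)
        sol_z = solve_unit_current(imp, "z")
        # rotating the cylinder 90 degrees about z maps the solution onto itself
        j = np.asarray(sol_z.j_field.values)
        j_rot = np.rot90(j, axes=(0, 1)).copy()
        # vector components rotate too: (jx, jy) -> (-jy, jx)
        j_rot_vec = np.stack([-j_rot[..., 1], j_rot[..., 0], j_rot[..., 2]], axis=-1)
        scale = np.abs(j).max()
        assert np.abs(j_rot_vec - j).max() < 1e-6 * scale

    def test_gauge_invariance(self, sphere_implant, sphere_unit_solutions):
        ref = np.asarray(sphere_unit_solutions[Axis.Z].j_field.values)
        shifted = solve_unit_current(
            sphere_implant,
            "z",
            gauge_origin=sphere_implant.barycentre + np.array([0.05, -0.02, 0.01]),
        )
        scale = sphere_implant.conductivity * np.pi * SPHERE_RADIUS
        assert np.abs(np.asarray(shifted.j_field.values) - ref).max() < 1e-5 * scale

    def test_divergence_residual_small(self, sphere_unit_solutions):
        for sol in sphere_unit_solutions.values():
            assert sol.div_residual < 1e-6

    def test_empty_mask_rejected(self):
        mask = VoxelField(np.zeros((4, 4, 4), dtype=np.int8), (1e-3,) * 3, kind="mask")
        with pytest.raises(ValidationError):
            ImplantModel(mask=mask)


class TestCoilFieldCoefficients:
    def test_isocentre_is_zero(self):
        assert np.allclose(coil_field_coefficients((0, 0, 0)).B, 0.0)

    def test_z_coil_on_axis(self):
        B = coil_field_coefficients((0, 0, 0.3)).B
        np.testing.assert_allclose(B[2], [0.0, 0.0, 0.3])

    def test_x_coil_concomitant(self):
        B = coil_field_coefficients((0.1, 0.0, 0.3)).B
        np.testing.assert_allclose(B[0], [0.3, 0.0, 0.1])

    def test_outside_working_volume_warns(self, caplog):
        with caplog.at_level("WARNING"):
            coil_field_coefficients((0.5, 0, 0))
        assert "working volume" in caplog.text


class TestAssembleQ:
    def test_identity_coeffs_diagonal_on_sphere(self, sphere_implant, sphere_unit_solutions):
        q = assemble_q(sphere_unit_solutions, _identity_coeffs(), sphere_implant)
        off = q.QV - np.diag(np.diag(q.QV))
        assert np.abs(off).max() < 1e-6 * np.trace(np.abs(q.QV))

    def test_sphere_closed_form_qzz(self, sphere_implant, sphere_unit_solutions):
        q = assemble_q(sphere_unit_solutions, _identity_coeffs(), sphere_implant)
        expected = np.pi**2 * sphere_implant.conductivity**2 * 2 * SPHERE_RADIUS**2 / 5
        assert q.QV[2, 2].real == pytest.approx(expected, rel=0.05)

    def test_bilinearity(self, sphere_implant, sphere_unit_solutions):
        coeffs1 = coil_field_coefficients((0.05, 0.02, 0.3))
        coeffs2 = coil_field_coefficients(
            (0, 0, 0), model="user_supplied", user_B=2 * coeffs1.B
        )
        q1 = assemble_q(sphere_unit_solutions, coeffs1, sphere_implant)
        q2 = assemble_q(sphere_unit_solutions, coeffs2, sphere_implant)
        np.testing.assert_allclose(q2.QV, 4 * q1.QV, rtol=1e-12)

    def test_psd_on_fixtures(self, sphere_implant, sphere_unit_solutions):
        for pos in [(0, 0, 0.3), (0.1, -0.05, 0.5), (0.02, 0.02, -0.2)]:
            q = assemble_q(
                sphere_unit_solutions, coil_field_coefficients(pos), sphere_implant
            )
            np.testing.assert_allclose(q.QV, q.QV.conj().T, atol=1e-12 * np.trace(np.abs(q.QV)))
            assert q.eigenvalues().min() >= -1e-12 * np.trace(np.abs(q.QV))


class TestAveragePower:
    def test_single_tone_hand_formula(self, sphere_implant):
        q11 = 3.0e9
        q = QMatrix(QV=np.diag([q11, 0.0, 0.0]))
        f0, A, duty = 1200.0, 0.01, 0.8
        spec = GradientSpectrum([f0], [[A, 0, 0]])
        p = average_power(q, spec, sphere_implant, duty_cycle=duty)
        assert p == pytest.approx(
            duty * f0**2 * A**2 * q11 / (2 * sphere_implant.conductivity)
        )

    def test_empty_spectrum(self, sphere_implant):
        q = QMatrix(QV=np.eye(3))
        spec = GradientSpectrum(np.empty(0), np.empty((0, 3)))
        assert average_power(q, spec, sphere_implant) == 0.0

    def test_sphere_power_closed_form(self, sphere_implant, sphere_unit_solutions):
        """Single z tone amplitude B: p = sigma * omega^2 * B^2 * a^2 / 20."""
        q = assemble_q(sphere_unit_solutions, _identity_coeffs(), sphere_implant)
        f0, B = 1000.0, 1e-3
        p = average_power(q, GradientSpectrum([f0], [[0, 0, B]]), sphere_implant)
        exact = (
            sphere_implant.conductivity
            * (2 * np.pi * f0) ** 2
            * B**2
            * SPHERE_RADIUS**2
            / 20
        )
        assert p == pytest.approx(exact, rel=0.05)

    def test_two_tone_matches_time_domain_oracle(self, sphere_implant, sphere_unit_solutions):
        rng = np.random.default_rng(5)
        coeffs = coil_field_coefficients((0.1, 0.05, 0.3))
        q = assemble_q(sphere_unit_solutions, coeffs, sphere_implant)
        freqs = np.array([800.0, 2100.0])
        g = (rng.normal(size=(2, 3)) + 1j * rng.normal(size=(2, 3))) * 1e-3
        p = average_power(q, GradientSpectrum(freqs, g), sphere_implant)
        # brute force: synthesize J(x,t) on the voxel grid, average |J|^2/sigma
        m = sphere_implant.mask_bool
        j_hat = np.stack(
            [np.asarray(sphere_unit_solutions[ax].j_field.values)[m] for ax in Axis]
        )
        j_coil = np.einsum("ki,ivc->kvc", coeffs.B, j_hat)
        nt = 512  # sampling 51.2 kHz over one period of gcd(800, 2100) = 100 Hz
        t = np.linspace(0, 1e-2, nt, endpoint=False)
        j_t = np.zeros((nt,) + j_coil.shape[1:])
        for fi, f in enumerate(freqs):
            phasor = np.exp(2j * np.pi * f * t)
            for k in range(3):
                j_t += f * np.real(np.einsum("t,vc->tvc", phasor * g[fi, k], j_coil[k]))
        p_oracle = np.mean(np.sum(j_t**2, axis=-1)) / sphere_implant.conductivity
        dv = sphere_implant.mask.voxel_volume
        p_oracle *= dv * m.sum() / sphere_implant.volume  # volume average (already uniform grid)
        assert p == pytest.approx(p_oracle, rel=0.01)

    def test_power_scales_linearly_with_conductivity(self, sphere_implant):
        """At fixed unit-solution normalisation, p is proportional to sigma."""
        small = make_implant("sphere", {"radius": 0.006}, spacing=1e-3)
        doubled = ImplantModel(
            mask=small.mask, conductivity=2 * small.conductivity, anatomy=small.anatomy
        )
        spec = GradientSpectrum([900.0], [[0, 0, 2e-3]])

        def power(imp):
            sols = {ax: solve_unit_current(imp, ax) for ax in Axis}
            q = assemble_q(sols, _identity_coeffs(), imp)
            return average_power(q, spec, imp)

        assert power(doubled) == pytest.approx(2 * power(small), rel=1e-6)

    def test_rotation_invariance_of_power(self):
        """Rigid 90-degree rotation of mask and coefficients leaves p unchanged."""
        imp = make_implant("cylinder", {"radius": 0.004, "length": 0.016}, spacing=1e-3)
        rot_mask = np.rot90(imp.mask.values, axes=(0, 1)).copy()
        imp_rot = ImplantModel(
            mask=VoxelField(rot_mask, imp.mask.spacing, imp.mask.origin, kind="mask"),
            conductivity=imp.conductivity,
            anatomy=imp.anatomy,
        )
        # rotation matrix for 90 deg about z as used by np.rot90(axes=(0,1))
        R = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        B = coil_field_coefficients((0.06, 0.03, 0.25)).B
        B_rot = B @ R.T  # rotate the field vectors into the rotated frame
        spec = GradientSpectrum([1500.0], [[1e-3, 2e-3, 0.5e-3]])

        def power(implant, coeff_matrix):
            sols = {ax: solve_unit_current(implant, ax) for ax in Axis}
            coeffs = coil_field_coefficients(
                (0, 0, 0), model="user_supplied", user_B=coeff_matrix
            )
            q = assemble_q(sols, coeffs, implant)
            return average_power(q, spec, implant)

        assert power(imp_rot, B_rot) == pytest.approx(power(imp, B), rel=1e-6)


class TestWorstCaseEpi:
    def _seq(self):
        ev = GradientEvent("x", amplitude=0.02, ramp_time=0.1e-3, flat_time=0.4e-3)
        return SequenceModel(
            "epi",
            TR=2e-3,
            duration=60.0,
            gradient_events=[ev],
            b1rms=0.0,
            freq_encode_axis="x",
            metadata={"family": "EPI"},
        )

    def test_isotropic_q_tie_breaks_to_x(self, sphere_implant):
        q = QMatrix(QV=np.eye(3))
        p, axis = worst_case_epi(self._seq(), q, sphere_implant)
        assert axis == Axis.X
        assert p > 0

    def test_zz_dominated_selects_z(self, sphere_implant):
        q = QMatrix(QV=np.diag([1.0, 1.0, 50.0]))
        _, axis = worst_case_epi(self._seq(), q, sphere_implant)
        assert axis == Axis.Z

    def test_matches_exhaustive_three_way(self, sphere_implant, sphere_unit_solutions):
        q = assemble_q(
            sphere_unit_solutions, coil_field_coefficients((0.08, 0.0, 0.35)), sphere_implant
        )
        seq = self._seq()
        p_best, axis_best = worst_case_epi(seq, q, sphere_implant)
        from implantheat.sequence import gradient_spectrum

        base = gradient_spectrum(seq)
        powers = {}
        for target in Axis:
            spec = base.permuted({Axis.X: target, target: Axis.X})
            powers[target] = average_power(q, spec, sphere_implant, duty_cycle=1.0)
        assert p_best == pytest.approx(max(powers.values()))
        assert powers[axis_best] == pytest.approx(p_best)
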