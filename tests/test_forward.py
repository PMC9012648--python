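"""Three-shell forward model against independent oracles and symmetries."""

import numpy as np
import pytest

from abrreref.forward import (
    HeadModel,
    LeadField,
    SourceLayer,
    cached_lead_field,
    compute_lead_field,
    dipole_gains,
    fibonacci_source_layer,
    homogeneous_sphere_potential,
)


def _series_oracle(electrode, dipole_pos, moment, sigma, R, n_terms=400):
    """Independent Legendre-series summation for the homogeneous sphere.

    Textbook expansion with explicit polynomial recurrences — shares no code
    with the shell-propagation machinery it checks.
    """
    b = np.linalg.norm(dipole_pos)
    b_hat = dipole_pos / b if b > 0 else np.array([0.0, 0.0, 1.0])
    r_hat = electrode / np.linalg.norm(electrode)
    x = float(np.clip(r_hat @ b_hat, -1, 1))
    q_r = moment @ b_hat
    q_dot_r = moment @ r_hat
    p_prev, p_cur = 1.0, x
    dp_prev, dp_cur = 0.0, 1.0
    total = 0.0
    tpow = 1.0  # (b/R)^(n-1), kept incremental to avoid under/overflow
    for n in range(1, n_terms + 1):
        coef = (2 * n + 1) / n * tpow / R**2
        total += coef * (n * q_r * p_cur + (q_dot_r - x * q_r) * dp_cur)
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        tpow *= b / R
    return total / (4 * np.pi * sigma)


class TestHomogeneousClosedForm:
    def test_matches_independent_series_summation(self, rng):
        R, sigma = 0.09, 0.33
        for _ in range(10):
            b = rng.normal(size=3)
            b = b / np.linalg.norm(b) * rng.uniform(0.1, 0.7) * R
            q = rng.normal(size=3)
            e = rng.normal(size=3)
            e = e / np.linalg.norm(e) * R
            v_closed = homogeneous_sphere_potential(e, b, q, sigma, R)
            v_series = _series_oracle(e, b, q, sigma, R)
            assert v_closed == pytest.approx(v_series, rel=1e-9)

    def test_zero_moment_gives_zero(self):
        v = homogeneous_sphere_potential([0, 0, 1.0], [0, 0, 0.5], [0, 0, 0.0])
        assert v == 0.0

    def test_no_net_monopole_on_dense_grid(self, rng):
        # uniform-ish grid: surface integral of the potential vanishes
        n = 4000
        i = np.arange(n)
        z = 1 - (2 * i + 1) / n
        phi = np.pi * (1 + np.sqrt(5)) * i
        s = np.sqrt(1 - z**2)
        grid = np.column_stack([np.cos(phi) * s, np.sin(phi) * s, z])
        b = np.array([0.1, 0.2, 0.3])
        q = np.array([1.0, -2.0, 0.5])
        vals = [homogeneous_sphere_potential(g, b, q, 1.0, 1.0) for g in grid]
        assert abs(np.mean(vals)) < 1e-3 * np.max(np.abs(vals))

    def test_dipole_outside_sphere_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            homogeneous_sphere_potential([0, 0, 1.0], [0, 0, 1.5], [1, 0, 0])


class TestShellSeries:
    def test_equal_conductivities_match_closed_form(self, montage, rng):
        head = HeadModel(conductivities=(0.33, 0.33, 0.33))
        R = head.scalp_radius_m
        for _ in range(5):
            b = rng.normal(size=3)
            b = b / np.linalg.norm(b) * rng.uniform(0.2, 0.8) * head.brain_radius_m
            q = rng.normal(size=3)
            gains = dipole_gains(montage, head, b, q, n_terms=60)[:, 0]
            oracle = np.array([
                homogeneous_sphere_potential(e.position * R, b, q, 0.33, R)
                for e in montage.electrodes
            ])
            err = np.max(np.abs(gains - oracle)) / np.max(np.abs(oracle))
            assert err < 1e-6

    def test_central_radial_dipole_is_cosine_topography(self, montage, head):
        gains = dipole_gains(montage, head, [0.0, 0.0, 0.0], [0.0, 0.0, 1.0])[:, 0]
        cos_angle = montage.positions()[:, 2]
        v_cz = gains[montage.names.index("Cz")]
        assert np.allclose(gains, v_cz * cos_angle, atol=1e-12 * abs(v_cz))

    def test_linear_in_moment_and_inverse_conductivity(self, montage, head):
        b = np.array([0.0, 0.01, 0.02])
        q = np.array([0.3, -0.1, 1.0])
        g1 = dipole_gains(montage, head, b, q)
        g2 = dipole_gains(montage, head, b, 2 * q)
        assert np.allclose(g2, 2 * g1, rtol=1e-12)
        head2 = HeadModel(conductivities=tuple(2 * s for s in head.conductivities))
        g3 = dipole_gains(montage, head2, b, q)
        assert np.allclose(g3, 0.5 * g1, rtol=1e-12)

    def test_series_converged_at_default_truncation(self, montage, head):
        layer = fibonacci_source_layer(40, head=head)
        lf60 = compute_lead_field(montage, head, layer, n_terms=60).matrix
        lf120 = compute_lead_field(montage, head, layer, n_terms=120).matrix
        rel = np.max(np.abs(lf60 - lf120)) / np.max(np.abs(lf120))
        assert rel < 1e-6

    def test_source_on_or_outside_brain_shell_rejected(self, montage, head):
        bad = SourceLayer(np.array([[0.0, 0.0, head.brain_radius_m]]),
                          np.eye(3)[None])
        with pytest.raises(ValueError, match="inside the brain"):
            compute_lead_field(montage, head, bad)
        with pytest.raises(ValueError, match="n_terms"):
            compute_lead_field(montage, head, fibonacci_source_layer(5, head=head), 0)


class TestLeadFieldObject:
    def test_surface_mean_of_dense_grid_leadfield_is_small(self, head):
        # no net monopole: over a whole-sphere electrode grid the
        # infinity-referenced potentials average to ~0 per source
        from abrreref.montage import Electrode, Montage

        n = 500
        i = np.arange(n)
        z = 1 - (2 * i + 1) / n
        phi = np.pi * (1 + np.sqrt(5)) * i
        s = np.sqrt(1 - z**2)
        electrodes = tuple(
            Electrode(f"G{k}", np.array([np.cos(p) * ss, np.sin(p) * ss, zz]))
            for k, (p, ss, zz) in enumerate(zip(phi, s, z))
        )
        sphere = Montage(electrodes, midline_subset=())
        layer = fibonacci_source_layer(20, head=head)
        lf = compute_lead_field(sphere, head, layer)
        col_rms = np.sqrt(np.mean(lf.matrix**2, axis=0))
        assert np.max(np.abs(lf.matrix.mean(axis=0)) / col_rms) < 2e-3

    def test_save_load_round_trip(self, tmp_path, montage, head):
        layer = fibonacci_source_layer(10, head=head)
        lf = compute_lead_field(montage, head, layer)
        lf.save(tmp_path / "lf.npz")
        back = LeadField.load(tmp_path / "lf.npz")
        assert np.array_equal(back.matrix, lf.matrix)
        assert back.channel_names == lf.channel_names
        assert back.montage_hash == lf.montage_hash
        assert np.array_equal(back.source_locations, lf.source_locations)

    def test_cache_hits_and_regenerates_on_mismatch(self, tmp_path, montage, head):
        layer = fibonacci_source_layer(10, head=head)
        lf1 = cached_lead_field(montage, head, layer, cache_dir=tmp_path)
        files = list(tmp_path.glob("leadfield-*.npz"))
        assert len(files) == 1
        lf2 = cached_lead_field(montage, head, layer, cache_dir=tmp_path)
        assert np.array_equal(lf1.matrix, lf2.matrix)
        other_head = HeadModel(scalp_radius_m=0.08)
        cached_lead_field(montage, other_head,
                          fibonacci_source_layer(10, head=other_head),
                          cache_dir=tmp_path)
        assert len(list(tmp_path.glob("leadfield-*.npz"))) == 2

    def test_row_subset_preserves_channel_alignment(self, recording_leadfield):
        sub = recording_leadfield.subset(["Cz", "M1"])
        i_cz = recording_leadfield.channel_names.index("Cz")
        assert np.array_equal(sub.matrix[0], recording_leadfield.matrix[i_cz])
        assert sub.channel_names == ("Cz", "M1")
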