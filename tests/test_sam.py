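"""Spectral angle mapper: angle formula, references, classification."""

import math

import numpy as np
import pytest

from nirhsi.bands import BandSet
from nirhsi.envi import Hypercube, WavelengthGrid
from nirhsi.roi import ROI
from nirhsi.sam import (
    BACKGROUND,
    UNCLASSIFIED,
    ReferenceLibrary,
    build_references,
    classify,
    spectral_angle,
)


def angle_oracle(t, r):
    """Pure-python arccos formula, independent of the vectorized path."""
    dot = sum(a * b for a, b in zip(t, r))
    nt = math.sqrt(sum(a * a for a in t))
    nr = math.sqrt(sum(b * b for b in r))
    return math.acos(max(-1.0, min(1.0, dot / (nt * nr))))


def _refl(values, lo=1000.0, hi=1400.0):
    values = np.asarray(values, dtype=float)
    grid = WavelengthGrid.linspace(lo, hi, values.shape[2])
    return Hypercube(values, grid, kind="reflectance")


class TestSpectralAngle:
    def test_identity_is_zero(self, rng):
        v = rng.random(6) + 0.1
        assert spectral_angle(v, v) == 0.0

    def test_positive_scaling_is_zero(self, rng):
        v = rng.random(8) + 0.1
        assert spectral_angle(2.0 * v, v) == 0.0

    def test_orthogonal_is_half_pi(self):
        assert spectral_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_hand_computed_quarter_pi(self):
        # arccos(1/sqrt(2))
        assert spectral_angle([1.0, 1.0], [1.0, 0.0]) == pytest.approx(np.pi / 4)

    def test_matches_oracle_on_random_vectors(self):
        r = np.random.default_rng(11)
        for _ in range(30):
            n = int(r.integers(2, 12))
            t = r.random(n) + 1e-3
            u = r.random(n) + 1e-3
            assert spectral_angle(t, u) == pytest.approx(
                angle_oracle(t, u), abs=1e-10
            )

    def test_scale_invariance_many_scalings(self):
        r = np.random.default_rng(4)
        t = r.random(6) + 0.1
        u = r.random(6) + 0.1
        base = spectral_angle(t, u)
        for _ in range(100):
            c = float(r.uniform(1e-4, 1e4))
            assert spectral_angle(c * t, u) == pytest.approx(base, abs=1e-10)

    def test_symmetry(self, rng):
        t, u = rng.random(5) + 0.1, rng.random(5) + 0.1
        assert spectral_angle(t, u) == spectral_angle(u, t)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBuildReferences:
    def test_single_pixel_rois(self, rng):
        cube = _refl(rng.random((3, 3, 5)) + 0.1)
        bands = BandSet(np.array([1000.0, 1200.0]))
        rois = [ROI("cancer", np.array([[0, 0]])), ROI("normal", np.array([[2, 2]]))]
        lib = build_references([(cube, rois)], bands)
        np.testing.assert_allclose(lib.entries["cancer"], cube.values[0, 0, [0, 2]])
        np.testing.assert_allclose(lib.entries["normal"], cube.values[2, 2, [0, 2]])

    def test_pooled_mean_matches_loop_oracle(self, rng):
        """10 + 30 pixels from two cubes pool to the 40-pixel flat mean."""
        cube_a = _refl(rng.random((6, 6, 4)) + 0.1)
        cube_b = _refl(rng.random((8, 8, 4)) + 0.1)
        pix_a = np.argwhere(np.ones((6, 6)))[:10]
        pix_b = np.argwhere(np.ones((8, 8)))[:30]
        bands = BandSet(np.array([1000.0, 1133.3, 1400.0]))
        lib = build_references(
            [(cube_a, [ROI("cancer", pix_a)]), (cube_b, [ROI("cancer", pix_b)])],
            bands,
        )
        idx = [0, 1, 3]
        acc = []
        for cube, pix in ((cube_a, pix_a), (cube_b, pix_b)):
            for r, c in pix:
                acc.append([cube.values[r, c, i] for i in idx])
        np.testing.assert_allclose(lib.entries["cancer"],
                                   np.mean(acc, axis=0), rtol=1e-12)
        assert lib.provenance["pixels_per_class"]["cancer"] == 40

    def test_empty_class_rejected(self, rng):
        cube = _refl(rng.random((3, 3, 4)) + 0.1)
        bands = BandSet(np.array([1000.0, 1400.0]))
        with pytest.raises(ValueError):
            build_references([(cube, [ROI("cancer", np.empty((0, 2), int))])], bands)

    def test_unresolvable_band_rejected(self, rng):
        cube = _refl(rng.random((3, 3, 4)) + 0.1)
        with pytest.raises(ValueError):
            build_references(
                [(cube, [ROI("cancer", np.array([[0, 0]]))])],
                BandSet(np.array([2500.0, 2600.0])),
            )


class TestClassify:
    def _library(self):
        bands = BandSet(np.array([1000.0, 1200.0, 1400.0]))
        return ReferenceLibrary(
            {"normal": np.array([0.3, 0.28, 0.25]),
             "cancer": np.array([0.45, 0.35, 0.3])},
            bands,
        )

    def test_scaled_reference_field_classifies_perfectly(self, rng):
        """Pixels equal to one reference times a random positive field."""
        lib = self._library()
        scale = rng.uniform(0.2, 3.0, size=(6, 6))
        vals = scale[:, :, None] * np.array([0.45, 0.0, 0.35, 0.0, 0.3])
        vals[:, :, [1, 3]] = rng.random((6, 6, 2))  # junk in unselected bands
        cube = _refl(vals)
        cmap = classify(cube, lib, np.ones((6, 6)))
        assert np.all(cmap.labels == 2)  # cancer is entry 2
        assert np.nanmax(cmap.best_angle) == pytest.approx(0.0, abs=1e-7)

    def test_tie_goes_to_first_entry(self, caplog):
        bands = BandSet(np.array([1000.0, 1400.0]))
        lib = ReferenceLibrary(
            {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}, bands
        )
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [1.0, 1.0]  # equidistant from both references
        with caplog.at_level("INFO"):
            cmap = classify(_refl(vals), lib, np.ones((1, 1)))
        assert cmap.labels[0, 0] == 1
        assert "tie" in caplog.text.lower()

    def test_three_by_three_hand_computed(self):
        """Label map matches per-pixel arccos computations done by hand."""
        bands = BandSet(np.array([1000.0, 1400.0]))
        lib = ReferenceLibrary(
            {"normal": np.array([1.0, 0.0]), "cancer": np.array([1.0, 1.0])}, bands
        )
        vecs = np.array([
            [[1.0, 0.1], [1.0, 0.9], [0.2, 1.0]],
            [[1.0, 0.4], [1.0, 0.6], [1.0, 1.0]],
            [[0.9, 0.0], [0.0, 0.8], [0.5, 0.5]],
        ])
        cmap = classify(_refl(vecs), lib, np.ones((3, 3)))
        expected = np.empty((3, 3), dtype=int)
        for r in range(3):
            for c in range(3):
                a_n = angle_oracle(vecs[r, c], [1.0, 0.0])
                a_c = angle_oracle(vecs[r, c], [1.0, 1.0])
                expected[r, c] = 1 if a_n <= a_c else 2
                assert cmap.best_angle[r, c] == pytest.approx(
                    min(a_n, a_c), abs=1e-12
                )
        np.testing.assert_array_equal(cmap.labels, expected)

    def test_background_exactly_where_mask_zero(self, rng):
        lib = self._library()
        cube = _refl(rng.random((5, 5, 3)) + 0.1, hi=1400.0)
        mask = rng.random((5, 5)) > 0.4
        cmap = classify(cube, lib, mask)
        np.testing.assert_array_equal(cmap.labels == BACKGROUND, ~mask)
        assert np.all(np.isnan(cmap.best_angle[~mask]))

    def test_zero_spectrum_unclassified(self, caplog):
        lib = self._library()
        vals = np.full((1, 2, 3), 0.3)
        vals[0, 1] = 0.0
        with caplog.at_level("WARNING"):
            cmap = classify(_refl(vals), lib, np.ones((1, 2)))
        assert cmap.labels[0, 1] == UNCLASSIFIED
        assert cmap.labels[0, 0] != UNCLASSIFIED

    def test_max_angle_rejects(self):
        lib = self._library()
        vals = np.zeros((1, 2, 3))
        vals[0, 0] = [0.45, 0.35, 0.30]      # exact cancer reference
        vals[0, 1] = [0.45, 0.05, 0.45]      # far from both references
        cmap = classify(_refl(vals), lib, np.ones((1, 2)), max_angle=0.05)
        assert cmap.labels[0, 0] == 2
        assert cmap.labels[0, 1] == UNCLASSIFIED

    def test_pixel_scale_invariance_of_labels(self, rng):
        lib = self._library()
        vals = rng.random((4, 4, 3)) + 0.1
        base = classify(_refl(vals), lib, np.ones((4, 4)))
        scaled = classify(_refl(vals * rng.uniform(0.5, 2.0, (4, 4, 1))),
                          lib, np.ones((4, 4)))
        np.testing.assert_array_equal(base.labels, scaled.labels)

    def test_band_restriction_no_leakage(self, rng):
        """Only selected band values influence the result."""
        lib = self._library()
        vals = rng.random((4, 4, 5)) + 0.1
        grid5 = WavelengthGrid(np.array([1000.0, 1100.0, 1200.0, 1300.0, 1400.0]))
        cube = Hypercube(vals, grid5, kind="reflectance")
        cmap = classify(cube, lib, np.ones((4, 4)))
        # brute force on the three selected columns only
        refs = lib.matrix()
        for r in range(4):
            for c in range(4):
                angles = [angle_oracle(vals[r, c, [0, 2, 4]], ref) for ref in refs]
                assert cmap.labels[r, c] == int(np.argmin(angles)) + 1
        # perturbing unselected bands changes nothing
        vals2 = vals.copy()
        vals2[:, :, [1, 3]] = rng.random((4, 4, 2))
        cmap2 = classify(Hypercube(vals2, grid5, kind="reflectance"),
                         lib, np.ones((4, 4)))
        np.testing.assert_array_equal(cmap.labels, cmap2.labels)


def test_library_json_round_trip(tmp_path):
    bands = BandSet(np.array([1000.0, 1200.0]))
    lib = ReferenceLibrary({"normal": np.array([0.3, 0.2]),
                            "cancer": np.array([0.5, 0.4])}, bands,
                           provenance={"pixels_per_class": {"normal": 7}})
    lib.to_json(tmp_path / "lib.json")
    back = ReferenceLibrary.from_json(tmp_path / "lib.json")
    assert back.class_names == ["normal", "cancer"]
    np.testing.assert_allclose(back.entries["cancer"], [0.5, 0.4])


def test_library_invariants():
    bands = BandSet(np.array([1000.0, 1200.0]))
    with pytest.raises(ValueError):
        ReferenceLibrary({}, bands)
    with pytest.raises(ValueError):
        ReferenceLibrary({"x": np.zeros(2)}, bands)
    with pytest.raises(ValueError):
        ReferenceLibrary({"x": np.ones(3)}, bands)
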