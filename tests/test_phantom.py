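"""Synthetic lesion phantom: geometry, physics monotonicity, labels, splits."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import label as sk_label, perimeter_crofton, regionprops

from perceptcad.birads import DescriptorVector
from perceptcad.phantom import (
    PhantomConfig,
    assign_label,
    case_rng,
    generate_dataset,
    render_case,
    sample_descriptors,
)


def _mask_circularity(mask: np.ndarray) -> float:
    area = mask.sum()
    perim = perimeter_crofton(mask, directions=4)
    return 4 * np.pi * area / perim**2


def _boundary_gradient(patch) -> float:
    gy, gx = np.gradient(patch.image)
    grad = np.hypot(gy, gx)
    boundary = patch.mask.astype(bool) ^ ndimage.binary_erosion(patch.mask.astype(bool))
    return float(grad[boundary].mean())


class TestSampleDescriptors:
    def test_deterministic_given_stream(self):
        a = sample_descriptors(case_rng(3, 0))
        b = sample_descriptors(case_rng(3, 0))
        assert a == b

    def test_degenerate_marginal(self):
        marginals = {
            f: {0.0: 1.0}
            for f in ("shape", "margin_sharpness", "microlobulated", "spiculated", "density")
        }
        for i in range(5):
            assert sample_descriptors(case_rng(0, i), marginals).as_array().tolist() == [0] * 5

    def test_uniform_three_way_marginal_frequencies(self):
        """10,000 draws with a uniform 3-way shape marginal hit 1/3 +- 0.02."""
        marginals = {
            "shape": {0.0: 1 / 3, 0.5: 1 / 3, 1.0: 1 / 3},
            "margin_sharpness": {0.0: 1 / 3, 0.5: 1 / 3, 1.0: 1 / 3},
            "microlobulated": {0.0: 0.5, 1.0: 0.5},
            "spiculated": {0.0: 0.5, 1.0: 0.5},
            "density": {0.0: 1 / 3, 0.5: 1 / 3, 1.0: 1 / 3},
        }
        rng = case_rng(7, 0)
        codes = np.array([sample_descriptors(rng, marginals).shape_code for _ in range(10_000)])
        for level in (0.0, 0.5, 1.0):
            assert abs((codes == level).mean() - 1 / 3) < 0.02


class TestRenderCase:
    def test_benign_sharp_lesion_is_circular(self):
        config = PhantomConfig(blur_sigmas=(1e-6, 1.6, 3.2))
        for s in range(10):
            case = render_case(
                DescriptorVector(0, 0, 0, 0, 0), config, case_rng(7, s), label="benign"
            )
            assert _mask_circularity(case.patches["CC"].mask) >= 0.9

    def test_same_seed_bit_identical(self):
        config = PhantomConfig()
        desc = DescriptorVector(1, 0.5, 1, 0, 1)
        a = render_case(desc, config, case_rng(1, 2))
        b = render_case(desc, config, case_rng(1, 2))
        for view in ("CC", "MLO"):
            assert np.array_equal(a.patches[view].image, b.patches[view].image)
            assert np.array_equal(a.patches[view].mask, b.patches[view].mask)

    def test_views_are_independent_renders(self):
        case = render_case(DescriptorVector(0, 0, 0, 0, 0), PhantomConfig(), case_rng(0, 1))
        assert not np.array_equal(case.patches["CC"].mask, case.patches["MLO"].mask)

    def test_spiculation_raises_boundary_complexity(self):
        config = PhantomConfig()
        for s in range(10):
            masks = {}
            for spic in (0, 1):
                case = render_case(
                    DescriptorVector(0, 0, 0, spic, 0), config, case_rng(100 + s, 0), label="benign"
                )
                m = case.patches["CC"].mask
                masks[spic] = perimeter_crofton(m, directions=4) ** 2 / m.sum()
            assert masks[1] > masks[0]

    def test_margin_blur_weakens_boundary_gradient(self):
        config = PhantomConfig()
        for s in range(10):
            grads = {}
            for margin in (0, 1):
                case = render_case(
                    DescriptorVector(0, margin, 0, 0, 1), config, case_rng(200 + s, 0), label="benign"
                )
                grads[margin] = _boundary_gradient(case.patches["CC"])
            assert grads[1] < grads[0]

    def test_patch_invariants_over_random_descriptors(self):
        config = PhantomConfig()
        for s in range(200):
            rng = case_rng(999, s)
            case = render_case(sample_descriptors(rng), config, rng)
            case.validate()  # shape match, binary, >=1 px, single component

    def test_geometry_error_when_lesion_cannot_fit(self):
        from perceptcad.phantom import GeometryError, _render_patch

        config = PhantomConfig(lesion_radius_frac=(0.6, 0.7))
        with pytest.raises(GeometryError):
            _render_patch(DescriptorVector(0, 0, 0, 0, 0), config, case_rng(0, 0), "CC")


class TestMonotonePhysics:
    """Averaged over seeds, the image physics track the descriptor codes."""

    N_SEEDS = 50

    def test_edge_strength_decreases_with_margin_code(self):
        config = PhantomConfig()
        means = []
        for margin in (0, 0.5, 1):
            vals = [
                _boundary_gradient(
                    render_case(
                        DescriptorVector(0, margin, 0, 0, 1), config, case_rng(s, 0), label="benign"
                    ).patches["CC"]
                )
                for s in range(self.N_SEEDS)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_solidity_decreases_with_spiculation(self):
        config = PhantomConfig()
        means = []
        for spic in (0, 1):
            vals = []
            for s in range(self.N_SEEDS):
                mask = render_case(
                    DescriptorVector(0, 0, 0, spic, 0), config, case_rng(s, 1), label="benign"
                ).patches["CC"].mask
                vals.append(regionprops(sk_label(mask))[0].solidity)
            means.append(np.mean(vals))
        assert means[1] < means[0]

    def test_contrast_increases_with_density_code(self):
        config = PhantomConfig()
        means = []
        for density in (0, 0.5, 1):
            vals = []
            for s in range(self.N_SEEDS):
                patch = render_case(
                    DescriptorVector(0, 0, 0, 0, density), config, case_rng(s, 2), label="benign"
                ).patches["CC"]
                vals.append(patch.image[patch.mask == 1].mean() - patch.image[patch.mask == 0].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAssignLabel:
    def test_extreme_weight_forces_malignant(self):
        config = PhantomConfig(malignancy_logit_weights=(0, 1e9, 0, 0, 0, 0))
        desc = DescriptorVector(1, 0, 0, 0, 0)
        labels = {assign_label(desc, config, case_rng(0, i)) for i in range(50)}
        assert labels == {"malignant"}

    def test_zero_weights_are_a_fair_coin(self):
        config = PhantomConfig(malignancy_logit_weights=(0, 0, 0, 0, 0, 0))
        desc = DescriptorVector(1, 1, 1, 1, 1)
        draws = [assign_label(desc, config, case_rng(1, i)) for i in range(4000)]
        assert abs(draws.count("malignant") / 4000 - 0.5) < 0.03

    def test_descriptor_separation_under_default_weights(self):
        """All-malignant vs all-benign descriptors differ in P(malignant) by > 0.5."""
        config = PhantomConfig()
        hi = [
            assign_label(DescriptorVector(1, 1, 1, 1, 1), config, case_rng(2, i))
            for i in range(2000)
        ]
        lo = [
            assign_label(DescriptorVector(0, 0, 0, 0, 0), config, case_rng(3, i))
            for i in range(2000)
        ]
        assert hi.count("malignant") / 2000 - lo.count("malignant") / 2000 > 0.5

    def test_label_marginal_near_half(self):
        config = PhantomConfig()
        labels = []
        for i in range(2000):
            rng = case_rng(5, i)
            labels.append(assign_label(sample_descriptors(rng), config, rng))
        assert abs(labels.count("malignant") / 2000 - 0.5) < 0.05


class TestGenerateDataset:
    def test_study_sized_split(self):
        _, manifest = generate_dataset(PhantomConfig(n_cases=416, train_size=214, seed=3))
        counts = manifest.drop_duplicates("case_id")["split"].value_counts()
        assert counts["train"] == 214
        assert counts["test"] == 202

    def test_manifest_reproducible(self):
        _, m1 = generate_dataset(PhantomConfig(n_cases=12, train_size=6, seed=9))
        _, m2 = generate_dataset(PhantomConfig(n_cases=12, train_size=6, seed=9))
        assert m1.equals(m2)

    def test_bad_split_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(PhantomConfig(n_cases=10, train_size=1.5))

    def test_blur_sigmas_must_increase(self):
        with pytest.raises(ValueError):
            PhantomConfig(blur_sigmas=(2.0, 1.0, 3.0))
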