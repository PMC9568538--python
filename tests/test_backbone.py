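"""Backbone contract, toy backbone, and the 22-block concatenation."""

import numpy as np
import pytest

from shutterblinds import (
    Backbone,
    ContractViolationError,
    FeatureMatrix,
    extract_all,
    extract_patch_features,
    load_features_csv,
    save_features_csv,
    toy_backbone,
)


class TestToyBackbone:
    def test_same_seed_same_extractor(self, checker_face):
        a = toy_backbone(seed=5, feature_dim=32)
        b = toy_backbone(seed=5, feature_dim=32)
        va = extract_patch_features(checker_face, a)
        vb = extract_patch_features(checker_face, b)
        assert np.array_equal(va, vb)

    def test_distinguishes_zero_from_saturated(self):
        bb = toy_backbone(seed=0, feature_dim=16)
        black = np.zeros((50, 50, 3), dtype=np.uint8)
        white = np.full((50, 50, 3), 255, dtype=np.uint8)
        assert not np.array_equal(
            extract_patch_features(black, bb), extract_patch_features(white, bb)
        )

    def test_sensitive_to_single_pooled_cell(self, rng):
        """Perturbing one pooled cell changes the vector (random projection)."""
        bb = toy_backbone(seed=9, input_side=64, feature_dim=16, grid=8)
        changed = 0
        for _ in range(100):
            img = rng.integers(0, 200, (64, 64, 3), dtype=np.uint8)
            other = img.copy()
            other[:8, :8] = np.clip(other[:8, :8].astype(int) + 50, 0, 255)
            v1 = extract_patch_features(img, bb)
            v2 = extract_patch_features(other, bb)
            changed += not np.allclose(v1, v2)
        assert changed == 100

    def test_feature_dim_validated(self):
        with pytest.raises(Exception):
            toy_backbone(seed=0, feature_dim=0)


class TestExtractPatchFeatures:
    def test_identical_patches_identical_vectors(self, rng):
        bb = toy_backbone(seed=1, feature_dim=12)
        patch = rng.integers(0, 255, (28, 224, 3), dtype=np.uint8)
        assert np.array_equal(
            extract_patch_features(patch, bb), extract_patch_features(patch.copy(), bb)
        )

    def test_extraction_sees_only_resized_input(self):
        """Strips of different heights but equal resized content agree."""
        bb = toy_backbone(seed=2, feature_dim=12)
        tall = np.full((112, 224, 3), 120, dtype=np.uint8)
        short = np.full((28, 224, 3), 120, dtype=np.uint8)
        assert np.array_equal(
            extract_patch_features(tall, bb), extract_patch_features(short, bb)
        )

    def test_wrong_output_length_is_contract_violation(self, checker_face):
        bad = Backbone("bad", 64, 10, lambda img: np.zeros(7))
        with pytest.raises(ContractViolationError, match="bad"):
            extract_patch_features(checker_face, bad)


class TestExtractAll:
    def test_full_configuration_length_is_22000(self, checker_face):
        bb = toy_backbone(seed=0, feature_dim=1000)
        vec = extract_all(checker_face, bb)
        assert vec.values.shape == (22000,)
        starts = [b[1] for b in vec.block_map]
        stops = [b[2] for b in vec.block_map]
        assert starts[0] == 0 and stops[-1] == 22000
        assert stops[:-1] == starts[1:]  # contiguous partition
        assert vec.block_map[-1][0] == "whole"

    def test_constant_face_gives_identical_blocks(self):
        bb = toy_backbone(seed=4, feature_dim=20)
        face = np.full((224, 224, 3), 90, dtype=np.uint8)
        vec = extract_all(face, bb)
        blocks = vec.values.reshape(22, 20)
        assert np.allclose(blocks, blocks[0])

    def test_blocks_match_per_patch_extraction(self, checker_face):
        from shutterblinds import make_blinds

        bb = toy_backbone(seed=6, feature_dim=15)
        vec = extract_all(checker_face, bb)
        ps = make_blinds(checker_face)
        for s, (name, start, stop) in zip(ps.strips, vec.block_map):
            assert name == f"strip_{s.scale}_{s.index}"
            assert np.array_equal(
                vec.values[start:stop], extract_patch_features(s.pixels, bb)
            )
        assert np.array_equal(
            vec.block("whole"), extract_patch_features(ps.whole, bb)
        )

    def test_edit_inside_one_strip_is_local(self, rng):
        """Content changes inside one finest strip touch only that block
        (at every scale containing it) and the whole-face block."""
        bb = toy_backbone(seed=7, feature_dim=10)
        face = rng.integers(0, 200, (224, 224, 3), dtype=np.uint8)
        other = face.copy()
        other[196:224] = np.clip(other[196:224].astype(int) + 55, 0, 255)  # last band
        v1, v2 = extract_all(face, bb), extract_all(other, bb)
        for name, start, stop in v1.block_map:
            same = np.array_equal(v1.values[start:stop], v2.values[start:stop])
            touched = name in ("strip_2_1", "strip_4_3", "strip_7_6", "strip_8_7", "whole")
            assert same != touched, name


def test_feature_csv_roundtrip_bit_exact(tmp_path, rng):
    X = rng.standard_normal((5, 7))
    fm = FeatureMatrix(X, [0, 1, 2, 3, 0], ids=[f"im{i}" for i in range(5)])
    p = tmp_path / "features.csv"
    save_features_csv(fm, p)
    back = load_features_csv(p)
    assert np.array_equal(back.X, fm.X)
    assert np.array_equal(back.y, fm.y)
    assert list(back.ids) == list(fm.ids)
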