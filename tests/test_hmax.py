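"""HMAX hierarchy: pyramid geometry, Gabor bank, S1/C1/S2/C2 oracles."""

import numpy as np
import pytest

import hmaxmli as h
from hmaxmli.hmax import (HmaxConfig, ImagePyramid, Prototype, PrototypeBank,
                          _similarity)

CFG = HmaxConfig()


class TestPyramid:
    def test_level_sides_match_quarter_octave_series(self):
        pyr = h.build_pyramid(np.ones((256, 256)))
        sides = [lv.shape[0] for lv in pyr.levels]
        assert sides == [256, 215, 181, 152, 128, 108, 91, 76, 64, 54]
        for a, b in zip(sides, sides[1:]):
            assert abs(a / b - 2 ** 0.25) < 0.02

    def test_constant_image_stays_constant(self):
        pyr = h.build_pyramid(np.full((256, 256), 0.37))
        for lv in pyr.levels:
            assert np.allclose(lv, 0.37, atol=1e-5)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError, match="256"):
            h.build_pyramid(np.ones((128, 128)))


class TestGaborBank:
    def test_bank_geometry_and_normalisation(self, gabor_bank):
        k = gabor_bank.kernels
        assert k.shape == (12, 11, 11)
        assert np.allclose(k.sum(axis=(1, 2)), 0.0, atol=1e-5)
        assert np.allclose(np.linalg.norm(k, axis=(1, 2)), 1.0, atol=1e-5)

    def test_quarter_turn_kernel_is_rotation_of_first(self, gabor_bank):
        """θ = 90° kernel must equal the 0° kernel rotated by a quarter turn."""
        k0, k90 = gabor_bank.kernels[0], gabor_bank.kernels[6]
        assert (np.allclose(k90, np.rot90(k0), atol=1e-5)
                or np.allclose(k90, np.rot90(k0, -1), atol=1e-5))


class TestS1:
    def test_constant_image_gives_zero_response(self, gabor_bank):
        s1 = h.apply_s1(h.build_pyramid(np.full((256, 256), 0.5)), gabor_bank)
        for level in s1:
            assert float(level.max()) < 1e-5

    def test_matches_direct_patch_evaluation(self, gabor_bank):
        """Toy image: every S1 value equals |kernel·patch| / ‖patch‖."""
        rng = np.random.default_rng(3)
        toy = rng.random((32, 32))
        pyr = ImagePyramid(levels=[toy.astype(np.float32)], config=CFG)
        s1 = h.apply_s1(pyr, gabor_bank)[0]
        g = 11
        for o in range(0, 12, 3):
            for (r, c) in [(0, 0), (5, 13), (21, 21)]:
                patch = toy[r:r + g, c:c + g]
                expected = abs(float(np.sum(
                    gabor_bank.kernels[o].astype(np.float64) * patch)))
                expected /= np.linalg.norm(patch)
                assert s1[o, r, c] == pytest.approx(min(expected, 1.0),
                                                    abs=1e-4)

    def test_horizontal_line_prefers_horizontal_filter(self, gabor_bank):
        """On-line units respond most to the horizontally tuned Gabor."""
        toy = np.ones((32, 32))
        toy[15:17, 4:28] = 0.0
        pyr = ImagePyramid(levels=[toy.astype(np.float32)], config=CFG)
        s1 = h.apply_s1(pyr, gabor_bank)[0]
        # centre of the line in valid coordinates
        best = int(np.argmax(s1[:, 10, 10]))
        # independently find the kernel most similar to a horizontal edge
        probe = np.ones((11, 11))
        probe[5:7, :] = 0.0
        expected = int(np.argmax([abs((k * probe).sum())
                                  for k in gabor_bank.kernels]))
        assert best == expected

    def test_orientation_axis_has_twelve_channels(self, gabor_bank):
        s1 = h.apply_s1(h.build_pyramid(np.ones((256, 256))), gabor_bank)
        assert all(level.shape[0] == 12 for level in s1)
        assert s1[0].shape == (12, 246, 246)


def brute_force_c1(s1_maps, cfg):
    """Window-membership oracle for the C1 pooling geometry.

    Window grids are centred: leftover rows/columns that do not fit a full
    stride are split between both edges, and so is the cross-scale crop.
    """
    size, stride = cfg.c1_pool_size, cfg.c1_stride
    pooled = []
    for s in s1_maps:
        if s is None or s.shape[1] < size:
            pooled.append(None)
            continue
        k, m, _ = s.shape
        off = ((m - size) % stride) // 2
        nout = (m - size - off) // stride + 1
        out = np.zeros((k, nout, nout), dtype=s.dtype)
        for o in range(k):
            for i in range(nout):
                for j in range(nout):
                    r, c = off + i * stride, off + j * stride
                    out[o, i, j] = s[o, r:r + size, c:c + size].max()
        pooled.append(out)
    bands = []
    for b in range(len(pooled) - cfg.c1_scale_depth + 1):
        group = [p for p in pooled[b:b + cfg.c1_scale_depth] if p is not None]
        hmin = min(p.shape[1] for p in group)
        wmin = min(p.shape[2] for p in group)
        acc = None
        for p in group:
            r0 = (p.shape[1] - hmin + 1) // 2
            c0 = (p.shape[2] - wmin + 1) // 2
            cut = p[:, r0:r0 + hmin, c0:c0 + wmin]
            acc = cut.copy() if acc is None else np.maximum(acc, cut)
        bands.append(acc)
    return bands


class TestC1:
    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        sizes = [33, 27, 22]
        cfg = HmaxConfig(n_levels=3)
        s1 = [rng.random((4, m, m)).astype(np.float32) for m in sizes]
        expected = brute_force_c1(s1, cfg)
        got = h.pool_c1(s1, cfg)
        assert len(got) == len(expected) == 2
        for g, e in zip(got, expected):
            assert np.array_equal(g, e)

    def test_constant_input_pools_to_constant(self):
        s1 = [np.full((2, 30, 30), 0.25, dtype=np.float32),
              np.full((2, 25, 25), 0.25, dtype=np.float32)]
        bands = h.pool_c1(s1, HmaxConfig(n_levels=2))
        assert np.allclose(bands[0], 0.25)

    def test_impulse_reaches_exactly_covering_windows(self):
        cfg = HmaxConfig(n_levels=2)
        s1 = [np.zeros((1, 30, 30), dtype=np.float32),
              np.zeros((1, 25, 25), dtype=np.float32)]
        s1[0][0, 17, 6] = 0.9
        bands = h.pool_c1(s1, cfg)
        expected = brute_force_c1(s1, cfg)
        assert np.array_equal(bands[0], expected[0])
        hit = np.argwhere(bands[0][0] > 0)
        # windows starting at rows {10, 15} and cols {0, 5} cover (17, 6);
        # the centred cross-scale crop (5×5 grid → 4×4, round-up split)
        # drops pooled row/col 0, shifting indices by −1
        assert {tuple(x) for x in hit} == {(1, 0), (2, 0)}

    def test_orientations_never_merged(self):
        s1 = [np.zeros((2, 30, 30), dtype=np.float32),
              np.zeros((2, 25, 25), dtype=np.float32)]
        s1[0][0] = 0.8           # all activity in channel 0
        bands = h.pool_c1(s1, HmaxConfig(n_levels=2))
        assert np.all(bands[0][0] == 0.8)
        assert np.all(bands[0][1] == 0.0)


class TestPrototypes:
    def test_requested_count_and_reproducibility(self, small_c1_sets):
        _, c1_sets = small_c1_sets
        a = h.sample_prototypes(c1_sets, 25, rng=np.random.default_rng(5))
        b = h.sample_prototypes(c1_sets, 25, rng=np.random.default_rng(5))
        assert len(a) == 25
        for pa, pb in zip(a, b):
            assert pa.source == pb.source
            assert np.array_equal(pa.patch, pb.patch)

    def test_replay_from_recorded_provenance(self, small_c1_sets):
        """Every prototype is recoverable bit-for-bit from its source."""
        _, c1_sets = small_c1_sets
        for p in h.sample_prototypes(c1_sets, 40, rng=np.random.default_rng(1)):
            img, band, r, c = p.source
            n = p.size
            again = c1_sets[img][band][:, r:r + n, c:c + n]
            assert np.array_equal(p.patch, again)

    def test_invalid_requests_rejected(self, small_c1_sets):
        _, c1_sets = small_c1_sets
        with pytest.raises(ValueError):
            h.sample_prototypes(c1_sets, 0)
        with pytest.raises(ValueError):
            h.sample_prototypes([], 5)


class TestS2C2:
    def make_toy(self, seed=0, n_protos=3):
        rng = np.random.default_rng(seed)
        bands = [rng.random((12, 8, 8)).astype(np.float32),
                 rng.random((12, 6, 6)).astype(np.float32), None]
        protos = []
        for i in range(n_protos):
            b = i % 2
            r = int(rng.integers(bands[b].shape[1] - 4 + 1))
            c = int(rng.integers(bands[b].shape[2] - 4 + 1))
            protos.append(Prototype(patch=np.array(bands[b][:, r:r + 4, c:c + 4]),
                                    size=4, source=(0, b, r, c)))
        return bands, protos

    def test_fused_path_equals_explicit_maps(self):
        """c2_from_c1 must agree with apply_s2 → pool_c2 (dual route)."""
        bands, protos = self.make_toy()
        explicit = h.pool_c2(h.apply_s2(bands, protos, CFG))
        fused = h.c2_from_c1(bands, PrototypeBank(protos, CFG))
        assert np.allclose(explicit, fused, atol=1e-5)

    def test_own_patch_matches_perfectly(self):
        bands, protos = self.make_toy()
        c2 = h.c2_from_c1(bands, PrototypeBank(protos, CFG))
        assert np.allclose(c2, 1.0, atol=1e-4)

    def test_response_decreases_with_distance(self):
        assert _similarity(np.array([0.0]), 192, CFG)[0] == 1.0
        d = _similarity(np.array([0.1, 0.5, 2.0]), 192, CFG)
        assert d[0] > d[1] > d[2] > 0.0

    def test_translation_within_band_leaves_c2_unchanged(self):
        rng = np.random.default_rng(4)
        blob = rng.random((12, 4, 4)).astype(np.float32)
        a = np.zeros((12, 10, 10), dtype=np.float32)
        b = np.zeros((12, 10, 10), dtype=np.float32)
        a[:, 1:5, 1:5] = blob
        b[:, 5:9, 4:8] = blob                    # same content, shifted
        proto = [Prototype(patch=blob.copy(), size=4, source=(0, 0, 1, 1))]
        pb = PrototypeBank(proto, CFG)
        assert np.allclose(h.c2_from_c1([a], pb), h.c2_from_c1([b], pb),
                           atol=1e-6)

    def test_dot_similarity_variant(self):
        import dataclasses
        cfg = dataclasses.replace(CFG, s2_similarity="dot")
        bands, protos = self.make_toy()
        explicit = h.pool_c2(h.apply_s2(bands, protos, cfg))
        fused = h.c2_from_c1(bands, PrototypeBank(protos, cfg))
        assert np.allclose(explicit, fused, atol=1e-5)
        assert np.allclose(fused, 1.0, atol=1e-4)   # own patch, cosine = 1


class TestEncode:
    def test_deterministic_and_correct_length(self, gabor_bank, small_c1_sets):
        images, c1_sets = small_c1_sets
        protos = h.sample_prototypes(c1_sets, 30, rng=np.random.default_rng(2))
        pb = PrototypeBank(protos, CFG)
        v1 = h.encode(images[0].pixels, gabor_bank, pb)
        v2 = h.encode(images[0].pixels, gabor_bank, pb)
        assert v1.shape == (30,)
        assert np.array_equal(v1, v2)
        assert np.all((v1 > 0.0) & (v1 <= 1.0))

    def test_source_image_recovers_perfect_response(self, gabor_bank,
                                                    small_c1_sets):
        """Encoding a prototype's own source image gives that entry 1."""
        images, c1_sets = small_c1_sets
        protos = h.sample_prototypes(c1_sets, 12, rng=np.random.default_rng(8))
        pb = PrototypeBank(protos, CFG)
        for i, p in enumerate(protos[:4]):
            v = h.encode(images[p.source[0]].pixels, gabor_bank, pb)
            assert v[i] == pytest.approx(1.0, abs=1e-4)

    def test_blank_image_matches_nontrivial_prototypes_poorly(
            self, gabor_bank, small_c1_sets):
        _, c1_sets = small_c1_sets
        protos = h.sample_prototypes(c1_sets, 60, rng=np.random.default_rng(3))
        pb = PrototypeBank(protos, CFG)
        v = h.encode(np.ones((256, 256)), gabor_bank, pb)
        for i, p in enumerate(protos):
            mean_sq = float((p.patch.astype(np.float64) ** 2).mean())
            if mean_sq > 0.02:                  # a clearly non-trivial patch
                assert v[i] < 0.1
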