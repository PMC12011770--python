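"""Dynamic head: deformable sampling oracle, attention order, gate bounds."""

import numpy as np
import pytest

from pdyolo import nn
from pdyolo.backbone import FeatureMap
from pdyolo.dyhead import (DeformParams, DyHead, ScaleAttention,
                           SpatialAttention, TaskAttention, deform_conv3x3,
                           dynamic_relu)
from pdyolo.nn import Tensor
from pdyolo.nn import functional as F


def _levels(rng, c=16, sizes=(8, 4, 2)):
    return [FeatureMap(Tensor(rng.standard_normal((1, c, s, s))
                              .astype(np.float32)), st)
            for s, st in zip(sizes, (8, 16, 32))]


# -- deformable sampling primitive ------------------------------------------

def test_zero_offsets_unit_masks_match_dense_conv(rng):
    """Eq-18 sampling with no deformation is a plain 3x3 convolution."""
    x = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
    w = rng.standard_normal((5, 4, 3, 3)).astype(np.float32)
    offsets = np.zeros((2, 18, 6, 6), dtype=np.float32)
    masks = Tensor(np.ones((2, 9, 6, 6), dtype=np.float32))
    got = deform_conv3x3(x, Tensor(w.reshape(5, 4, 9)), offsets, masks).data
    ref = F.conv2d(x, Tensor(w), None, stride=1, padding=1).data
    np.testing.assert_allclose(got, ref, rtol=1e-5, atol=1e-5)


def test_integer_offset_equals_shifted_input(rng):
    """Shifting every sample by (1, 0) equals convolving the row-shifted map."""
    x = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
    w = rng.standard_normal((3, 3, 9)).astype(np.float32)
    masks = Tensor(np.ones((1, 9, 8, 8), dtype=np.float32))
    off = np.zeros((1, 18, 8, 8), dtype=np.float32)
    off[:, 0::2] = 1.0  # dy = 1 for every sampling point
    shifted = np.roll(x, -1, axis=2)
    got = deform_conv3x3(Tensor(x), Tensor(w), off, masks).data
    ref = deform_conv3x3(Tensor(shifted), Tensor(w),
                         np.zeros_like(off), masks).data
    np.testing.assert_allclose(got[:, :, 2:-2], ref[:, :, 2:-2],
                               rtol=1e-5, atol=1e-5)


def test_zero_masks_zero_output(rng):
    x = Tensor(rng.standard_normal((1, 3, 5, 5)).astype(np.float32))
    w = Tensor(rng.standard_normal((3, 3, 9)).astype(np.float32))
    out = deform_conv3x3(x, w, np.zeros((1, 18, 5, 5), np.float32),
                         Tensor(np.zeros((1, 9, 5, 5), np.float32)))
    assert np.all(out.data == 0)


# -- scale attention ---------------------------------------------------------

def test_scale_gate_bounds_and_symmetry(rng):
    att = ScaleAttention()
    levels = [f.data for f in _levels(rng)]
    out = att(levels)
    for o, i in zip(out, levels):
        assert np.all(np.abs(o.data) <= np.abs(i.data) + 1e-7)
    twin = att([levels[0], levels[0]])
    np.testing.assert_array_equal(twin[0].data, twin[1].data)


def test_scale_gate_forced_to_one_is_identity(rng):
    att = ScaleAttention()
    att.fc.weight.data[...] = 0.0
    att.fc.bias.data[...] = 100.0  # deep in the hard-sigmoid saturation
    levels = [f.data for f in _levels(rng)]
    out = att(levels)
    for o, i in zip(out, levels):
        np.testing.assert_allclose(o.data, i.data, rtol=1e-6)


# -- task attention ----------------------------------------------------------

def test_dynamic_relu_degenerate_cases(rng):
    x = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
    rect = dynamic_relu(x, 1.0, 0.0, 0.0, 0.0)
    np.testing.assert_allclose(rect.data, np.maximum(x.data, 0), rtol=1e-6)
    ident = dynamic_relu(x, 1.0, 1.0, 0.0, 0.0)
    np.testing.assert_allclose(ident.data, x.data, rtol=1e-6)


def test_dynamic_relu_monotone_for_nonnegative_slopes(rng):
    """With a1, a2 >= 0 the activation is nondecreasing in the input."""
    grid = np.sort(rng.uniform(-3, 3, 101)).astype(np.float32)
    for a1, a2, b1, b2 in rng.uniform([0, 0, -1, -1], [2, 2, 1, 1], (20, 4)):
        y = dynamic_relu(Tensor(grid), float(a1), float(a2),
                         float(b1), float(b2)).data
        assert np.all(np.diff(y) >= -1e-6)


def test_task_attention_coefficients_bounded(rng):
    att = TaskAttention(16)
    f = Tensor(rng.standard_normal((2, 16, 4, 4)).astype(np.float32))
    a1, a2, b1, b2 = att.coefficients(f)
    assert np.all(np.abs(a1.data - 1.0) < 1.0)   # a1 in (0, 2)
    for v in (a2, b1, b2):
        assert np.all(np.abs(v.data) < 1.0)


# -- full head ---------------------------------------------------------------

def test_shapes_preserved_through_blocks(rng):
    for n_blocks in (1, 2):
        head = DyHead(16, n_blocks)
        head.eval()
        levels = _levels(rng)
        with nn.no_grad():
            out = head(levels)
        for o, i in zip(out, levels):
            assert o.data.shape == i.data.shape
            assert o.stride == i.stride


def test_zero_blocks_is_identity(rng):
    head = DyHead(16, 0)
    levels = _levels(rng)
    out = head(levels)
    for o, i in zip(out, levels):
        np.testing.assert_array_equal(o.data.data, i.data.data)


def test_eval_mode_deterministic(rng):
    head = DyHead(16, 2)
    head.eval()
    levels = _levels(rng)
    with nn.no_grad():
        a = head(levels)
        b = head(levels)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.data.data, y.data.data)


def test_attention_order_matters(rng):
    """Applying (scale, spatial, task) in a permuted order changes outputs."""
    block_chan = 16
    scale, spatial, task = (ScaleAttention(), SpatialAttention(block_chan),
                            TaskAttention(block_chan))
    levels = [f.data for f in _levels(rng, c=block_chan, sizes=(4, 4, 4))]
    with nn.no_grad():
        ordered = task(spatial(scale(levels)))
        permuted = scale(spatial(task(levels)))
    assert any(not np.allclose(a.data, b.data)
               for a, b in zip(ordered, permuted))
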