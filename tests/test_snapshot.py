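"""Rotation-grid combinatorics and deterministic rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snapqsar as sq
from snapqsar.snapshot import (
    BACKGROUND_COLORS,
    encode_png,
    rotation_grid,
    rotation_matrix,
    snap_molecule,
    snapshot_filename,
)


def brute_force_axis(theta):
    """Independent oracle: enumerate multiples of theta in [0, 360)."""
    angles, k = [], 0
    while k * theta < 360:
        angles.append(k * theta)
        k += 1
    return angles


@pytest.mark.parametrize(
    "theta, expected", [(120, 27), (180, 8), (240, 8), (300, 8), (360, 1), (90, 64)]
)
def test_grid_sizes(theta, expected):
    assert len(rotation_grid(theta)) == expected


@settings(max_examples=60, derandomize=True, deadline=None)
@given(theta=st.integers(min_value=36, max_value=360))
def test_grid_matches_brute_force(theta):
    axis = brute_force_axis(theta)
    grid = rotation_grid(theta)
    assert len(grid) == len(axis) ** 3 == math.ceil(360 / theta) ** 3
    assert grid == [(x, y, z) for x in axis for y in axis for z in axis]
    assert len(set(grid)) == len(grid)
    assert all(0 <= a < 360 for t in grid for a in t)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(theta=st.integers(min_value=1, max_value=360))
def test_axis_angles_match_brute_force_all_increments(theta):
    """Per-axis angle list equals the enumerated multiples for every integer
    increment, so |grid| = ceil(360/theta)^3 without materializing the cube."""
    axis = brute_force_axis(theta)
    assert len(axis) == math.ceil(360 / theta)
    grid_axis = sorted({t[0] for t in rotation_grid(max(theta, 36))})
    assert grid_axis == brute_force_axis(max(theta, 36))


@pytest.mark.parametrize("theta", [0, -5, 361])
def test_grid_rejects_bad_increment(theta):
    with pytest.raises(ValueError):
        rotation_grid(theta)


def test_render_dimensions_default(methane):
    img = sq.render_snapshot(methane, (0, 0, 0), sq.RenderConfig())
    assert img.shape == (256, 256, 3)
    assert img.dtype == np.uint8


def test_corners_equal_background(methane):
    for name, rgb in BACKGROUND_COLORS.items():
        cfg = sq.RenderConfig(image_px=64, background_rgb=rgb)
        img = sq.render_snapshot(methane, (0, 0, 0), cfg)
        for corner in (img[0, 0], img[0, -1], img[-1, 0], img[-1, -1]):
            assert tuple(corner) == rgb, name


def test_single_atom_white_background():
    mol = sq.Molecule(id="c1", atoms=[("C", 0.0, 0.0, 0.0)], bonds=[])
    img = sq.render_snapshot(mol, (0, 0, 0), sq.RenderConfig(image_px=64))
    assert tuple(img[0, 0]) == (255, 255, 255)
    # sphere visible in the middle
    assert tuple(img[32, 32]) != (255, 255, 255)


def test_render_byte_deterministic(benzene, fast_render):
    a = encode_png(sq.render_snapshot(benzene, (120, 0, 240), fast_render))
    b = encode_png(sq.render_snapshot(benzene, (120, 0, 240), fast_render))
    assert a == b


def test_background_changes_only_uncovered_pixels(benzene, fast_render):
    white = sq.render_snapshot(benzene, (0, 0, 0), fast_render)
    cfg = sq.RenderConfig(image_px=96, background_rgb=(0, 0, 255))
    blue = sq.render_snapshot(benzene, (0, 0, 0), cfg)
    was_bg = np.all(white == 255, axis=2)
    # geometry pixels identical under both backgrounds
    assert np.array_equal(white[~was_bg], blue[~was_bg])
    assert np.all(blue[was_bg] == np.array([0, 0, 255]))


def test_rotation_consistency(benzene, fast_render):
    """Pre-rotating coordinates equals passing the rotation to the renderer."""
    rot = (120.0, 240.0, 300.0)
    R = rotation_matrix(*rot)
    coords = benzene.coordinates() - benzene.coordinates().mean(axis=0)
    rotated = coords @ R.T
    pre = sq.Molecule(
        id=benzene.id,
        atoms=[(s, *xyz) for (s, *_), xyz in zip(benzene.atoms, rotated)],
        bonds=list(benzene.bonds),
    )
    img_arg = sq.render_snapshot(benzene, rot, fast_render)
    img_pre = sq.render_snapshot(pre, (0, 0, 0), fast_render)
    frac_diff = np.mean(np.any(img_arg != img_pre, axis=2))
    assert frac_diff <= 0.01


def test_empty_molecule_rejected(fast_render):
    empty = sq.Molecule(id="none", atoms=[], bonds=[])
    with pytest.raises(ValueError):
        sq.render_snapshot(empty, (0, 0, 0), fast_render)


def test_coincident_atoms_render_single_sphere(fast_render):
    mol = sq.Molecule(
        id="coincident",
        atoms=[("C", 0.0, 0.0, 0.0), ("C", 0.0, 0.0, 0.0)],
        bonds=[(0, 1, 1)],
    )
    img = sq.render_snapshot(mol, (0, 0, 0), fast_render)  # no error
    assert img.shape == (96, 96, 3)


@pytest.mark.parametrize("theta, n", [(300, 8), (120, 27)])
def test_snap_molecule_file_counts(tmp_path, methane, theta, n):
    cfg = sq.RenderConfig(angle_increment_deg=theta, image_px=48)
    ss = snap_molecule(methane, cfg, out_dir=tmp_path)
    assert len(ss) == n
    assert len(list(tmp_path.glob("*.png"))) == n
    assert len(set(ss.rotations())) == n


def test_two_molecules_disjoint_filenames(methane, benzene):
    grid = rotation_grid(300)
    a = {snapshot_filename(methane.id, r) for r in grid}
    b = {snapshot_filename(benzene.id, r) for r in grid}
    assert not (a & b)


def test_select_combination_subsets(methane):
    cfg = sq.RenderConfig(angle_increment_deg=300, image_px=48)
    ss = snap_molecule(methane, cfg)
    two = sq.select_combination(ss, [(0, 0, 0), (0, 300, 0)])
    assert two.rotations() == [(0, 0, 0), (0, 300, 0)]
    # published combination lists include repeated tuples
    rep = sq.select_combination(ss, [(0, 300, 300), (0, 300, 300), (300, 300, 0)])
    assert len(rep) == 3
    assert rep.rotations()[0] == rep.rotations()[1]
    full = sq.select_combination(ss, ss.rotations())
    assert full.rotations() == ss.rotations()
    with pytest.raises(KeyError, match="150"):
        sq.select_combination(ss, [(150, 0, 0)])


def test_render_config_validation():
    with pytest.raises(ValueError):
        sq.RenderConfig(image_px=8)
    with pytest.raises(ValueError):
        sq.RenderConfig(background_rgb=(256, 0, 0))
    with pytest.raises(ValueError):
        sq.RenderConfig(zoom_factor_pct=0)
    assert sq.RenderConfig.with_background("black").background_rgb == (0, 0, 0)
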