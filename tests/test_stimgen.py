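import numpy as np
import pytest

from gnet import io
from gnet.stimgen import (
    Category,
    NOVEL_CATEGORIES,
    GenerationConfig,
    Stimulus,
    generate_pool,
    make_variant,
    random_stimulus,
    render_stimulus,
)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GenerationConfig(n_elements=10).validate()  # > 9 cells
    with pytest.raises(ValueError):
        GenerationConfig(n_colors=0).validate()
    with pytest.raises(ValueError):
        random_stimulus(GenerationConfig(n_elements=10), np.random.default_rng(0))


def test_random_stimulus_structure_and_determinism():
    cfg = GenerationConfig()
    s1 = random_stimulus(cfg, np.random.default_rng(5))
    s2 = random_stimulus(cfg, np.random.default_rng(5))
    assert s1.layout.sum() == 5
    s1.validate(cfg)
    assert s1.same_vectors(s2)


def test_random_stimulus_uniform_marginals():
    """Per-cell fill ~ 5/9, shape marginal ~ 1/3, color marginal ~ 1/6."""
    cfg = GenerationConfig()
    rng = np.random.default_rng(0)
    n = 10_000
    fills = np.zeros(9)
    shapes = np.zeros(4)
    colors = np.zeros(7)
    for _ in range(n):
        s = random_stimulus(cfg, rng)
        fills += s.layout
        for v in s.shapes[s.shapes > 0]:
            shapes[v] += 1
        for v in s.colors[s.colors > 0]:
            colors[v] += 1
    # ~4 binomial SEs
    assert np.all(np.abs(fills / n - 5 / 9) < 4 * np.sqrt((5 / 9) * (4 / 9) / n))
    assert np.all(np.abs(shapes[1:] / (5 * n) - 1 / 3) < 0.02)
    assert np.all(np.abs(colors[1:] / (5 * n) - 1 / 6) < 0.02)


def test_pool_structure(pool):
    cfg = pool.config
    assert len(pool.familiars) == 5
    assert len(pool.unused_originals) == 5
    assert len(pool.novels) == 100
    for cat in NOVEL_CATEGORIES:
        assert len(pool.novels_by_category(cat)) == 20
    step1 = [*pool.familiars, *pool.unused_originals]
    layouts = {tuple(s.layout) for s in step1}
    assert len(layouts) == 10
    # each familiar has exactly 4 novels per familiar-derived category
    for fam in pool.familiars:
        for cat in NOVEL_CATEGORIES[:-1]:
            kids = [s for s in pool.novels_by_category(cat) if s.base_familiar_id == fam.id]
            assert len(kids) == 4
    # fully novel quartets pair bijectively onto the familiars
    fn = pool.novels_by_category(Category.FULLY_NOVEL)
    paired = {s.base_familiar_id for s in fn}
    assert paired == {f.id for f in pool.familiars}
    del cfg


def test_category_invariants(pool):
    by_id = {s.id: s for s in pool.all_stimuli()}
    step1 = [*pool.familiars, *pool.unused_originals]
    for s in pool.novels:
        base = by_id[s.base_familiar_id]
        if s.category is Category.NOVEL_COLOR_COMBINATIONS:
            assert np.array_equal(s.layout, base.layout)
            assert np.array_equal(s.shapes, base.shapes)
            used = set(s.colors[s.colors > 0])
            assert used <= set(base.colors[base.colors > 0])
        elif s.category is Category.NOVEL_SHAPES:
            assert np.array_equal(s.layout, base.layout)
            assert np.array_equal(s.colors, base.colors)
            assert not np.array_equal(s.shapes, base.shapes)
        elif s.category is Category.NOVEL_COLORS:
            assert np.array_equal(s.layout, base.layout)
            assert np.array_equal(s.shapes, base.shapes)
            assert not np.array_equal(s.colors, base.colors)
        elif s.category is Category.NOVEL_COLORS_AND_SHAPES:
            assert np.array_equal(s.layout, base.layout)
        else:  # FULLY_NOVEL: layout from its unused original, not the familiar
            origin = s.id.split("-")[1]
            assert np.array_equal(s.layout, by_id[origin].layout)
        # no novel duplicates its base or (for step-2 categories) any step-1 stimulus
        if s.category in (Category.NOVEL_COLORS_AND_SHAPES, Category.FULLY_NOVEL):
            assert not any(s.same_vectors(t) for t in step1)
        else:
            assert not s.same_vectors(base)


def test_generation_deterministic(pool):
    again = generate_pool(seed=1)
    assert io.pool_to_dict(again) == io.pool_to_dict(pool)


def test_make_variant_usage_errors(pool):
    cfg = pool.config
    rng = np.random.default_rng(0)
    fam = pool.familiars[0]
    with pytest.raises(ValueError):
        make_variant(fam, Category.FAMILIAR, cfg, rng)
    with pytest.raises(ValueError):
        # fully novel variants derive from unused originals, not familiars
        make_variant(fam, Category.FULLY_NOVEL, cfg, rng)
    with pytest.raises(ValueError):
        make_variant(pool.novels[0], Category.NOVEL_SHAPES, cfg, rng)


def test_novel_colors_keeps_shapes_even_when_uniform():
    """A familiar whose five cells share one shape keeps that shapes vector
    under color re-randomization."""
    cfg = GenerationConfig()
    layout = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
    shapes = layout * 2
    colors = np.array([1, 2, 3, 4, 5, 0, 0, 0, 0])
    fam = Stimulus(layout, shapes, colors, id="F1", category=Category.FAMILIAR)
    v = make_variant(fam, Category.NOVEL_COLORS, cfg, np.random.default_rng(3))
    assert np.array_equal(v.shapes, fam.shapes)
    assert not np.array_equal(v.colors, fam.colors)


def test_variant_collision_resampling_is_bounded():
    """A degenerate config (one shape) makes a novel-shapes variant impossible."""
    from gnet.stimgen import GenerationError

    cfg = GenerationConfig(n_shapes=1)
    fam = random_stimulus(cfg, np.random.default_rng(0), category=Category.FAMILIAR)
    with pytest.raises(GenerationError):
        make_variant(fam, Category.NOVEL_SHAPES, cfg, np.random.default_rng(1))


# --------------------------------------------------------------------------
# Rendering


def test_render_rejects_invalid_stimulus():
    bad = Stimulus(np.zeros(9, int), np.zeros(9, int), np.zeros(9, int), id="bad",
                   category=Category.FAMILIAR)
    with pytest.raises(ValueError):
        render_stimulus(bad, 60)


def test_render_rejects_tiny_pixel_size(pool):
    with pytest.raises(ValueError):
        render_stimulus(pool.familiars[0], 10)


def test_render_deterministic_and_color_faithful(pool):
    s = pool.familiars[0]
    img1 = render_stimulus(s, 60)
    img2 = render_stimulus(s, 60)
    assert img1.tobytes() == img2.tobytes()
    pixels = set(img1.getdata())
    pixels.discard((255, 255, 255))  # background
    n_colors = len(set(s.colors[s.colors > 0]))
    assert len(pixels) == n_colors
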