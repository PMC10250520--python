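"""Stimulus generation for the Graded Novelty Encoding Task (GNET).

A GNET stimulus is a 3x3 grid holding five colored geometric shapes, encoded
as three length-9 vectors (row-major flattening of the grid):

* ``layout``: 1 where a cell is filled, 0 where it is empty;
* ``shapes``: 0 for empty cells, otherwise 1 = circle, 2 = square, 3 = triangle;
* ``colors``: 0 for empty cells, otherwise a palette index 1..6
  (1 = red, 2 = green, 3 = blue, 4 = yellow, 5 = orange, 6 = purple).

The pool-generation algorithm proceeds in three steps:

1. Draw 10 fully random stimuli with pairwise-distinct layouts. The first
   five become the *familiars* that participants memorize; the last five are
   *unused originals* that only donate their layouts.
2. For each Step-1 stimulus, draw four variants that keep its layout but
   re-randomize shapes and colors. Variants of familiars form the *novel
   colors and shapes* category; variants of unused originals form the
   *fully novel* category. None of these may equal any Step-1 stimulus.
3. For each familiar, draw four variants per remaining category:
   *novel shapes* (re-randomized shapes), *novel colors* (re-randomized
   colors), and *novel color combinations* (colors re-drawn from the set of
   distinct colors already present in the familiar). None may equal its base.

Re-randomization is uniform *with replacement* per cell — a cell may keep its
original value — followed by a whole-stimulus collision check, so the expected
number of changed cells per matrix is ``n_elements * (1 - 1/n_values)``.

Each fully-novel quartet is randomly paired (a bijection) with a familiar so
that a "difference to the corresponding familiar" is defined for it as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Category",
    "NOVEL_CATEGORIES",
    "GenerationConfig",
    "Stimulus",
    "StimulusPool",
    "GenerationError",
    "random_stimulus",
    "make_variant",
    "generate_pool",
    "render_stimulus",
    "DEFAULT_PALETTE",
    "SHAPE_NAMES",
]

#: Retry cap for the whole-stimulus collision check. Collisions are
#: astronomically rare at the default configuration; the cap guards
#: degenerate configurations (e.g. a one-color palette).
MAX_COLLISION_RETRIES = 1000


class Category(str, Enum):
    """Stimulus categories; novel categories are ordered by expected DTF."""

    FAMILIAR = "FAMILIAR"
    UNUSED_ORIGINAL = "UNUSED_ORIGINAL"
    NOVEL_COLOR_COMBINATIONS = "NOVEL_COLOR_COMBINATIONS"
    NOVEL_SHAPES = "NOVEL_SHAPES"
    NOVEL_COLORS = "NOVEL_COLORS"
    NOVEL_COLORS_AND_SHAPES = "NOVEL_COLORS_AND_SHAPES"
    FULLY_NOVEL = "FULLY_NOVEL"


#: The five novel categories in the canonical low-to-high expected-difference
#: order used for ordinal contrasts in the analysis module.
NOVEL_CATEGORIES: tuple[Category, ...] = (
    Category.NOVEL_COLOR_COMBINATIONS,
    Category.NOVEL_SHAPES,
    Category.NOVEL_COLORS,
    Category.NOVEL_COLORS_AND_SHAPES,
    Category.FULLY_NOVEL,
)

SHAPE_NAMES: Mapping[int, str] = {1: "circle", 2: "square", 3: "triangle"}

#: Palette index -> RGB, used by :func:`render_stimulus`.
DEFAULT_PALETTE: Mapping[int, tuple[int, int, int]] = {
    1: (220, 40, 40),    # red
    2: (40, 160, 60),    # green
    3: (45, 90, 220),    # blue
    4: (235, 210, 35),   # yellow
    5: (240, 140, 30),   # orange
    6: (140, 60, 190),   # purple
}


class GenerationError(RuntimeError):
    """Raised when stimulus generation cannot satisfy its constraints."""


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the pool-generation algorithm.

    The defaults reproduce the task as used in practice: five elements on a
    3x3 grid, three shapes, six colors, five familiars, and four variants of
    each base stimulus per category.
    """

    n_rows: int = 3
    n_cols: int = 3
    n_elements: int = 5
    n_shapes: int = 3
    n_colors: int = 6
    variants_per_familiar: int = 4
    n_familiars: int = 5
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def validate(self) -> None:
        counts = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_elements": self.n_elements,
            "n_shapes": self.n_shapes,
            "n_colors": self.n_colors,
            "variants_per_familiar": self.variants_per_familiar,
            "n_familiars": self.n_familiars,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_elements > self.n_cells:
            raise ValueError(
                f"n_elements={self.n_elements} exceeds grid size "
                f"{self.n_rows}x{self.n_cols}={self.n_cells}"
            )


@dataclass(frozen=True)
class Stimulus:
    """One GNET picture: three parallel categorical vectors over the grid."""

    layout: np.ndarray
    shapes: np.ndarray
    colors: np.ndarray
    id: str
    category: Category
    base_familiar_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("layout", "shapes", "colors"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))

    def validate(self, config: GenerationConfig | None = None) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        cfg = config or GenerationConfig()
        n = cfg.n_cells
        if not (len(self.layout) == len(self.shapes) == len(self.colors) == n):
            raise ValueError(f"stimulus {self.id}: vectors must have length {n}")
        if not np.isin(self.layout, (0, 1)).all():
            raise ValueError(f"stimulus {self.id}: layout must be 0/1")
        if self.layout.sum() != cfg.n_elements:
            raise ValueError(
                f"stimulus {self.id}: layout must contain exactly "
                f"{cfg.n_elements} filled cells, got {int(self.layout.sum())}"
            )
        filled = self.layout == 1
        if ((self.shapes > 0) != filled).any() or ((self.colors > 0) != filled).any():
            raise ValueError(
                f"stimulus {self.id}: shapes/colors must be non-zero exactly "
                "on filled cells"
            )
        if (self.shapes[filled] > cfg.n_shapes).any():
            raise ValueError(f"stimulus {self.id}: shape code out of range")
        if (self.colors[filled] > cfg.n_colors).any():
            raise ValueError(f"stimulus {self.id}: color code out of range")

    def same_vectors(self, other: "Stimulus") -> bool:
        """Element-wise equality of all three matrices."""
        return (
            np.array_equal(self.layout, other.layout)
            and np.array_equal(self.shapes, other.shapes)
            and np.array_equal(self.colors, other.colors)
        )

    def as_stack(self) -> np.ndarray:
        """The three vectors concatenated into one code vector (for metrics)."""
        return np.concatenate([self.layout, self.shapes, self.colors])


@dataclass
class StimulusPool:
    """A complete generated stimulus set.

    ``novels`` holds 100 stimuli at the default configuration — 20 per
    novel category — each carrying the identifier of the familiar its
    difference-to-familiar score is computed against.
    """

    familiars: list[Stimulus]
    unused_originals: list[Stimulus]
    novels: list[Stimulus]
    seed: int
    config: GenerationConfig = field(default_factory=GenerationConfig)

    def all_stimuli(self) -> list[Stimulus]:
        return [*self.familiars, *self.unused_originals, *self.novels]

    def by_id(self, stimulus_id: str) -> Stimulus:
        for s in self.all_stimuli():
            if s.id == stimulus_id:
                return s
        raise KeyError(stimulus_id)

    def novels_by_category(self, category: Category) -> list[Stimulus]:
        return [s for s in self.novels if s.category is category]

    def validate(self) -> None:
        cfg = self.config
        cfg.validate()
        for s in self.all_stimuli():
            s.validate(cfg)
        step1 = [*self.familiars, *self.unused_originals]
        layouts = {tuple(s.layout) for s in step1}
        if len(layouts) != len(step1):
            raise ValueError("Step-1 layouts are not pairwise distinct")
        for cat in NOVEL_CATEGORIES:
            n_expected = cfg.n_familiars * cfg.variants_per_familiar
            got = len(self.novels_by_category(cat))
            if got != n_expected:
                raise ValueError(f"category {cat.value}: expected {n_expected} novels, got {got}")
        fam_ids = {f.id for f in self.familiars}
        for s in self.novels:
            if s.base_familiar_id not in fam_ids:
                raise ValueError(f"novel {s.id} has no valid base familiar pairing")
            if any(s.same_vectors(t) for t in step1):
                raise ValueError(f"novel {s.id} duplicates a Step-1 stimulus")


# --------------------------------------------------------------------------
# Step 0: fully random stimuli


def random_stimulus(
    config: GenerationConfig,
    rng: np.random.Generator,
    *,
    id: str = "S",
    category: Category = Category.FAMILIAR,
) -> Stimulus:
    """Draw one fully random stimulus.

    The filled cells are a uniform draw of ``n_elements`` of the grid cells;
    each filled cell receives an independent uniform shape and color.
    """
    config.validate()
    n = config.n_cells
    layout = np.zeros(n, dtype=int)
    filled = rng.choice(n, size=config.n_elements, replace=False)
    layout[filled] = 1
    shapes = np.zeros(n, dtype=int)
    colors = np.zeros(n, dtype=int)
    shapes[filled] = rng.integers(1, config.n_shapes + 1, size=config.n_elements)
    colors[filled] = rng.integers(1, config.n_colors + 1, size=config.n_elements)
    return Stimulus(layout, shapes, colors, id=id, category=category)


# --------------------------------------------------------------------------
# Steps 2-3: category variants


def _randomize(
    base: Stimulus,
    category: Category,
    config: GenerationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One unconditioned re-randomization draw for the given category."""
    filled = np.flatnonzero(base.layout)
    k = len(filled)
    shapes = base.shapes.copy()
    colors = base.colors.copy()
    if category in (Category.NOVEL_SHAPES, Category.NOVEL_COLORS_AND_SHAPES, Category.FULLY_NOVEL):
        shapes[filled] = rng.integers(1, config.n_shapes + 1, size=k)
    if category in (Category.NOVEL_COLORS, Category.NOVEL_COLORS_AND_SHAPES, Category.FULLY_NOVEL):
        colors[filled] = rng.integers(1, config.n_colors + 1, size=k)
    if category is Category.NOVEL_COLOR_COMBINATIONS:
        # Colors drawn uniformly from the SET of distinct colors of the base.
        palette = np.unique(base.colors[filled])
        colors[filled] = rng.choice(palette, size=k, replace=True)
    return base.layout.copy(), shapes, colors


def make_variant(
    base: Stimulus,
    category: Category,
    config: GenerationConfig,
    rng: np.random.Generator,
    *,
    id: str | None = None,
    forbidden: Sequence[Stimulus] | None = None,
) -> Stimulus:
    """Generate one category variant of ``base``.

    ``forbidden`` lists stimuli the variant must not equal element-wise; it
    defaults to the base alone. Draws are repeated (uniform with replacement
    per cell) until the variant avoids all forbidden stimuli, up to
    :data:`MAX_COLLISION_RETRIES` attempts.
    """
    if category in (Category.FAMILIAR, Category.UNUSED_ORIGINAL):
        raise ValueError(f"cannot make a variant of category {category.value}")
    if category is Category.FULLY_NOVEL:
        if base.category is not Category.UNUSED_ORIGINAL:
            raise ValueError("FULLY_NOVEL variants derive from an unused original")
    elif base.category is not Category.FAMILIAR:
        raise ValueError(f"{category.value} variants derive from a familiar")
    avoid = list(forbidden) if forbidden is not None else [base]
    for _ in range(MAX_COLLISION_RETRIES):
        layout, shapes, colors = _randomize(base, category, config, rng)
        candidate = Stimulus(
            layout,
            shapes,
            colors,
            id=id or f"{category.value}:{base.id}",
            category=category,
            base_familiar_id=base.id if base.category is Category.FAMILIAR else None,
        )
        if not any(candidate.same_vectors(s) for s in avoid):
            return candidate
    raise GenerationError(
        f"could not draw a {category.value} variant of {base.id} distinct from "
        f"{len(avoid)} forbidden stimuli in {MAX_COLLISION_RETRIES} attempts"
    )


# --------------------------------------------------------------------------
# The full three-step pool


_CATEGORY_TAGS = {
    Category.NOVEL_COLOR_COMBINATIONS: "NCC",
    Category.NOVEL_SHAPES: "NS",
    Category.NOVEL_COLORS: "NC",
    Category.NOVEL_COLORS_AND_SHAPES: "NCS",
    Category.FULLY_NOVEL: "FN",
}


def generate_pool(config: GenerationConfig | None = None, seed: int | None = None) -> StimulusPool:
    """Run the three-step algorithm and return a validated pool.

    Generation is a pure function of the configuration (including its seed);
    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or GenerationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # Step 1: 10 random stimuli with pairwise distinct layouts.
    step1: list[Stimulus] = []
    seen_layouts: set[tuple[int, ...]] = set()
    attempts = 0
    while len(step1) < 2 * cfg.n_familiars:
        idx = len(step1)
        is_familiar = idx < cfg.n_familiars
        stim = random_stimulus(
            cfg,
            rng,
            id=f"F{idx + 1}" if is_familiar else f"U{idx - cfg.n_familiars + 1}",
            category=Category.FAMILIAR if is_familiar else Category.UNUSED_ORIGINAL,
        )
        attempts += 1
        if attempts > MAX_COLLISION_RETRIES * 2 * cfg.n_familiars:
            raise GenerationError("cannot draw valid pairwise-distinct Step-1 stimuli")
        if tuple(stim.layout) in seen_layouts:
            continue
        # A familiar with a single distinct color makes the novel-color-
        # combinations category unsatisfiable (every draw equals the base),
        # so such familiars (probability 6^-4 per draw) are redrawn.
        if is_familiar and len(np.unique(stim.colors[stim.layout == 1])) < 2:
            continue
        seen_layouts.add(tuple(stim.layout))
        step1.append(stim)
    familiars = step1[: cfg.n_familiars]
    unused = step1[cfg.n_familiars:]

    novels: list[Stimulus] = []

    def add_variants(base: Stimulus, category: Category, forbidden: Sequence[Stimulus]) -> None:
        tag = _CATEGORY_TAGS[category]
        for k in range(cfg.variants_per_familiar):
            novels.append(
                make_variant(
                    base, category, cfg, rng,
                    id=f"{tag}-{base.id}-{k + 1}", forbidden=forbidden,
                )
            )

    # Step 2: layout-preserving full re-randomizations, checked against ALL
    # Step-1 stimuli.
    for fam in familiars:
        add_variants(fam, Category.NOVEL_COLORS_AND_SHAPES, step1)
    for orig in unused:
        add_variants(orig, Category.FULLY_NOVEL, step1)

    # Step 3: single-matrix categories, checked against their own base.
    for fam in familiars:
        add_variants(fam, Category.NOVEL_SHAPES, [fam])
        add_variants(fam, Category.NOVEL_COLORS, [fam])
        add_variants(fam, Category.NOVEL_COLOR_COMBINATIONS, [fam])

    # Random bijective pairing of fully-novel quartets to familiars.
    perm = rng.permutation(cfg.n_familiars)
    pairing = {unused[i].id: familiars[perm[i]].id for i in range(cfg.n_familiars)}
    for i, s in enumerate(novels):
        if s.category is Category.FULLY_NOVEL:
            origin = s.id.split("-")[1]  # "FN-U3-2" -> "U3"
            novels[i] = replace(s, base_familiar_id=pairing[origin])

    pool = StimulusPool(familiars, unused, novels, seed=cfg.seed, config=cfg)
    pool.validate()
    return pool


# --------------------------------------------------------------------------
# Rendering


def render_stimulus(
    stimulus: Stimulus,
    pixel_size: int = 100,
    palette_map: Mapping[int, tuple[int, int, int]] | None = None,
    *,
    background: tuple[int, int, int] = (255, 255, 255),
    config: GenerationConfig | None = None,
):
    """Rasterize a stimulus as a PIL image (one ``pixel_size`` square per cell).

    Shapes are drawn without antialiasing or outlines, so the set of distinct
    non-background pixel colors equals the set of palette colors present in
    the stimulus.
    """
    from PIL import Image, ImageDraw

    cfg = config or GenerationConfig()
    stimulus.validate(cfg)
    if pixel_size < 30:
        raise ValueError("pixel_size must be at least 30")
    palette = dict(palette_map or DEFAULT_PALETTE)
    img = Image.new("RGB", (cfg.n_cols * pixel_size, cfg.n_rows * pixel_size), background)
    draw = ImageDraw.Draw(img)
    margin = max(2, pixel_size // 10)
    for i in range(cfg.n_cells):
        if stimulus.layout[i] == 0:
            continue
        shape = int(stimulus.shapes[i])
        color_code = int(stimulus.colors[i])
        if shape not in SHAPE_NAMES:
            raise ValueError(f"unknown shape code {shape} in stimulus {stimulus.id}")
        if color_code not in palette:
            raise ValueError(f"unknown color code {color_code} in stimulus {stimulus.id}")
        row, col = divmod(i, cfg.n_cols)
        x0 = col * pixel_size + margin
        y0 = row * pixel_size + margin
        x1 = (col + 1) * pixel_size - margin
        y1 = (row + 1) * pixel_size - margin
        fill = tuple(palette[color_code])
        if shape == 1:
            draw.ellipse([x0, y0, x1, y1], fill=fill)
        elif shape == 2:
            draw.rectangle([x0, y0, x1, y1], fill=fill)
        else:
            draw.polygon([((x0 + x1) // 2, y0), (x0, y1), (x1, y1)], fill=fill)
    return img
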