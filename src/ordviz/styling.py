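"""Map metadata to visual attributes.

Categorical columns get colors from a repeating discrete palette in
first-appearance order; continuous columns are min-max mapped through a
piecewise-linear colormap.  Size, opacity and visibility are assigned per
category with explicit overrides.  All palettes and colormaps are plain
numeric constants (and loadable from a small text config), so serialized
bundles are self-describing and bit-identical across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .io_formats import MISSING, MetadataTable, ValidationError

RGB = tuple[int, int, int]

#: Color given to samples whose gradient value is missing ("Unknown").
UNKNOWN_COLOR: RGB = (64, 64, 64)

#: Discrete palette for categorical metadata, 24 distinguishable colors.
CATEGORICAL_24: tuple[RGB, ...] = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
    (57, 59, 121), (140, 162, 82), (189, 158, 57), (173, 73, 74),
)


@dataclass(frozen=True)
class Colormap:
    """A named piecewise-linear colormap given by ordered RGB stops."""

    name: str
    stops: tuple[tuple[float, RGB], ...]

    def __post_init__(self) -> None:
        if len(self.stops) < 2:
            raise ValidationError("a colormap needs at least 2 stops")
        positions = [p for p, _ in self.stops]
        if positions[0] != 0.0 or positions[-1] != 1.0:
            raise ValidationError("colormap stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError("colormap positions must strictly increase")

    def __call__(self, t: float) -> RGB:
        return interpolate_colormap(self, t)


BLUE_RED = Colormap("blue-red", ((0.0, (0, 0, 255)), (1.0, (255, 0, 0))))

# ColorBrewer-style diverging rainbow, 11 stops.
SPECTRAL = Colormap(
    "spectral",
    tuple(
        (i / 10.0, rgb)
        for i, rgb in enumerate(
            [
                (158, 1, 66), (213, 62, 79), (244, 109, 67), (253, 174, 97),
                (254, 224, 139), (255, 255, 191), (230, 245, 152),
                (171, 221, 164), (102, 194, 165), (50, 136, 189),
                (94, 79, 162),
            ]
        )
    ),
)

COLORMAPS: dict[str, Colormap] = {c.name: c for c in (BLUE_RED, SPECTRAL)}


@dataclass
class StyleMap:
    """Visual attributes for one metadata value or one sample."""

    key: str
    color: RGB
    opacity: float = 1.0
    scale: float = 1.0
    visible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise ValidationError("opacity must be in [0, 1]")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")


def _round_half_away(x: float) -> int:
    # channels are non-negative, so half-away-from-zero == floor(x + 0.5)
    return int(math.floor(x + 0.5))


def interpolate_colormap(cmap: Colormap, t: float) -> RGB:
    """Piecewise-linear per-channel interpolation, rounded half away from
    zero so bundles are bit-identical across platforms."""
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"colormap position {t} outside [0, 1]")
    stops = cmap.stops
    for (p0, c0), (p1, c1) in zip(stops, stops[1:]):
        if t <= p1:
            f = (t - p0) / (p1 - p0)
            return tuple(
                _round_half_away(a + (b - a) * f) for a, b in zip(c0, c1)
            )  # type: ignore[return-value]
    return stops[-1][1]


def assign_categorical_colors(
    values: Iterable[str],
    palette: Sequence[RGB] = CATEGORICAL_24,
) -> dict[str, StyleMap]:
    """Assign palette colors to categories in first-appearance order,
    wrapping modularly when there are more categories than colors."""
    if not palette:
        raise ValidationError("empty palette")
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v)
    return {
        cat: StyleMap(cat, tuple(palette[i % len(palette)]))
        for i, cat in enumerate(seen)
    }


def assign_gradient_colors(
    meta: MetadataTable,
    column: str,
    cmap: Colormap = BLUE_RED,
) -> dict[str, StyleMap]:
    """Color each sample by its position along a numeric metadata column.

    Missing ("Unknown") samples get :data:`UNKNOWN_COLOR` and stay visible.
    """
    vals, missing = meta.numeric_column(column)
    present = vals[~missing]
    if present.size == 0:
        raise ValidationError(f"column {column!r} has no numeric values")
    vmin, vmax = float(present.min()), float(present.max())
    if vmax == vmin:
        raise ValidationError(
            f"column {column!r} has zero gradient range"
        )
    styles = {}
    for sid, v, miss in zip(meta.sample_ids, vals, missing):
        if miss:
            styles[sid] = StyleMap(sid, UNKNOWN_COLOR)
        else:
            t = (v - vmin) / (vmax - vmin)
            styles[sid] = StyleMap(sid, interpolate_colormap(cmap, t))
    return styles


def build_category_styles(
    meta: MetadataTable,
    column: str,
    per_category: Mapping[str, tuple[float, float, bool]] = {},
    palette: Sequence[RGB] = CATEGORICAL_24,
) -> dict[str, StyleMap]:
    """Per-category styles with (scale, opacity, visible) overrides.

    Unlisted categories get the defaults (scale 1, opacity 1, visible);
    hidden categories keep their color so visibility stays separate from
    coloring.  An override naming a category absent from the column is an
    error.
    """
    cats = meta.categories(column)
    unknown = set(per_category) - set(cats)
    if unknown:
        raise ValidationError(
            f"overrides reference unknown categories in {column!r}: "
            + ", ".join(sorted(unknown))
        )
    colors = assign_categorical_colors(cats, palette)
    styles = {}
    for cat in cats:
        scale, opacity, visible = per_category.get(cat, (1.0, 1.0, True))
        styles[cat] = StyleMap(
            cat, colors[cat].color, opacity=opacity, scale=scale,
            visible=visible,
        )
    return styles


def load_style_config(
    source: str | TextIO,
) -> tuple[dict[str, list[RGB]], dict[str, Colormap]]:
    """Load user palettes and colormaps from a plain-text config.

    Format: a ``palette NAME`` line followed by ``R G B`` lines, or a
    ``colormap NAME`` line followed by ``POS R G B`` lines; blank lines and
    ``#`` comments are ignored.
    """
    if hasattr(source, "read"):
        source = source.read()
    palettes: dict[str, list[RGB]] = {}
    stops: dict[str, list[tuple[float, RGB]]] = {}
    target: tuple[str, str] | None = None
    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] in ("palette", "colormap"):
            if len(parts) != 2:
                raise ValidationError(f"line {lineno}: expected '{parts[0]} NAME'")
            target = (parts[0], parts[1])
            (palettes if parts[0] == "palette" else stops).setdefault(parts[1], [])
            continue
        if target is None:
            raise ValidationError(
                f"line {lineno}: color line before any palette/colormap header"
            )
        kind, name = target
        try:
            nums = [float(p) for p in parts]
        except ValueError:
            raise ValidationError(f"line {lineno}: non-numeric color entry") from None
        if kind == "palette":
            if len(nums) != 3:
                raise ValidationError(f"line {lineno}: palette lines are 'R G B'")
            palettes[name].append(tuple(int(c) for c in nums))
        else:
            if len(nums) != 4:
                raise ValidationError(f"line {lineno}: colormap lines are 'POS R G B'")
            stops[name].append((nums[0], tuple(int(c) for c in nums[1:])))
    colormaps = {name: Colormap(name, tuple(s)) for name, s in stops.items()}
    return palettes, colormaps
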