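"""Assemble and serialize visualization bundles.

A :class:`VizBundle` is the self-contained document a viewer loads: sample
points, per-axis variance information, the metadata table stored exactly
once, optional default styles, and optional decorations (taxa biplot
spheres, gradient trajectories, comparison edges, jackknife ellipsoid
radii).  The JSON form is deliberately compact: coordinates appear once
regardless of how many metadata columns exist, reals are rounded to a fixed
number of decimals, and low-cardinality metadata columns are
dictionary-encoded with bit-packed indices when that is smaller than the
plain value list.  The companion HTML writer embeds the JSON verbatim in a
single ``<script type="application/json" id="ordviz-bundle">`` block, so the
page needs no external resources and the data can be extracted by that
marker.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import styling
from .compare import compare_series, jackknife_summary, pad_axes
from .geometry import biplot_coords, flip_axes, make_explicit_axis, make_trajectories
from .io_formats import (
    MetadataTable,
    OrdinationResult,
    TaxaTable,
    ValidationError,
)

FORMAT_VERSION = "1"

#: Maximum number of dictionary levels for bit-packed column encoding.
_MAX_LEVELS = 64


@dataclass
class BundleOptions:
    """Optional features requested for a bundle (all off by default)."""

    custom_axes: tuple[str, ...] = ()
    taxa: TaxaTable | None = None
    n_taxa_to_keep: int = 10
    trajectory: tuple[str, str] | None = None  # (trajectory col, gradient col)
    compare: tuple[OrdinationResult, ...] = ()
    jackknife: tuple[OrdinationResult, ...] = ()
    jackknife_method: str = "stddev"
    number_of_axes: int | None = None
    color_by: str | None = None
    colormap: str = "blue-red"
    flip: tuple[int, ...] = ()


@dataclass
class VizBundle:
    """The serializable visualization document."""

    sample_ids: list[str]
    coords: np.ndarray
    axes: list[dict]
    metadata_columns: list[str]
    metadata_rows: list[list[str]]
    styles: dict | None = None
    decorations: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n, k = self.coords.shape
        if n != len(self.sample_ids):
            raise ValidationError("point count does not match sample IDs")
        if k != len(self.axes):
            raise ValidationError("axis records do not match coordinate columns")
        if len(self.metadata_rows) != n:
            raise ValidationError("metadata rows do not match point count")
        m = len(self.metadata_columns)
        if any(len(r) != m for r in self.metadata_rows):
            raise ValidationError("ragged metadata rows")
        ids = set(self.sample_ids)
        for traj in self.decorations.get("trajectories", []):
            bad = set(traj["ids"]) - ids
            if bad:
                raise ValidationError(
                    "trajectory references unknown samples: " + ", ".join(sorted(bad))
                )
        for edge in self.decorations.get("edges", []):
            if edge["id"] not in ids:
                raise ValidationError(
                    f"edge references unknown sample {edge['id']!r}"
                )
        ell = self.decorations.get("ellipsoids")
        if ell is not None and len(ell["radii"]) != n:
            raise ValidationError("ellipsoid radii do not cover every sample")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]


def _axis_records(
    ord_res: OrdinationResult, explicit_names: Sequence[str]
) -> list[dict]:
    e = len(explicit_names)
    records = []
    for j in range(ord_res.n_axes):
        if j < e:
            records.append(
                {
                    "label": explicit_names[j],
                    "eigval": 0.0,
                    "pct_explained": 0.0,
                    "explicit": True,
                }
            )
        else:
            records.append(
                {
                    "label": f"PC{j - e + 1}",
                    "eigval": float(ord_res.eigvals[j]),
                    "pct_explained": float(ord_res.pct_explained[j]),
                    "explicit": False,
                }
            )
    return records


def _default_styles(meta: MetadataTable, column: str, colormap: str) -> dict:
    cmap = styling.COLORMAPS.get(colormap)
    if cmap is None:
        raise ValidationError(f"unknown colormap {colormap!r}")
    gradient = False
    if meta.is_numeric(column):
        vals, missing = meta.numeric_column(column)
        present = vals[~missing]
        gradient = present.size > 0 and present.min() < present.max()
    if gradient:
        return {
            "column": column,
            "kind": "gradient",
            "colormap": {
                "name": cmap.name,
                "stops": [[p, list(rgb)] for p, rgb in cmap.stops],
            },
            "min": float(present.min()),
            "max": float(present.max()),
            "missing_color": list(styling.UNKNOWN_COLOR),
        }
    entries = styling.build_category_styles(meta, column)
    return {
        "column": column,
        "kind": "categorical",
        "entries": [
            {
                "key": s.key,
                "color": list(s.color),
                "opacity": s.opacity,
                "scale": s.scale,
                "visible": s.visible,
            }
            for s in entries.values()
        ],
    }


def build_bundle(
    ord_res: OrdinationResult,
    meta: MetadataTable,
    options: BundleOptions | None = None,
) -> VizBundle:
    """Assemble a bundle from overlap-validated inputs.

    Decorations are computed in full dimensionality; explicit metadata axes
    are prepended afterwards (trajectories and biplots see them, replicate
    alignments do not), and axis-count truncation is applied last to points
    and every geometric decoration alike.
    """
    opts = options or BundleOptions()
    if opts.custom_axes and (opts.compare or opts.jackknife):
        raise ValidationError(
            "custom axes cannot be combined with comparison or jackknife "
            "inputs (partner ordinations carry no metadata axis)"
        )
    if opts.compare and opts.jackknife:
        raise ValidationError("choose either comparison or jackknife, not both")

    work = flip_axes(ord_res, opts.flip) if opts.flip else ord_res
    decorations: dict = {}

    if opts.jackknife:
        summary = jackknife_summary(list(opts.jackknife), opts.jackknife_method)
        meta_ids = set(meta.sample_ids)
        keep = [s for s in summary.sample_ids if s in meta_ids]
        if not keep:
            raise ValidationError(
                "no jackknife samples present in the mapping file"
            )
        rows = [summary.sample_ids.index(s) for s in keep]
        d_max = max(o.n_axes for o in opts.jackknife)
        master = pad_axes(opts.jackknife[0], d_max)
        work = OrdinationResult(
            keep,
            summary.mean_coords[rows],
            master.eigvals,
            master.pct_explained,
        )
        decorations["ellipsoids"] = {
            "method": summary.method,
            "radii": summary.radii[rows],
        }
    elif opts.compare:
        edges = compare_series([work, *opts.compare])
        ids = [sid for sid, _ in edges]
        work = work.subset(ids)
        decorations["edges"] = [
            {"id": sid, "polyline": poly} for sid, poly in edges
        ]

    meta_w = meta.subset(work.sample_ids)

    explicit_names = list(opts.custom_axes)
    for col in reversed(explicit_names):
        work = make_explicit_axis(work, meta_w, col)

    if opts.taxa is not None:
        points = biplot_coords(work, opts.taxa, opts.n_taxa_to_keep)
        decorations["biplot"] = [
            {"id": p.taxon_id, "position": p.position, "weight": p.weight}
            for p in points
        ]

    if opts.trajectory is not None:
        traj_col, grad_col = opts.trajectory
        trajs = make_trajectories(work, meta_w, traj_col, grad_col)
        decorations["trajectories"] = [
            {
                "label": t.label,
                "ids": t.ordered_sample_ids,
                "gradient": [float(v) for v in t.gradient_values],
            }
            for t in trajs
        ]

    # truncation is applied last, to points and geometry alike
    k = opts.number_of_axes or min(work.n_axes, 10)
    if not 1 <= k <= work.n_axes:
        raise ValidationError(
            f"number_of_axes must be in 1..{work.n_axes}, got {k}"
        )
    coords = work.coords[:, :k]
    if "biplot" in decorations:
        for p in decorations["biplot"]:
            p["position"] = [float(x) for x in np.asarray(p["position"])[:k]]
            p["weight"] = float(p["weight"])
    if "edges" in decorations:
        for e in decorations["edges"]:
            e["polyline"] = [
                [float(x) for x in row[:k]] for row in np.asarray(e["polyline"])
            ]
    if "ellipsoids" in decorations:
        decorations["ellipsoids"]["radii"] = [
            [float(x) for x in row[:k]]
            for row in np.asarray(decorations["ellipsoids"]["radii"])
        ]

    styles = None
    if opts.color_by is not None:
        styles = _default_styles(meta_w, opts.color_by, opts.colormap)

    return VizBundle(
        sample_ids=list(work.sample_ids),
        coords=coords,
        axes=_axis_records(work, explicit_names)[:k],
        metadata_columns=list(meta_w.column_names),
        metadata_rows=[list(r) for r in meta_w.values],
        styles=styles,
        decorations=decorations,
        settings={"n_axes": k, "explicit_axes": explicit_names},
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _pack_indices(indices: Sequence[int], bits: int) -> str:
    acc = 0
    for i, v in enumerate(indices):
        acc |= v << (i * bits)
    nbytes = (len(indices) * bits + 7) // 8
    return base64.b64encode(acc.to_bytes(max(nbytes, 1), "little")).decode("ascii")


def _unpack_indices(packed: str, bits: int, n: int) -> list[int]:
    acc = int.from_bytes(base64.b64decode(packed), "little")
    mask = (1 << bits) - 1
    return [(acc >> (i * bits)) & mask for i in range(n)]


def _encode_column(name: str, values: list[str]) -> dict:
    plain = {"name": name, "values": values}
    levels: dict[str, int] = {}
    for v in values:
        levels.setdefault(v, len(levels))
    if 0 < len(levels) <= _MAX_LEVELS:
        bits = max(1, (len(levels) - 1).bit_length())
        packed = {
            "name": name,
            "levels": list(levels),
            "bits": bits,
            "packed": _pack_indices([levels[v] for v in values], bits),
        }
        if len(json.dumps(packed, separators=(",", ":"))) < len(
            json.dumps(plain, separators=(",", ":"))
        ):
            return packed
    return plain


def _decode_column(col: dict, n: int) -> list[str]:
    if "values" in col:
        return list(col["values"])
    idx = _unpack_indices(col["packed"], col["bits"], n)
    levels = col["levels"]
    return [levels[i] for i in idx]


def _round_floats(obj, precision: int):
    if isinstance(obj, float):
        r = round(obj, precision)
        return 0.0 if r == 0 else r
    if isinstance(obj, dict):
        return {k: _round_floats(v, precision) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, precision) for v in obj]
    return obj


def write_bundle_json(bundle: VizBundle, precision: int = 5) -> str:
    """Serialize a bundle to compact JSON with reals rounded to ``precision``
    decimals.  Output size depends only on (n, d, m) — coordinates are
    written exactly once no matter how the metadata is later grouped."""
    if precision < 1:
        raise ValidationError("precision must be at least 1")
    obj = {
        "version": bundle.version,
        "points": {
            "ids": bundle.sample_ids,
            "coords": [[float(x) for x in row] for row in bundle.coords],
        },
        "axes": bundle.axes,
        "metadata": {
            "n": bundle.n_samples,
            "columns": [
                _encode_column(name, [row[j] for row in bundle.metadata_rows])
                for j, name in enumerate(bundle.metadata_columns)
            ],
        },
        "styles": bundle.styles,
        "decorations": bundle.decorations,
        "settings": {**bundle.settings, "precision": precision},
    }
    return json.dumps(_round_floats(obj, precision), separators=(",", ":"))


def parse_bundle_json(text: str) -> VizBundle:
    """Re-parse a serialized bundle into an equal :class:`VizBundle`."""
    obj = json.loads(text)
    n = obj["metadata"]["n"]
    columns = [c["name"] for c in obj["metadata"]["columns"]]
    col_values = [_decode_column(c, n) for c in obj["metadata"]["columns"]]
    rows = [[col[i] for col in col_values] for i in range(n)]
    return VizBundle(
        sample_ids=list(obj["points"]["ids"]),
        coords=np.array(obj["points"]["coords"], dtype=float),
        axes=obj["axes"],
        metadata_columns=columns,
        metadata_rows=rows,
        styles=obj.get("styles"),
        decorations=obj.get("decorations", {}),
        settings=obj.get("settings", {}),
        version=obj.get("version", FORMAT_VERSION),
    )


# ---------------------------------------------------------------------------
# HTML
# ---------------------------------------------------------------------------

_SCRIPT_OPEN = '<script type="application/json" id="ordviz-bundle">'

_DEFAULT_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>ordination bundle</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; }}
</style>
</head>
<body>
<h1>Ordination visualization bundle</h1>
<p>{n} samples &times; {d} axes, {m} metadata columns.
The embedded JSON document below is the complete dataset; any viewer can
extract it from the script block with id <code>ordviz-bundle</code>.</p>
<div id="axes"></div>
{script_open}{bundle_json}</script>
<script>
(function () {{
  var b = JSON.parse(document.getElementById("ordviz-bundle").textContent);
  var rows = b.axes.map(function (a) {{
    return "<tr><td>" + a.label + "</td><td>" +
      a.pct_explained.toFixed(2) + "%</td></tr>";
  }}).join("");
  document.getElementById("axes").innerHTML =
    "<table><tr><th>axis</th><th>% variation</th></tr>" + rows + "</table>";
}})();
</script>
</body>
</html>
"""


def render_html(
    bundle: VizBundle,
    template: str | None = None,
    precision: int = 5,
) -> str:
    """Render a single self-contained HTML page embedding the bundle JSON
    verbatim.  ``template`` may override the default page; it receives the
    fields ``n``, ``d``, ``m``, ``script_open`` and ``bundle_json``."""
    payload = write_bundle_json(bundle, precision=precision)
    tmpl = template if template is not None else _DEFAULT_TEMPLATE
    return tmpl.format(
        n=bundle.n_samples,
        d=bundle.n_axes,
        m=len(bundle.metadata_columns),
        script_open=_SCRIPT_OPEN,
        bundle_json=payload,
    )


def extract_bundle_json(html: str) -> str:
    """Pull the embedded bundle JSON back out of a rendered page."""
    start = html.find(_SCRIPT_OPEN)
    if start < 0:
        raise ValidationError("no embedded bundle found in HTML")
    start += len(_SCRIPT_OPEN)
    end = html.find("</script>", start)
    if end < 0:
        raise ValidationError("embedded bundle script block is unterminated")
    return html[start:end]
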