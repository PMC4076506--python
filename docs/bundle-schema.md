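# Bundle JSON schema (version "1")

`bundle.json` is a single JSON object. All reals are rounded to the number
of decimals recorded in `settings.precision` (default 5). Coordinates are
stored exactly once; decorations reference sample IDs wherever the geometry
already lives in the points section.

```jsonc
{
  "version": "1",
  "points": {
    "ids":    ["s00000", ...],          // n unique sample IDs
    "coords": [[x1, ..., xk], ...]      // n rows x k axes, row i belongs to ids[i]
  },
  "axes": [                             // k records, in column order
    {"label": "Age", "eigval": 0.0, "pct_explained": 0.0, "explicit": true},
    {"label": "PC1", "eigval": 2.91, "pct_explained": 45.8, "explicit": false}
  ],
  "metadata": {
    "n": 40,                            // row count (= points)
    "columns": [                        // one entry per column, two encodings:
      {"name": "Desc", "values": ["...", ...]},          // plain: n strings
      {"name": "BodySite",                               // dictionary-encoded
       "levels": ["site_0", "site_1"],                   // first-appearance order
       "bits": 1,                                        // bits per index
       "packed": "qv8A..."}                              // base64 little-endian
    ]                                   // bitstream; index i at bit offset i*bits
  },
  "styles": {                           // null unless --color_by was given
    // categorical:
    "column": "BodySite", "kind": "categorical",
    "entries": [{"key": "site_0", "color": [31,119,180],
                 "opacity": 1.0, "scale": 1.0, "visible": true}, ...]
    // or gradient:
    // "column": "Age", "kind": "gradient",
    // "colormap": {"name": "blue-red", "stops": [[0.0,[0,0,255]],[1.0,[255,0,0]]]},
    // "min": 0.5, "max": 33.0, "missing_color": [64,64,64]
  },
  "decorations": {                      // each key present only if requested
    "biplot": [
      {"id": "taxon_006", "position": [..k reals..], "weight": 0.10173}
    ],
    "trajectories": [                   // geometry via sample IDs -> points
      {"label": "site_0", "ids": ["s00003", ...], "gradient": [0.5, ...]}
    ],
    "edges": [                          // procrustes comparison polylines,
      {"id": "s00000", "polyline": [[..k..], [..k..]]}   // one vertex per ordination
    ],
    "ellipsoids": {                     // jackknife confidence half-widths
      "method": "stddev",               // or "iqr"
      "radii": [[..k reals..], ...]     // n rows, centered on points.coords
    }
  },
  "settings": {"n_axes": 6, "explicit_axes": ["Age"], "precision": 5}
}
```

The whole document is embedded verbatim in `index.html` inside
`<script type="application/json" id="ordviz-bundle"> ... </script>`;
`ordviz.extract_bundle_json(html)` returns it byte-for-byte.

Decoding a dictionary-encoded column: base64-decode `packed` into a
little-endian integer, then value *i* is `levels[(acc >> (i*bits)) & ((1<<bits)-1)]`
for `i` in `0..n-1`. The encoder picks whichever of the two encodings
serializes smaller, so both must be handled.
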