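# View-config JSON reference

A view config is a JSON object. All keys are optional; unknown keys are
rejected.

```json
{
  "mark": "sphere",
  "color": {"field": "gene_density", "scale_type": "continuous",
            "domain": [0, 50], "range": "viridis"},
  "scale": {"field": "gene_density", "scale_type": "continuous",
            "range": [0.25, 1.5]},
  "base_size": "auto",
  "links": false
}
```

| key | type | default | meaning |
|---|---|---|---|
| `mark` | `"sphere"` \| `"box"` | `"sphere"` | geometric primitive per bin |
| `color` | channel | `"#808080"` | per-bin RGBA |
| `scale` | channel | `1.0` | positive size multiplier |
| `base_size` | number > 0 \| `"auto"` | `"auto"` | mark size in model units before the multiplier; `"auto"` = half the median consecutive same-chromosome bin distance |
| `links` | boolean | `false` | draw 8-sided prisms between consecutive bins of a chromosome |

## Channels

A channel is either a bare constant (color string or number, shorthand
for `{"constant": ...}`) or an object with exactly one of:

- `constant`: a color (`#RRGGBB`, `#RRGGBBAA`, or a named color) for the
  color channel; a positive number for the scale channel.
- `field`: a column name of the bin table, with:
  - `scale_type`: `"continuous"` (numeric columns only; the default) or
    `"categorical"` (any column);
  - `domain`: `[min, max]` for continuous (defaults to the data extent,
    recomputed per structure — pin it for cross-structure comparison) or
    an ordered category list for categorical;
  - `range`: for continuous color, a colormap name (`"viridis"`,
    `"bluered"`) or an explicit color list to interpolate through; for
    categorical color, a color list (cycled); for scale, a `[lo, hi]`
    pair of positive numbers (default `[0.25, 1.5]`).

Categorical colors default to a fixed 12-color qualitative palette
assigned by first appearance in row order, cycling with a warning.
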