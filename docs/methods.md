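# Methods

This note records how the diagram is computed, the defaults and why they
were chosen, what the synthetic fixtures do and do not emulate, and the
places where the design was genuinely open.

## Pipeline

1. **Identifier resolution** (`pfam_client.resolve_accession`). The gene
   symbol is looked up in the UniProt REST query interface. Only reviewed
   (SwissProt) entries are considered; among them, human (taxon 9606)
   entries are preferred, and any remaining tie breaks lexicographically by
   accession. The preference order is a package decision: the tool serves
   human precision-medicine reporting, and the tie-break makes resolution a
   pure function of the response. Callers who already know the accession
   bypass this step (`-U`).
2. **Architecture retrieval** (`pfam_client.fetch_architecture` /
   `load_architecture_json`). The graphics document is parsed
   all-or-nothing into a `ProteinArchitecture`: residue length, ordered
   Pfam-A `DomainRegion`s, and `MotifRegion`s drawn from the closed kind
   set {`disorder`, `low_complexity`, `sig_p`, `coiled_coil`,
   `transmembrane`}. Unknown motif kinds are dropped with a logged warning
   rather than failing the plot — schema dialects drift, and a missing
   decoration is preferable to a dead pipeline. Structural errors (missing
   length, inverted or out-of-range intervals) raise a parse error naming
   the JSON path; no partial architecture is ever returned. The accepted
   dialect is documented in `docs/pfam_graphics_schema.json`; which fields
   the upstream service guarantees is not published, so the schema is a
   reverse-engineering of the commonly served shape (object or one-element
   array, integer or numeric-string coordinates).
3. **Layout** (`layout_engine`), then **rendering** (`svg_renderer`).
   Residue positions are 1-based inclusive everywhere; the only
   residue→pixel conversion is `aa_to_px(i) = pad + (i − 0.5)·(W −
   2·pad)/L`, the center of residue `i`'s cell, strictly increasing and
   confined to the padded plot area.

Responses are cached on disk keyed by `(service, identifier)` with no
expiry; `-no-cache` bypasses it. Determinism across runs matters more here
than freshness — domain annotations change on database release timescales.

## Layout heuristics

**Axis ticks.** Candidates are variant positions (priority 3), domain
starts/ends (priority 2), and the termini (priority 1); identical positions
deduplicate to the highest priority. There are no regularly spaced filler
ticks by design: evenly spaced labels force the reader to interpolate,
while data-driven labels put the exact numbers they need on the axis.
Candidates are accepted greedily in (priority desc, position asc) order; a
candidate is culled when its label box (text width estimated from the
packaged font table, centered on the tick) comes within `min_tick_gap` of
an already-accepted label. Consequences: a culled tick is always
attributable to a surviving neighbor of greater or equal priority, and at
equal priority the leftmost wins — both properties are enforced by an
exhaustive pairwise oracle in the tests.

**Domain labels.** Candidates in order: full description, short name,
`..SUFFIX`. The suffix is the short name minus its longest
underscore-delimited prefix shared by at least two of the protein's
domains; splitting on underscores reproduces both the `P53_`-family and
`Fib_`-family behaviors. A name without underscores (e.g. `P53`) never
abbreviates. "Fits" means estimated width ≤ box width − 4 px. The text
metric is a packaged advance-width table for DejaVu Sans (generated once
from the TTF at 1000 px and scaled linearly); characters outside printable
ASCII fall back to the mean advance. The estimate is deliberately
approximate — SVG viewers substitute fonts — and is used only to decide
what to attempt, never to position glyphs.

**Staggering.** Variants are processed sorted by position (ties keep input
order) and each takes the lowest slot `s ≥ 0` such that its head circle,
centered `stem_base_height + s·slot_step` px above the backbone, intersects
no previously placed head (exact circle–circle test). Duplicate specs are
preserved on purpose: two reports of the same variant are two lollipops,
and staggering is what makes them visible. If a variant would need a slot
above the lollipop zone, the layout fails with advice to widen the plot —
silently stacking or dropping data would misrepresent a clinical sample.
The same policy applies to variants beyond the protein length: an error by
default, a logged skip only under `-skip-invalid`.

**Radius scaling.** With any unequal magnitudes, radii interpolate between
`min_radius` and `max_radius` by √ of the min–max-normalized magnitude;
equal magnitudes all use `base_radius`. The square root keeps head area
roughly proportional to magnitude while clamping extremes; rank order of
magnitudes is preserved (non-strictly, at the clamp ends).

## Geometry defaults

| parameter | default | notes |
|---|---|---|
| `plot_width` | 740 px | compact report width |
| `pad` | 15 px | also absorbs edge tick labels |
| `backbone_height` | 14 px | motif overlays use the same band |
| `lollipop_zone_height` | 90 px | caps stagger slots (≈5 at defaults) |
| `axis_height` | 24 px | tick mark + one text line |
| `font_size` | 12 px | all labels |
| `base_radius` / `min` / `max` | 5 / 4 / 12 px | head sizes |
| `min_tick_gap` | 4 px | gap between label boxes, not centers |
| `stem_base_height` | 24 px | slot-0 head center above backbone |
| `slot_step` | 12 px | one head diameter at default radius |

All values live in `DrawConfig` and are overridable per render; the chosen
defaults give a visual density suited to a one-protein report panel.
Disordered regions are hidden unless `show_disordered` is set (they are
long and would dominate the backbone); signal peptides draw orange
(`#F0A000`), low-complexity cyan (`#00C0C0`), disorder dark grey
(`#555555`), coiled-coil and transmembrane muted grey-blue — named colors
pinned to hex values so output is reproducible.

## Rendering and determinism

The SVG is assembled with the standard XML toolkit in a fixed layer order
(backbone, motifs, domains + labels, axis, stems, heads, optional variant
labels), elements within a layer sorted by position then input order. All
coordinates are rounded to two decimals before formatting, the document
embeds no timestamps, scripts or external references, and tooltips are
native `<title>` elements on the head circles. Identical inputs therefore
produce byte-identical bytes on any platform, which the golden-file tests
pin for three canonical fixtures.

## Synthetic fixtures and what tests show

No network is used anywhere in the tests. The UniProt and Pfam replay
documents under `src/needleplot/data/` are *synthetic*: hand-written to
mirror the live response shapes, with the TP53-like entry carrying the
real protein length and domain coordinates of P04637 and the FGA-like
entry carrying a plausible fibrinogen-alpha-chain-style architecture
(three `Fib_`-prefixed domains, signal peptide, disorder and
low-complexity stretches). The `fixtures` module additionally generates
seeded random architectures (disjoint domains via sorted distinct cut
points; shared name prefixes in half the seeds to exercise abbreviation)
and variant spec lists.

Passing tests therefore demonstrate the parsing, layout and rendering
contracts, not fidelity to the live services: the real endpoints may serve
additional fields, other motif vocabularies, or overlapping domains, and
the parser's tolerance for those is exercised only as far as the dialect
schema describes. Sequence-level verification (checking that `R273` really
is an arginine) is deliberately out of scope — the tool sits downstream of
a variant-calling pipeline that has already validated calls against the
reference.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) sweeps 500 random
layout/tick/radius oracles, 1000 variant round-trips and 200 architecture
round-trips per run, seeded from `--seed`; the test suite runs the same
oracles at 1000 renders. These sizes give every branch (0–5 domains, 0–12
variants, decorated and bare specs, shared and unshared name prefixes)
hundreds of visits while the whole suite stays in the sub-minute range a
pre-commit hook can afford. Crowded random inputs that legitimately
overflow the stagger zone are counted and reported
(`stagger_overflow_renders`), not treated as oracle failures — the
documented behavior there is the layout error.

## Known limitations

* One-letter amino-acid codes only; `p.Arg273His` is rejected with a
  pointer to the one-letter form.
* The text metric is approximate; a viewer substituting a much wider font
  may truncate a label the fit test accepted.
* No population y-axis, no rasterization, no genomic (DNA-coordinate)
  mode, no 3-D structure views: single-sample protein reporting only.
* Domain boxes are drawn in document order without horizontal de-overlap;
  overlapping domains (rare in Pfam-A) will overplot.
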