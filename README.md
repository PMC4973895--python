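# needleplot

Information-dense lollipop (needle) diagrams of protein variants, built for
automated variant-reporting pipelines.

Given an HGNC gene symbol (or a UniProt/SwissProt accession) and a list of
protein variant specs such as `R273H`, `R273H#FF0000` or `S45F@42`, the tool
assembles the protein's Pfam-A domain architecture and renders a deterministic
SVG: each variant is a circle on a stem rising from its residue position on
the protein backbone, drawn over the domains, signal peptides, low-complexity
and disordered regions that give the positions meaning. Single-sample clinical
reports are the target use case: one protein, a handful of variants, no
population y-axis, output that drops straight into a web page or illustration
tool.

## What makes the plots dense

* **Data-driven axis.** There are no regularly spaced residue ticks. The axis
  labels exactly the positions a reader needs: every variant site (priority
  3), every domain start/end (priority 2), and the protein termini (priority
  1). When two labels would collide (estimated extents closer than
  `min_tick_gap`), the lower-priority tick is culled; at equal priority the
  leftmost survives.
* **Adaptive domain labels.** Each domain box tries, in order: the full
  description (`P53 DNA-binding domain`), the Pfam short name (`P53_TAD`),
  and an abbreviation `..SUFFIX` that drops the longest underscore-delimited
  name prefix shared with at least one sibling domain (`P53_TAD` → `..TAD`,
  `Fib_aC` → `..aC`); if nothing fits, the label is hidden. Fit decisions use
  a packaged DejaVu Sans advance-width table.
* **Staggered lollipops.** Variants are placed in stem-height slots greedily
  by position; each takes the lowest slot whose head circle clears every head
  already placed, so closely spaced or duplicated variants remain separable.
* **Relative head scaling.** A variant magnitude `m` (from an `@m` suffix on the variant spec string)
  maps to a radius `r = r_min + (r_max − r_min)·√((m − m_min)/(m_max −
  m_min))`, so head *area* tracks magnitude roughly linearly while a 42×
  lollipop stays bounded next to a 1× one. Equal magnitudes all draw at the
  base radius.

Architecture documents come from the UniProt REST query interface (symbol →
reviewed accession, human preferred) and a Pfam-graphics-style JSON endpoint,
through an injectable fetch function with an on-disk cache — or from a local
JSON file (`-local`), for air-gapped clinical use. The JSON dialect is
described in `docs/pfam_graphics_schema.json`.

## Command line

```sh
needleplot [flags] GENE_SYMBOL [VARIANT ...]

  -U ACCESSION      skip symbol resolution, use this UniProt accession
  -o FILE           output path (default GENE.svg)
  -w PX             plot width in pixels (default 740)
  -labels           print a text label above each lollipop
  -hide-motifs      hide structural motif regions
  -hide-axis        hide the residue axis
  -show-disordered  also draw predicted disordered regions
  -local FILE       read the architecture from a local JSON document
  -no-cache         bypass the on-disk response cache
  -skip-invalid     skip variants beyond the protein length instead of failing
  -help             full flag listing
```

Exit status: 0 success, 2 bad input (unknown gene, bad variant spec), 3
network failure. Logs go to stderr; the SVG is written atomically.

## Worked example

Render the bundled TP53-like architecture (length 393, domains `P53_TAD`
6–29, `P53` 95–288, `P53_tetramer` 318–358) with five hotspot variants, one
colored and one magnified 8×:

```sh
needleplot -local tp53.json -labels -o TP53.svg \
    TP53 R175H G245S R248Q R273H#FF8800 R282W@8
# INFO: wrote TP53.svg (3 domains, 5 variants)
```

The same decisions through the library:

```python
import needleplot as nd
from needleplot import fixtures, layout_engine as le

arch = nd.load_architecture_json(fixtures.bundled_document("tp53"))
variants = nd.parse_variants(["R175H", "G245S", "R248Q", "R273H#FF8800", "R282W@8"])
config = nd.DrawConfig()

for domain in arch.domains:
    _, width = le.residue_span_px(domain.start, domain.end, arch.length, config)
    choice = nd.choose_domain_label(domain, arch.domains, width, config)
    print(f"{domain.short_name:13s} box {width:6.1f}px -> {choice.mode:12s} {choice.text!r}")
print("axis ticks:", nd.select_ticks(arch, variants, config).positions())
print("radii:", [round(r, 1) for r in nd.scale_radii(variants, config)])
```

prints

```
P53_TAD       box   43.4px -> abbreviated  '..TAD'
P53           box  350.5px -> description  'P53 DNA-binding domain'
P53_tetramer  box   74.1px -> abbreviated  '..tetramer'
axis ticks: (6, 29, 95, 175, 245, 273, 288, 318, 358, 393)
radii: [4.0, 4.0, 4.0, 4.0, 12.0]
```

Reading it: the narrow N-terminal box cannot fit `P53 transactivation motif`
or `P53_TAD`, so the shared `P53` name prefix is dropped (`..TAD`); the wide
central box takes its full description. The axis carries every domain
boundary and variant site except two casualties of collision culling: the
N-terminus `1` loses to the higher-priority boundary `6`, and `248` loses to
the equal-priority, more leftward `245`. Four variants share the default
magnitude (minimum radius here, since one variant is scaled); the `@8`
variant gets the maximum radius.

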