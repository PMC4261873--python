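# Methods

## The partition model

vennkit compares up to six named lists of identifiers. After
normalization (whitespace trimming, duplicate collapse within a list —
keeping first occurrence; in count lists the values of collapsed
duplicates are summed so list totals are preserved), lists are labelled
A–F in input order. Every identifier in the union belongs to exactly one
exclusive region, keyed by the sorted labels of the lists containing it.
This is a true partition, so three conservation laws hold and are tested
on every change:

* the regions are pairwise disjoint and exhaust the union;
* inclusion consistency: `|L| = Σ_{S∋L} count(R_S)` for every list L;
* the shared-by-k distribution `Σ_{|S|=k} count(R_S)` totals `|union|`.

For count lists the region figure is the sum of each member list's values
over the region's exclusive elements. The wording "sums of counts of all
elements shared between lists" admits a per-list and an across-lists
reading; vennkit sums **across all member lists**, because that is the
only reading under which the grand total over regions equals the grand
total of the input values (a conservation law worth having when the
values are sequencing read counts), and it treats all member lists
symmetrically. User-supplied intersection counts are accepted as-is;
regions omitted from the input default to 0 rather than erroring, since
sparse documents that list only non-empty regions are the common case.

Search is case-insensitive substring matching, reflecting how live search
boxes behave; each hit is reported with its unique exclusive region.
Canonical region order (subset size ascending, then lexicographic:
A, B, …, AB, AC, …, ABCDEF) is used everywhere — reports, CSV columns,
rendering — so all outputs are reproducible and diffable.

## Layout geometry

Templates are original constructions. Correctness is defined
topologically, not by pixel coordinates: a template is valid when each of
the `2^n − 1` regions contains its label anchor under the even-odd
(crossing-parity) membership rule, the same rule SVG uses to fill the
shapes — so what is drawn and what is computed cannot disagree.
`validate_layout` checks exactly this and must return an empty report for
every shipped template; the test suite runs it for classic and Edwards at
every n in 2–6.

Anchors are the centres of each region's maximum inscribed circle
(computed with shapely on the region polygon = intersection of member
shapes minus the union of the rest; for multi-part regions the largest
part is used). The in-place character budget of a region is how many
digit glyphs fit across that inscribed circle, assuming a glyph width of
0.62 × font size (a sans-serif average). Both are deterministic functions
of (mode, n).

**Classic.** Circles for 2–3 sets; for 4–5 sets the standard ellipse
arrangements; for 6 sets a six-triangle arrangement. A rotationally
symmetric six-set diagram of congruent shapes does not exist (symmetric
Venn diagrams require prime n), so the six triangles are not congruent;
they are the widely used public-domain template vertices, validated by
the anchor test. Coordinates live on an abstract 700×700 canvas, y down
(SVG viewBox semantics).

**Edwards.** Set A is the left half and B the top half of an inset chart
frame (the frame, not the full canvas, so names and callout labels have a
margin ring); C is a central circle of radius r = 160. Sets k = 4, 5, 6
are closed serpentine bands of half-width w_k around the oscillating
radius

```
ρ_k(θ) = r · (1 + a · s_k(θ)),   s_k(θ) = tanh(β cos(2^(k−3) θ)) / tanh(β)
```

with amplitude a = 0.28, squareness β = 6 and nested half-widths
w₄ = 40 > w₅ = 24 > w₆ = 11. The smoothed square wave gives each band
`2^(k−3)` teeth alternating outside/inside the circle, hence exactly
`2·2^(k−3)` circle crossings. The cosine phases form a binary-counter
(Gray-code) pattern: within every quadrant all eight sign combinations of
(s₄, s₅, s₆) occur, and because the bands share centre radii when on the
same side of the circle while their widths are strictly nested, every
subset of {D, E, F} is realized as an annular strip both inside and
outside the circle, in every quadrant — which is what makes all 63
regions non-empty. The constants were chosen so the smallest region of
the six-set template keeps a usable area (≈ 400 square units) while the
outermost band stays inside the frame; they are fixed, not user knobs.

**Display rules.** A count that needs more characters than its region's
budget is drawn as `?`; the full value is always embedded as a `<title>`
metadata element, so no information is lost in the SVG. A region whose
count does not fit **and** whose area is below 900 square units (≈ a
30×30 box) instead gets a callout: the count is drawn on a rectangle just
inside the canvas border, connected to the region anchor by a straight
leader line. Callout labels are ordered by the angular position of their
anchors and spread to a minimum angular gap; a repair pass swaps label
slots until the leader lines are pairwise non-crossing (checked by
segment-intersection tests on the shipped templates).

## Rendering

SVG output is a pure, byte-deterministic function of (layout, table,
options): fixed float formatting, fixed element order, no timestamps.
Defaults: the Okabe–Ito colourblind-safe palette at fill opacity 0.4,
one sans-serif family, font size 13. The companion statistics are two bar
charts (per-list sizes; elements shared by exactly k lists) with numeric
captions. PNG export rasterizes the SVG subset vennkit emits —
evenodd-filled paths, polylines, anchored text — with Pillow; output
pixel dimensions are canvas × scale. PNG bytes are not guaranteed
byte-stable across Pillow versions (only the SVG is); tests assert
dimensions and content, not raster bytes.

## Synthetic data

The generator emulates the package's real inputs — gene/OTU identifier
lists — by planting an exact identifier count in every exclusive region
and assigning each identifier to precisely the lists of its region, so
the true partition is known by construction and recovery must be exact,
not approximate. Identifiers are `<prefix><zero-padded index>` in
canonical region order; a single seed fixes everything. Optional
per-element values model sequencing read counts with a negative-binomial
distribution (mean 48, dispersion 2 — overdispersed, as real read counts
are). What the generator does **not** emulate: realistic gene
nomenclature, correlated membership structure between biological
replicates, or differential-expression effect sizes. Passing the
planted-recovery and oracle-equivalence suites therefore demonstrates
correctness of the set algebra and geometry on any list contents, but
says nothing about the statistical quality of upstream list-making.

Test problem sizes — a thousand random oracle instances of up to 200
elements, two hundred CSV round trips, and one six-list instance of
10,000 identifiers (the documented large-input scenario, checked for
completion, with no wall-clock assertion) — were chosen as comfortable
desk-scale sizes that exercise every n.

## Degenerate inputs and numerical choices

* One list is allowed for statistics (a single region A); diagrams need
  2–6 sets. Seven or more lists are rejected everywhere.
* Empty lists are valid: all regions exist with count 0, CSV export is
  header-only, diagrams render zeros.
* Curves are polygonized on fixed grids (256 points per circle/ellipse,
  512 for the Edwards circle, 1024 per band ring); membership, anchors
  and rendering all operate on the same vertices, so no tolerance
  mismatch can arise between them.
* Values must be non-negative; intersection-count documents must declare
  every label a region key uses, and element lists (when given) must
  match their declared counts.
* CSV uses comma separators, LF line endings and minimal quoting.

## Known limitations

* Layouts are not area-proportional, deliberately: proportional diagrams
  do not extend past three sets, and vennkit's design point is five and
  six.
* Both layout modes are offered for all of n = 2–6, including Edwards at
  n < 4 where its half-plane construction is unusual but valid.
* Interactive behaviours of browser-based viewers (hover highlighting,
  switch panels, pop-ups) are out of scope; the equivalent information is
  available statically (callouts, `<title>` metadata, the search and
  export commands).
* With six sets and large counts, many classic-layout regions exceed
  their budgets and the chart grows dense with callouts; the Edwards
  layout is the readable choice there.
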