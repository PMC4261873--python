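# vennkit

Batch computation, export and drawing of Venn diagrams for up to six
named lists.

High-throughput biology routinely produces lists of identifiers — gene
names from differential-expression analyses, OTUs from microbiome
pipelines — obtained under different conditions or with different methods.
The standard way to compare such lists is a Venn diagram: each list is a
translucent shape, and each diagram area shows the number of elements
belonging to exactly that combination of lists. vennkit is a library and
command-line tool for scientists and pipeline authors who need those
numbers, the member identifiers, and publication-ready figures without a
browser in the loop.

## What it computes

Given lists `L_A, …, L_F` (at most six), every identifier in the union is
assigned to exactly one **exclusive region**: the region keyed by the
sorted subset `S ⊆ {A,…,F}` of the lists that contain it,

```
R_S = ( ⋂_{i∈S} L_i ) \ ( ⋃_{j∉S} L_j ),        |regions| = 2^n − 1.
```

Region figures are cardinalities `|R_S|`, or — for *count lists*, where
every identifier carries a numeric value such as an OTU read count —
value sums `Σ_{i∈S} Σ_{x∈R_S} v_i(x)`, which conserve the grand total of
the input values. Companion statistics are the per-list sizes and the
distribution of elements specific to one list or shared by exactly *k*
lists (`Σ_{|S|=k} |R_S|`).

Diagrams come in two layouts, both defined by a topological contract —
every region's label anchor must lie inside exactly its member shapes
under the even-odd rule:

* **classic** — circles (2–3 sets), the standard ellipse arrangements
  (4–5 sets), and a six-triangle arrangement (6 sets);
* **Edwards** — two half-plane rectangles, a central circle, and
  serpentine "cogwheel" bands with `2^(k−3)` teeth that cross the circle
  `2·2^(k−3)` times, which stays readable at five and six sets.

Counts that cannot fit their region are replaced by `?` (the full value is
kept as SVG metadata), and small regions get leader-line callouts outside
the chart.

## Worked example

Three JSON input formats are accepted: `lists` (shown below),
`intersection_counts` (user-supplied region counts) and `count_lists`
(per-identifier values). With `table2.json`:

```json
{"series": [
 {"name": "sample1", "data": ["Otu1","Otu2","Otu3","Otu4","Otu5","Otu6","Otu7"]},
 {"name": "sample2", "data": ["Otu1","Otu2","Otu5","Otu7","Otu8","Otu9"]}
]}
```

```text
$ vennkit compute -i table2.json
A 3
B 2
AB 4
```

Three OTUs are specific to sample1, two to sample2, and four are shared.
The other subcommands work on the same inputs:

```text
$ vennkit search -i table2.json -q Otu8
Otu8 B

$ vennkit stats -i table2.json
size A sample1 7
size B sample2 6
shared 1 5
shared 2 4

$ vennkit export -i table2.json -o table2.csv && cat table2.csv
A,B,AB
Otu3,Otu8,Otu1
Otu4,Otu9,Otu2
Otu6,,Otu5
,,Otu7

$ vennkit plot -i table2.json --layout edwards -o table2.svg --stats-out charts.svg
```

`shared 1 5` means five identifiers occur in exactly one list and
`shared 2 4` that four are shared by both; the CSV holds each region's
member identifiers in one column. With count-list input (`values` arrays),
`compute` appends the per-region value sums (here `A 3 328`, `B 2 54`,
`AB 4 534` for read counts `5,15,250,20,23,58,89` / `90,300,10,2,45,9`).

The same operations are available as library functions
(`vennkit.compute_partition`, `vennkit.render_diagram`, …), and
`vennkit generate` emits synthetic instances with planted region sizes for
testing pipelines.

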