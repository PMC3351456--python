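# cogvenn

Disjoint-region Venn analysis and Edwards "cogwheel" diagrams for 2–6
named sets of string labels — protein symbols, GO term names, pathway
names, or any identifiers that compare exactly.

## The problem

Comparing more than three or four lists is where ordinary Venn tools
give out: a valid diagram must draw every one of the 2^n − 1
intersection regions, and circles or ellipses cannot do that past
n = 4. The Edwards construction can, for any n: two orthogonal
half-planes and a circle realize three sets, and each further set is
bounded by a wavy closed curve that weaves across the circle with a
doubling number of teeth — the planar projection of hemispheres and a
tennis-ball-seam curve on a sphere, producing "cogwheel" diagrams.

The motivating use case is pharmacological: a log dose–response
experiment yields six phosphoprotein lists (a non-stimulated reference
plus five agonist doses). Partitioning them into their 63 disjoint
intersection regions, and classifying each region against the
reference, separates the *dose-unique* response from the shared one.

## The model

Each element of the union carries an n-bit membership **signature**
(bit *i* − 1 set iff the element is in set *i*; set 1 is the first
input column). The signature's integer value is its region index, so a
six-set comparison has regions 1…63. Relative to a reference set *r*
(by default set 1), each region gets one of five category codes:

| code  | meaning |
|-------|---------|
| BLUE  | unique to the reference set |
| RED   | unique to exactly one dose set ("dose-unique") |
| GREY  | in ≥ 2 dose sets, absent from the reference |
| BLACK | in the reference plus some, but not all, dose sets |
| GREEN | in every set |

For n = 6 these cover the 63 signatures with counts
(1, 5, 26, 30, 1). The dose-unique profile reports each dose's RED
count, its share of the total RED count, and the *stimulated-unique
fraction*: total RED over all members present in at least one dose set
but absent from the reference.

The diagram geometry uses, for sets 4–6, radial cog curves
ρ < r·(1 + a_k·cos(m_k·θ + φ_k)) with teeth m = (2, 4, 8), nested
amplitudes a = (0.50, 0.30, 0.17) and zero phases. Rather than trust
the constants, `validate_layout` grid-samples the frame and certifies
that all 2^n membership patterns are realized; every shipped layout
passes this check at 1000×1000.

## Worked example

```
$ cogvenn fixture --plan control --scale 100 --seed 1 --out out/
out/control_s1.csv
$ cogvenn profile --input out/control_s1.csv --out out/
out/control_s1_doseprofile.csv
out/control_s1_histogram.csv
$ head -4 out/control_s1_doseprofile.csv
# reference=NS denominator=stimulated stimulated_unique_fraction_pct=36 raw=35.9712
dose,unique_count,unique_fraction_pct,raw_fraction_pct
10nM,15,15,15.0
100nM,15,15,15.0
```

The fixture is a six-condition dose–response collection (reference
`NS` plus five doses) whose ground truth is known by construction: 36%
of the stimulated-only members are dose-unique, split 15/15/21/22/27%
across the five doses — the header line and the `unique_fraction_pct`
column recover exactly those numbers from the partition.

```
$ cogvenn partition --input out/control_s1.csv --out out/
$ cogvenn draw --input out/control_s1.csv --display counts --png 150 --out out/
```

`partition` writes a per-region membership table (one column per
non-empty region, headed `index:Name∩Name…`) and a summary CSV
(region index, signature, size, category code — 63 rows for six
sets). `draw` renders the cogwheel diagram as SVG with a count, index
or text label anchored inside each non-empty region and a `<title>`
tooltip listing the full membership; `--png` adds a raster export.

Python API equivalents live in `cogvenn` directly:
`read_collection`, `compute_partition`, `classify_region`,
`dose_unique_profile`, `cross_context_compare`, `build_layout`,
`render_svg`.

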