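# Methods

## Partitioning and signatures

The core operation maps each element of the union of n input sets
(2 ≤ n ≤ 6) to its n-bit membership signature, bit i−1 set iff the
element belongs to set i, with set 1 — the first spreadsheet column —
as the least-significant bit. The partition always stores all
2^n − 1 signatures, empty regions included, so a six-set comparison
always has 63 region keys. Region numbering equals the signature's
integer value: a deterministic, order-respecting bijection onto
1…2^n − 1 that is used consistently in every export. This convention
is this package's choice; nothing canonical forces it, but any
alternative would only permute column order.

Labels are compared string-exactly after canonicalization: whitespace
is trimmed, empty and whitespace-only cells dropped, duplicates
collapsed (with a logged count). Comparison is case-sensitive by
default because official gene and protein symbols are case-meaningful
(human GIT1 vs murine Git1); `--ignore-case` casefolds instead. No
fuzzy matching or identifier mapping is attempted.

## Classification against a reference set

A dose–response design lists the non-stimulated reference first and
the doses after it. Each signature gets exactly one of five codes:
GREEN iff all n bits are set; BLUE iff only the reference bit; RED iff
exactly one non-reference bit and no reference bit; GREY iff two or
more non-reference bits and no reference bit; BLACK otherwise
(reference plus some but not all doses). The reference-plus-exactly-
one-dose case is assigned to BLACK: such members are present in the
reference set and not unique to any dose, which is BLACK's defining
property, even though it involves only one dose. Exhaustive
enumeration for n = 6, reference = set 1 gives the census
(BLUE, RED, GREY, BLACK, GREEN) = (1, 5, 26, 30, 1).

## Dose-unique profile

`unique_counts` are the sizes of the RED regions; `unique_fractions`
divide by the total RED count and round half-up to integer percent
(raw fractions are retained in machine output). The
*stimulated-unique fraction* divides the total RED count by the number
of members present in at least one dose set but absent from the
reference — the RED + GREY mass. The denominator choice is genuinely
open (one could instead count all members of any dose set, reference
members included), so it is isolated in one place and switchable with
`--denominator all-stimulated`; the default matches the reading that
members shared with the non-stimulated state are not part of the
stimulated response.

## Cogwheel geometry

Screen coordinates, y growing downward. On a 600×600 canvas with a
20-unit margin: set 1 is the left half of the frame (x < cx), set 2
the upper half (y < cy), set 3 the disc ρ < r about the frame center
(r = 160 by default), and sets k = 4, 5, 6 the radial-graph cogwheels

    ρ < r · (1 + a_k · cos(m_k · θ + φ_k))

with teeth m = (2, 4, 8) — each successive curve doubles its teeth —
and nested amplitudes a = (0.50, 0.30, 0.17), chosen so each cog's
undulation stays well inside the previous one's and 1.5·r fits the
frame. All phases are zero. That phase choice is load-bearing: the
zeros of cos(m_k θ) fall at θ = π/4 + jπ/2, π/8 + jπ/4 and
π/16 + jπ/8 respectively, so every cog crosses the circle mid-quadrant
(never on the half-plane axes) and successive cogs' crossings
interleave. Phase offsets that put crossings on the axes (for example
φ₄ = π/2 with m₄ = 2) make patterns like {set 1, set 3} unrealizable
and fail validation.

These constants are configuration, not truth. `validate_layout`
grid-samples membership over the frame (default 1000×1000; it refuses
fewer than 10⁵ samples) and reports every realized n-bit pattern, the
missing ones, and the minimum sample count over the 2^n − 1 inside
patterns. The shipped defaults realize all patterns for every
n ∈ 2…6, with a minimum of 922 samples per region at n = 6 — the
thinnest cells are the outermost cog slivers. `build_layout` runs the
check and raises on failure, so an invalid geometry cannot be drawn.
A zero amplitude is the canonical degenerate case (the cog collapses
onto the circle, merging two predicates); equal amplitudes on
*different* cogs, perhaps surprisingly, still validate because the
differing teeth counts keep the curves crossing.

## Anchors and rendering

Region label anchors come from the same sampling: the anchor is the
centroid of the region's largest connected sample component (default
600×600 grid, connected components via scipy.ndimage); if the centroid
of a crescent-shaped cell falls outside the region, the anchor snaps
to the nearest in-region sample. The anchor invariant — its own
membership signature equals the region's — is asserted in tests for
every region at every n.

SVG output is one closed path per set (half-planes as frame-clipped
rectangles, the circle as two arcs, cogs as 720-point polylines),
translucent fills at 35% opacity over a fixed six-color palette, a
text element per non-empty region in the chosen display mode (counts,
region index, or member text truncated at 12 labels with an ellipsis)
and a `<title>` tooltip carrying the full membership — the static
analog of an interactive roll-over. Rendering is deterministic:
coordinates are formatted to two decimals and regions emitted in index
order, so identical inputs give identical bytes. The layout parameters
are embedded in the SVG `<desc>` as JSON; PNG export re-rasterizes the
membership grid from those parameters at pixel size canvas·dpi/96,
alpha-blending fills over white, which keeps the raster path free of
any external SVG renderer and byte-deterministic.

## Synthetic collections

The fixture generator inverts the partition: a plan prescribes a
member count per signature, and labels (`P<seed>_000001`, …) are
synthesized fresh and placed into exactly the sets their signature
names. The returned ground-truth partition must be recovered exactly
by `compute_partition` — an integer-arithmetic round trip asserted
property-based over hundreds of random plans. Distinct seeds embed the
seed in the label text and therefore give label-disjoint collections.
Columns are presented shuffled, as real input would be.

The shaped six-set plans model a muscarinic-receptor dose–response
phosphoproteomics design (reference plus doses 10 nM…100 µM, in a
normal and a chronic-minimal-peroxide-stressed cellular context).
Dose-unique (RED) counts follow published proportional splits —
control 15/15/21/22/27%; CMP 7% and 11% at the two lowest doses; GO
terms 24% (control 10 nM) vs 4%/54% (CMP 10 nM/100 µM); pathways 11%
(control 10 nM) — and the GREY mass is sized so the dose-unique
members are 36% (control family) or 38% (CMP family) of the
stimulated-only members, matching the published overall fractions by
integer construction. Splits the publication does not print are
synthetic fill summing to 100, and BLUE/BLACK/GREEN mass uses fixed
uncalibrated ratios; the plans therefore reproduce the printed
percentages through the real analysis code path but carry no
information about which individual proteins were involved, no
mass-spectrometry identification noise, and no peptide-level evidence
— passing tests certify the set arithmetic, not the biology. The
default scale of 100 dose-unique members per context mirrors the
order of magnitude of a six-condition phosphoprotein screen while
keeping all percentages exact integers.

## Numerical and interface choices

- Percentages round half-up to integers for display; raw values are
  kept alongside.
- XLSX reading touches only the first worksheet; numeric-looking cells
  are stringified verbatim (integral floats lose the spurious `.0`).
- Output format follows the file extension (`.xlsx` vs `.csv`);
  empty regions are omitted from region tables unless requested.
- Grid resolutions: 1000×1000 for validation, 600×600 for anchors,
  both tunable; tests use 400×400 to stay fast, which is already far
  above the coarseness floor.
- CLI exit codes: 2 unreadable/malformed input, 3 unsupported set
  count, 4 geometry failing validation, 5 mismatched condition names.

## Limitations

Layouts are topological, not area-proportional: region area carries no
information about region size, and no attempt is made to match any
particular published drawing — realizability of all regions is the
correctness criterion. Set counts outside 2…6 are hard errors. Label
matching is exact; synonyms, accession mapping and fuzzy matching are
out of scope, as are enrichment computations themselves (GO/pathway
lists are consumed as plain label sets).
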