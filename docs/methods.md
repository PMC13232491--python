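# Methods

## Statistics

All statistics are computed from per-scaffold records holding a length and
exact base-class counts (GC, AT, N), where classification is
case-insensitive and every character that is not A, C, G or T — including
IUPAC ambiguity codes and gap symbols — counts as N. This "non-ATGC"
policy is a deliberate conservative choice: ambiguity codes carry partial
information, but for contiguity scoring they behave like missing sequence.

- **Nx** uses the ≥ threshold: the length of the first scaffold, in
  descending order, at which cumulative length reaches x% of span. Ties are
  resolved by that first-reaching scaffold; scaffolds of equal length keep
  input order (stable sort), so all derived outputs are deterministic.
- **auN** is ΣL²/S. The **adjusted auN** substitutes squared ACGT counts in
  the numerator while the denominator remains the full span including Ns.
  The alternative (dividing by the ACGT sum) was rejected because it merely
  rescales auN by the ACGT fraction: under uniform N content f the ratio
  adjusted/unadjusted must be (1−f)², and only the full-span denominator
  produces that signature, which also matches the published values for an
  assembly with ~13% Ns (ratio 91.26/119.46 ≈ 0.76 ≈ 0.87²). A unit test
  pins this choice against the rescaling alternative.
- **Relative auN** is auN/Lmax; the **snail score** is adjusted auN/Lmax.
  Both lie in (0, 1] and equal 1 only for a single-scaffold (or
  equal-length) N-free assembly.

## Score corrections

With r_G = span/expected_span and r_S = longest/expected_longest:
g = base·min(1, r_G); gs = g·min(1, r_S); ag = base·r_G or base/r_G when
r_G > 1; ags = g·r_S or g/r_S when r_S > 1. Both scaffold-level corrections
(gs, ags) chain from the **clamped** g, not from ag: this is the only
chaining arithmetically consistent with the published reference-corrected
score table, which is treated as the binding oracle (the accompanying prose
quotes one value that contradicts the table's own arithmetic; the table is
followed). Variants whose expectation is absent are reported as absent
rather than defaulted. A reference assembly supplies expected_span (its
span) and expected_longest (its longest scaffold); explicit `--max-span` /
`--max-scaffold` values override the reference-derived ones, so the same
flags control both plot scaling and score correction.

## Binning

Size-sorted scaffolds are laid end to end along the cumulative span and
summarized over `segments` equal-width bins (default 1,000, i.e. 0.1% of
the axis each). Intervals are half-open in 0-based cumulative coordinates,
so a scaffold overlaps a bin iff the intervals intersect; no boundary is
counted twice. Each bin records min/max overlapping scaffold length, GC
mean/min/max, mean N fraction, and the cumulative scaffold count. Bins
beyond the assembly span (when the axis is scaled to a larger `--max-span`
or reference) are flagged empty and not drawn. The drawn radial value per
bin is the *shortest* overlapping scaffold — the conservative reading of
the track's meaning — while the longest is retained in the statistics
export for consumers that prefer it.

## BUSCO summarization

Markers are resolved from the full hit table: ≥2 retained
Complete/Duplicated hits → Duplicated; exactly one → Complete (single);
otherwise Fragmented if any retained hit is Fragmented; else Missing.
Complete includes the duplicated subset (BUSCO convention). Scaffold
filtering drops hits before resolution, so removing one copy of a
duplicated marker correctly demotes it to complete-single. When records
come from a stored dataset (which holds only hits), the marker total is
carried in the dataset metadata so the missing fraction stays correct.

## Rendering

The SVG is a pure function of its inputs (fixed palette, fixed float
formatting), so identical inputs give byte-identical documents. Radius
budget (fractions of plot radius): cumulative-count region 0–0.25, scaffold
lengths 0.25–0.85, composition track 0.85–1.0 — invented plumbing with no
external meaning. The count axis is log₁₀ with count 1 at the center and
full shading out to 10^⌈log₁₀ n⌉ at the region's outer edge; white gridline
circles mark each crossed power of ten from 10. Angles start at 12 o'clock
and run clockwise; the swept angle is 360°·span/max_span. The N50/N90
overlays span exactly 50%/90% of the swept angle at the radius of their
respective lengths; the red longest-scaffold overlay is drawn only when the
first bin contains exactly one scaffold. Radial scale functions: linear
L/Lmax (default), sqrt, and log₁₀ with lengths below 1 clamped to 0; badge
mode forces linear so text-free badges stay comparable, and removes every
text element. Composition-track band widths split the track as: N fraction
as white space halved onto both edges, the remainder GC (dark, outer) vs AT
(light, inner) in proportion, with the per-bin GC min–max range drawn as a
mid-tone band about the mean boundary. Reference overlays draw shading
below the target distribution and a line above it, continuing across the
composition track when the reference span ends before the target's.

Number formatting: absolute values are rounded to `--significant-digits`
(default 3) with kb/Mb/Gb suffixes at 10³ steps; percentages to
`--decimal-precision` (default 2) decimal places. Strategies: `round` is
half-away-from-zero, `down` truncates toward zero, `up` rounds away from
zero. Scores are stored at full precision and displayed at 3 dp.

PNG export rasterizes the SVG through the optional `cairosvg` package and
raises a clear configuration error when it is not installed; SVG, JSON and
YAML outputs have no optional dependencies.

## Synthetic data generator

The generator emulates only the statistical structure the statistics
consume: scaffold length distributions, per-scaffold GC targets, and
interspersed N runs — not genes, repeats, or other biological sequence
features, so passing tests say nothing about, e.g., BUSCO behaviour on real
gene content. Profiles:

- **chromosomal**: `chromosome_count` near-equal chromosomes (deterministic
  ±10% linear spread over 96% of the genome) plus a short-scaffold tail
  holding ~4% of the span, mirroring the long/short split typical of
  chromosome-level assemblies.
- **fragmented / custom**: log-normal lengths with median `mean_length` and
  log-sd `length_sigma` (default 1.0, a realistically heavy tail), drawn by
  stratified inverse-CDF sampling — scaffold i takes the (i−0.5)/n quantile
  — then rescaled to sum exactly to `genome_size`. Lengths are therefore a
  deterministic function of the profile; the seeded generator drives only
  base composition (per-scaffold GC ~ Normal(gc_mean, gc_sd), default
  0.41 ± 0.02) and N-run placement (`n_run_rate` expected N bases per kb,
  placed as geometric runs of mean ~300 bases). This makes contiguity
  statistics reproducible across seeds while keeping sequence content
  seed-dependent; identical seeds give byte-identical FASTA output.

A `CONTIGUITY_LADDER` of five stock profiles at a 10 Mb genome spans
scaffold scales from ~1 kb fragments (with 6–8% Ns) to a single
chromosome; its snail scores (~0.09, 0.16, 0.34, 0.88, 0.96) increase
strictly with contiguity and separate the fragmented (<0.4) from the
chromosomal (>0.6) regimes. The 10 Mb genome size keeps the full ladder
under a few seconds while leaving >3 orders of magnitude between scaffold
scales.

Exact truth records (per-scaffold lengths and base counts, recounted from
the final sequences) are written as a YAML sidecar next to each FASTA so
tests can verify the FASTA reader independently.

## Interfaces and numerical choices

The minimal dataset directory stores one JSON file per field (`meta.json`,
`length.json`, `gc.json`, `n.json`, `ncount.json`, optional
`{lineage}_busco.json`), with `.json.gz` accepted on read. GC is stored as
the proportion of ATGC bases and N counts as integers, so integer base
counts round-trip exactly. Remote sources are fetched over http(s) only.
Zero-length FASTA records are rejected (their proportions are undefined).
Empty scaffold sets after filtering are an error rather than an empty
result, since every downstream statistic would be undefined.

## Known limitations

- No alignment-derived fields (coverage, taxonomy hits) and no windowed
  within-scaffold GC; composition is averaged per scaffold, so one
  chromosome contributes a constant value to all its bins.
- Contig-level (gap-split) statistics are not computed; the N adjustment of
  the snail score is the only gap-awareness.
- The score ceiling depends on karyotype; cross-taxon comparisons should
  consult the plot, not the score alone.
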