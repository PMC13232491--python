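# snailplot

Snail plots are circular "badge" summaries of genome assembly quality: one
SVG that simultaneously shows assembly span, the full size-sorted scaffold
length distribution, N50/N90, cumulative scaffold counts, base composition
(GC/AT/N), and BUSCO completeness. Because the radial axis is scaled to the
longest scaffold and the circumferential axis to the assembly span, badges
can be compared at a glance across taxa whose genomes differ by orders of
magnitude.

`snailplot` computes the underlying statistics from any assembly FASTA
(plain or gzip, local or http), optionally with a BUSCO full-table TSV
(v4/v5/v6), renders the layered SVG badge, and computes the **snail score**
family of scale-independent contiguity metrics.

## The snail score

For scaffold lengths L₁…Lₙ with span S = ΣLᵢ and longest scaffold Lmax:

- **auN** (E-size): ΣLᵢ²⁄S — the expected length of the scaffold containing
  a randomly chosen base.
- **relative auN**: auN⁄Lmax ∈ (0, 1], a scale-independent contiguity value.
- **snail score**: Σaᵢ²⁄S⁄Lmax where aᵢ is the count of ACGT bases in
  scaffold i. Substituting ACGT counts for lengths in the numerator (the
  denominator keeps the full span, Ns included) stops long N gap runs from
  inflating apparent contiguity.

With an expected genome size G* (e.g. a T2T reference span) and expected
longest scaffold L* the corrected variants are, with r_G = S⁄G* and
r_S = Lmax⁄L*:

| variant | formula | guards against |
|---|---|---|
| snail-G | base · min(1, r_G) | over-filtering / incomplete assembly |
| snail-GS | G · min(1, r_S) | premature scaffold breaks |
| snail-aG | base · (r_G if r_G ≤ 1 else 1/r_G) | off-target data, uncollapsed haplotypes |
| snail-aGS | G · (r_S if r_S ≤ 1 else 1/r_S) | overly aggressive scaffolding |

Scores above ~0.6 broadly indicate chromosome-quality assemblies, though the
ceiling for a taxon depends on its karyotype (a single dominant chromosome
depresses the maximum achievable score even for a perfect assembly).

## Worked example

Generate a synthetic chromosome-level assembly (12 chromosomes, 10 Mb) and a
BUSCO table, then plot and score it:

```sh
snail fixtures assembly --kind chromosomal --genome-size 10000000 \
      --chromosome-count 12 --seed 42 -o .
snail fixtures busco --markers 255 --complete 0.95 --duplicated 0.02 \
      --fragmented 0.02 --scaffold-ids chr_1,chr_2,...,chr_12 -o full_table.tsv

snail --fasta assembly.fasta --busco full_table.tsv -d blobdir -o plot.svg
snail --fasta assembly.fasta --score-only
```

This writes `plot.svg`, a reusable intermediate dataset in `blobdir/`, and
prints:

```
0.877
```

The assembly summarizes to span 10,000,000 bp in 62 scaffolds (12
chromosomes plus a short-scaffold tail), longest 880,000 bp, N50 807,273 bp,
N90 720,000 bp. A base snail score of 0.877 reflects near-equal chromosome
lengths: auN sits close to the longest scaffold. A fragmented variant of the
same genome (`--kind fragmented --mean-length 5000 --n-run-rate 60`) scores
0.135, and comparing it against the chromosomal assembly as a reference adds
the corrected variants:

```sh
snail --fasta frag.fasta --reference assembly.fasta --score-json
```

```json
{
 "base": 0.13512467048786672,
 "g": 0.13512467048786672,
 "gs": 0.021805129496931818,
 ...
}
```

The span matches the reference, so snail-G is unchanged, but the longest
fragment is far below the reference's longest chromosome, so snail-GS
collapses to 0.022.

Other output formats: `-o plot.png` (needs cairosvg), `-o stats.yaml` /
`-o stats.json` for the full processed statistics; `--badge` renders a
text-free badge; `-f "length:min=1,000"` filters scaffolds before all
statistics.

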