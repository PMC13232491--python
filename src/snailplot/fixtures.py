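"""Deterministic synthetic assemblies and BUSCO tables for testing.

The generator emulates the statistical structure that the QC statistics
consume — scaffold length distributions, per-scaffold GC, interspersed N
runs, BUSCO status mixes — not biologically realistic sequence.

Two stock profile kinds mirror the extremes seen in real assemblies:

* ``chromosomal``: a handful of near-equal chromosome-scale scaffolds with a
  short-scaffold tail holding ~4% of the span.
* ``fragmented``: a heavy-tailed log-normal length distribution with many
  scaffolds and, optionally, interspersed N runs.

``custom`` exposes the log-normal parameters directly. Scaffold lengths are
drawn deterministically by stratified inverse-CDF sampling (the i-th
scaffold takes the (i-0.5)/n quantile of the length distribution), so a
profile's contiguity statistics are a fixed function of its parameters; the
seeded random generator drives base composition and N-run placement only.
Identical seeds therefore produce byte-identical output.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import ndtri

from .assembly_io import SequenceRecord
from .errors import ConfigError

_LUT = np.frombuffer(b"GCAT", dtype=np.uint8)
_N = ord("N")


@dataclass
class AssemblyProfile:
    """Parameters controlling one synthetic assembly.

    ``mean_length`` is the median scaffold length of the log-normal kinds
    (bases); ``length_sigma`` its log-scale sd; ``n_run_rate`` the expected
    N bases per kb of scaffold; ``gc_mean``/``gc_sd`` the per-scaffold GC
    target distribution.
    """

    kind: str = "chromosomal"
    genome_size: int = 10_000_000
    chromosome_count: int = 10
    mean_length: float = 10_000.0
    length_sigma: float = 1.0
    gc_mean: float = 0.41
    gc_sd: float = 0.02
    n_run_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("chromosomal", "fragmented", "custom"):
            raise ConfigError(f"unknown profile kind {self.kind!r}")
        if self.genome_size < 1000:
            raise ConfigError("genome_size must be at least 1 kb")
        if self.kind == "chromosomal" and self.chromosome_count > self.genome_size // 1000:
            raise ConfigError(
                f"chromosome_count {self.chromosome_count} infeasible for genome_size {self.genome_size}"
            )
        if self.mean_length <= 0 or self.length_sigma < 0:
            raise ConfigError("mean_length must be positive and length_sigma non-negative")
        if not 0 < self.gc_mean < 1:
            raise ConfigError("gc_mean must be in (0, 1)")
        if self.n_run_rate < 0 or self.n_run_rate > 1000:
            raise ConfigError("n_run_rate must be within [0, 1000] N bases per kb")


def _rescale_to_genome(raw: np.ndarray, genome_size: int, min_length: int = 100) -> np.ndarray:
    """Scale raw lengths to sum exactly to genome_size (largest absorbs rounding)."""
    lengths = np.maximum(np.round(raw * (genome_size / raw.sum())).astype(np.int64), min_length)
    lengths = -np.sort(-lengths)
    lengths[0] += genome_size - lengths.sum()
    if lengths[0] < 1:
        raise ConfigError("infeasible profile: rescaling produced a non-positive scaffold length")
    return lengths


def scaffold_lengths(profile: AssemblyProfile) -> np.ndarray:
    """Deterministic descending scaffold lengths summing to genome_size."""
    g = profile.genome_size
    if profile.kind == "chromosomal":
        count = profile.chromosome_count
        # near-equal chromosomes with a deterministic +/-10% linear spread
        spread = np.linspace(1.1, 0.9, count) if count > 1 else np.array([1.0])
        main = spread * (0.96 * g / count)
        tail_unit = max(1000.0, main.mean() / 100.0)
        tail_count = max(1, int(round(0.04 * g / tail_unit)))
        tail = np.full(tail_count, tail_unit) * np.linspace(1.2, 0.8, tail_count)
        raw = np.concatenate([main, tail])
    else:
        mu = np.log(profile.mean_length)
        sigma = profile.length_sigma
        mean_len = profile.mean_length * np.exp(sigma**2 / 2.0)
        n = max(1, int(round(g / mean_len)))
        if n == 1:
            raw = np.array([float(g)])
        else:
            q = (np.arange(n) + 0.5) / n
            raw = np.exp(mu + sigma * ndtri(q))
    return _rescale_to_genome(raw, g)


def _synthesize_sequence(length: int, gc_target: float, n_run_rate: float, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(length)
    codes = np.digitize(u, [gc_target / 2.0, gc_target, gc_target + (1.0 - gc_target) / 2.0])
    seq = _LUT[codes].copy()
    if n_run_rate > 0:
        target_n = int(length * n_run_rate / 1000.0)
        placed = 0
        # geometric run lengths, mean ~300 bases, overlaps allowed
        while placed < target_n:
            run = int(min(rng.geometric(1.0 / 300.0), target_n - placed, length))
            start = int(rng.integers(0, max(1, length - run + 1)))
            seq[start : start + run] = _N
            placed += run
    return seq


def build_assembly(profile: AssemblyProfile) -> tuple[list[SequenceRecord], list[np.ndarray], dict]:
    """Generate records, raw sequence arrays (uint8), and the truth record.

    The truth record holds exact per-scaffold lengths and base counts,
    recomputed from the final sequences, so it can be checked independently
    against a re-read of the written FASTA.
    """
    rng = np.random.default_rng(profile.seed)
    lengths = scaffold_lengths(profile)
    prefix = "chr" if profile.kind == "chromosomal" else "scaffold"
    records: list[SequenceRecord] = []
    sequences: list[np.ndarray] = []
    truth_scaffolds = []
    for i, length in enumerate(lengths):
        gc_target = float(np.clip(rng.normal(profile.gc_mean, profile.gc_sd), 0.05, 0.95))
        seq = _synthesize_sequence(int(length), gc_target, profile.n_run_rate, rng)
        counts = np.bincount(seq, minlength=256)
        gc = int(counts[ord("G")] + counts[ord("C")])
        at = int(counts[ord("A")] + counts[ord("T")])
        n = int(length) - gc - at
        rec = SequenceRecord(id=f"{prefix}_{i + 1}", length=int(length), gc_count=gc, at_count=at, n_count=n)
        records.append(rec)
        sequences.append(seq)
        truth_scaffolds.append(
            {"id": rec.id, "length": rec.length, "gc_count": gc, "at_count": at, "n_count": n}
        )
    truth = {
        "profile": asdict(profile),
        "span": int(lengths.sum()),
        "scaffold_count": len(records),
        "scaffolds": truth_scaffolds,
    }
    return records, sequences, truth


def generate_assembly(
    profile: AssemblyProfile,
    out_dir,
    name: str = "assembly",
    compress: bool = False,
) -> tuple[Path, dict]:
    """Write a synthetic assembly FASTA plus a YAML truth sidecar.

    Returns ``(fasta_path, truth)``. ``compress`` writes gzip FASTA.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, sequences, truth = build_assembly(profile)
    fasta_path = out_dir / (f"{name}.fasta.gz" if compress else f"{name}.fasta")
    opener = _gzip.open if compress else open
    with opener(fasta_path, "wb") as fh:
        for rec, seq in zip(records, sequences):
            fh.write(f">{rec.id}\n".encode())
            raw = seq.tobytes()
            for off in range(0, len(raw), 80):
                fh.write(raw[off : off + 80] + b"\n")
    truth_path = out_dir / f"{name}.truth.yaml"
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return fasta_path, truth


_BUSCO_HEADERS = {
    4: (
        "# BUSCO version is: 4.1.4",
        "# The lineage dataset is: {lineage} (Creation date: 2024-01-08, number of species: 70, number of BUSCOs: {markers})",
        "# Busco id\tStatus\tSequence\tGene Start\tGene End\tScore\tLength",
    ),
    5: (
        "# BUSCO version is: 5.7.1",
        "# The lineage dataset is: {lineage} (Creation date: 2024-01-08, number of species: 70, number of BUSCOs: {markers})",
        "# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength\tOrthoDB url\tDescription",
    ),
    6: (
        "# BUSCO version is: 6.0.0",
        "# The lineage dataset is: {lineage} (Creation date: 2025-01-15, number of species: 70, number of BUSCOs: {markers})",
        "# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength\tOrthoDB url\tDescription",
    ),
}


def generate_busco_table(
    markers: int,
    complete_fraction: float,
    duplicated_fraction: float,
    fragmented_fraction: float,
    scaffold_ids: Sequence[str],
    version: int = 5,
    seed: int = 1,
    dest=None,
    lineage: str = "eukaryota_odb10",
) -> Path:
    """Write a BUSCO full-table TSV with the requested status mix.

    Marker counts are exact (``round(fraction * markers)``), so summarizing
    the parsed table reproduces the requested fractions to within 1/markers.
    Duplicated markers are a subset of complete and get two rows each.
    """
    if version not in _BUSCO_HEADERS:
        raise ConfigError(f"unsupported BUSCO table version {version}; supported: 4, 5, 6")
    for name, frac in (
        ("complete_fraction", complete_fraction),
        ("duplicated_fraction", duplicated_fraction),
        ("fragmented_fraction", fragmented_fraction),
    ):
        if not 0 <= frac <= 1:
            raise ConfigError(f"{name} must be in [0, 1], got {frac}")
    if duplicated_fraction > complete_fraction:
        raise ConfigError("duplicated_fraction cannot exceed complete_fraction")
    if complete_fraction + fragmented_fraction > 1 + 1e-9:
        raise ConfigError("complete_fraction + fragmented_fraction cannot exceed 1")
    if markers < 1:
        raise ConfigError("markers must be >= 1")
    if not scaffold_ids:
        raise ConfigError("scaffold_ids must be non-empty")
    if dest is None:
        raise ConfigError("dest path is required")

    n_complete = round(markers * complete_fraction)
    n_dup = round(markers * duplicated_fraction)
    n_frag = round(markers * fragmented_fraction)
    n_dup = min(n_dup, n_complete)
    n_frag = min(n_frag, markers - n_complete)

    rng = np.random.default_rng(seed)
    ids = [f"{10000 + i}at2759" for i in range(markers)]
    scaffolds = list(scaffold_ids)

    def row(busco_id: str, status: str, scaffold: Optional[str]) -> str:
        if scaffold is None:
            return f"{busco_id}\t{status}"
        start = int(rng.integers(1, 1_000_000))
        end = start + int(rng.integers(200, 5000))
        score = f"{rng.uniform(100, 2000):.1f}"
        length = end - start
        if version == 4:
            return f"{busco_id}\t{status}\t{scaffold}\t{start}\t{end}\t{score}\t{length}"
        strand = "+" if rng.random() < 0.5 else "-"
        url = f"https://v100.orthodb.org/?query={busco_id.split('at')[0]}"
        return (
            f"{busco_id}\t{status}\t{scaffold}\t{start}\t{end}\t{strand}\t{score}\t{length}\t{url}\tsynthetic marker"
        )

    lines = list(_BUSCO_HEADERS[version])
    lines = [line.format(lineage=lineage, markers=markers) for line in lines]
    for i, busco_id in enumerate(ids):
        if i < n_dup:
            for _ in range(2):
                lines.append(row(busco_id, "Duplicated", scaffolds[int(rng.integers(0, len(scaffolds)))]))
        elif i < n_complete:
            lines.append(row(busco_id, "Complete", scaffolds[int(rng.integers(0, len(scaffolds)))]))
        elif i < n_complete + n_frag:
            lines.append(row(busco_id, "Fragmented", scaffolds[int(rng.integers(0, len(scaffolds)))]))
        else:
            lines.append(row(busco_id, "Missing", None))

    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text("\n".join(lines) + "\n")
    return dest


#: Profiles ordered by increasing contiguity at a 10 Mb genome, spanning
#: scaffold-length scales from ~1 kb to a single chromosome. Fragmented
#: entries carry interspersed N runs, as real scaffolded assemblies do.
CONTIGUITY_LADDER: tuple[tuple[str, AssemblyProfile], ...] = (
    ("fragmented-1kb", AssemblyProfile(kind="fragmented", mean_length=1_000.0, length_sigma=1.0, n_run_rate=80.0)),
    ("fragmented-10kb", AssemblyProfile(kind="fragmented", mean_length=10_000.0, length_sigma=1.0, n_run_rate=60.0)),
    ("scaffolded-100kb", AssemblyProfile(kind="custom", mean_length=100_000.0, length_sigma=1.0)),
    ("chromosomal-10", AssemblyProfile(kind="chromosomal", chromosome_count=10)),
    ("chromosomal-1", AssemblyProfile(kind="chromosomal", chromosome_count=1)),
)
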