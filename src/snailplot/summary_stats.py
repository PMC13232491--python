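"""Whole-assembly statistics, Nx/auN contiguity metrics, and bin series.

The statistics here are the standard contiguity family: Nx (length of the
scaffold at which cumulative size-sorted length first reaches x% of span),
auN / E-size (sum of squared scaffold lengths over span — the expected length
of the scaffold containing a randomly chosen base), and an N-adjusted auN in
which each scaffold's squared length is replaced by the squared count of its
ACGT bases while the denominator remains the full span including Ns.

``bin_assembly`` lays size-sorted scaffolds end to end along the cumulative
span and summarizes them over equal-width half-open bins; this series drives
the circular plot axis.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .assembly_io import BuscoGene, SequenceRecord
from .errors import ConfigError, InputError


@dataclass
class AssemblySummary:
    """Whole-assembly statistics over the (filtered) scaffold set."""

    span: int
    scaffold_count: int
    longest: int
    n50: int
    n90: int
    aun: float
    adjusted_aun: float
    gc_fraction: float
    at_fraction: float
    n_fraction: float
    sorted_lengths: list[int]


@dataclass
class BinSummary:
    """Per-segment summary of all scaffolds overlapping one cumulative-span bin."""

    index: int
    span_start: float
    span_end: float
    min_length: int
    max_length: int
    gc_mean: float
    gc_min: float
    gc_max: float
    n_fraction_mean: float
    cumulative_count: int
    empty: bool = False


@dataclass
class BuscoSummary:
    """BUSCO status proportions over distinct markers.

    ``complete`` follows BUSCO convention and includes the duplicated subset,
    so ``complete == single + duplicated``.
    """

    lineage: str
    total: int
    complete_fraction: float
    single_fraction: float
    duplicated_fraction: float
    fragmented_fraction: float
    missing_fraction: float


def _descending(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    # stable sort: equal lengths stay in input order
    return sorted(records, key=lambda r: -r.length)


def compute_nx(sorted_lengths: Sequence[int], x: float) -> int:
    """Nx: length of the first scaffold at which cumulative length >= x% of span.

    ``sorted_lengths`` must be non-increasing. The threshold uses >=, with
    ties resolved by the scaffold that first reaches it in descending order.
    """
    if len(sorted_lengths) == 0:
        raise InputError("cannot compute Nx of an empty assembly")
    if not 0 < x <= 100:
        raise ConfigError(f"Nx percentage must be in (0, 100], got {x}")
    span = sum(sorted_lengths)
    threshold = span * x / 100.0
    cumulative = 0
    for length in sorted_lengths:
        cumulative += length
        if cumulative >= threshold:
            return length
    return sorted_lengths[-1]  # unreachable barring float corner cases


def compute_aun(records: Sequence[SequenceRecord], adjusted: bool = False) -> float:
    """auN = sum(L_i^2) / span; adjusted replaces L_i^2 by (ACGT_i)^2.

    The denominator is always the full span including Ns, so the adjusted
    value is <= the unadjusted one and equal only for N-free assemblies.
    """
    if not records:
        raise InputError("cannot compute auN of an empty assembly")
    span = sum(r.length for r in records)
    if span <= 0:
        raise InputError("cannot compute auN: zero span")
    if adjusted:
        num = sum(r.acgt_count ** 2 for r in records)
    else:
        num = sum(r.length ** 2 for r in records)
    return num / span


def summarize_assembly(records: Sequence[SequenceRecord]) -> AssemblySummary:
    """Compute the full statistics set for one assembly (order-invariant)."""
    if not records:
        raise InputError("cannot summarize an empty assembly")
    lengths = sorted((r.length for r in records), reverse=True)
    span = sum(lengths)
    gc = sum(r.gc_count for r in records)
    at = sum(r.at_count for r in records)
    n = sum(r.n_count for r in records)
    atgc = gc + at
    return AssemblySummary(
        span=span,
        scaffold_count=len(lengths),
        longest=lengths[0],
        n50=compute_nx(lengths, 50),
        n90=compute_nx(lengths, 90),
        aun=compute_aun(records, adjusted=False),
        adjusted_aun=compute_aun(records, adjusted=True),
        gc_fraction=gc / atgc if atgc else 0.0,
        at_fraction=at / atgc if atgc else 0.0,
        n_fraction=n / span,
        sorted_lengths=lengths,
    )


def bin_assembly(
    records: Sequence[SequenceRecord],
    segments: int,
    max_span: Optional[float] = None,
) -> list[BinSummary]:
    """Summarize size-sorted scaffolds over equal-width cumulative-span bins.

    Scaffolds are laid end to end in descending length order; a scaffold with
    cumulative interval [s, e) overlaps bin b iff it intersects the bin's
    half-open interval [b*w, (b+1)*w) where w = max_span / segments. Bins
    entirely beyond the assembly span (when ``max_span`` exceeds it) are
    flagged ``empty``.
    """
    if segments < 1:
        raise ConfigError(f"segments must be >= 1, got {segments}")
    if not records:
        raise InputError("cannot bin an empty assembly")
    recs = _descending(records)
    lengths = np.array([r.length for r in recs], dtype=float)
    span = float(lengths.sum())
    if max_span is None:
        max_span = span
    width = max_span / segments
    ends = np.cumsum(lengths)
    starts = ends - lengths
    gcs = np.array([r.gc_fraction for r in recs])
    nfracs = np.array([r.n_fraction for r in recs])
    n = len(recs)
    bins: list[BinSummary] = []
    lo = 0
    hi = 0
    for b in range(segments):
        bs = b * width
        be = (b + 1) * width
        if bs >= span:
            bins.append(
                BinSummary(
                    index=b, span_start=bs, span_end=be,
                    min_length=0, max_length=0,
                    gc_mean=0.0, gc_min=0.0, gc_max=0.0,
                    n_fraction_mean=0.0, cumulative_count=n, empty=True,
                )
            )
            continue
        while hi < n and starts[hi] < be:
            hi += 1
        while lo < hi - 1 and ends[lo] <= bs:
            lo += 1
        sl = slice(lo, hi)
        bins.append(
            BinSummary(
                index=b,
                span_start=bs,
                span_end=be,
                min_length=int(lengths[hi - 1]),
                max_length=int(lengths[lo]),
                gc_mean=float(gcs[sl].mean()),
                gc_min=float(gcs[sl].min()),
                gc_max=float(gcs[sl].max()),
                n_fraction_mean=float(nfracs[sl].mean()),
                cumulative_count=hi,
            )
        )
    return bins


def summarize_busco(
    genes: Sequence[BuscoGene],
    filter_scaffolds: Optional[set[str]] = None,
    lineage: str = "unknown",
    total: Optional[int] = None,
) -> BuscoSummary:
    """Resolve per-marker statuses and return proportions over distinct markers.

    A marker is Duplicated if it has >= 2 retained Complete/Duplicated hits,
    Complete (single) if it has exactly one, Fragmented if its best retained
    hit is Fragmented, else Missing. ``filter_scaffolds``, when given, drops
    hits on excluded scaffolds before status resolution. ``total`` overrides
    the marker count (used when Missing markers are not listed explicitly,
    as in dataset-derived hit lists).
    """
    if not genes and total is None:
        raise InputError("cannot summarize an empty BUSCO gene list")
    by_id: dict[str, list[BuscoGene]] = defaultdict(list)
    for g in genes:
        by_id[g.busco_id].append(g)
    n_markers = total if total is not None else len(by_id)
    single = duplicated = fragmented = 0
    for hits in by_id.values():
        retained = [
            h for h in hits
            if h.scaffold_id is not None
            and (filter_scaffolds is None or h.scaffold_id in filter_scaffolds)
        ]
        complete_hits = [h for h in retained if h.status in ("Complete", "Duplicated")]
        if len(complete_hits) >= 2:
            duplicated += 1
        elif len(complete_hits) == 1:
            single += 1
        elif any(h.status == "Fragmented" for h in retained):
            fragmented += 1
    missing = n_markers - single - duplicated - fragmented
    complete = single + duplicated
    if n_markers <= 0:
        raise InputError("BUSCO marker total must be positive")
    return BuscoSummary(
        lineage=lineage,
        total=n_markers,
        complete_fraction=complete / n_markers,
        single_fraction=single / n_markers,
        duplicated_fraction=duplicated / n_markers,
        fragmented_fraction=fragmented / n_markers,
        missing_fraction=missing / n_markers,
    )
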