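"""Assembly and BUSCO ingest plus the minimal BlobDir-style dataset.

Reads assembly FASTA files (plain or gzip, local path or http(s) URL) into
:class:`SequenceRecord` values carrying per-scaffold base composition, parses
BUSCO full-table TSVs (v4/v5/v6 column dialects, odb10/odb12 lineages), and
round-trips the minimal per-field JSON dataset directory used as the
intermediate representation between ingest and plotting.

Base classification is case-insensitive; any character that is not A, C, G or
T (so N, IUPAC ambiguity codes, and gap characters) is counted as N.
"""

from __future__ import annotations

import glob as _glob
import gzip
import json
import os
import re
import shutil
import tempfile
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConsistencyError, InputError, ParseError

BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")

# mandatory per-field files of the minimal dataset
_MANDATORY_FIELDS = ("meta", "length", "gc", "n", "ncount")


@dataclass
class SequenceRecord:
    """One scaffold: identifier, length, and exact base-class counts.

    ``gc_count + at_count + n_count == length`` always holds; every base is
    classified into exactly one of the three classes.
    """

    id: str
    length: int
    gc_count: int
    at_count: int
    n_count: int
    busco_hits: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty identifier")
        if self.length < 1:
            raise InputError(f"sequence {self.id!r} has length {self.length}; empty sequences are not allowed")
        if self.gc_count + self.at_count + self.n_count != self.length:
            raise ConsistencyError(
                f"sequence {self.id!r}: base counts {self.gc_count}+{self.at_count}+{self.n_count} "
                f"do not sum to length {self.length}"
            )

    @property
    def acgt_count(self) -> int:
        """Number of unambiguous bases (length minus Ns)."""
        return self.length - self.n_count

    @property
    def gc_fraction(self) -> float:
        """GC proportion of ATGC bases (0.0 when the scaffold is all Ns)."""
        atgc = self.gc_count + self.at_count
        return self.gc_count / atgc if atgc else 0.0

    @property
    def n_fraction(self) -> float:
        return self.n_count / self.length


@dataclass
class BuscoGene:
    """A single BUSCO full-table row: marker id, status, and scaffold hit.

    Missing markers carry no scaffold. Duplicated markers appear as multiple
    rows sharing one ``busco_id``.
    """

    busco_id: str
    status: str
    scaffold_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in BUSCO_STATUSES:
            raise ParseError(
                f"unknown BUSCO status {self.status!r}; expected one of {', '.join(BUSCO_STATUSES)}"
            )
        if self.status == "Missing":
            self.scaffold_id = None


@dataclass
class BlobDirBundle:
    """In-memory mirror of an on-disk minimal dataset directory."""

    meta: dict
    length_values: list[int]
    gc_values: list[float]
    n_values: list[float]
    ncount_values: list[int]
    busco_values: Optional[dict[str, list]] = None

    def __post_init__(self) -> None:
        n = self.meta.get("records")
        for name in ("length_values", "gc_values", "n_values", "ncount_values"):
            vals = getattr(self, name)
            if len(vals) != n:
                raise ConsistencyError(f"{name} has {len(vals)} entries but meta reports {n} records")


def _is_url(source) -> bool:
    return isinstance(source, str) and re.match(r"https?://", source) is not None


def _fetch(source) -> Path:
    """Resolve a path-or-URL to a local file path, downloading if needed."""
    if _is_url(source):
        suffix = os.path.basename(source.split("?")[0]) or "download"
        tmp = tempfile.NamedTemporaryFile(delete=False, prefix="snailplot-", suffix="-" + suffix)
        tmp.close()
        try:
            with urllib.request.urlopen(source) as resp, open(tmp.name, "wb") as out:
                shutil.copyfileobj(resp, out)
        except OSError as exc:
            raise InputError(f"cannot fetch {source}: {exc}") from exc
        return Path(tmp.name)
    path = Path(source)
    if not path.exists():
        raise InputError(f"cannot read input: {path}")
    return path


def _open_text(path: Path):
    """Open plain or gzip-compressed text transparently (magic-byte sniff)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _classify(seq: str) -> tuple[int, int, int]:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    return gc, at, len(s) - gc - at


def read_fasta(source) -> list[SequenceRecord]:
    """Read an assembly FASTA (plain/gzip, path or URL) into sequence records.

    One record per sequence, in file order. Raises :class:`InputError` for
    missing/empty sources and :class:`ParseError` for malformed content.
    """
    path = _fetch(source)
    with _open_text(path) as fh:
        # Locate the first non-blank line to give a line-numbered error for
        # content that precedes any FASTA header.
        lineno = 0
        first = None
        for line in fh:
            lineno += 1
            if line.strip():
                first = line
                break
        if first is None:
            raise InputError(f"no sequences in {source}")
        if not first.startswith(">"):
            raise ParseError(f"{source}: line {lineno}: expected FASTA header starting with '>'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else ""
            if not name:
                raise ParseError(f"{source}: FASTA record with empty identifier")
            if name in seen:
                raise ParseError(f"{source}: duplicate sequence identifier {name!r}")
            seen.add(name)
            seq = "".join(seq.split())
            if not seq:
                raise InputError(f"{source}: sequence {name!r} is empty")
            gc, at, n = _classify(seq)
            records.append(SequenceRecord(id=name, length=len(seq), gc_count=gc, at_count=at, n_count=n))
    if not records:
        raise InputError(f"no sequences in {source}")
    return records


_LINEAGE_PATTERNS = (
    re.compile(r"lineage dataset is:\s*(\S+)"),
    re.compile(r"lineage_dataset:\s*(\S+)"),
)


def parse_busco_table(source) -> tuple[str, list[BuscoGene]]:
    """Parse a BUSCO full-table TSV into ``(lineage, genes)``.

    Compatible with the v4, v5 and v6 column dialects: only the first three
    columns (busco id, status, sequence) are used. The lineage name is taken
    from the header comments when present, else ``"unknown"``.
    """
    path = _fetch(source)
    lineage = "unknown"
    genes: list[BuscoGene] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for pat in _LINEAGE_PATTERNS:
                    m = pat.search(line)
                    if m:
                        lineage = m.group(1)
                        break
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{source}: expected tab-separated busco_id and status, got {line!r}")
            busco_id, status = cols[0].strip(), cols[1].strip()
            scaffold = cols[2].strip() if len(cols) > 2 and cols[2].strip() else None
            if status not in BUSCO_STATUSES:
                raise ParseError(
                    f"{source}: unknown BUSCO status {status!r}; expected one of {', '.join(BUSCO_STATUSES)}"
                )
            genes.append(BuscoGene(busco_id=busco_id, status=status, scaffold_id=scaffold))
    if not genes:
        raise ParseError(f"{source}: no data rows in BUSCO table")
    return lineage, genes


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def write_blobdir(
    records: list[SequenceRecord],
    lineage: Optional[str],
    dest,
    name: str = "assembly",
    busco_total: Optional[int] = None,
) -> BlobDirBundle:
    """Write records to a minimal dataset directory of per-field JSON files.

    Files: ``meta.json``, ``length.json``, ``gc.json`` (GC proportion of ATGC
    bases), ``n.json`` (N proportion of length), ``ncount.json`` (integer N
    counts) and, when BUSCO hits are present, ``{lineage}_busco.json``. All
    value arrays share the scaffold order recorded in ``meta.json``.
    """
    if not records:
        raise InputError("cannot write dataset: no records")
    dest = Path(dest)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create dataset directory {dest}: {exc}") from exc

    identifiers = [r.id for r in records]
    length_values = [r.length for r in records]
    gc_values = [round(r.gc_fraction, 6) for r in records]
    n_values = [round(r.n_fraction, 6) for r in records]
    ncount_values = [r.n_count for r in records]

    has_busco = any(r.busco_hits for r in records)
    lineage_name = lineage or "unknown"
    meta = {
        "name": name,
        "records": len(records),
        "record_type": "scaffold",
        "identifiers": identifiers,
        "fields": [
            {"id": "length", "type": "variable", "datatype": "integer"},
            {"id": "gc", "type": "variable", "datatype": "float"},
            {"id": "n", "type": "variable", "datatype": "float"},
            {"id": "ncount", "type": "variable", "datatype": "integer"},
        ],
    }
    busco_values = None
    if has_busco:
        meta["fields"].append({"id": f"{lineage_name}_busco", "type": "multi_array", "datatype": "mixed"})
        meta["busco_lineage"] = lineage_name
        if busco_total is not None:
            meta["busco_total"] = busco_total
        busco_values = {lineage_name: [[list(hit) for hit in r.busco_hits] for r in records]}

    def dump(fname: str, obj) -> None:
        try:
            with open(dest / fname, "w") as fh:
                json.dump(obj, fh)
        except OSError as exc:
            raise InputError(f"cannot write {dest / fname}: {exc}") from exc

    dump("meta.json", meta)
    dump("length.json", {"values": length_values})
    dump("gc.json", {"values": gc_values})
    dump("n.json", {"values": n_values})
    dump("ncount.json", {"values": ncount_values})
    if busco_values is not None:
        dump(f"{lineage_name}_busco.json", {"values": busco_values[lineage_name]})

    return BlobDirBundle(
        meta=meta,
        length_values=length_values,
        gc_values=gc_values,
        n_values=n_values,
        ncount_values=ncount_values,
        busco_values=busco_values,
    )


def _read_field_file(source_dir: Path, stem: str):
    for suffix in (".json", ".json.gz"):
        path = source_dir / (stem + suffix)
        if path.exists():
            with _open_text(path) as fh:
                return json.load(fh)
    raise InputError(f"missing field: {stem} (no {stem}.json in {source_dir})")


def read_blobdir(source) -> tuple[list[SequenceRecord], Optional[str]]:
    """Read a minimal dataset directory back into sequence records.

    Integer base counts are reconstructed from stored proportions and lengths:
    ``gc_count = round(gc * (length - ncount))``, ``at_count`` as the
    remainder, so the write/read round trip is exact.
    Returns ``(records, lineage)`` with ``lineage`` ``None`` when no BUSCO
    field is present.
    """
    source_dir = Path(source)
    if not source_dir.is_dir():
        raise InputError(f"cannot read dataset: {source_dir} is not a directory")

    meta = _read_field_file(source_dir, "meta")
    n_records = meta.get("records")
    identifiers = meta.get("identifiers")
    if identifiers is None:
        identifiers = [f"seq_{i}" for i in range(n_records)]

    arrays = {}
    for stem in ("length", "gc", "n", "ncount"):
        payload = _read_field_file(source_dir, stem)
        values = payload.get("values", payload)
        if len(values) != n_records:
            raise ConsistencyError(
                f"field {stem!r} has {len(values)} values but meta reports {n_records} records"
            )
        arrays[stem] = values

    lineage = meta.get("busco_lineage")
    busco_values = None
    if lineage is not None:
        busco_values = _read_field_file(source_dir, f"{lineage}_busco").get("values")
    else:
        hits = _glob.glob(str(source_dir / "*_busco.json")) + _glob.glob(str(source_dir / "*_busco.json.gz"))
        if hits:
            fname = os.path.basename(sorted(hits)[0])
            lineage = re.sub(r"_busco\.json(\.gz)?$", "", fname)
            busco_values = _read_field_file(source_dir, f"{lineage}_busco").get("values")
    if busco_values is not None and len(busco_values) != n_records:
        raise ConsistencyError(
            f"busco field has {len(busco_values)} values but meta reports {n_records} records"
        )

    records = []
    for i, ident in enumerate(identifiers):
        length = int(arrays["length"][i])
        ncount = int(arrays["ncount"][i])
        atgc = length - ncount
        gc_count = _round_half_up(float(arrays["gc"][i]) * atgc) if atgc else 0
        gc_count = min(gc_count, atgc)
        hits = [tuple(h) for h in busco_values[i]] if busco_values is not None else []
        records.append(
            SequenceRecord(
                id=str(ident),
                length=length,
                gc_count=gc_count,
                at_count=atgc - gc_count,
                n_count=ncount,
                busco_hits=hits,
            )
        )
    return records, lineage
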