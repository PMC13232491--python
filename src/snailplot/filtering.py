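"""Scaffold filter grammar: ``{field}:{kind}=value`` expressions.

Filters restrict the scaffold set before statistics and plotting. Numeric
kinds ``min``/``max`` are inclusive bounds; ``keys`` excludes the listed
keyword values and ``inv`` keeps only the listed values. A dialect with a
``--`` separator and capitalized kind (``length--Min=1,000``) is accepted
for compatibility with pipeline-style parameter strings. Multiple filters
combine as a conjunction (AND).

Filterable fields are exactly those present in the minimal dataset:
``length``, ``gc`` (GC proportion of ATGC bases), ``n`` (N proportion),
``ncount`` (integer N count) and ``id`` (scaffold identifier, for
``keys``/``inv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

from .assembly_io import SequenceRecord
from .errors import ConfigError, ParseError

VALID_KINDS = ("min", "max", "keys", "inv")

_COLON = re.compile(r"^(?P<field>[^:=]+):(?P<kind>[A-Za-z]+)=(?P<value>.+)$")
_DASHES = re.compile(r"^(?P<field>.+?)--(?P<kind>[A-Za-z]+)=(?P<value>.+)$")


@dataclass
class FilterExpression:
    field: str
    kind: str
    value: Union[float, list[str]]


def parse_filter(text: str) -> FilterExpression:
    """Parse one filter expression in either syntax dialect."""
    m = _DASHES.match(text) or _COLON.match(text)
    if m is None:
        raise ParseError(f"cannot parse filter {text!r}; expected field:kind=value")
    field = m.group("field").strip()
    kind = m.group("kind").lower()
    raw = m.group("value").strip()
    if kind not in VALID_KINDS:
        raise ParseError(
            f"unknown filter kind {m.group('kind')!r} in {text!r}; valid kinds: {', '.join(VALID_KINDS)}"
        )
    if kind in ("min", "max"):
        try:
            value: Union[float, list[str]] = float(raw.replace(",", ""))
        except ValueError as exc:
            raise ParseError(f"non-numeric value {raw!r} for {kind} filter on {field!r}") from exc
    else:
        value = [tok.strip() for tok in raw.split(",") if tok.strip()]
        if not value:
            raise ParseError(f"empty keyword list in filter {text!r}")
    return FilterExpression(field=field, kind=kind, value=value)


def _resolve(record: SequenceRecord, field: str):
    if field == "length":
        return record.length
    if field == "gc":
        return record.gc_fraction
    if field == "n":
        return record.n_fraction
    if field == "ncount":
        return record.n_count
    if field in ("id", "identifiers"):
        return record.id
    raise ConfigError(
        f"cannot filter on unknown field {field!r}; available fields: length, gc, n, ncount, id"
    )


def _matches(record: SequenceRecord, expr: FilterExpression) -> bool:
    value = _resolve(record, expr.field)
    if expr.kind == "min":
        return value >= expr.value
    if expr.kind == "max":
        return value <= expr.value
    if expr.kind == "keys":
        return str(value) not in expr.value
    return str(value) in expr.value  # inv


def apply_filters(
    records: Sequence[SequenceRecord],
    expressions: Sequence[FilterExpression],
) -> list[SequenceRecord]:
    """Keep records satisfying every expression; error if none survive."""
    retained = [r for r in records if all(_matches(r, e) for e in expressions)]
    if records and not retained:
        raise ConfigError("empty assembly after filtering")
    return retained
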