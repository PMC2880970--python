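"""Lossless semantic + structural compression of number streams.

The semantic stage rewrites a stream of numbers as tuples
``value,persistence`` followed by sign-prefixed successive increments:
``value`` opens the tuple, ``persistence`` counts how many consecutive
samples stay at that value, and each increment is the delta from the
previous sample.  A new tuple is opened at the first element of every
maximal constant run of length >= 2; non-repeating samples stay as
increments of the open tuple.  Examples::

    [7, 7, 7, 7]     ->  "7,4"
    [1, 2, 4]        ->  "1,1+1+2"
    [3, 3, 5, 5, 6]  ->  "3,2;5,2+1"

The tuple text is then gzip-compressed and Base64-encoded (standard
alphabet, padded, unwrapped) so it can be embedded in XML.

Integer streams are processed as Python ints.  Decimal streams are
processed in exact decimal arithmetic on their shortest round-trip
serialisations, so cumulative sums are exactly invertible — binary
floating addition does not guarantee ``v + (w - v) == w``.
"""

from __future__ import annotations

import base64
import binascii
import gzip
import re
import zlib
from dataclasses import dataclass
from decimal import Context, Decimal
from typing import Sequence

# doubles span ~17 significant digits over e±308; differences of two such
# values need < 700 digits, so this context keeps every sum/difference exact
_EXACT = Context(prec=800)

import numpy as np

__all__ = [
    "TupleRun",
    "EncodedStream",
    "IntegrityError",
    "semantic_encode",
    "semantic_decode",
    "compress_stream",
    "decompress_stream",
]


class IntegrityError(ValueError):
    """Corrupt payload or metadata that contradicts the decoded stream."""


@dataclass
class TupleRun:
    """One decoded tuple: `persistence` copies of `value`, then the
    cumulative sums value+d1, value+d1+d2, ..."""

    value: int | Decimal
    persistence: int
    increments: list[int | Decimal]

    def __post_init__(self) -> None:
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")

    def expand(self) -> list:
        out = [self.value] * self.persistence
        acc = self.value
        for d in self.increments:
            acc = _EXACT.add(acc, d) if isinstance(acc, Decimal) else acc + d
            out.append(acc)
        return out


@dataclass
class EncodedStream:
    """Base64(gzip(tuple text)) plus first/last/count metadata."""

    payload: str
    count: int
    first_value: int | float | None
    last_value: int | float | None
    numeric_kind: str  # "integer" | "decimal"


def _classify(stream: Sequence) -> str:
    """Return "integer" or "decimal"; reject mixed streams."""
    kinds = set()
    for v in stream:
        if isinstance(v, (bool, np.bool_)):
            raise TypeError("boolean values are not a numeric stream")
        if isinstance(v, (int, np.integer)):
            kinds.add("integer")
        elif isinstance(v, (float, np.floating, Decimal)):
            kinds.add("decimal")
        else:
            raise TypeError(f"non-numeric stream element {v!r}")
    if len(kinds) > 1:
        raise ValueError("mixed integer/decimal stream")
    return kinds.pop() if kinds else "integer"


def _to_decimal(v) -> Decimal:
    if isinstance(v, Decimal):
        return v
    # repr() of a float is its shortest round-trip form
    return Decimal(repr(float(v)))


def _fmt(d: int | Decimal) -> str:
    if isinstance(d, Decimal):
        s = format(d, "f")  # fixed point, no exponent notation
        if s.startswith("-") and Decimal(s) == 0:
            s = s[1:]  # normalise negative zero so sign prefixes stay unambiguous
        return s
    return str(d)


def _encode_exact(values: list) -> str:
    """Tuple text for an already-exact (int or Decimal) value list."""
    n = len(values)
    if n == 0:
        return ""
    # starts of maximal constant runs of length >= 2 open new tuples
    run_len = [1] * n
    for i in range(n - 2, -1, -1):
        if values[i] == values[i + 1]:
            run_len[i] = run_len[i + 1] + 1
    starts = [0]
    i = 1
    while i < n:
        if values[i] == values[i - 1]:
            i += 1  # interior of a run
            continue
        if run_len[i] >= 2:
            starts.append(i)
            i += run_len[i]
        else:
            i += 1
    starts.append(n)
    parts = []
    for a, b in zip(starts[:-1], starts[1:]):
        persistence = run_len[a]
        incs = []
        for k in range(a + persistence, b):
            if isinstance(values[k], Decimal):
                d = _EXACT.subtract(values[k], values[k - 1])
            else:
                d = values[k] - values[k - 1]
            incs.append(("+" if d >= 0 else "") + _fmt(d))
        parts.append(f"{_fmt(values[a])},{persistence}" + "".join(incs))
    return ";".join(parts)


def semantic_encode(stream: Sequence) -> str:
    """Encode a homogeneous numeric stream as ';'-separated tuple text."""
    kind = _classify(stream)
    if kind == "integer":
        values = [int(v) for v in stream]
    else:
        values = [_to_decimal(v) for v in stream]
    return _encode_exact(values)


_NUM = r"-?\d+(?:\.\d+)?"
_TUPLE_RE = re.compile(rf"^({_NUM}),(\d+)((?:[+-]{_NUM})*)$")
_INC_RE = re.compile(rf"[+-]{_NUM}")


def _parse_number(text: str, kind: str):
    if "." in text:
        return Decimal(text)
    return int(text) if kind == "integer" else Decimal(text)


def semantic_decode(text: str, numeric_kind: str = "integer") -> list:
    """Exact inverse of :func:`semantic_encode`.

    ``numeric_kind`` selects the output type: Python ints, or floats
    reconstructed from exact decimal sums.
    """
    if numeric_kind not in ("integer", "decimal"):
        raise ValueError(f"unknown numeric kind {numeric_kind!r}")
    if text == "":
        return []
    out: list = []
    for chunk in text.split(";"):
        m = _TUPLE_RE.match(chunk)
        if m is None:
            raise ValueError(f"malformed tuple {chunk!r}")
        value = _parse_number(m.group(1), numeric_kind)
        persistence = int(m.group(2))
        if persistence < 1:
            raise ValueError(f"persistence must be >= 1 in tuple {chunk!r}")
        incs = [_parse_number(s, numeric_kind) for s in _INC_RE.findall(m.group(3))]
        out.extend(TupleRun(value, persistence, incs).expand())
    if numeric_kind == "decimal":
        return [float(v) for v in out]
    return out


def compress_stream(stream: Sequence) -> EncodedStream:
    """Full pipeline: semantic tuples -> gzip -> Base64, with metadata."""
    kind = _classify(stream)
    text = semantic_encode(stream)
    payload = base64.b64encode(gzip.compress(text.encode("utf-8"))).decode("ascii")
    n = len(stream)
    if kind == "integer":
        first = int(stream[0]) if n else None
        last = int(stream[-1]) if n else None
    else:
        first = float(stream[0]) if n else None
        last = float(stream[-1]) if n else None
    return EncodedStream(
        payload=payload, count=n, first_value=first, last_value=last, numeric_kind=kind
    )


def decompress_stream(enc: EncodedStream) -> list:
    """Invert :func:`compress_stream`; verify payload and metadata."""
    try:
        raw = base64.b64decode(enc.payload.encode("ascii"), validate=True)
        text = gzip.decompress(raw).decode("utf-8")
    except (binascii.Error, ValueError, OSError, zlib.error, UnicodeDecodeError) as e:
        raise IntegrityError(f"corrupt payload: {e}") from e
    try:
        values = semantic_decode(text, enc.numeric_kind)
    except ValueError as e:
        raise IntegrityError(f"corrupt tuple text: {e}") from e
    if len(values) != enc.count:
        raise IntegrityError(
            f"count mismatch: metadata says {enc.count}, payload has {len(values)}"
        )
    if values:
        if enc.first_value is not None and values[0] != enc.first_value:
            raise IntegrityError("first value metadata mismatch")
        if enc.last_value is not None and values[-1] != enc.last_value:
            raise IntegrityError("last value metadata mismatch")
    return values
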