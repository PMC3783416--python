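"""Standalone structural PDF parser used to probe emitted figures.

This is a deliberately independent check: it reads a PDF file the way a
consumer would — locate ``startxref``, walk the cross-reference table, parse
each numbered object with a small recursive-descent tokenizer — and shares no
code or intermediate state with :mod:`fig3d.pdfwriter`.  It implements the
subset of PDF syntax needed to validate single-figure documents: literal
object syntax (dictionaries, arrays, names, numbers, strings, references) and
streams with direct or indirect lengths.

Typical use::

    doc = PDFDocument(pdf_bytes)
    annots = doc.annotations_of_subtype("3D")
    stream = doc.stream_bytes(annots[0]["3DD"])
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ParseError


@dataclass(frozen=True)
class Ref:
    """Indirect object reference ``num gen R``."""

    num: int
    gen: int = 0


class Name(str):
    """A PDF name token (without the leading slash)."""


_WS = b"\x00\t\n\x0c\r "
_DELIM = b"()<>[]{}/%"


class _Lexer:
    def __init__(self, data: bytes, pos: int = 0) -> None:
        self.data = data
        self.pos = pos

    def skip_ws(self) -> None:
        d = self.data
        while self.pos < len(d):
            c = d[self.pos : self.pos + 1]
            if c == b"%":  # comment to end of line
                while self.pos < len(d) and d[self.pos] not in b"\r\n":
                    self.pos += 1
            elif d[self.pos] in _WS:
                self.pos += 1
            else:
                break

    def peek(self, n: int = 1) -> bytes:
        return self.data[self.pos : self.pos + n]

    def parse_object(self):
        self.skip_ws()
        c = self.peek()
        if c == b"<":
            if self.peek(2) == b"<<":
                return self._parse_dict()
            return self._parse_hex_string()
        if c == b"[":
            return self._parse_array()
        if c == b"(":
            return self._parse_literal_string()
        if c == b"/":
            return self._parse_name()
        token = self._read_token()
        if token in (b"true", b"false"):
            return token == b"true"
        if token == b"null":
            return None
        # number, possibly the start of "num gen R"
        save = self.pos
        try:
            value = int(token)
        except ValueError:
            try:
                return float(token)
            except ValueError as exc:
                raise ParseError(f"unexpected token {token!r} at {save}") from exc
        self.skip_ws()
        mark = self.pos
        if self.peek().isdigit():
            nxt = self._read_token()
            self.skip_ws()
            if nxt.isdigit() and self.peek() == b"R":
                self.pos += 1
                return Ref(value, int(nxt))
            self.pos = mark
        return value

    def _read_token(self) -> bytes:
        self.skip_ws()
        start = self.pos
        d = self.data
        while self.pos < len(d) and d[self.pos] not in _WS and d[self.pos] not in _DELIM:
            self.pos += 1
        if self.pos == start:
            raise ParseError(f"empty token at offset {start}")
        return d[start : self.pos]

    def _parse_name(self) -> Name:
        assert self.peek() == b"/"
        self.pos += 1
        start = self.pos
        d = self.data
        while self.pos < len(d) and d[self.pos] not in _WS and d[self.pos] not in _DELIM:
            self.pos += 1
        raw = d[start : self.pos].decode("latin-1")
        raw = re.sub(
            "#([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), raw
        )
        return Name(raw)

    def _parse_dict(self) -> dict:
        self.pos += 2
        out: dict[str, object] = {}
        while True:
            self.skip_ws()
            if self.peek(2) == b">>":
                self.pos += 2
                return out
            key = self._parse_name()
            out[str(key)] = self.parse_object()

    def _parse_array(self) -> list:
        self.pos += 1
        out = []
        while True:
            self.skip_ws()
            if self.peek() == b"]":
                self.pos += 1
                return out
            out.append(self.parse_object())

    def _parse_literal_string(self) -> bytes:
        self.pos += 1
        depth = 1
        out = bytearray()
        d = self.data
        while self.pos < len(d):
            ch = d[self.pos]
            self.pos += 1
            if ch == 0x5C:  # backslash escape
                if self.pos < len(d):
                    out.append(d[self.pos])
                    self.pos += 1
            elif ch == 0x28:
                depth += 1
                out.append(ch)
            elif ch == 0x29:
                depth -= 1
                if depth == 0:
                    return bytes(out)
                out.append(ch)
            else:
                out.append(ch)
        raise ParseError("unterminated literal string")

    def _parse_hex_string(self) -> bytes:
        self.pos += 1
        end = self.data.index(b">", self.pos)
        hexstr = re.sub(rb"\s", b"", self.data[self.pos : end])
        self.pos = end + 1
        if len(hexstr) % 2:
            hexstr += b"0"
        return bytes.fromhex(hexstr.decode("ascii"))


class PDFDocument:
    """Parsed single-xref PDF document."""

    def __init__(self, data: bytes) -> None:
        if not data.startswith(b"%PDF-"):
            raise ParseError("missing %PDF header")
        if b"%%EOF" not in data[-1024:]:
            raise ParseError("missing %%EOF marker")
        self.data = data
        self.offsets = self._read_xref()
        self._cache: dict[int, object] = {}
        trailer_at = data.rindex(b"trailer")
        lex = _Lexer(data, trailer_at + len(b"trailer"))
        self.trailer = lex.parse_object()
        if not isinstance(self.trailer, dict) or "Root" not in self.trailer:
            raise ParseError("trailer lacks /Root")

    def _read_xref(self) -> dict[int, int]:
        data = self.data
        sx = data.rindex(b"startxref")
        m = re.search(rb"startxref\s+(\d+)", data[sx:])
        if not m:
            raise ParseError("unreadable startxref")
        at = int(m.group(1))
        if data[at : at + 4] != b"xref":
            raise ParseError(f"startxref {at} does not point at an xref table")
        lex = _Lexer(data, at + 4)
        offsets: dict[int, int] = {}
        while True:
            lex.skip_ws()
            if lex.peek(7) == b"trailer":
                break
            first = int(lex._read_token())
            count = int(lex._read_token())
            lex.skip_ws()
            for i in range(count):
                entry = data[lex.pos : lex.pos + 20]
                if len(entry) < 18:
                    raise ParseError("truncated xref entry")
                off, gen, kind = entry[:10], entry[11:16], entry[17:18]
                if kind == b"n":
                    offsets[first + i] = int(off)
                lex.pos += 20
        return offsets

    # -- object access --------------------------------------------------------

    def object(self, ref: Ref | int):
        num = ref.num if isinstance(ref, Ref) else ref
        if num in self._cache:
            return self._cache[num]
        if num not in self.offsets:
            raise ParseError(f"object {num} not in xref")
        lex = _Lexer(self.data, self.offsets[num])
        onum = int(lex._read_token())
        int(lex._read_token())
        if lex._read_token() != b"obj" or onum != num:
            raise ParseError(f"xref offset for object {num} is wrong")
        obj = lex.parse_object()
        lex.skip_ws()
        if lex.peek(6) == b"stream":
            obj = ("stream", obj, lex.pos + len(b"stream"))
        self._cache[num] = obj
        return obj

    def resolve(self, obj):
        while isinstance(obj, Ref):
            obj = self.object(obj)
        return obj

    def stream_bytes(self, ref: Ref) -> bytes:
        obj = self.object(ref)
        if not (isinstance(obj, tuple) and obj[0] == "stream"):
            raise ParseError(f"object {ref.num} is not a stream")
        _, sdict, at = obj
        length = self.resolve(sdict["Length"])
        start = at
        # EOL after the `stream` keyword
        if self.data[start : start + 2] == b"\r\n":
            start += 2
        elif self.data[start : start + 1] in (b"\n", b"\r"):
            start += 1
        return self.data[start : start + int(length)]

    def stream_dict(self, ref: Ref) -> dict:
        obj = self.object(ref)
        if not (isinstance(obj, tuple) and obj[0] == "stream"):
            raise ParseError(f"object {ref.num} is not a stream")
        return obj[1]

    # -- document structure ---------------------------------------------------

    def catalog(self) -> dict:
        return self.resolve(self.trailer["Root"])

    def pages(self) -> list[dict]:
        root = self.resolve(self.catalog()["Pages"])
        out: list[dict] = []

        def rec(node):
            node = self.resolve(node)
            if node.get("Type") == "Pages":
                for kid in self.resolve(node["Kids"]):
                    rec(kid)
            else:
                out.append(node)

        rec(root)
        return out

    def annotations(self) -> list[dict]:
        out = []
        for page in self.pages():
            for ref in self.resolve(page.get("Annots", [])):
                out.append(self.resolve(ref))
        return out

    def annotations_of_subtype(self, subtype: str) -> list[dict]:
        return [a for a in self.annotations() if a.get("Subtype") == subtype]
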