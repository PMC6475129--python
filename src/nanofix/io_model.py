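"""Tabular data model and readers/writers for the pipeline's inputs.

Everything downstream consumes three kinds of flat files:

* a tab-separated sequence/cluster metadata table (one environmental protein
  per row, with its CD-HIT cluster, sampling site, depth and size fraction);
* BLAST/DIAMOND tabular alignments ("outfmt 6", optionally extended with
  query and subject lengths as columns 13-14);
* a module-definition file expressing KEGG-style boolean enzyme logic over
  KO identifiers, one module per line.

All alignment coordinates are 1-based inclusive (BLAST convention) and are
converted nowhere else in the package.  Subject coordinates may arrive
reversed (``sstart > send``); they are accepted as-is and every consumer uses
``min``/``max``, so no silent clamping or flipping happens on load.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

PathLike = Union[str, Path]

DEPTHS = ("SRF", "DCM", "MES", "MIX")
SIZE_FRACTIONS = ("ultrasmall", "other")

#: Default taxonomic groups mirroring the nine dataset-composition categories:
#: best hits classified at domain level, domain-only annotations, the two
#: nano-prokaryote superphyla, viruses, and sequences with no usable hit.
DEFAULT_GROUPS = (
    "known_bacteria",
    "known_archaea",
    "known_eukaryota",
    "unclassified",
    "unassigned_bacteria",
    "unassigned_archaea",
    "viruses",
    "CPR",
    "DPANN",
)

KO_PATTERN = re.compile(r"K\d{5}")


class SchemaError(ValueError):
    """A required column is missing or a file has the wrong shape."""


class ValidationError(ValueError):
    """A field value violates its contract (reported with line number)."""


class ParseError(ValueError):
    """Module-definition grammar error, with character offset."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class SequenceMeta:
    """Provenance of one environmental protein sequence."""

    seq_id: str
    cluster_id: str
    sample_id: str
    site_id: str
    depth: str
    size_fraction: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.depth not in DEPTHS:
            raise ValidationError(f"unknown depth {self.depth!r}")
        if self.size_fraction not in SIZE_FRACTIONS:
            raise ValidationError(f"unknown size_fraction {self.size_fraction!r}")
        if self.length_aa < 1:
            raise ValidationError(f"length_aa must be >= 1, got {self.length_aa}")


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """One pairwise local-alignment record (BLAST tabular row + lengths)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.aln_len < 1:
            raise ValidationError(f"aln_len must be >= 1, got {self.aln_len}")
        if self.qlen < 1 or self.slen < 1:
            raise ValidationError("qlen and slen must be positive")
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValidationError(
                f"query coordinates violate 1 <= qstart <= qend <= qlen: "
                f"{self.qstart}..{self.qend} on qlen={self.qlen}"
            )
        lo, hi = min(self.sstart, self.send), max(self.sstart, self.send)
        if lo < 1 or hi > self.slen:
            raise ValidationError(
                f"subject coordinates out of range: {self.sstart}..{self.send} "
                f"on slen={self.slen}"
            )
        if self.evalue < 0:
            raise ValidationError(f"evalue must be non-negative, got {self.evalue}")

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart + 1

    @property
    def subject_span(self) -> int:
        return abs(self.send - self.sstart) + 1


@dataclass(frozen=True, slots=True)
class TaxonAnnotation:
    """Taxonomic annotation of one reference (subject) sequence."""

    subject_id: str
    group: str
    lineage: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Module-definition expression trees
# ---------------------------------------------------------------------------
#
# Grammar (one module definition): whitespace separates AND terms, commas
# separate OR alternatives within a term (binding tighter than whitespace,
# KEGG-style), parentheses group.  A leading "-" marks a KO as optional (it
# is excluded from the presence expression and only reported when observed);
# a leading "*" marks a key enzyme.  Markers may combine in either order.


@dataclass(frozen=True, slots=True)
class KOAtom:
    ko: str

    def evaluate(self, kos: frozenset[str] | set[str]) -> bool:
        return self.ko in kos

    def kos(self) -> frozenset[str]:
        return frozenset((self.ko,))


@dataclass(frozen=True, slots=True)
class And:
    terms: tuple["Expr", ...]

    def evaluate(self, kos) -> bool:
        return all(t.evaluate(kos) for t in self.terms)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(t.kos() for t in self.terms))


@dataclass(frozen=True, slots=True)
class Or:
    terms: tuple["Expr", ...]

    def evaluate(self, kos) -> bool:
        return any(t.evaluate(kos) for t in self.terms)

    def kos(self) -> frozenset[str]:
        return frozenset().union(*(t.kos() for t in self.terms))


Expr = Union[KOAtom, And, Or]


def parse_module_expression(text: str) -> tuple[Expr, frozenset[str], frozenset[str]]:
    """Parse one module definition into (expression, optional_kos, key_kos).

    Optional KOs are removed from the expression; an OR alternative that is
    optional simply disappears from the alternatives, and an AND term whose
    alternatives were all optional disappears from the conjunction.  The
    expression must be non-empty after removal.
    """
    optional: set[str] = set()
    key: set[str] = set()
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos] in " \t":
            pos += 1

    def parse_atom() -> Expr | None:
        nonlocal pos
        if pos < n and text[pos] == "(":
            open_pos = pos
            pos += 1
            node = parse_and(open_pos)
            skip_ws()
            if pos >= n or text[pos] != ")":
                raise ParseError(
                    f"unbalanced parenthesis opened at offset {open_pos}", open_pos
                )
            pos += 1
            return node
        m = re.match(r"([*-]{0,2})(K\d{5})", text[pos:])
        if m is None or len(set(m.group(1))) != len(m.group(1)):
            raise ParseError(f"invalid KO token at offset {pos}", pos)
        markers, ko = m.group(1), m.group(2)
        pos += m.end()
        if pos < n and text[pos] not in " \t(),":
            raise ParseError(f"invalid KO token at offset {pos - m.end()}", pos - m.end())
        if "*" in markers:
            key.add(ko)
        if "-" in markers:
            optional.add(ko)
            return None
        return KOAtom(ko)

    def parse_or() -> Expr | None:
        nonlocal pos
        alternatives = [parse_atom()]
        while pos < n and text[pos] == ",":
            pos += 1
            skip_ws()
            alternatives.append(parse_atom())
        kept = [a for a in alternatives if a is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Or(tuple(kept))

    def parse_and(open_pos: int | None = None) -> Expr:
        nonlocal pos
        terms: list[Expr] = []
        skip_ws()
        while pos < n and text[pos] != ")":
            term = parse_or()
            if term is not None:
                terms.append(term)
            skip_ws()
        if not terms:
            where = open_pos if open_pos is not None else 0
            raise ParseError(f"empty expression at offset {where}", where)
        if len(terms) == 1:
            return terms[0]
        return And(tuple(terms))

    expr = parse_and()
    if pos < n:
        raise ParseError(f"unbalanced ')' at offset {pos}", pos)
    return expr, frozenset(optional), frozenset(key)


def _format_expr(expr: Expr, key_kos: frozenset[str], inside_or: bool = False) -> str:
    if isinstance(expr, KOAtom):
        return ("*" if expr.ko in key_kos else "") + expr.ko
    if isinstance(expr, Or):
        return ",".join(_format_expr(t, key_kos, inside_or=True) for t in expr.terms)
    # And: needs parentheses when nested under an Or alternative
    body = " ".join(
        _format_expr(t, key_kos) if not isinstance(t, And) else
        "(" + _format_expr(t, key_kos) + ")"
        for t in expr.terms
    )
    return f"({body})" if inside_or else body


@dataclass(frozen=True, slots=True)
class ModuleDefinition:
    """One reaction block of a pathway: boolean logic over KO ids."""

    module_id: str
    expression: Expr
    optional_kos: frozenset[str] = frozenset()
    key_kos: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        expr_kos = self.expression.kos()
        if expr_kos & self.optional_kos:
            raise ValidationError(
                f"module {self.module_id}: optional KOs overlap the expression"
            )
        if not self.key_kos <= (expr_kos | self.optional_kos):
            raise ValidationError(
                f"module {self.module_id}: key KOs outside expression/optional sets"
            )

    @classmethod
    def from_string(cls, module_id: str, definition: str) -> "ModuleDefinition":
        expr, optional, key = parse_module_expression(definition)
        return cls(module_id, expr, optional, key)

    def all_kos(self) -> frozenset[str]:
        return self.expression.kos() | self.optional_kos

    def definition_string(self) -> str:
        """Canonical serialization; round-trips through :func:`parse_module_expression`."""
        parts = [_format_expr(self.expression, self.key_kos)]
        for ko in sorted(self.optional_kos):
            parts.append(("*-" if ko in self.key_kos else "-") + ko)
        return " ".join(parts)


@dataclass(frozen=True, slots=True)
class PathwaySpec:
    """A pathway (or protein complex) as an ordered list of modules."""

    pathway_id: str
    modules: tuple[ModuleDefinition, ...]

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValidationError(f"pathway {self.pathway_id} has no modules")
        seen: set[str] = set()
        for m in self.modules:
            if m.module_id in seen:
                raise ValidationError(
                    f"pathway {self.pathway_id}: duplicate module {m.module_id}"
                )
            seen.add(m.module_id)

    @property
    def key_modules(self) -> tuple[ModuleDefinition, ...]:
        return tuple(m for m in self.modules if m.key_kos)

    @property
    def key_kos(self) -> frozenset[str]:
        if not self.modules:
            return frozenset()
        return frozenset().union(*(m.key_kos for m in self.modules))

    def all_kos(self) -> frozenset[str]:
        return frozenset().union(*(m.all_kos() for m in self.modules))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = (
    "seq_id",
    "cluster_id",
    "sample_id",
    "site_id",
    "depth",
    "size_fraction",
    "length_aa",
)


def read_sequence_meta(path: PathLike) -> list[SequenceMeta]:
    """Read the sequence metadata TSV; rejects duplicate ids and bad enums."""
    records: list[SequenceMeta] = []
    seen: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _META_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SequenceMeta(
                    seq_id=row["seq_id"],
                    cluster_id=row["cluster_id"],
                    sample_id=row["sample_id"],
                    site_id=row["site_id"],
                    depth=row["depth"],
                    size_fraction=row["size_fraction"],
                    length_aa=int(row["length_aa"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            except (TypeError, KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row ({exc})") from None
            if rec.seq_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate seq_id {rec.seq_id!r} "
                    f"(first seen on line {seen[rec.seq_id]})"
                )
            seen[rec.seq_id] = lineno
            records.append(rec)
    return records


def write_sequence_meta(records: Iterable[SequenceMeta], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_META_COLUMNS)
        for r in records:
            writer.writerow(
                [r.seq_id, r.cluster_id, r.sample_id, r.site_id, r.depth,
                 r.size_fraction, r.length_aa]
            )


def _parse_hit_fields(fields: Sequence[str], lineno: int, path: PathLike,
                      qlen: int, slen: int) -> AlignmentHit:
    try:
        return AlignmentHit(
            query_id=fields[0],
            subject_id=fields[1],
            pct_identity=float(fields[2]),
            aln_len=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            qstart=int(fields[6]),
            qend=int(fields[7]),
            sstart=int(fields[8]),
            send=int(fields[9]),
            evalue=float(fields[10]),
            bitscore=float(fields[11]),
            qlen=qlen,
            slen=slen,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from None
    except ValueError as exc:
        raise ValidationError(f"{path}:{lineno}: non-numeric field ({exc})") from None


def read_hits(
    path: PathLike,
    dialect: str = "outfmt6+lens",
    lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Read BLAST/DIAMOND tabular hits.

    ``dialect="outfmt6+lens"`` expects 14 columns (standard 12 + qlen, slen).
    ``dialect="outfmt6"`` expects the standard 12 and requires a companion
    ``lengths`` mapping (sequence id -> length in residues) covering every
    query and subject.
    """
    if dialect not in ("outfmt6", "outfmt6+lens"):
        raise ValueError(f"unknown dialect {dialect!r}")
    expected = 14 if dialect == "outfmt6+lens" else 12
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise SchemaError(
                    f"{path}:{lineno}: expected {expected} columns, got {len(fields)}"
                )
            if dialect == "outfmt6+lens":
                try:
                    qlen, slen = int(fields[12]), int(fields[13])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric length field ({exc})"
                    ) from None
            else:
                if lengths is None:
                    raise SchemaError(
                        f"{path}:{lineno}: lengths unavailable — outfmt6 input "
                        "requires a companion length table"
                    )
                try:
                    qlen = lengths[fields[0]]
                    slen = lengths[fields[1]]
                except KeyError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: lengths unavailable for {exc.args[0]!r}"
                    ) from None
            hits.append(_parse_hit_fields(fields, lineno, path, qlen, slen))
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: PathLike) -> None:
    """Write hits in the 14-column (outfmt6 + qlen, slen) dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            # repr() is the shortest exact decimal for a float, so files
            # round-trip losslessly through read_hits
            writer.writerow(
                [h.query_id, h.subject_id, repr(h.pct_identity), h.aln_len,
                 h.mismatches, h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
                 repr(h.evalue), repr(h.bitscore), h.qlen, h.slen]
            )


def read_module_definitions(path: PathLike) -> list[PathwaySpec]:
    """Read the module flat file: ``pathway_id<TAB>module_id<TAB>definition``.

    Modules are grouped into pathways preserving file order.
    """
    grouped: dict[str, list[ModuleDefinition]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SchemaError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            pathway_id, module_id, definition = parts
            try:
                module = ModuleDefinition.from_string(module_id, definition)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}", exc.position) from None
            if pathway_id not in grouped:
                grouped[pathway_id] = []
                order.append(pathway_id)
            grouped[pathway_id].append(module)
    return [PathwaySpec(pid, tuple(grouped[pid])) for pid in order]


def write_module_definitions(specs: Iterable[PathwaySpec], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        for spec in specs:
            for m in spec.modules:
                fh.write(f"{spec.pathway_id}\t{m.module_id}\t{m.definition_string()}\n")


def read_taxonomy(path: PathLike) -> dict[str, TaxonAnnotation]:
    """Read the reference taxonomy TSV (subject_id, group, lineage)."""
    annotations: dict[str, TaxonAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("subject_id", "group"):
            if col not in header:
                raise SchemaError(f"{path}: missing column {col}")
        for lineno, row in enumerate(reader, start=2):
            lineage = tuple(row.get("lineage", "").split(";")) if row.get("lineage") else ()
            ann = TaxonAnnotation(row["subject_id"], row["group"], lineage)
            if ann.subject_id in annotations:
                raise ValidationError(f"{path}:{lineno}: duplicate subject {ann.subject_id!r}")
            annotations[ann.subject_id] = ann
    return annotations


def write_taxonomy(annotations: Mapping[str, TaxonAnnotation] | Iterable[TaxonAnnotation],
                   path: PathLike) -> None:
    if isinstance(annotations, Mapping):
        annotations = annotations.values()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "group", "lineage"])
        for a in annotations:
            writer.writerow([a.subject_id, a.group, ";".join(a.lineage)])


def read_ko_map(path: PathLike) -> dict[str, str]:
    """Read the subject-id -> KO mapping TSV."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("subject_id", "ko_id"):
            if col not in header:
                raise SchemaError(f"{path}: missing column {col}")
        for lineno, row in enumerate(reader, start=2):
            ko = row["ko_id"]
            if not KO_PATTERN.fullmatch(ko):
                raise ValidationError(f"{path}:{lineno}: malformed KO id {ko!r}")
            mapping[row["subject_id"]] = ko
    return mapping


def write_ko_map(mapping: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "ko_id"])
        for subject in sorted(mapping):
            writer.writerow([subject, mapping[subject]])
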