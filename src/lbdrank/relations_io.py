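"""Parse, normalize and write entity-relation records.

The interchange format is the pipe-delimited tabular output of sentence-level
entity/relation extractors such as PKDE4J or SemRep::

    pmid | sentence location | entity1 | type | entity2 | type | relations

One record per line, UTF-8. PMIDs may carry thousands separators
("19,395,124"); a terminal "|" producing a trailing empty field is tolerated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import IO, Iterable, Iterator, Sequence

ENTITY_TYPES = frozenset({"GENE", "DRUG", "DISEASE", "OTHER"})

_WS = re.compile(r"\s+")


class RelationFormatError(ValueError):
    """A line does not conform to the 7-field pipe-delimited record format."""


@dataclass(frozen=True)
class RelationRecord:
    """One extracted entity-pair mention in one sentence of one abstract.

    Entities are stored in normalized form (trimmed, case-folded, internal
    whitespace collapsed); the pair is unordered at the graph level but field
    order of the source line is preserved here.
    """

    pmid: int
    sentence_index: int
    entity_a: str
    type_a: str
    entity_b: str
    type_b: str
    relation_label: str

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if self.sentence_index < 0:
            raise ValueError(f"sentence_index must be >= 0, got {self.sentence_index}")
        if self.type_a not in ENTITY_TYPES or self.type_b not in ENTITY_TYPES:
            raise ValueError(
                f"entity types must be in {sorted(ENTITY_TYPES)}, "
                f"got {self.type_a!r}/{self.type_b!r}"
            )
        if self.entity_a == self.entity_b:
            raise ValueError(f"self-pair after normalization: {self.entity_a!r}")


class Thesaurus:
    """Synonym/association groups with case-insensitive membership.

    Each group is a set of >= 2 entity labels (normalized on load). The
    canonical head of a group is its lexicographically smallest member, so
    canonicalization is independent of the order groups were listed in.
    """

    def __init__(self, groups: Iterable[Iterable[str]], provenance: str = "") -> None:
        self.provenance = provenance
        self.groups: list[frozenset[str]] = []
        self._member_to_group: dict[str, int] = {}
        for raw in groups:
            members = frozenset(_basic_normalize(m) for m in raw if m.strip())
            if len(members) < 2:
                raise ValueError(f"thesaurus group needs >= 2 members, got {sorted(members)}")
            idx = len(self.groups)
            self.groups.append(members)
            for m in members:
                self._member_to_group[m] = idx

    def group_of(self, label: str) -> frozenset[str] | None:
        idx = self._member_to_group.get(_basic_normalize(label))
        return self.groups[idx] if idx is not None else None

    def canonical(self, label: str) -> str:
        """Head word (lexicographically smallest group member) or the label itself."""
        norm = _basic_normalize(label)
        group = self.group_of(norm)
        return min(group) if group is not None else norm

    def __len__(self) -> int:
        return len(self.groups)

    @classmethod
    def from_file(cls, stream: IO[str] | str, provenance: str = "") -> "Thesaurus":
        """Load from tab-separated text, one group per line."""
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        try:
            groups = [
                [f for f in line.rstrip("\n").split("\t") if f.strip()]
                for line in stream
                if line.strip()
            ]
        finally:
            if close:
                stream.close()
        return cls(groups, provenance=provenance)

    def to_file(self, stream: IO[str] | str) -> None:
        close = False
        if isinstance(stream, str):
            stream = open(stream, "w", encoding="utf-8")
            close = True
        try:
            for group in self.groups:
                stream.write("\t".join(sorted(group)) + "\n")
        finally:
            if close:
                stream.close()


def _basic_normalize(label: str) -> str:
    return _WS.sub(" ", label.strip()).casefold()


def normalize_entity(label: str, thesaurus: Thesaurus | None = None) -> str:
    """Canonical form of an entity label.

    Trim, case-fold, collapse internal whitespace; when a thesaurus is given
    and the label belongs to a group, the group's lexicographically smallest
    member is the canonical head. Idempotent.

    Raises
    ------
    ValueError
        If the label is empty or whitespace-only.
    """
    norm = _basic_normalize(label)
    if not norm:
        raise ValueError("entity label is empty after trimming")
    if thesaurus is not None:
        norm = thesaurus.canonical(norm)
    return norm


def _parse_line(line: str, thesaurus: Thesaurus | None) -> RelationRecord:
    fields = [f.strip() for f in line.split("|")]
    # a terminal "|" yields one trailing empty field; tolerate it
    if len(fields) == 8 and fields[7] == "":
        fields = fields[:7]
    if len(fields) != 7:
        raise RelationFormatError(f"expected 7 pipe-delimited fields, got {len(fields)}: {line!r}")
    pmid_txt = fields[0].replace(",", "")
    if not pmid_txt.isdigit():
        raise RelationFormatError(f"non-numeric pmid {fields[0]!r}")
    if not fields[1].isdigit():
        raise RelationFormatError(f"non-numeric sentence location {fields[1]!r}")
    try:
        return RelationRecord(
            pmid=int(pmid_txt),
            sentence_index=int(fields[1]),
            entity_a=normalize_entity(fields[2], thesaurus),
            type_a=fields[3].upper(),
            entity_b=normalize_entity(fields[4], thesaurus),
            type_b=fields[5].upper(),
            relation_label=fields[6],
        )
    except ValueError as exc:
        raise RelationFormatError(str(exc)) from exc


def parse_relation_records(
    stream: IO[str] | str | Iterable[str],
    strict: bool = True,
    thesaurus: Thesaurus | None = None,
) -> tuple[list[RelationRecord], int]:
    """Parse pipe-delimited relation records.

    Parameters
    ----------
    stream
        File path, open text stream, or iterable of lines.
    strict
        If True, a malformed line raises :class:`RelationFormatError`;
        otherwise malformed lines are skipped and counted.
    thesaurus
        Optional synonym groups applied during entity normalization.

    Returns
    -------
    (records, n_skipped)
        Parsed records in input order and the number of skipped lines
        (always 0 in strict mode).
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, encoding="utf-8")
        close = True
    records: list[RelationRecord] = []
    skipped = 0
    try:
        for line in stream:
            if not line.strip():
                continue
            try:
                records.append(_parse_line(line, thesaurus))
            except RelationFormatError:
                if strict:
                    raise
                skipped += 1
    finally:
        if close:
            stream.close()
    return records, skipped


def format_record(record: RelationRecord) -> str:
    return (
        f"{record.pmid} | {record.sentence_index} | {record.entity_a} | "
        f"{record.type_a} | {record.entity_b} | {record.type_b} | "
        f"{record.relation_label} |"
    )


def write_records(records: Sequence[RelationRecord], stream: IO[str] | str) -> None:
    """Write records in the pipe-delimited interchange format (round-trippable)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w", encoding="utf-8")
        close = True
    try:
        for record in records:
            stream.write(format_record(record) + "\n")
    finally:
        if close:
            stream.close()


def filter_by_type(
    records: Iterable[RelationRecord], allowed_types: Iterable[str]
) -> list[RelationRecord]:
    """Keep records whose BOTH entity types are in ``allowed_types`` (order preserved)."""
    allowed = {t.upper() for t in allowed_types}
    if not allowed:
        raise ValueError("allowed_types must be non-empty")
    return [r for r in records if r.type_a in allowed and r.type_b in allowed]


def apply_thesaurus(
    records: Iterable[RelationRecord], thesaurus: Thesaurus
) -> Iterator[RelationRecord]:
    """Re-canonicalize already-parsed records under a thesaurus, dropping pairs
    that collapse to self-pairs."""
    for r in records:
        a = thesaurus.canonical(r.entity_a)
        b = thesaurus.canonical(r.entity_b)
        if a == b:
            continue
        yield replace(r, entity_a=a, entity_b=b)
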