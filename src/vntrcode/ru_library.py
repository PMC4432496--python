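"""The repeat-unit (RU) alphabet of VNTR composite retrotransposons.

The central domain of SVA, LAVA, PVA and FVA elements is a VNTR built from
30-53 bp GC-rich repeat units.  Units fall into a small number of *types*,
coded by single letters A-T: A (40 bp) and B (39 bp) are the ancestral types
already present in SVA2 elements, the remainder arose later and derive from
A, B or from each other.  Within a type, lineage- or position-specific
*sequence variants* are distinguished by prime or superscript tags (B', C'',
B5', C^T ...).

This module holds the in-memory representation of that alphabet
(:class:`RULibrary`), reads and writes it as FASTA with structured headers,
and exposes the curated derivation relationships as a directed graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from Bio import SeqIO

__all__ = [
    "RepeatUnitType",
    "RepeatUnitVariant",
    "RULibrary",
    "LibraryError",
    "LibraryParseError",
    "load_library",
    "write_library",
    "derivation_graph",
    "graph_roots",
    "packaged_library_path",
    "load_packaged_library",
]

_VALID_CODES = frozenset("ABCDEFGHIJKLMNOPQRST")
_VALID_BASES = frozenset("ACGT")
_VALID_SCOPES = frozenset({"shared", "SVA", "LAVA", "orangutan_SVA", "chimp_SVA"})


class LibraryError(ValueError):
    """A repeat-unit library violates one of its invariants."""


class LibraryParseError(LibraryError):
    """A library FASTA record could not be parsed."""


@dataclass(frozen=True)
class RepeatUnitType:
    """One repeat-unit type of the coded alphabet.

    ``parents`` lists the types this one was derived from (empty for the
    ancestral roots A and B).  ``underived`` marks a type whose origin cannot
    be determined (the chimpanzee-specific S type), so that an empty parent
    list does not make it a root of the derivation graph.
    """

    code: str
    consensus: str
    family_scope: str
    parents: tuple[str, ...] = ()
    terminal: bool = False
    underived: bool = False
    note: str = ""

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class RepeatUnitVariant:
    """A sequence variant of a base type, named by a prime/superscript tag."""

    base_code: str
    tag: str
    consensus: str
    scope_note: str = ""

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def label(self) -> str:
        return self.base_code + self.tag


@dataclass
class RULibrary:
    """A validated collection of repeat-unit types and their variants."""

    units: dict[str, RepeatUnitType] = field(default_factory=dict)
    variants: dict[tuple[str, str], RepeatUnitVariant] = field(default_factory=dict)
    name: str = ""
    provenance: str = ""

    # -- access helpers -------------------------------------------------
    def entries(self):
        """All (code, tag, consensus) triples: base types have an empty tag."""
        for u in self.units.values():
            yield (u.code, "", u.consensus)
        for v in self.variants.values():
            yield (v.base_code, v.tag, v.consensus)

    def consensus(self, code: str, tag: str = "") -> str:
        if tag:
            return self.variants[(code, tag)].consensus
        return self.units[code].consensus

    def variants_of(self, code: str) -> list[RepeatUnitVariant]:
        return [v for v in self.variants.values() if v.base_code == code]

    # -- validation -----------------------------------------------------
    def validate(self) -> "RULibrary":
        if "A" not in self.units or "B" not in self.units:
            raise LibraryError(
                "library must contain the ancestral types A and B; "
                f"present: {sorted(self.units)}"
            )
        for u in self.units.values():
            if u.code not in _VALID_CODES or len(u.code) != 1:
                raise LibraryError(f"invalid type code {u.code!r} (must be one of A..T)")
            if not u.consensus or set(u.consensus) - _VALID_BASES:
                raise LibraryError(f"type {u.code}: consensus must be uppercase ACGT only")
            if u.family_scope not in _VALID_SCOPES:
                raise LibraryError(f"type {u.code}: unknown family_scope {u.family_scope!r}")
            for p in u.parents:
                if p not in self.units and not u.underived:
                    raise LibraryError(f"type {u.code}: unknown parent {p!r}")
        for (code, tag), v in self.variants.items():
            if code not in self.units:
                raise LibraryError(f"variant {code}{tag}: base type {code} not in library")
            if not tag:
                raise LibraryError(f"variant of {code} with empty tag (use the base type)")
            if set(v.consensus) - _VALID_BASES:
                raise LibraryError(f"variant {v.label}: consensus must be ACGT only")
            if abs(v.length - self.units[code].length) > 3:
                raise LibraryError(
                    f"variant {v.label}: length {v.length} departs from base "
                    f"length {self.units[code].length} by more than 3 bp"
                )
        derivation_graph(self, _validated=True)  # raises on cycles
        return self


# ----------------------------------------------------------------------
# FASTA dialect
#
#   >CODE|TAG|FAMILY_SCOPE|PARENTS=X,Y|NOTE=...
#
# TAG is empty for base types.  Additional KEY=VALUE fields (TERMINAL,
# UNDERIVED) may appear between FAMILY_SCOPE and NOTE.  Sequence lines are
# wrapped at 60 columns.
# ----------------------------------------------------------------------

def _parse_header(header: str):
    parts = header.split("|")
    if len(parts) < 3:
        raise LibraryParseError(
            f"malformed header {header!r}: expected CODE|TAG|FAMILY_SCOPE|..."
        )
    code, tag, scope = parts[0].strip(), parts[1].strip(), parts[2].strip()
    kv = {}
    for fieldstr in parts[3:]:
        if "=" not in fieldstr:
            raise LibraryParseError(f"record {header!r}: field {fieldstr!r} is not KEY=VALUE")
        k, _, v = fieldstr.partition("=")
        kv[k.strip().upper()] = v.strip()
    return code, tag, scope, kv


def load_library(path) -> RULibrary:
    """Read a repeat-unit library from its FASTA dialect and validate it."""
    lib = RULibrary(name=str(path))
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        code, tag, scope, kv = _parse_header(header)
        seq = str(record.seq).upper()
        if tag:
            key = (code, tag)
            if key in lib.variants:
                raise LibraryParseError(f"duplicate variant record {code}{tag}")
            lib.variants[key] = RepeatUnitVariant(
                base_code=code, tag=tag, consensus=seq, scope_note=kv.get("NOTE", "")
            )
        else:
            if code in lib.units:
                raise LibraryParseError(f"duplicate type record {code}")
            parents = tuple(p for p in kv.get("PARENTS", "").split(",") if p)
            lib.units[code] = RepeatUnitType(
                code=code,
                consensus=seq,
                family_scope=scope,
                parents=parents,
                terminal=kv.get("TERMINAL", "").lower() == "true",
                underived=kv.get("UNDERIVED", "").lower() == "true",
                note=kv.get("NOTE", ""),
            )
    return lib.validate()


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_library(lib: RULibrary, path) -> None:
    """Write a library in the structured-header FASTA dialect (60-col wrap)."""
    lines = []
    for u in lib.units.values():
        fields = [u.code, "", u.family_scope, "PARENTS=" + ",".join(u.parents)]
        if u.terminal:
            fields.append("TERMINAL=true")
        if u.underived:
            fields.append("UNDERIVED=true")
        if u.note:
            fields.append("NOTE=" + u.note)
        lines.append(">" + "|".join(fields))
        lines.append(_wrap(u.consensus))
    for v in lib.variants.values():
        fields = [v.base_code, v.tag, lib.units[v.base_code].family_scope, "PARENTS="]
        if v.scope_note:
            fields.append("NOTE=" + v.scope_note)
        lines.append(">" + "|".join(fields))
        lines.append(_wrap(v.consensus))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Derivation graph
# ----------------------------------------------------------------------

def derivation_graph(lib: RULibrary, _validated: bool = False) -> nx.DiGraph:
    """Directed graph of curated derivation relationships (parent -> child).

    Nodes are base-type codes.  Types with no parents and no
    ``underived`` flag are the ancestral roots; a type flagged underived
    (S: its source type cannot be determined) is annotated, not a root.
    Raises :class:`LibraryError` if the curated edges contain a cycle.
    """
    g = nx.DiGraph()
    for u in lib.units.values():
        g.add_node(u.code, underived=u.underived, terminal=u.terminal)
    for u in lib.units.values():
        for p in u.parents:
            if p in lib.units:
                g.add_edge(p, u.code)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise LibraryError(f"derivation graph contains a cycle: {cycle}")
    return g


def graph_roots(g: nx.DiGraph) -> list[str]:
    """Ancestral types: in-degree zero and derivation not flagged unknown."""
    return sorted(
        n for n in g.nodes if g.in_degree(n) == 0 and not g.nodes[n].get("underived")
    )


# ----------------------------------------------------------------------
# Packaged library
# ----------------------------------------------------------------------

def packaged_library_path():
    """Path of the packaged (synthetic-consensus) repeat-unit library."""
    from importlib.resources import files

    return files("vntrcode") / "data" / "ru_library.synthetic.fasta"


def load_packaged_library() -> RULibrary:
    lib = load_library(packaged_library_path())
    lib.name = "packaged"
    return lib
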