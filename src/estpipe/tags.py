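"""Library tag schemes embedded in the cDNA synthesis primers.

Both normalized CNS libraries were built with primers carrying a short tag
that records the tissue (head ganglia ``HG`` vs ventral nerve cord ``VNC``)
and the rearing phase (isolated ``I`` vs crowded ``C``) of each sample:

* library 1 — oligo-dT primers with a 4-mer tag directly after a NotI site,
  so the tag sits next to the poly(A) tail at the 3' end of the insert;
* library 2 — SMART-style 5' oligos with a 3/5-mer tag right after the
  template-switch anchor, at the 5' end of the insert.

Tag parsing for the phase screen lives in :mod:`estpipe.phasescreen`; the
read simulator (:mod:`estpipe.synthio`) uses the same tables when emitting
reads, so parse/emit cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TagEntry", "LibraryTagScheme", "LIB1", "LIB2", "BUILTIN_SCHEMES"]

_VALID_TISSUES = {"HG", "VNC"}
_VALID_PHASES = {"I", "C"}


@dataclass(frozen=True)
class TagEntry:
    tag: str  # DNA tag as written in the primer
    tissue: str  # HG | VNC
    phase: str  # I (isolated) | C (crowded)


@dataclass(frozen=True)
class LibraryTagScheme:
    """A set of tags sharing one anchor sequence that precedes them."""

    scheme_id: str
    anchor: str  # DNA immediately 5' of the tag in the primer
    entries: tuple[TagEntry, ...]
    tag_side: str = "5p"  # where the tag ends up on the insert: 5p | 3p
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        tags = [e.tag for e in self.entries]
        if len(set(tags)) != len(tags):
            raise ValueError(f"duplicate tags in scheme {self.scheme_id}")
        for e in self.entries:
            if e.tissue not in _VALID_TISSUES or e.phase not in _VALID_PHASES:
                raise ValueError(f"bad tissue/phase in scheme {self.scheme_id}: {e}")
            if set(e.tag) - set("ACGT") or set(self.anchor) - set("ACGT"):
                raise ValueError("tags and anchors must be plain DNA")

    def lookup(self, tag: str) -> TagEntry | None:
        for e in self.entries:
            if e.tag == tag:
                return e
        return None

    def tags_longest_first(self) -> list[TagEntry]:
        """Entries sorted longest tag first, so a 5-mer is tried before its
        3-mer suffix (the lib2 tags all end in GGG)."""
        return sorted(self.entries, key=lambda e: (-len(e.tag), e.tag))


#: First normalized library: NotI site, then a 4-mer tag, then oligo(dT).
LIB1 = LibraryTagScheme(
    scheme_id="lib1",
    anchor="GCGGCCGC",
    entries=(
        TagEntry("ACGC", "HG", "I"),
        TagEntry("ACCG", "VNC", "I"),
        TagEntry("TCGC", "VNC", "C"),
        TagEntry("TCCG", "HG", "C"),
    ),
    tag_side="3p",
    description="oligo-dT primers; tag follows the NotI site at the 3' end",
)

#: Second normalized library: SMART anchor, then the tag at the insert 5' end.
LIB2 = LibraryTagScheme(
    scheme_id="lib2",
    anchor="AAGCAGTGGTATCAACGCAGAGTGGCCATTACGGCC",
    entries=(
        TagEntry("GGG", "HG", "I"),
        TagEntry("AAGGG", "VNC", "I"),
        TagEntry("TTGGG", "HG", "C"),
        TagEntry("GAGGG", "VNC", "C"),
    ),
    tag_side="5p",
    description="SMART 5' oligos; tag follows the template-switch anchor",
)

BUILTIN_SCHEMES: dict[str, LibraryTagScheme] = {"lib1": LIB1, "lib2": LIB2}
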