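"""In-silico restriction digestion and the frag-end reduced genome.

4C-seq reads are not mapped to the full genome but to a *reduced* genome
made of the short sequences directly flanking every primary restriction
site (DpnII, ``GATC`` by default) — the "frag-ends".  This module performs
the double digestion in silico, extracts frag-end sequences, flags frag-ends
whose sequence is not unique genome-wide (these are discarded from
profiles), and flags *blind* fragments that carry no secondary-enzyme
(Csp6I, ``GTAC``) site.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "GenomeSequence",
    "RestrictionScheme",
    "Fragment",
    "FragEnd",
    "digest",
    "build_fragend_library",
    "mark_unique",
    "fragend_id",
]

_VALID_MOTIF = re.compile(r"^[ACGT]+$")

LEFT = "left_of_fragment"
RIGHT = "right_of_fragment"


class InvalidSchemeError(ValueError):
    """Restriction motif outside the plain ACGT alphabet."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: a name and its sequence over {A,C,G,T,N}."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chromosome {self.chrom_name!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RestrictionScheme:
    """Primary/secondary enzyme motifs and the frag-end extraction length.

    Defaults mirror a DpnII (GATC) primary digest with Csp6I (GTAC)
    secondary digest.  ``extract_len`` is the number of bases read inward
    from each primary cut site; 36 bp matches a typical trimmed read.
    """

    primary_motif: str = "GATC"
    secondary_motif: str = "GTAC"
    extract_len: int = 36

    def __post_init__(self) -> None:
        for motif in (self.primary_motif, self.secondary_motif):
            if not _VALID_MOTIF.match(motif):
                raise InvalidSchemeError(
                    f"restriction motif {motif!r} must be non-empty uppercase ACGT"
                )
        if self.extract_len < len(self.primary_motif):
            raise InvalidSchemeError(
                "extract_len must be at least the primary motif length"
            )


@dataclass(frozen=True)
class Fragment:
    """A primary restriction fragment [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragEnd:
    """One flank of a primary restriction fragment.

    ``pos`` is the coordinate of the primary-site boundary the frag-end
    abuts; ``side`` says which flank of its fragment it is.  ``sequence``
    is plus-strand genome text read inward from ``pos`` (reverse-complement
    matching is the read-assignment stage's job).  ``is_blind`` marks
    frag-ends of fragments with no secondary-motif occurrence.
    """

    chrom: str
    pos: int
    side: str  # LEFT or RIGHT
    sequence: str
    fragment_index: int
    is_unique: bool = True
    is_blind: bool = False

    @property
    def id(self) -> str:
        return fragend_id(self.chrom, self.pos, self.side)


def fragend_id(chrom: str, pos: int, side: str) -> str:
    tag = "L" if side == LEFT else "R"
    return f"{chrom}:{pos}:{tag}"


def find_motif_positions(sequence: str, motif: str) -> list[int]:
    """All start positions of ``motif`` in ``sequence``, overlaps allowed.

    Matching is case-insensitive on the sequence side; ``N`` never matches.
    """
    if not _VALID_MOTIF.match(motif):
        raise InvalidSchemeError(f"motif {motif!r} must be non-empty uppercase ACGT")
    seq = sequence.upper()
    positions: list[int] = []
    start = seq.find(motif)
    while start != -1:
        positions.append(start)
        start = seq.find(motif, start + 1)
    return positions


def digest(genome_seq: str, motif: str) -> list[Fragment]:
    """Cut ``genome_seq`` at every motif occurrence start.

    Returns the ordered fragments tiling [0, len) exactly.  A cut at
    position 0 produces no empty leading fragment.
    """
    if not genome_seq:
        raise ValueError("cannot digest an empty sequence")
    cuts = find_motif_positions(genome_seq, motif)
    boundaries = [0] + [c for c in cuts if c > 0] + [len(genome_seq)]
    fragments = []
    for i, (start, end) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        fragments.append(Fragment(chrom="", start=start, end=end, index=i))
    return fragments


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def build_fragend_library(
    genome: Iterable[GenomeSequence],
    scheme: RestrictionScheme = RestrictionScheme(),
) -> list[FragEnd]:
    """Digest every chromosome and emit annotated frag-ends.

    For each fragment, a frag-end is emitted at each boundary that abuts a
    primary cut site (the outer boundaries of terminal fragments yield
    none).  The frag-end sequence is the first ``extract_len`` bases of the
    fragment read inward from that boundary, truncated at the opposite
    fragment boundary.  Uniqueness flags are set by :func:`mark_unique`.
    """
    genome = list(genome)
    if not genome:
        raise ValueError("empty genome")
    names = [g.chrom_name for g in genome]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in genome")

    library: list[FragEnd] = []
    for chrom in genome:
        seq = chrom.sequence.upper()
        cuts = set(find_motif_positions(seq, scheme.primary_motif))
        fragments = digest(seq, scheme.primary_motif)
        for frag in fragments:
            frag_seq = seq[frag.start : frag.end]
            blind = scheme.secondary_motif not in frag_seq
            if frag.start in cuts:  # left boundary abuts a cut site
                library.append(
                    FragEnd(
                        chrom=chrom.chrom_name,
                        pos=frag.start,
                        side=LEFT,
                        sequence=frag_seq[: scheme.extract_len],
                        fragment_index=frag.index,
                        is_blind=blind,
                    )
                )
            if frag.end in cuts:  # right boundary abuts a cut site
                library.append(
                    FragEnd(
                        chrom=chrom.chrom_name,
                        pos=frag.end,
                        side=RIGHT,
                        sequence=frag_seq[-scheme.extract_len :],
                        fragment_index=frag.index,
                        is_blind=blind,
                    )
                )
    return mark_unique(library)


def mark_unique(library: Sequence[FragEnd]) -> list[FragEnd]:
    """Flag frag-ends whose sequence occurs ≥2 times as non-unique.

    Case-insensitive exact string comparison; frag-ends containing ``N``
    are conservatively marked non-unique (mirrors unmappable regions).
    Library order is preserved; input objects are not mutated.
    """
    counts: dict[str, int] = {}
    for fe in library:
        key = fe.sequence.upper()
        counts[key] = counts.get(key, 0) + 1
    marked = []
    for fe in library:
        key = fe.sequence.upper()
        unique = counts[key] == 1 and "N" not in key
        marked.append(replace(fe, is_unique=unique))
    return marked
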