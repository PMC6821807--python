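"""Read assignment, filtering, normalization and running-mean smoothing.

A 4C read reports one ligation partner of the viewpoint fragment: it starts
with the viewpoint's reading primer and continues into the captured
frag-end.  Assignment is exact-prefix matching of the post-primer bases
against the frag-end library (forward or reverse complement); reads hitting
non-unique frag-ends are discarded.  The highest-covered frag-end (in
practice the viewpoint itself) is removed, coverage is scaled so that the
intrachromosomal (cis) total is one million, and the displayed contact
profile is a running mean over 21 consecutive frag-ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragends import LEFT, FragEnd, _reverse_complement

__all__ = [
    "Viewpoint",
    "CoverageProfile",
    "assign_reads",
    "remove_top_fragend",
    "normalize",
    "running_mean",
    "NORMALIZATION_TARGET",
    "DEFAULT_WINDOW",
]

#: cis coverage after normalization sums to this many "reads"
NORMALIZATION_TARGET = 1_000_000
#: number of consecutive frag-ends averaged in the displayed profile
DEFAULT_WINDOW = 21


@dataclass(frozen=True)
class Viewpoint:
    """A 4C viewpoint: locus plus the inverse-PCR reading primer."""

    name: str
    chrom: str
    position: int
    reading_primer: str
    nonreading_primer: str = ""

    def __post_init__(self) -> None:
        if not self.reading_primer:
            raise ValueError("reading_primer must be non-empty")


class ProfileStateError(RuntimeError):
    """Operation applied to a profile in the wrong processing state."""


@dataclass
class CoverageProfile:
    """Per-frag-end coverage for one viewpoint in one sample.

    ``counts`` is aligned with ``library``; ``state`` tracks the processing
    stage (raw → filtered → normalized → smoothed).
    """

    viewpoint: Viewpoint
    library: Sequence[FragEnd]
    counts: np.ndarray
    state: str = "raw"
    total_reads: int = 0
    discarded: dict = field(default_factory=dict)
    scale_factor: float | None = None
    removed_fragend: FragEnd | None = None
    window: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.library):
            raise ValueError("counts and library lengths differ")

    # -- views ------------------------------------------------------------

    def cis_mask(self) -> np.ndarray:
        chroms = np.array([fe.chrom for fe in self.library])
        return chroms == self.viewpoint.chrom

    @property
    def intrachromosomal_total(self) -> float:
        return float(self.counts[self.cis_mask()].sum())

    def count_of(self, fragend: FragEnd) -> float:
        for i, fe in enumerate(self.library):
            if fe.id == fragend.id:
                return float(self.counts[i])
        raise KeyError(fragend.id)

    def copy(self) -> "CoverageProfile":
        return CoverageProfile(
            viewpoint=self.viewpoint,
            library=self.library,
            counts=self.counts.copy(),
            state=self.state,
            total_reads=self.total_reads,
            discarded=dict(self.discarded),
            scale_factor=self.scale_factor,
            removed_fragend=self.removed_fragend,
            window=self.window,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [fe.chrom for fe in self.library],
                "pos": [fe.pos for fe in self.library],
                "fragend_id": [fe.id for fe in self.library],
                "value": self.counts,
            }
        )


def genomic_order(library: Sequence[FragEnd]) -> np.ndarray:
    """Indices sorting frag-ends by (chrom, coordinate).

    At a shared cut coordinate the right flank of the upstream fragment
    precedes the left flank of the downstream fragment.
    """
    keys = [(fe.chrom, fe.pos, 1 if fe.side == LEFT else 0) for fe in library]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)


def _read_sequence(read) -> str:
    if isinstance(read, str):
        return read
    if isinstance(read, tuple):
        return read[1]
    seq = getattr(read, "seq", None)  # Bio.SeqRecord
    if seq is not None:
        return str(seq)
    raise TypeError(f"cannot interpret read of type {type(read)!r}")


def assign_reads(
    reads: Iterable,
    viewpoint: Viewpoint,
    library: Sequence[FragEnd],
    extract_len: int | None = None,
) -> CoverageProfile:
    """Count reads per unique frag-end; returns a raw profile.

    A read is assigned to frag-end *f* iff it begins with the viewpoint's
    reading primer and the following bases exactly match *f*'s sequence or
    its reverse complement.  Reads failing the primer, matching nothing, or
    matching only non-unique frag-ends are tallied under ``discarded`` as
    ``no_primer`` / ``no_match`` / ``non_unique``.

    ``reads`` may be plain strings, ``(id, seq, qual)`` tuples, or Biopython
    ``SeqRecord`` objects.
    """
    library = list(library)
    if not library:
        raise ValueError("empty frag-end library")
    if extract_len is None:
        extract_len = max(len(fe.sequence) for fe in library)

    # match tables keyed by sequence, bucketed per sequence length
    by_len: dict[int, dict[str, int]] = {}
    nonunique: dict[int, set[str]] = {}
    for i, fe in enumerate(library):
        seq = fe.sequence.upper()
        bucket_len = len(seq)
        for variant in (seq, _reverse_complement(seq)):
            if fe.is_unique:
                by_len.setdefault(bucket_len, {}).setdefault(variant, i)
            else:
                nonunique.setdefault(bucket_len, set()).add(variant)
    lengths = sorted(set(by_len) | set(nonunique), reverse=True)

    primer = viewpoint.reading_primer.upper()
    counts = np.zeros(len(library))
    tallies = {"no_primer": 0, "no_match": 0, "non_unique": 0}
    assigned = 0
    for read in reads:
        seq = _read_sequence(read).upper()
        if not seq.startswith(primer):
            tallies["no_primer"] += 1
            continue
        rest = seq[len(primer) : len(primer) + extract_len]
        hit = None
        hit_nonunique = False
        for length in lengths:  # prefer the longest (most specific) match
            if length > len(rest):
                continue
            prefix = rest[:length]
            idx = by_len.get(length, {}).get(prefix)
            if idx is not None:
                hit = idx
                break
            if prefix in nonunique.get(length, ()):
                hit_nonunique = True
                break
        if hit is not None:
            counts[hit] += 1
            assigned += 1
        elif hit_nonunique:
            tallies["non_unique"] += 1
        else:
            tallies["no_match"] += 1

    return CoverageProfile(
        viewpoint=viewpoint,
        library=library,
        counts=counts,
        state="raw",
        total_reads=assigned,
        discarded=tallies,
    )


def remove_top_fragend(profile: CoverageProfile) -> CoverageProfile:
    """Drop the genome-wide highest-covered frag-end (filtered state).

    In practice this is the self-ligated viewpoint frag-end, whose enormous
    count would otherwise dominate the scale factor.  Ties break toward
    the lowest genomic coordinate, then chromosome name order.
    """
    if profile.state != "raw":
        raise ProfileStateError(f"expected raw profile, got {profile.state!r}")
    if not np.any(profile.counts > 0):
        raise ValueError("empty profile")
    order = sorted(
        range(len(profile.library)),
        key=lambda i: (
            -profile.counts[i],
            profile.library[i].pos,
            profile.library[i].chrom,
        ),
    )
    top = order[0]
    out = profile.copy()
    out.counts[top] = 0.0
    out.removed_fragend = profile.library[top]
    out.state = "filtered"
    return out


def normalize(
    profile: CoverageProfile, target: float = NORMALIZATION_TARGET
) -> CoverageProfile:
    """Scale all counts so cis coverage sums to ``target`` (default 1e6)."""
    if profile.state != "filtered":
        raise ProfileStateError(f"expected filtered profile, got {profile.state!r}")
    cis_sum = profile.intrachromosomal_total
    if cis_sum <= 0:
        raise ValueError("no intrachromosomal signal")
    s = target / cis_sum
    out = profile.copy()
    out.counts = profile.counts * s
    out.scale_factor = s
    out.state = "normalized"
    return out


def _running_mean_1d(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean; near the edges the window shrinks
    symmetrically to the largest centered window that fits (minimum 1)."""
    n = len(values)
    half = (window - 1) // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)


def running_mean(
    profile: CoverageProfile, window: int = DEFAULT_WINDOW
) -> CoverageProfile:
    """Smooth the normalized profile: per-chromosome centered running mean
    over ``window`` consecutive frag-ends (default 21)."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    if profile.state != "normalized":
        raise ProfileStateError(f"expected normalized profile, got {profile.state!r}")
    order = genomic_order(profile.library)
    chroms = np.array([profile.library[i].chrom for i in order])
    smoothed = np.empty_like(profile.counts)
    for chrom in pd.unique(chroms):
        sel = order[chroms == chrom]
        smoothed[sel] = _running_mean_1d(profile.counts[sel], window)
    out = profile.copy()
    out.counts = smoothed
    out.state = "smoothed"
    out.window = window
    return out
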