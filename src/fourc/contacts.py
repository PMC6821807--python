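"""Anchor-based differential contact testing.

Fixed-width anchors (10 Kb by default) are placed at positions of interest
along the viewpoint chromosome; the normalized (unsmoothed) coverage of the
frag-ends inside each anchor is summed per replicate, and genotype groups
are compared with an unpaired two-sample Student's t test (pooled
variance).  Welch's unequal-variance variant is available behind a flag.
Raw two-sided p-values are reported; a Benjamini-Hochberg column can be
added for convenience but the primary output is uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragends import FragEnd
from .profiles import CoverageProfile, ProfileStateError

__all__ = [
    "Anchor",
    "AnchorTestResult",
    "build_anchors",
    "anchor_sums",
    "anchor_ttest",
    "differential_contact_table",
    "DEFAULT_HALFWIDTH",
]

#: anchors span 2 × halfwidth = 10 Kb by default
DEFAULT_HALFWIDTH = 5_000


@dataclass
class Anchor:
    """A half-open window [center − halfwidth, center + halfwidth) owning
    the frag-ends whose coordinate falls inside it."""

    name: str
    chrom: str
    center: int
    halfwidth: int = DEFAULT_HALFWIDTH
    member_fragends: list[FragEnd] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.center - self.halfwidth

    @property
    def end(self) -> int:
        return self.center + self.halfwidth

    @property
    def is_empty(self) -> bool:
        return not self.member_fragends

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class AnchorTestResult:
    anchor: Anchor
    group_a_sums: np.ndarray
    group_b_sums: np.ndarray
    mean_a: float
    mean_b: float
    t_stat: float
    dof: int
    p_value: float
    note: str = ""


def build_anchors(
    centers: Iterable[tuple[str, int]],
    library: Sequence[FragEnd],
    halfwidth: int = DEFAULT_HALFWIDTH,
    chrom_lengths: dict[str, int] | None = None,
) -> list[Anchor]:
    """One anchor per (chrom, center); membership by frag-end coordinate.

    Overlapping anchors are allowed and share frag-ends.  When
    ``chrom_lengths`` is given, centers outside the chromosome raise.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    anchors = []
    for chrom, center in centers:
        if chrom_lengths is not None:
            length = chrom_lengths.get(chrom)
            if length is None or not (0 <= center < length):
                raise ValueError(f"anchor center {chrom}:{center} is off-chromosome")
        anchor = Anchor(name=f"{chrom}:{center}", chrom=chrom, center=center,
                        halfwidth=halfwidth)
        anchor.member_fragends = [
            fe for fe in library if anchor.contains(fe.chrom, fe.pos)
        ]
        anchors.append(anchor)
    return anchors


def anchor_sums(
    profiles: Sequence[CoverageProfile], anchors: Sequence[Anchor]
) -> pd.DataFrame:
    """Sum normalized coverage over each anchor's frag-ends, per replicate.

    Rows are anchors, columns replicates.  Profiles must be in the
    normalized (not smoothed) state: the running mean is display-only.
    """
    for p in profiles:
        if p.state != "normalized":
            raise ProfileStateError(
                f"anchor sums require normalized profiles, got {p.state!r}"
            )
    table = np.zeros((len(anchors), len(profiles)))
    for j, profile in enumerate(profiles):
        index = {fe.id: i for i, fe in enumerate(profile.library)}
        for i, anchor in enumerate(anchors):
            members = [index[fe.id] for fe in anchor.member_fragends]
            table[i, j] = profile.counts[members].sum() if members else 0.0
    return pd.DataFrame(
        table,
        index=[a.name for a in anchors],
        columns=[f"rep{j + 1}" for j in range(len(profiles))],
    )


def anchor_ttest(
    sums_a: Sequence[float],
    sums_b: Sequence[float],
    anchor: Anchor | None = None,
    welch: bool = False,
) -> AnchorTestResult:
    """Unpaired two-sample t test on per-replicate anchor sums.

    Student's pooled-variance form by default, two-sided p from the t
    distribution with n_a + n_b − 2 degrees of freedom.  Zero pooled
    variance is handled explicitly: equal means give t = 0, p = 1
    ("degenerate"); unequal means give p = 0 ("infinite_t").
    """
    a = np.asarray(sums_a, dtype=float)
    b = np.asarray(sums_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    na, nb = len(a), len(b)
    mean_a, mean_b = a.mean(), b.mean()
    dof = na + nb - 2
    note = ""

    if welch:
        t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
        var_a, var_b = a.var(ddof=1), b.var(ddof=1)
        if var_a == 0 and var_b == 0:
            if mean_a == mean_b:
                t_stat, p_value, note = 0.0, 1.0, "degenerate"
            else:
                t_stat = math.copysign(math.inf, mean_a - mean_b)
                p_value, note = 0.0, "infinite_t"
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        pooled_var = (
            (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
        ) / dof
        if pooled_var == 0:
            if mean_a == mean_b:
                t_stat, p_value, note = 0.0, 1.0, "degenerate"
            else:
                t_stat = math.copysign(math.inf, mean_a - mean_b)
                p_value, note = 0.0, "infinite_t"
        else:
            se = math.sqrt(pooled_var * (1 / na + 1 / nb))
            t_stat = (mean_a - mean_b) / se
            p_value = 2 * float(stats.t.sf(abs(t_stat), dof))

    return AnchorTestResult(
        anchor=anchor if anchor is not None else Anchor("", "", 0, 1),
        group_a_sums=a,
        group_b_sums=b,
        mean_a=float(mean_a),
        mean_b=float(mean_b),
        t_stat=t_stat,
        dof=dof,
        p_value=p_value,
        note=note,
    )


def differential_contact_table(
    profiles_a: Sequence[CoverageProfile],
    profiles_b: Sequence[CoverageProfile],
    anchors: Sequence[Anchor],
    welch: bool = False,
    bh_column: bool = True,
) -> pd.DataFrame:
    """End-to-end anchor comparison of two replicate groups.

    Returns one row per anchor: interval, member count, per-replicate sums,
    group means, t, dof and the raw two-sided p.  When ``bh_column`` is set
    a Benjamini-Hochberg adjusted column (``p_bh``) is appended for
    convenience; the raw p-values remain the primary result.
    """
    sums_a = anchor_sums(profiles_a, anchors)
    sums_b = anchor_sums(profiles_b, anchors)
    rows = []
    for anchor in anchors:
        res = anchor_ttest(
            sums_a.loc[anchor.name].to_numpy(),
            sums_b.loc[anchor.name].to_numpy(),
            anchor=anchor,
            welch=welch,
        )
        row = {
            "anchor": anchor.name,
            "chrom": anchor.chrom,
            "start": anchor.start,
            "end": anchor.end,
            "n_fragends": len(anchor.member_fragends),
            "mean_a": res.mean_a,
            "mean_b": res.mean_b,
            "t": res.t_stat,
            "dof": res.dof,
            "p": res.p_value,
            "note": res.note or ("empty" if anchor.is_empty else ""),
        }
        for j, v in enumerate(res.group_a_sums):
            row[f"a_rep{j + 1}"] = v
        for j, v in enumerate(res.group_b_sums):
            row[f"b_rep{j + 1}"] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    if bh_column and len(table):
        table["p_bh"] = stats.false_discovery_control(
            table["p"].to_numpy(), method="bh"
        )
    return table
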