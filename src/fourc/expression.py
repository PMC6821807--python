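"""Reference-gene-normalized expression and the monoallelic deletion model.

RT-qPCR quantities (LinRegPCR-style relative start concentrations) are
normalized per sample to the geometric mean of reference genes (cTnI and
Hprt in heart), fold changes are ratios of group means, and a two-allele
activity model predicts the expression reduction caused by cis-regulatory
deletions: a heterozygote whose deleted allele is fully silenced keeps one
fully active allele and therefore loses exactly half its output —
monoallelic expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import AnchorTestResult, anchor_ttest

__all__ = [
    "ExpressionTable",
    "AlleleModel",
    "normalize_expression",
    "fold_change",
    "monoallelic_prediction",
    "expression_ttest",
]


@dataclass
class ExpressionTable:
    """Gene × sample quantities with sample genotype/tissue labels.

    ``quantities``: DataFrame indexed by gene, columns are sample names.
    ``sample_info``: DataFrame indexed by sample with ``genotype`` and
    ``tissue`` columns.  ``reference_genes`` must be measured (> 0) in
    every sample.
    """

    quantities: pd.DataFrame
    sample_info: pd.DataFrame
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.reference_genes) - set(self.quantities.index)
        if missing:
            raise ValueError(f"reference genes absent from table: {sorted(missing)}")

    def samples_of(self, genotype: str) -> list[str]:
        sel = self.sample_info["genotype"] == genotype
        return list(self.sample_info.index[sel])


@dataclass(frozen=True)
class AlleleModel:
    """Transcriptional output per allele, wildtype allele ≡ 1.

    ``variant_alleles`` optionally names the bases at a diagnostic site
    distinguishing the two alleles (e.g. a strain-specific variant), used
    only for labelling the predicted transcript fractions.
    """

    allele_activities: tuple[float, float] = (1.0, 1.0)
    variant_alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.allele_activities):
            raise ValueError("allele activities must be non-negative")


def normalize_expression(table: ExpressionTable) -> pd.DataFrame:
    """Divide each sample's quantities by the geometric mean of that
    sample's reference-gene quantities.

    Removes per-sample loading/input differences: scaling one sample's
    column by any factor leaves its normalized values unchanged.
    """
    refs = table.quantities.loc[table.reference_genes]
    bad = refs.columns[(refs <= 0).any(axis=0)]
    if len(bad):
        raise ValueError(
            f"non-positive reference quantity in sample(s): {list(bad)}"
        )
    geomeans = stats.gmean(refs.to_numpy(), axis=0)
    return table.quantities / geomeans


def fold_change(
    normalized: pd.DataFrame,
    group_ref: Sequence[str],
    group_test: Sequence[str],
    gene: str,
) -> float:
    """mean(test) / mean(ref) of normalized quantities for one gene."""
    if not len(group_ref) or not len(group_test):
        raise ValueError("both groups must be non-empty")
    ref_mean = normalized.loc[gene, list(group_ref)].mean()
    if ref_mean == 0:
        raise ZeroDivisionError(f"reference group mean is 0 for gene {gene!r}")
    return float(normalized.loc[gene, list(group_test)].mean() / ref_mean)


def monoallelic_prediction(model: AlleleModel) -> dict:
    """Percent reduction vs wildtype and the silenced allele's transcript
    fraction under the two-allele activity model.

    Wildtype total output is 1 + 1; percent reduction is
    100 × (1 − (a1 + a2)/2).  Activities (1, 0) — one allele fully
    silenced — give a 50% reduction and a transcript pool containing no
    silenced-allele transcripts (fraction 0): monoallelic expression.
    """
    a1, a2 = model.allele_activities
    total = a1 + a2
    reduction = 100.0 * (1.0 - total / 2.0)
    if total == 0:
        return {"percent_reduction": 100.0, "silenced_fraction": None,
                "note": "both alleles silent"}
    silenced = min(a1, a2)
    return {
        "percent_reduction": reduction,
        "silenced_fraction": silenced / total,
        "note": "",
    }


def expression_ttest(
    normalized: pd.DataFrame,
    group_ref: Sequence[str],
    group_test: Sequence[str],
    gene: str,
) -> AnchorTestResult:
    """Unpaired Student's t test on normalized quantities (shared kernel
    with the anchor contact test)."""
    a = normalized.loc[gene, list(group_ref)].to_numpy(dtype=float)
    b = normalized.loc[gene, list(group_test)].to_numpy(dtype=float)
    return anchor_ttest(a, b)


def expression_results(
    table: ExpressionTable,
    ref_genotype: str,
    test_genotype: str,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold change + t test per gene between two genotype groups."""
    normalized = normalize_expression(table)
    ref_samples = table.samples_of(ref_genotype)
    test_samples = table.samples_of(test_genotype)
    if genes is None:
        genes = [g for g in table.quantities.index
                 if g not in table.reference_genes]
    rows = []
    for gene in genes:
        fc = fold_change(normalized, ref_samples, test_samples, gene)
        res = expression_ttest(normalized, ref_samples, test_samples, gene)
        rows.append({"gene": gene, "fold_change": fc, "t": res.t_stat,
                     "dof": res.dof, "p": res.p_value, "note": res.note})
    return pd.DataFrame(rows)
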