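"""Cohort-level statistics: mutational-signature refitting and SBS3 positivity,
homologous-recombination (HR) subset assignment, pairwise two-sided Fisher
enrichment tests and clinical-actionability tallies.

Signature attribution is supervised non-negative refitting against a fixed
reference catalog (per-sample NNLS on the 96 trinucleotide channels), not de
novo extraction: weights are rescaled to mutation counts and a sample is
SBS3-positive when at least 100 mutations are attributed to SBS3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import fisher_exact

SBS3_MIN_MUTATIONS = 100
HR_GENES = (
    "BRCA1", "BRCA2", "PALB2", "BARD1", "CHEK2", "ATM",
    "BLM", "RAD51C", "FANCA", "FANCC", "ERCC4",
)


@dataclass
class SignatureAttribution:
    sample_id: str
    attributed_counts: dict[str, float]
    total_mutations: float
    residual: float = 0.0

    @property
    def sbs3_positive(self) -> bool:
        return self.attributed_counts.get("SBS3", 0.0) >= SBS3_MIN_MUTATIONS


def attribute_signatures(
    sample_counts96: np.ndarray | Sequence[float],
    catalog: pd.DataFrame,
    sample_id: str = "sample",
) -> SignatureAttribution:
    """Refit a 96-channel mutation count vector onto a signature catalog.

    ``catalog`` is 96 rows x signatures, each column summing to 1. Non-negative
    least squares gives per-signature activities on the count scale; the
    residual is the L2 misfit of the reconstruction.
    """
    counts = np.asarray(sample_counts96, dtype=float)
    if counts.shape[0] != catalog.shape[0]:
        raise ValueError("count vector and catalog channel dimension differ")
    if np.any(counts < 0):
        raise ValueError("negative mutation counts")
    mat = catalog.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("degenerate catalog: rank-deficient signature matrix")
    weights, rnorm = nnls(mat, counts)
    attributed = dict(zip(catalog.columns, weights))
    return SignatureAttribution(sample_id, attributed, float(counts.sum()), float(rnorm))


def fisher_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (rows = datasets, columns =
    positive/negative), using the minimum-likelihood convention: sum the
    probabilities of all tables no more likely than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in contingency table; p = 1.0 by convention")
        return 1.0
    return float(fisher_exact(t, alternative="two-sided").pvalue)


def hr_subset_assign(
    germline_variants: Sequence,
    somatic_variants: Sequence,
    hr_gene_list: Sequence[str] = HR_GENES,
) -> str:
    """HR_germline if any germline LP/P variant hits an HR gene; else HR_somatic
    for qualifying somatic HR variants; else HR_negative. Germline precedence
    applies when both exist."""
    genes = set(hr_gene_list)

    def hits(variants):
        return any((getattr(v, "gene", v) in genes) for v in variants)

    if hits(germline_variants):
        return "HR_germline"
    if hits(somatic_variants):
        return "HR_somatic"
    return "HR_negative"


def cohort_enrichment(groups: Mapping[str, tuple[int, int]]) -> dict:
    """Pairwise SBS3 enrichment between sample groups.

    ``groups`` maps group name -> (positive, total). Returns per-group positive
    fractions and a two-sided Fisher p for every unordered pair. No
    multiple-testing correction is applied (each pair is reported as-is).
    """
    fractions = {g: pos / total if total else 0.0 for g, (pos, total) in groups.items()}
    names = list(groups)
    pvalues = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, na = groups[a]
            pb, nb = groups[b]
            pvalues[(a, b)] = fisher_two_sided([[pa, na - pa], [pb, nb - pb]])
    return {"fractions": fractions, "pvalues": pvalues}


def actionability_tally(
    findings: pd.DataFrame,
    cohort_denominator: int,
    somatic_denominator: int,
    somatic_categories: Sequence[str] = ("A", "B", "C"),
) -> dict:
    """Clinical-utility tally over a findings table with columns
    ``participant`` and ``category``.

    A participant with findings in several categories appears once per relevant
    category but is counted only once in the 'any utility' class. Categories in
    ``somatic_categories`` use the somatic-analysis denominator; the rest and
    'any' use the full-cohort denominator. The findings-per-participant
    distribution is binned into {1, 2, >2}.
    """
    if findings.empty:
        return {
            "any_fraction": 0.0,
            "per_category": {},
            "findings_distribution": {"1": 0, "2": 0, ">2": 0},
        }
    dedup = findings.drop_duplicates()
    participants = dedup["participant"].unique()
    per_category = {}
    for cat, sub in dedup.groupby("category"):
        denom = somatic_denominator if cat in somatic_categories else cohort_denominator
        per_category[cat] = {
            "participants": int(sub["participant"].nunique()),
            "fraction": sub["participant"].nunique() / denom,
        }
    counts = dedup.groupby("participant").size()
    dist = {
        "1": int((counts == 1).sum()),
        "2": int((counts == 2).sum()),
        ">2": int((counts > 2).sum()),
    }
    return {
        "any_fraction": len(participants) / cohort_denominator,
        "per_category": per_category,
        "findings_distribution": dist,
    }
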