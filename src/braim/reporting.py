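"""Bookkeeping over validation and clustering counts.

Small closed-form summaries used when reporting a screen: precision of
the candidate list after orthogonal validation, the relative growth of
the known-gene catalogue, and the clustered/isolated breakdown of hits.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ValidationSummary:
    n_candidates: int
    n_confirmed: int
    precision_pct: float
    catalogue_before: int
    catalogue_after: int
    catalogue_increase_pct: float


def validation_summary(
    n_known: int,
    n_novel_candidates: int,
    n_novel_confirmed: int,
    catalogue_before: int,
) -> ValidationSummary:
    """Precision of a candidate list and catalogue growth.

    Known genes (already validated elsewhere) count as confirmed; novel
    candidates contribute only their orthogonally confirmed subset.  The
    catalogue grows by the confirmed novel genes.
    """
    n_candidates = n_known + n_novel_candidates
    n_confirmed = n_known + n_novel_confirmed
    after = catalogue_before + n_novel_confirmed
    return ValidationSummary(
        n_candidates=n_candidates,
        n_confirmed=n_confirmed,
        precision_pct=100.0 * n_confirmed / n_candidates,
        catalogue_before=catalogue_before,
        catalogue_after=after,
        catalogue_increase_pct=100.0 * (after - catalogue_before) / catalogue_before,
    )


def clustered_fraction_pct(n_clustered: int, n_total: int) -> float:
    """Percentage of genes lying within 1 MB of another imprinted gene."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_clustered / n_total
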