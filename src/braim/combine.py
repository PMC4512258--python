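"""Collapse lowly-identifiable transcripts via posterior anti-correlation.

Transcripts of the same gene that the read data cannot distinguish show
strongly anti-correlated posterior expression draws (reads flow to one or
the other).  Pairs whose mean per-sample Pearson correlation is below a
cutoff (default -0.25) on BOTH alleles are merged, most negative first,
their draws summed elementwise; merging repeats until no pair qualifies.
Requiring both alleles keeps the combined units identical across alleles
so they remain testable for parental bias.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import AllelicPosterior, CombineDecision

DEFAULT_CUTOFF = -0.25


def posterior_correlation(
    draws_a: Mapping[str, np.ndarray],
    draws_b: Mapping[str, np.ndarray],
    samples: Sequence[str],
) -> float:
    """Mean per-sample Pearson correlation of two transcripts' draws.

    Draws are paired by draw index within each sample.  Samples where
    either transcript has zero draw variance contribute r = 0.
    """
    rs = []
    for sid in samples:
        a = np.asarray(draws_a[sid], dtype=float)
        b = np.asarray(draws_b[sid], dtype=float)
        if a.size != b.size:
            raise ValueError(f"sample {sid}: mismatched draw counts {a.size} != {b.size}")
        if a.std() == 0.0 or b.std() == 0.0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs))


class _Unit:
    """A transcript or an already-combined group of transcripts."""

    __slots__ = ("members", "draws")

    def __init__(self, members: frozenset[str], draws: dict[str, dict[str, np.ndarray]]):
        self.members = members
        self.draws = draws  # allele -> sample -> draws

    @property
    def unit_id(self) -> str:
        return "+".join(sorted(self.members))


def combine_iteration(
    transcripts: Sequence[AllelicPosterior],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[AllelicPosterior], list[CombineDecision]]:
    """Greedy iterative merging of anti-correlated units of one gene.

    Returns the resulting posterior records (combined units carry ids of
    sorted members joined by "+") and the merge decisions in order.
    """
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"combine_iteration expects one gene, got {sorted(gene_ids)}")
    gene_id = gene_ids.pop()
    samples = sorted({t.sample_id for t in transcripts})

    units: dict[str, _Unit] = {}
    for t in transcripts:
        u = units.setdefault(
            t.transcript_id,
            _Unit(frozenset([t.transcript_id]), {"paternal": {}, "maternal": {}}),
        )
        u.draws[t.allele][t.sample_id] = np.asarray(t.draws, dtype=float)

    decisions: list[CombineDecision] = []
    while True:
        keys = sorted(units)
        best = None  # (mean_r_both, key_a, key_b, r_pat, r_mat)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = units[keys[i]], units[keys[j]]
                r_pat = posterior_correlation(a.draws["paternal"], b.draws["paternal"], samples)
                r_mat = posterior_correlation(a.draws["maternal"], b.draws["maternal"], samples)
                if r_pat < cutoff and r_mat < cutoff:
                    mean_r = 0.5 * (r_pat + r_mat)
                    if best is None or mean_r < best[0]:
                        best = (mean_r, keys[i], keys[j], r_pat, r_mat)
        if best is None:
            break
        _, ka, kb, r_pat, r_mat = best
        a, b = units.pop(ka), units.pop(kb)
        merged_draws = {
            allele: {
                sid: a.draws[allele][sid] + b.draws[allele][sid] for sid in samples
            }
            for allele in ("paternal", "maternal")
        }
        merged = _Unit(a.members | b.members, merged_draws)
        units[merged.unit_id] = merged
        decisions.append(
            CombineDecision(
                members=merged.members,
                combined_id=merged.unit_id,
                mean_r_paternal=r_pat,
                mean_r_maternal=r_mat,
            )
        )

    out: list[AllelicPosterior] = []
    for key in sorted(units):
        u = units[key]
        for allele in ("paternal", "maternal"):
            for sid in samples:
                out.append(AllelicPosterior(u.unit_id, gene_id, sid, allele, u.draws[allele][sid]))
    return out, decisions


def combine_transcripts(
    records: Iterable[AllelicPosterior],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[AllelicPosterior], list[CombineDecision], dict[str, str]]:
    """Run the combining pass gene by gene.

    Returns the new records, all merge decisions, and an original-id ->
    combined-id map (identity for transcripts left alone).
    """
    by_gene: dict[str, list[AllelicPosterior]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    out_records: list[AllelicPosterior] = []
    out_decisions: list[CombineDecision] = []
    id_map: dict[str, str] = {}
    for gene_id in sorted(by_gene):
        combined, decisions = combine_iteration(by_gene[gene_id], cutoff)
        out_records.extend(combined)
        out_decisions.extend(decisions)
        for unit_id in {r.transcript_id for r in combined}:
            for member in unit_id.split("+"):
                id_map[member] = unit_id
    return out_records, out_decisions, id_map
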