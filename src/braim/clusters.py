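"""Imprinted-cluster assignment and bias-decay regression.

Imprinted genes concentrate in genomic clusters anchored by strongly
biased "center" genes (preferred-allele fraction above 85:15).  Each
chromosome is scanned 5'->3'; genes within 1 MB of the previous gene chain
into a cluster; consecutive candidate centers group into a single center
interval; clusters with several center groups split into sub-clusters at
midpoints between adjacent groups.  The parental bias of non-center
members is then regressed on their distance from the center.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import BraimFit, ClusterAssignment, GeneCoordinate

DEFAULT_CENTER_BIAS = 0.85
DEFAULT_MAX_GAP = 1_000_000


def select_representative(fits: Sequence[BraimFit]) -> str:
    """Pick the isoform with the most significant parental bias.

    Maximal parental-effect PP; ties broken by larger |beta|, then by
    lexicographically smaller transcript id.
    """
    if not fits:
        raise ValueError("no fitted transcripts")
    return min(
        fits,
        key=lambda f: (
            -f.effect_pp("parental"),
            -abs(f.beta_mean[f.effect_index("parental")]),
            f.transcript_id,
        ),
    ).transcript_id


@dataclass
class _Gene:
    coord: GeneCoordinate
    bias: float

    @property
    def lo(self) -> int:
        return self.coord.start

    @property
    def hi(self) -> int:
        return self.coord.end

    @property
    def start_site(self) -> int:
        # antisense genes' start/end are represented swapped to sense
        return self.coord.tss


def assign_clusters(
    genes: Sequence[GeneCoordinate],
    biases: Mapping[str, float],
    center_threshold: float = DEFAULT_CENTER_BIAS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[ClusterAssignment]:
    """Chain genes into clusters, detect centers, assign distances.

    Genes whose start site ends up more than ``max_gap`` from their center
    are dropped; members of clusters with no center gene keep their
    cluster id but carry NaN distance (they cannot enter the decay
    regression).
    """
    items = [ _Gene(g, float(biases[g.gene_id])) for g in genes ]
    by_chrom: dict[str, list[_Gene]] = {}
    for it in items:
        by_chrom.setdefault(it.coord.chromosome, []).append(it)

    out: list[ClusterAssignment] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.lo, g.hi, g.coord.gene_id))
        clusters: list[list[_Gene]] = []
        prev_end: int | None = None
        for g in chrom_genes:
            if prev_end is not None and g.lo - prev_end <= max_gap:
                clusters[-1].append(g)
            else:
                clusters.append([g])
            prev_end = g.hi if prev_end is None else max(prev_end, g.hi)
            if clusters[-1] == [g]:
                prev_end = g.hi
        for ci, members in enumerate(clusters):
            out.extend(
                _assign_within_cluster(
                    members, f"{chrom}:c{ci}", center_threshold, max_gap
                )
            )
    return out


def _assign_within_cluster(
    members: list[_Gene], cluster_id: str, center_threshold: float, max_gap: int
) -> list[ClusterAssignment]:
    chrom = members[0].coord.chromosome
    is_candidate = [g.bias > center_threshold for g in members]

    # group physically consecutive candidate centers into intervals
    groups: list[list[_Gene]] = []
    for i, (g, cand) in enumerate(zip(members, is_candidate)):
        if cand:
            if i > 0 and is_candidate[i - 1]:
                groups[-1].append(g)
            else:
                groups.append([g])

    if not groups:
        return [
            ClusterAssignment(
                gene_id=g.coord.gene_id,
                cluster_id=cluster_id,
                is_center=False,
                center_interval=None,
                distance_bp=float("nan"),
                bias=g.bias,
            )
            for g in members
        ]

    intervals = [
        (chrom, min(g.lo for g in grp), max(g.hi for g in grp)) for grp in groups
    ]
    center_ids = {g.coord.gene_id for grp in groups for g in grp}

    # sub-cluster boundaries: midpoints between adjacent center intervals,
    # max_gap flanks at the extremes
    bounds: list[tuple[float, float]] = []
    for k, (_, lo, hi) in enumerate(intervals):
        left = lo - max_gap if k == 0 else 0.5 * (intervals[k - 1][2] + lo)
        right = hi + max_gap if k == len(intervals) - 1 else 0.5 * (hi + intervals[k + 1][1])
        bounds.append((left, right))

    out: list[ClusterAssignment] = []
    for g in members:
        s = g.start_site
        # the sub-cluster whose downstream boundary lies past the start site
        k = next((i for i, (_, r) in enumerate(bounds) if s <= r), len(bounds) - 1)
        chrom_, lo, hi = intervals[k]
        dist = 0.0 if lo <= s <= hi else float(min(abs(s - lo), abs(s - hi)))
        if dist > max_gap:
            continue  # too far from any center
        sub_id = cluster_id if len(intervals) == 1 else f"{cluster_id}.{k}"
        out.append(
            ClusterAssignment(
                gene_id=g.coord.gene_id,
                cluster_id=sub_id,
                is_center=g.coord.gene_id in center_ids,
                center_interval=intervals[k],
                distance_bp=dist,
                bias=g.bias,
            )
        )
    return out


def decay_regression(
    assignments: Sequence[ClusterAssignment],
) -> tuple[float, float, float]:
    """OLS fit of parental bias on distance from the cluster center.

    Uses non-center members with finite distances, pooled across clusters.
    Returns (slope per bp, intercept, two-sided p-value on the slope).
    """
    pts = [
        (a.distance_bp, a.bias)
        for a in assignments
        if not a.is_center and np.isfinite(a.distance_bp)
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 non-center genes with finite distances")
    x, y = np.array(pts).T
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)
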