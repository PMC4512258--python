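"""Readers and writers for the on-disk tabular formats.

All tables are plain TSV: posterior draws in long (tidy) layout, the sample
design, gene coordinates as 6-column BED, and the per-transcript results.
Parsers validate invariants and reject rather than repair.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    ALLELES,
    AllelicPosterior,
    GeneCall,
    GeneCoordinate,
    HyperParams,
    SampleDesign,
)

logger = logging.getLogger("braim")

POSTERIOR_COLUMNS = ["transcript_id", "gene_id", "sample_id", "allele", "draw_index", "tpm"]
DESIGN_COLUMNS = ["sample_id", "cross", "sex", "age"]


def read_posterior_table(path: str | Path) -> list[AllelicPosterior]:
    """Read a long-format posterior draw TSV into grouped records.

    Validates that every (transcript, sample) pair carries both alleles,
    that all records share the same number of draws S, and that no draw is
    negative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str, "sample_id": str})
    missing = [c for c in POSTERIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"posterior table {path}: missing columns {missing}")
    if df.empty:
        logger.warning("posterior table %s is empty", path)
        return []
    bad_allele = set(df["allele"]) - set(ALLELES)
    if bad_allele:
        raise ValueError(f"posterior table {path}: unknown allele values {sorted(bad_allele)}")
    records: list[AllelicPosterior] = []
    s_ref: int | None = None
    for (tid, gid, sid, allele), grp in df.groupby(
        ["transcript_id", "gene_id", "sample_id", "allele"], sort=True
    ):
        draws = grp.sort_values("draw_index")["tpm"].to_numpy(dtype=float)
        if np.any(draws < 0):
            raise ValueError(f"negative TPM for transcript {tid} sample {sid}")
        if s_ref is None:
            s_ref = draws.size
        elif draws.size != s_ref:
            raise ValueError(
                f"inconsistent draw count for transcript {tid} sample {sid}: "
                f"{draws.size} != {s_ref}"
            )
        records.append(AllelicPosterior(tid, gid, sid, allele, draws))
    _check_allele_pairs(records)
    return records


def _check_allele_pairs(records: Iterable[AllelicPosterior]) -> None:
    seen: dict[tuple[str, str], set[str]] = {}
    for r in records:
        seen.setdefault((r.transcript_id, r.sample_id), set()).add(r.allele)
    for (tid, sid), alleles in seen.items():
        for allele in ALLELES:
            if allele not in alleles:
                raise ValueError(
                    f"missing {allele} allele for transcript {tid} sample {sid}"
                )


def write_posterior_table(path: str | Path, records: Sequence[AllelicPosterior]) -> None:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": r.transcript_id,
                    "gene_id": r.gene_id,
                    "sample_id": r.sample_id,
                    "allele": r.allele,
                    "draw_index": np.arange(r.draws.size),
                    "tpm": r.draws,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=POSTERIOR_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read the sample design TSV; rejects duplicate ids and unknown levels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table {path}: missing columns {missing}")
    if df.empty:
        logger.warning("design table %s is empty", path)
        return []
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id in design table: {sorted(set(dup))}")
    return [
        SampleDesign(row.sample_id, row.cross, row.sex, row.age)
        for row in df.itertuples(index=False)
    ]


def write_design(path: str | Path, designs: Sequence[SampleDesign]) -> None:
    pd.DataFrame(
        [(d.sample_id, d.cross, d.sex, d.age) for d in designs], columns=DESIGN_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GeneCoordinate]:
    """Read gene coordinates from 6-column BED (chrom start end name score strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
        comment="#",
    )
    return [
        GeneCoordinate(row.gene_id, row.chrom, int(row.start), int(row.end), row.strand)
        for row in df.itertuples(index=False)
    ]


def write_bed(path: str | Path, genes: Sequence[GeneCoordinate]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


RESULT_COLUMNS = [
    "transcript_id",
    "gene_id",
    "beta_parental_mean",
    "beta_parental_sd",
    "beta_cross_mean",
    "beta_cross_sd",
    "beta_sex_mean",
    "beta_sex_sd",
    "beta_age_mean",
    "beta_age_sd",
    "pp_parental",
    "pp_cross",
    "pp_sex",
    "pp_age",
    "paternal_fraction",
    "maternal_fraction",
    "bias",
    "imprinted",
    "age_regulated",
    "preferred_allele",
    "source_fit",
]


def write_results(path: str | Path, calls: Sequence[GeneCall], fits: dict) -> None:
    """Write one TSV row per transcript: coefficient summaries, PPs, call."""
    rows = []
    for call in calls:
        fit = fits.get(call.transcript_id)
        row: dict = {
            "transcript_id": call.transcript_id,
            "gene_id": call.gene_id,
            "paternal_fraction": call.paternal_fraction,
            "maternal_fraction": call.maternal_fraction,
            "bias": call.bias,
            "imprinted": int(call.imprinted),
            "age_regulated": int("age" in call.significant_effects),
            "preferred_allele": call.preferred_allele,
            "source_fit": call.source_fit,
        }
        for effect in ("parental", "cross", "sex", "age"):
            if fit is not None and effect in fit.column_labels:
                i = fit.effect_index(effect)
                row[f"beta_{effect}_mean"] = fit.beta_mean[i]
                row[f"beta_{effect}_sd"] = fit.beta_sd[i]
                row[f"pp_{effect}"] = fit.pp[i]
            else:
                row[f"beta_{effect}_mean"] = np.nan
                row[f"beta_{effect}_sd"] = np.nan
                row[f"pp_{effect}"] = np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> HyperParams:
    """Load hyper-parameters from a YAML config mirroring HyperParams."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in HyperParams.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    return HyperParams(**raw)
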