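"""Synthetic allele-specific posterior-draw cohorts with known truth.

The generator mirrors the model's own data-generating assumptions: each
sample's true log paternal-minus-maternal contrast is Normal around the
design effect, the two allelic log levels sit symmetrically (+-d/2) around
a base expression so bias is unconfounded with overall expression, and
each allele emits lognormal "posterior draws" whose spread emulates the
estimation uncertainty of expression-inference software.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .types import (
    AGES,
    CROSSES,
    SEXES,
    AllelicPosterior,
    GeneCall,
    SampleDesign,
    SimTranscriptSpec,
    SimTruth,
)
from .response import build_design_matrix

#: below this absolute parental effect a simulated transcript is scored
#: as not imprinted (effects used by default cohorts are >= 1)
IMPRINTED_EFFECT_MIN = 0.5


def balanced_design(n_per_block: int = 6) -> list[SampleDesign]:
    """Fully crossed cross x sex x age design, n_per_block replicates each."""
    designs = []
    i = 0
    for cross in CROSSES:
        for sex in SEXES:
            for age in AGES:
                for _ in range(n_per_block):
                    designs.append(SampleDesign(f"s{i:03d}", cross, sex, age))
                    i += 1
    return designs


def simulate_cohort(
    specs: Sequence[SimTranscriptSpec],
    designs: Sequence[SampleDesign],
    floor_c: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[list[AllelicPosterior], list[SimTruth]]:
    """Draw a full cohort of posterior records plus ground truth.

    Per transcript and sample j: d_j ~ N(x_j' beta_true, sigma2_true);
    maternal true log-TPM = base - d_j/2 and paternal = base + d_j/2; each
    allele emits s_draws values exp(logTPM + N(0, meas_sd^2)) - floor_c,
    clamped at 0, so the downstream +floor_c inside the log recentres the
    draws on the true level.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    dm = build_design_matrix(designs, factors=("cross", "sex", "age"))
    X = dm.X
    records: list[AllelicPosterior] = []
    truth: list[SimTruth] = []
    for spec in specs:
        beta = np.asarray(spec.beta_true, dtype=float)
        d = X @ beta + np.sqrt(spec.sigma2_true) * rng.standard_normal(X.shape[0])
        log_pat = spec.base_log_tpm + d / 2.0
        log_mat = spec.base_log_tpm - d / 2.0
        for j, sd in enumerate(designs):
            for allele, log_mu in (("paternal", log_pat[j]), ("maternal", log_mat[j])):
                noise = spec.meas_sd * rng.standard_normal(spec.s_draws)
                draws = np.maximum(np.exp(log_mu + noise) - floor_c, 0.0)
                records.append(
                    AllelicPosterior(spec.transcript_id, spec.gene_id, sd.sample_id, allele, draws)
                )
        truth.append(
            SimTruth(
                transcript_id=spec.transcript_id,
                gene_id=spec.gene_id,
                beta_true=tuple(beta),
                paternal_fraction_true=float(expit(beta[0])),
                is_imprinted=abs(beta[0]) >= IMPRINTED_EFFECT_MIN,
            )
        )
    return records, truth


def default_cohort_specs(
    n_transcripts: int = 500,
    n_imprinted: int = 50,
    effect_min: float = 1.0,
    effect_max: float = 3.0,
    sigma2_true: float = 0.25,
    meas_sd: float = 0.1,
    s_draws: int = 100,
    base_log_tpm_mean: float = 2.0,
    base_log_tpm_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[SimTranscriptSpec]:
    """Cohort specs for recovery studies: n_imprinted transcripts with
    |parental effect| >= effect_min (alternating sign), the rest null."""
    if rng is None:
        rng = np.random.default_rng(0)
    specs = []
    for i in range(n_transcripts):
        imprinted = i < n_imprinted
        if imprinted:
            mag = rng.uniform(effect_min, effect_max)
            b_par = mag if i % 2 == 0 else -mag
        else:
            b_par = 0.0
        specs.append(
            SimTranscriptSpec(
                transcript_id=f"tx{i:04d}",
                gene_id=f"g{i:04d}",
                base_log_tpm=float(rng.normal(base_log_tpm_mean, base_log_tpm_sd)),
                beta_true=(b_par, 0.0, 0.0, 0.0),
                sigma2_true=sigma2_true,
                meas_sd=meas_sd,
                s_draws=s_draws,
            )
        )
    return specs


def simulate_anticorrelated_pair(
    gene_id: str,
    designs: Sequence[SampleDesign],
    base_log_tpm: float = 2.0,
    s_draws: int = 100,
    rng: np.random.Generator | None = None,
) -> list[AllelicPosterior]:
    """Two same-gene isoforms sharing reads: per draw a random share of a
    roughly constant total goes to each, producing the strong posterior
    anti-correlation the combiner targets."""
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    for sd in designs:
        for allele in ("paternal", "maternal"):
            total = np.exp(base_log_tpm + 0.02 * rng.standard_normal(s_draws))
            share = rng.beta(2.0, 2.0, size=s_draws)
            for tid, draws in ((f"{gene_id}_iso1", total * share), (f"{gene_id}_iso2", total * (1 - share))):
                records.append(AllelicPosterior(tid, gene_id, sd.sample_id, allele, draws))
    return records


@dataclass
class RecoveryReport:
    """Confusion summary of calls against simulated truth."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fraction_mae: float  # mean abs error of paternal fraction, true imprinted only

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def recovery_report(calls: Sequence[GeneCall], truth: Sequence[SimTruth]) -> RecoveryReport:
    """Score imprinting calls against ground truth by transcript id."""
    truth_by_id = {t.transcript_id: t for t in truth}
    missing = [c.transcript_id for c in calls if c.transcript_id not in truth_by_id]
    if missing:
        raise ValueError(f"calls without matching truth: {missing[:5]}")
    tp = fp = tn = fn = 0
    errs = []
    for c in calls:
        t = truth_by_id[c.transcript_id]
        if t.is_imprinted:
            if c.imprinted:
                tp += 1
            else:
                fn += 1
            errs.append(abs(c.paternal_fraction - t.paternal_fraction_true))
        else:
            if c.imprinted:
                fp += 1
            else:
                tn += 1
    return RecoveryReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        fraction_mae=float(np.mean(errs)) if errs else float("nan"),
    )
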