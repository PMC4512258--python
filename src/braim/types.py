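"""Core domain types shared across the pipeline.

The pipeline operates on per-sample, per-allele posterior expression draws
(MMSEQ-style Monte-Carlo samples of TPM), a factorial sample design
(reciprocal cross x sex x age), and the fitted per-transcript posteriors of
the allelic-imbalance regression.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CROSSES = ("F1i", "F1r")
SEXES = ("M", "F")
AGES = ("P8", "P60")
#: factor order of the full design matrix; column 0 is the intercept
#: (the parental effect), the rest are ±1-coded binary factors.
FACTORS = ("parental", "cross", "sex", "age")

ALLELES = ("paternal", "maternal")


@dataclass
class AllelicPosterior:
    """Posterior expression draws for one (transcript, sample, allele).

    ``draws`` holds the S Monte-Carlo samples of the expression level in
    TPM units; S must be >= 2 so a posterior variance is defined.
    """

    transcript_id: str
    gene_id: str
    sample_id: str
    allele: str
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.allele not in ALLELES:
            raise ValueError(
                f"unknown allele {self.allele!r} for transcript "
                f"{self.transcript_id} sample {self.sample_id}"
            )
        if self.draws.ndim != 1 or self.draws.size < 2:
            raise ValueError(
                f"transcript {self.transcript_id} sample {self.sample_id}: "
                "need at least 2 posterior draws"
            )
        if np.any(self.draws < 0):
            raise ValueError(
                f"negative TPM draw for transcript {self.transcript_id} "
                f"sample {self.sample_id}"
            )

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)


@dataclass(frozen=True)
class SampleDesign:
    """One sample's position in the cross x sex x age factorial design."""

    sample_id: str
    cross: str
    sex: str
    age: str

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise ValueError(f"sample {self.sample_id}: unknown cross {self.cross!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id}: unknown sex {self.sex!r}")
        if self.age not in AGES:
            raise ValueError(f"sample {self.sample_id}: unknown age {self.age!r}")


@dataclass
class DesignMatrix:
    """±1-coded design matrix with an all-ones intercept column.

    The intercept carries the parental effect (the response is already the
    paternal-minus-maternal contrast); the remaining columns are coded +1
    for F1i / male / P8 and -1 for F1r / female / P60.
    """

    X: np.ndarray
    column_labels: tuple[str, ...]
    sample_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class HyperParams:
    """Hyper-parameters of the spike-and-slab measurement-error regression.

    tau scales the spike (null) normal of each coefficient; c_mult is the
    slab multiplier; nu and lam parameterise the inverse-gamma prior
    IG(nu/2, nu*lam/2) on the biological variance; prior_p is the prior
    inclusion probability of each effect.  lam=None computes the default
    from the unit variance of the scaled response.
    """

    tau: float = 0.1
    c_mult: float = 4.25
    nu: float = 2.5
    lam: float | None = None
    prior_p: float = 0.1
    n_iter: int = 10_000
    burn_in: int = 1_000
    pp_cutoff: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.c_mult < 1:
            raise ValueError("c_mult must be >= 1")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2")
        if self.lam is None:
            from .gibbs import default_lambda

            self.lam = default_lambda(self.nu, 1.0)
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.prior_p < 1:
            raise ValueError("prior_p must lie in (0, 1)")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if not 0 < self.pp_cutoff < 1:
            raise ValueError("pp_cutoff must lie in (0, 1)")

    def replace(self, **kwargs) -> "HyperParams":
        from dataclasses import asdict

        d = asdict(self)
        d.update(kwargs)
        return HyperParams(**d)


@dataclass(frozen=True)
class GeneCoordinate:
    """Gene interval, 0-based half-open (BED convention)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: `start` on +, `end` on - strand."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ResponseSet:
    """Scaled per-transcript response with measurement-error variances.

    ``y_scaled`` is the per-sample posterior-mean log-expression contrast
    divided by its across-sample standard deviation; ``err_var_scaled`` are
    the per-sample posterior variances on the same scale; ``scale_sd``
    converts fitted coefficients back to the unscaled log scale.
    """

    transcript_id: str
    y_scaled: np.ndarray
    err_var_scaled: np.ndarray
    scale_sd: float
    mode: str = "diff"
    floor_c: float = 0.01
    gene_id: str = ""

    @property
    def n(self) -> int:
        return int(self.y_scaled.size)


@dataclass
class BraimFit:
    """Posterior draws and summaries of one transcript's fit."""

    transcript_id: str
    pp: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    sigma2_mean: float
    scale_sd: float
    column_labels: tuple[str, ...]
    post_beta: np.ndarray | None = None
    post_sigma2: np.ndarray | None = None
    post_delta: np.ndarray | None = None
    gene_id: str = ""

    def effect_index(self, effect: str) -> int:
        return self.column_labels.index(effect)

    def effect_pp(self, effect: str) -> float:
        return float(self.pp[self.effect_index(effect)])

    @property
    def beta_parental_unscaled(self) -> float:
        """Parental coefficient mapped back to the unscaled log response."""
        return float(self.beta_mean[self.effect_index("parental")] * self.scale_sd)


@dataclass
class GeneCall:
    """Imprinting verdict for one transcript."""

    transcript_id: str
    gene_id: str
    imprinted: bool
    preferred_allele: str  # paternal | maternal | none
    paternal_fraction: float
    maternal_fraction: float
    bias: float
    significant_effects: tuple[str, ...]
    source_fit: str  # combined | P8_only | P60_only


@dataclass
class ClusterAssignment:
    """Membership of one gene in an imprinted genomic (sub-)cluster."""

    gene_id: str
    cluster_id: str
    is_center: bool
    center_interval: tuple[str, int, int] | None
    distance_bp: float
    bias: float


@dataclass(frozen=True)
class SimTranscriptSpec:
    """Generative parameters of one simulated transcript.

    ``beta_true`` holds the true (parental, cross, sex, age) effects on the
    log paternal-minus-maternal scale; ``sigma2_true`` is the biological
    variance of that contrast across animals; ``meas_sd`` the per-draw
    log-scale measurement noise emulating posterior spread.
    """

    transcript_id: str
    gene_id: str
    base_log_tpm: float
    beta_true: tuple[float, float, float, float]
    sigma2_true: float
    meas_sd: float
    s_draws: int = 100

    def __post_init__(self) -> None:
        if self.sigma2_true < 0 or self.meas_sd < 0:
            raise ValueError("variances must be nonnegative")
        if self.s_draws < 2:
            raise ValueError("need at least 2 draws per sample")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth used to score recovery on simulated cohorts."""

    transcript_id: str
    gene_id: str
    beta_true: tuple[float, float, float, float]
    paternal_fraction_true: float
    is_imprinted: bool


@dataclass
class CombineDecision:
    """Record of one merge of anti-correlated same-gene transcripts."""

    members: frozenset[str]
    combined_id: str
    mean_r_paternal: float
    mean_r_maternal: float


@dataclass
class PerturbationResult:
    """AUC of one hyper-parameter perturbation against unperturbed calls."""

    parameter: str
    value: float
    auc: float
    n_transcripts: int
    evaluable: bool = True
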