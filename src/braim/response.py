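"""Build the scaled regression response from allele-specific posterior draws.

For each transcript the per-sample response is the posterior mean of the
log paternal-minus-maternal expression contrast (mode="diff"); the
posterior variance of the same contrast is carried forward as a known
per-sample measurement-error variance.  Alternate response modes use a
single allele or the allele sum instead of the contrast.  The response is
divided by its across-sample standard deviation so that coefficients share
a common scale across transcripts.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import (
    AllelicPosterior,
    DesignMatrix,
    ResponseSet,
    SampleDesign,
    FACTORS,
)

logger = logging.getLogger("braim")

MODES = ("diff", "paternal", "maternal", "overall")

#: floored transcripts have exactly-zero posterior variance; a tiny floor
#: keeps the measurement-error covariance invertible in the sampler
ERR_VAR_FLOOR = 1e-8


def floor_expression(draws: np.ndarray, c: float = 0.01) -> np.ndarray:
    """Apply the minimum-expression floor to one sample's draws.

    If the posterior median is below the floor ``c`` the whole draw vector
    is replaced by the constant ``c`` (the minimal measurable expression);
    otherwise draws pass through unchanged.
    """
    if c <= 0:
        raise ValueError("floor must be positive")
    draws = np.asarray(draws, dtype=float)
    if np.median(draws) < c:
        return np.full_like(draws, c)
    return draws


def build_response(
    pat: Mapping[str, np.ndarray],
    mat: Mapping[str, np.ndarray],
    sample_order: Sequence[str],
    mode: str = "diff",
    c: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample posterior mean and variance of the chosen log response.

    ``pat``/``mat`` map sample_id -> floored TPM draw vector.  mode="diff"
    uses log(pat+c) - log(mat+c) per draw; "paternal"/"maternal" the single
    allele's log(tpm+c); "overall" log(pat+mat+c).
    """
    if mode not in MODES:
        raise ValueError(f"unknown response mode {mode!r}")
    n = len(sample_order)
    y_hat = np.empty(n)
    err_var = np.empty(n)
    for j, sid in enumerate(sample_order):
        p_draws = np.asarray(pat[sid], dtype=float)
        m_draws = np.asarray(mat[sid], dtype=float)
        if p_draws.size < 2 or m_draws.size < 2:
            raise ValueError(f"sample {sid}: need S >= 2 draws for an error variance")
        if mode == "diff":
            per_draw = np.log(p_draws + c) - np.log(m_draws + c)
        elif mode == "paternal":
            per_draw = np.log(p_draws + c)
        elif mode == "maternal":
            per_draw = np.log(m_draws + c)
        else:  # overall
            per_draw = np.log(p_draws + m_draws + c)
        y_hat[j] = per_draw.mean()
        err_var[j] = per_draw.var(ddof=1)
    return y_hat, err_var


def scale_response(
    transcript_id: str,
    y_hat: np.ndarray,
    err_var: np.ndarray,
    mode: str = "diff",
    c: float = 0.01,
    gene_id: str = "",
) -> ResponseSet | None:
    """Divide the response by its across-sample sd; returns None if sd == 0.

    Measurement-error variances are divided by the squared scale factor so
    the observation model stays consistent on the scaled response.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    err_var = np.asarray(err_var, dtype=float)
    if y_hat.size < 2:
        raise ValueError("need at least 2 samples to scale a response")
    sd = float(np.std(y_hat, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        logger.warning("transcript %s: constant response, skipped as un-fittable", transcript_id)
        return None
    return ResponseSet(
        transcript_id=transcript_id,
        y_scaled=y_hat / sd,
        err_var_scaled=np.maximum(err_var / sd**2, ERR_VAR_FLOOR),
        scale_sd=sd,
        mode=mode,
        floor_c=c,
        gene_id=gene_id,
    )


def build_design_matrix(
    designs: Sequence[SampleDesign],
    factors: Sequence[str] = ("cross", "sex", "age"),
) -> DesignMatrix:
    """±1-coded design: +1 for F1i, males and P8; -1 for F1r, females, P60."""
    if not designs:
        raise ValueError("empty design")
    for f in factors:
        if f not in FACTORS[1:]:
            raise ValueError(f"unknown factor {f!r}")
    coding = {
        "cross": lambda d: 1.0 if d.cross == "F1i" else -1.0,
        "sex": lambda d: 1.0 if d.sex == "M" else -1.0,
        "age": lambda d: 1.0 if d.age == "P8" else -1.0,
    }
    cols = [np.ones(len(designs))]
    labels = ["parental"]
    for f in factors:
        col = np.array([coding[f](d) for d in designs])
        if len(np.unique(col)) < 2:
            raise ValueError(f"factor {f!r} has a single observed level")
        cols.append(col)
        labels.append(f)
    return DesignMatrix(
        X=np.column_stack(cols),
        column_labels=tuple(labels),
        sample_ids=tuple(d.sample_id for d in designs),
    )


def group_by_transcript(
    records: Iterable[AllelicPosterior],
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """transcript_id -> allele -> sample_id -> draws, plus gene ids."""
    grouped: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for r in records:
        grouped.setdefault(r.transcript_id, {"paternal": {}, "maternal": {}, "_gene": r.gene_id})[
            r.allele
        ][r.sample_id] = r.draws
    return grouped


def build_responses(
    records: Iterable[AllelicPosterior],
    designs: Sequence[SampleDesign],
    mode: str = "diff",
    c: float = 0.01,
    stringent_log_tpm: float | None = None,
) -> dict[str, ResponseSet]:
    """Floor, contrast and scale every transcript's response.

    ``stringent_log_tpm`` optionally drops transcripts whose mean
    ln(TPM) over samples, alleles and draws falls below the cutoff
    (e.g. -1.6); off by default.  Un-fittable (constant-response)
    transcripts are skipped with a warning.
    """
    grouped = group_by_transcript(records)
    sample_order = [d.sample_id for d in designs]
    out: dict[str, ResponseSet] = {}
    for tid, alleles in grouped.items():
        pat = {sid: floor_expression(d, c) for sid, d in alleles["paternal"].items()}
        mat = {sid: floor_expression(d, c) for sid, d in alleles["maternal"].items()}
        missing = [s for s in sample_order if s not in pat or s not in mat]
        if missing:
            raise ValueError(f"transcript {tid}: no posterior draws for samples {missing}")
        if stringent_log_tpm is not None:
            mean_log = np.mean(
                [np.log(np.concatenate([pat[s], mat[s]]) + c).mean() for s in sample_order]
            )
            if mean_log < stringent_log_tpm:
                logger.info("transcript %s below stringent expression cutoff, dropped", tid)
                continue
        y_hat, err_var = build_response(pat, mat, sample_order, mode=mode, c=c)
        rs = scale_response(tid, y_hat, err_var, mode=mode, c=c, gene_id=alleles["_gene"])
        if rs is not None:
            out[tid] = rs
    return out


def expressed_in_age(
    alleles: Mapping[str, Mapping[str, np.ndarray]],
    designs: Sequence[SampleDesign],
    age: str,
    c: float = 0.01,
) -> bool:
    """True if any sample of the given age has posterior median TPM >= c
    on either allele (i.e. the transcript is not entirely floored there)."""
    for d in designs:
        if d.age != age:
            continue
        for allele in ("paternal", "maternal"):
            draws = alleles[allele].get(d.sample_id)
            if draws is not None and np.median(draws) >= c:
                return True
    return False
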