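"""Top-level fit workflow: combined-ages plus per-age model fits.

The combined fit (factors cross, sex, age) detects imprinting across the
whole cohort; independent P8-only and P60-only fits (factors cross, sex)
catch transcripts whose parental bias is confined to one age.  Optional
single-allele refits classify which parental allele drives an age effect.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import call_imprinting
from .gibbs import run_gibbs, transcript_rng
from .response import (
    build_design_matrix,
    build_responses,
    expressed_in_age,
    group_by_transcript,
)
from .types import AllelicPosterior, BraimFit, GeneCall, HyperParams, ResponseSet, SampleDesign

logger = logging.getLogger("braim")

__version__ = "0.1.0"


def fit_cohort(
    responses: Mapping[str, ResponseSet],
    X: np.ndarray,
    hyper: HyperParams,
    column_labels: tuple[str, ...] = ("parental", "cross", "sex", "age"),
    keep_draws: bool = False,
) -> dict[str, BraimFit]:
    """Fit every transcript with its own order-invariant RNG stream."""
    fits: dict[str, BraimFit] = {}
    for i, tid in enumerate(sorted(responses)):
        fits[tid] = run_gibbs(
            responses[tid],
            X,
            hyper,
            rng=transcript_rng(hyper.seed, tid),
            keep_draws=keep_draws,
            column_labels=column_labels,
        )
        if (i + 1) % 100 == 0:
            logger.info("fitted %d/%d transcripts", i + 1, len(responses))
    return fits


def run_fit_workflow(
    records: Sequence[AllelicPosterior],
    designs: Sequence[SampleDesign],
    hyper: HyperParams,
    mode: str = "diff",
    per_age: bool = True,
    allele_mode_fits: bool = False,
    floor_c: float = 0.01,
    input_paths: Sequence[str | Path] = (),
) -> tuple[list[GeneCall], dict[str, BraimFit], dict]:
    """Fit combined and per-age models and apply the calling rules.

    Returns the per-transcript calls, the combined fits, and a run
    manifest (config snapshot, input digests, seed, timings).  When
    ``allele_mode_fits`` is set, paternal-only and maternal-only responses
    are also fitted and each transcript annotated with which allele shows
    a significant age effect.
    """
    t0 = time.time()
    timings: dict[str, float] = {}

    grouped = group_by_transcript(records)
    designs_by_age = {
        age: [d for d in designs if d.age == age] for age in ("P8", "P60")
    }

    responses = build_responses(records, designs, mode=mode, c=floor_c)
    factors = tuple(
        f
        for f in ("cross", "sex", "age")
        if len({getattr(d, f) for d in designs}) > 1
    )
    X_combined = build_design_matrix(designs, factors=factors)
    fits_combined = fit_cohort(responses, X_combined.X, hyper, X_combined.column_labels)
    timings["combined_fit"] = time.time() - t0

    ages_present = [age for age in ("P8", "P60") if designs_by_age[age]]
    fits_age: dict[str, dict[str, BraimFit]] = {"P8": {}, "P60": {}}
    if per_age and len(ages_present) > 1:
        for age, age_designs in designs_by_age.items():
            t1 = time.time()
            age_records = _subset_records(records, {d.sample_id for d in age_designs})
            age_responses = build_responses(age_records, age_designs, mode=mode, c=floor_c)
            X_age = build_design_matrix(age_designs, factors=("cross", "sex"))
            fits_age[age] = fit_cohort(
                age_responses, X_age.X, hyper, X_age.column_labels
            )
            timings[f"{age}_fit"] = time.time() - t1

    calls: list[GeneCall] = []
    all_tids = sorted(set(fits_combined) | set(fits_age["P8"]) | set(fits_age["P60"]))
    for tid in all_tids:
        alleles = grouped[tid]
        expr = {
            age: expressed_in_age(alleles, designs, age, c=floor_c)
            for age in ("P8", "P60")
        }
        exclusive = None
        if len(ages_present) > 1 and expr["P8"] != expr["P60"]:
            exclusive = "P8" if expr["P8"] else "P60"
        calls.append(
            call_imprinting(
                # the combined model presumes expression at both ages; an
                # exclusively-expressed transcript is judged by its age fit
                fit_combined=None if exclusive else fits_combined.get(tid),
                fit_P8=fits_age["P8"].get(tid),
                fit_P60=fits_age["P60"].get(tid),
                cutoff=hyper.pp_cutoff,
                exclusive_age=exclusive,
            )
        )

    manifest = {
        "version": __version__,
        "seed": hyper.seed,
        "mode": mode,
        "hyperparams": {
            k: getattr(hyper, k)
            for k in ("tau", "c_mult", "nu", "lam", "prior_p", "n_iter", "burn_in", "pp_cutoff")
        },
        "n_samples": len(designs),
        "n_transcripts": len(all_tids),
        "input_digests": {str(p): _sha256(p) for p in input_paths},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }

    if allele_mode_fits:
        manifest["age_regulation"] = classify_age_regulation(
            records, designs, hyper, calls, floor_c=floor_c
        )
    return calls, fits_combined, manifest


def classify_age_regulation(
    records: Sequence[AllelicPosterior],
    designs: Sequence[SampleDesign],
    hyper: HyperParams,
    calls: Iterable[GeneCall],
    floor_c: float = 0.01,
) -> dict[str, str]:
    """Which allele of each imprinted transcript is age-regulated.

    Refits the model with the response set to each single allele's log
    level; an allele is age-regulated when its fit has age PP above the
    cutoff.  Returns transcript_id -> one of 'preferred', 'non_preferred',
    'both', 'none'.
    """
    X = build_design_matrix(designs, factors=("cross", "sex", "age"))
    out: dict[str, str] = {}
    allele_fits: dict[str, dict[str, BraimFit]] = {}
    for allele_mode in ("paternal", "maternal"):
        responses = build_responses(records, designs, mode=allele_mode, c=floor_c)
        allele_fits[allele_mode] = fit_cohort(responses, X.X, hyper, X.column_labels)
    for call in calls:
        if not call.imprinted:
            continue
        regulated = {
            allele: (
                tid_fit := allele_fits[allele].get(call.transcript_id)
            )
            is not None
            and tid_fit.effect_pp("age") > hyper.pp_cutoff
            for allele in ("paternal", "maternal")
        }
        pref = call.preferred_allele
        non_pref = "maternal" if pref == "paternal" else "paternal"
        if regulated[pref] and regulated[non_pref]:
            out[call.transcript_id] = "both"
        elif regulated[pref]:
            out[call.transcript_id] = "preferred"
        elif regulated[non_pref]:
            out[call.transcript_id] = "non_preferred"
        else:
            out[call.transcript_id] = "none"
    return out


def _subset_records(
    records: Sequence[AllelicPosterior], sample_ids: set[str]
) -> list[AllelicPosterior]:
    return [r for r in records if r.sample_id in sample_ids]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Write the manifest atomically next to the results."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)
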