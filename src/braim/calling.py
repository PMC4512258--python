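"""Turn fitted posteriors into imprinting calls.

An effect is significant when its posterior inclusion probability exceeds
the cutoff (0.95 by default).  The parental coefficient, mapped back to
the unscaled log response, converts to paternal/maternal expression
fractions through the logistic function; the parental bias is the larger
fraction.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

from .types import BraimFit, GeneCall


def posterior_probability(delta_draws: np.ndarray) -> float:
    """Mean of the retained inclusion-indicator draws."""
    delta_draws = np.asarray(delta_draws)
    if delta_draws.size == 0:
        raise ValueError("no retained draws")
    return float(delta_draws.mean())


def parental_fractions(beta_parental_unscaled: float) -> tuple[float, float]:
    """Paternal and maternal median expression fractions.

    The parental coefficient is the mean log paternal/maternal ratio, so
    exp(beta)/(1+exp(beta)) is the paternal share of total expression.
    """
    pf = float(expit(beta_parental_unscaled))
    return pf, 1.0 - pf


def preferred_bias(fractions: tuple[float, float]) -> float:
    """Expression fraction of the preferred (more expressed) allele."""
    return max(fractions)


def call_imprinting(
    fit_combined: BraimFit | None = None,
    fit_P8: BraimFit | None = None,
    fit_P60: BraimFit | None = None,
    cutoff: float = 0.95,
    exclusive_age: str | None = None,
) -> GeneCall:
    """Apply the combined/per-age imprinting rules to one transcript.

    A transcript is imprinted when:
      (i)   parental PP > cutoff in the combined fit; or
      (ii)  it is expressed exclusively in one age group
            (``exclusive_age``) and that group's fit has parental
            PP > cutoff; or
      (iii) age PP > cutoff in the combined fit and parental PP > cutoff
            in either single-age fit.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    if fit_combined is None and fit_P8 is None and fit_P60 is None:
        raise ValueError("at least one fit is required")

    age_fits = {"P8": fit_P8, "P60": fit_P60}
    imprinted = False
    source = "combined"

    if fit_combined is not None and fit_combined.effect_pp("parental") > cutoff:
        imprinted = True
    elif exclusive_age is not None:
        f = age_fits.get(exclusive_age)
        if f is not None and f.effect_pp("parental") > cutoff:
            imprinted = True
            source = f"{exclusive_age}_only"
    if (
        not imprinted
        and fit_combined is not None
        and "age" in fit_combined.column_labels
        and fit_combined.effect_pp("age") > cutoff
    ):
        for age, f in age_fits.items():
            if f is not None and f.effect_pp("parental") > cutoff:
                imprinted = True
                source = f"{age}_only"
                break

    # report fractions from the fit that drove the call (combined preferred)
    if source == "combined" and fit_combined is not None:
        ref = fit_combined
    elif source.endswith("_only"):
        ref = age_fits[source[: -len("_only")]]
    else:
        ref = fit_combined or fit_P8 or fit_P60

    beta_hat = ref.beta_parental_unscaled
    pf, mf = parental_fractions(beta_hat)
    bias = preferred_bias((pf, mf))
    if imprinted:
        preferred = "paternal" if beta_hat > 0 else "maternal"
    else:
        preferred = "none"

    significant = tuple(
        eff
        for eff in ("parental", "cross", "sex", "age")
        if fit_combined is not None
        and eff in fit_combined.column_labels
        and fit_combined.effect_pp(eff) > cutoff
    )
    return GeneCall(
        transcript_id=ref.transcript_id,
        gene_id=ref.gene_id,
        imprinted=imprinted,
        preferred_allele=preferred,
        paternal_fraction=pf,
        maternal_fraction=mf,
        bias=bias,
        significant_effects=significant,
        source_fit=source if imprinted else "combined" if fit_combined else source,
    )
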