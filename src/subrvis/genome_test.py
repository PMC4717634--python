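"""Genome-wide localization test.

Across all sub-regions of a division (restricted to genes that carry at
least one reported pathogenic variant), let ``Y_i`` indicate the presence
of a pathogenic variant in sub-region ``i``, ``Z_i`` its mutation rate and
``X_i`` its intolerance score scaled to unit standard deviation. The model

    logit Pr(Y_i = 1) = alpha + beta1 * log(Z_i) + beta2 * X_i

is fitted by maximum likelihood; ``beta2`` is the score effect size (per
standard deviation of the score), with a Wald p-value. Supporting
machinery:

* a mutability-weighted resampling null — the ones of ``Y`` are reassigned
  by weighted sampling without replacement with probabilities Z / sum(Z),
  preserving the number of ones, and the observed model p-value is ranked
  against the null p-values: p = (R - C + 1) / (R + 1) with C the number
  of null p-values strictly larger than the observed one;
* relative AIC probabilities, p = exp((AIC_min - AIC_max) / 2);
* the biological-vs-shuffled-division permutation p-value,
  p = (n_p - X + 1) / (n_p + 1) with X the number of shuffled-division
  effect sizes smaller in absolute value than the biological one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "GenomeTestInput",
    "GenomeFit",
    "scale_scores",
    "fit_region_model",
    "resample_response",
    "resampling_pvalue",
    "aic_probability",
    "division_permutation_test",
    "genome_resampling_test",
]


@dataclass(frozen=True)
class GenomeTestInput:
    Y: np.ndarray  # binary presence vector
    Z: np.ndarray  # mutation rates, all > 0
    scores: Mapping[str, np.ndarray]  # score name -> raw score vector

    def __post_init__(self) -> None:
        n = len(self.Y)
        if n < 10:
            raise ValueError("need at least 10 regions")
        if len(self.Z) != n or any(len(x) != n for x in self.scores.values()):
            raise ValueError("length mismatch")
        if np.any(np.asarray(self.Z) <= 0):
            raise ValueError("mutation rates must be positive")


@dataclass(frozen=True)
class GenomeFit:
    """Logistic fit summary; score effect sizes are per score SD."""

    alpha: float
    beta1: float
    beta2: dict[str, float]
    p_values: dict[str, float]
    alpha_p: float
    beta1_p: float
    aic: float
    log_likelihood: float
    n_regions: int
    std_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    extras: dict = field(default_factory=dict)


def scale_scores(x: np.ndarray) -> np.ndarray:
    """Divide a score vector by its (population) standard deviation so the
    fitted effect size reads per-SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance score vector")
    return x / sd


def fit_region_model(inp: GenomeTestInput, scale: bool = True) -> GenomeFit:
    """Maximum-likelihood logistic regression of pathogenic presence on
    log mutation rate and one or more (SD-scaled) score vectors.

    Raises on a degenerate response (all zeros or all ones), a
    zero-variance score, or perfect separation.
    """
    Y = np.asarray(inp.Y, dtype=float)
    if Y.min() == Y.max():
        raise ValueError("degenerate response: Y has no variation")
    cols = [np.log(np.asarray(inp.Z, dtype=float))]
    names = ["log_Z"]
    for name, x in inp.scores.items():
        cols.append(scale_scores(x) if scale else np.asarray(x, dtype=float))
        names.append(name)
    exog = sm.add_constant(np.column_stack(cols))
    try:
        fit = sm.Logit(Y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (possible separation)")
    params = fit.params
    pvals = fit.pvalues
    bse = fit.bse
    score_names = names[1:]
    return GenomeFit(
        alpha=float(params[0]),
        beta1=float(params[1]),
        beta2={nm: float(params[2 + i]) for i, nm in enumerate(score_names)},
        p_values={nm: float(pvals[2 + i]) for i, nm in enumerate(score_names)},
        alpha_p=float(pvals[0]),
        beta1_p=float(pvals[1]),
        aic=float(fit.aic),
        log_likelihood=float(fit.llf),
        n_regions=len(Y),
        std_errors={nm: float(bse[i]) for i, nm in enumerate(["alpha", "log_Z"] + score_names)},
    )


def resample_response(
    Y: np.ndarray,
    Z: np.ndarray,
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Mutability-weighted null responses.

    Each resample redistributes the ones of ``Y`` by weighted sampling
    without replacement with probabilities Z / sum(Z) (successive draws
    with renormalised remaining weights), so more mutable regions are more
    likely to receive a one and every resample keeps sum(Y*) = sum(Y).

    Returns an (n_resamples, n) 0/1 array.
    """
    Y = np.asarray(Y)
    Z = np.asarray(Z, dtype=float)
    m = int(Y.sum())
    if m == 0:
        raise ValueError("response has no ones to redistribute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(Y)
    w = Z / Z.sum()
    out = np.zeros((n_resamples, n), dtype=np.int8)
    for r in range(n_resamples):
        chosen = rng.choice(n, size=m, replace=False, p=w)
        out[r, chosen] = 1
    return out


def resampling_pvalue(observed_p: float, null_ps: Sequence[float]) -> float:
    """Rank-based resampling p-value: with C the number of null p-values
    strictly larger than the observed one, p = (R - C + 1) / (R + 1)."""
    null_ps = np.asarray(null_ps, dtype=float)
    R = len(null_ps)
    C = int(np.count_nonzero(null_ps > observed_p))
    return (R - C + 1) / (R + 1)


def aic_probability(
    aic_a: float,
    aic_b: float,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[str, float]:
    """Relative AIC probability that the larger-AIC model minimizes
    information loss: p = exp((AIC_min - AIC_max) / 2).

    Returns (label of the lower-AIC model, p).
    """
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ValueError("AIC values must be finite")
    if aic_a <= aic_b:
        minimal, p = label_a, float(np.exp((aic_a - aic_b) / 2.0))
    else:
        minimal, p = label_b, float(np.exp((aic_b - aic_a) / 2.0))
    return minimal, p


def division_permutation_test(
    biological_beta2: float,
    permuted_beta2s: Sequence[float],
) -> float:
    """p-value for the biological division carrying more information than
    size-matched random divisions: with X the number of shuffled-division
    effect sizes strictly smaller in absolute value than the biological
    one, p = (n_p - X + 1) / (n_p + 1)."""
    permuted = np.asarray(permuted_beta2s, dtype=float)
    n_p = len(permuted)
    X = int(np.count_nonzero(np.abs(permuted) < abs(biological_beta2)))
    return (n_p - X + 1) / (n_p + 1)


def genome_resampling_test(
    inp: GenomeTestInput,
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[GenomeFit, dict[str, float], np.ndarray]:
    """Observed fit plus the weighted-resampling null assessment.

    Refits the same model against each resampled response and returns the
    observed fit, the per-score resampling p-values, and the (R, k) matrix
    of null Wald p-values (one column per score, in input order). Null
    refits that fail (e.g. separation on an unlucky draw) contribute a
    p-value of 1, the conservative choice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = fit_region_model(inp)
    null_Y = resample_response(inp.Y, inp.Z, n_resamples, rng)
    names = list(inp.scores.keys())
    null_ps = np.ones((n_resamples, len(names)))
    for r in range(n_resamples):
        try:
            fit = fit_region_model(GenomeTestInput(null_Y[r], inp.Z, inp.scores))
        except ValueError:
            continue
        for j, nm in enumerate(names):
            null_ps[r, j] = fit.p_values[nm]
    resampling = {
        nm: resampling_pvalue(observed.p_values[nm], null_ps[:, j])
        for j, nm in enumerate(names)
    }
    return observed, resampling, null_ps
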