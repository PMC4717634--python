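"""Gene-specific localization test.

For one gene with ``n`` sub-regions, let ``Y`` be the pathogenic counts
per sub-region, ``Z`` the sub-region mutation rates, and ``X`` the
intolerance scores. The expected placement under mutability alone is

    E_i = (sum Y) * Z_i / (sum Z),

and the test statistic is the sample covariance

    C = cov(Y - E, X),

negative when pathogenic excess concentrates in low (intolerant) scores.
Significance comes from a multinomial permutation null: counts are redrawn
as Multinomial(sum Y, Z / sum Z), and with G the number of permuted
statistics less than or equal to the observed one (inclusive), the
p-value is (G + 1) / (n_p + 1). Genes with fewer than two regions or no
pathogenic variant are skipped, and p-values across genes are adjusted by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneTestInput",
    "GeneTestResult",
    "expected_counts",
    "departure_covariance",
    "gene_permutation_test",
    "fdr_adjust",
    "run_gene_tests",
    "gene_substream",
]


@dataclass(frozen=True)
class GeneTestInput:
    gene_id: str
    Y: np.ndarray  # pathogenic counts per sub-region
    Z: np.ndarray  # mutation rates, all > 0
    X: np.ndarray  # intolerance scores


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    n_regions: int
    C: float
    p_value: float
    n_permutations: int
    fdr_p: float | None = None
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


def expected_counts(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Expected pathogenic counts per sub-region under mutability alone:
    the gene's total spread proportionally to the mutation rates."""
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    total_rate = Z.sum()
    if total_rate <= 0:
        raise ValueError("mutation rates sum to zero")
    return Y.sum() * Z / total_rate


def departure_covariance(Y: np.ndarray, E: np.ndarray, X: np.ndarray) -> float:
    """Sample covariance (n-1 denominator) of the departure Y - E with the
    score vector X."""
    D = np.asarray(Y, dtype=float) - np.asarray(E, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(D) < 2:
        raise ValueError("covariance needs at least two regions")
    return float(np.cov(D, X, ddof=1)[0, 1])


def _validate(inp: GeneTestInput) -> str | None:
    n = len(inp.Y)
    if not (len(inp.Z) == len(inp.X) == n):
        return "length mismatch"
    if n < 2:
        return "fewer than two regions"
    if inp.Y.sum() < 1:
        return "no reported pathogenic variant"
    if np.any(np.asarray(inp.Z) <= 0):
        return "non-positive mutation rate"
    if not np.all(np.isfinite(np.asarray(inp.X, dtype=float))):
        return "missing score"
    return None


def gene_permutation_test(
    inp: GeneTestInput,
    n_permutations: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> GeneTestResult:
    """Multinomial permutation test of pathogenic-variant localization for
    one gene. Invalid inputs yield a structured skip record, not an error.
    """
    reason = _validate(inp)
    if reason is not None:
        return GeneTestResult(
            gene_id=inp.gene_id,
            n_regions=len(inp.Y),
            C=np.nan,
            p_value=np.nan,
            n_permutations=n_permutations,
            skip_reason=reason,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(inp.Y, dtype=float)
    Z = np.asarray(inp.Z, dtype=float)
    X = np.asarray(inp.X, dtype=float)
    n = len(Y)
    p = Z / Z.sum()
    E = expected_counts(Y, Z)
    C_obs = departure_covariance(Y, E, X)

    total = int(round(Y.sum()))
    Y_perm = rng.multinomial(total, p, size=n_permutations).astype(float)
    D = Y_perm - E  # (n_p, n)
    Xc = X - X.mean()
    C_perm = (D - D.mean(axis=1, keepdims=True)) @ Xc / (n - 1)
    G = int(np.count_nonzero(C_perm <= C_obs))
    p_value = (G + 1) / (n_permutations + 1)
    return GeneTestResult(
        gene_id=inp.gene_id,
        n_regions=n,
        C=C_obs,
        p_value=p_value,
        n_permutations=n_permutations,
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def gene_substream(seed: int, gene_id: str) -> np.random.Generator:
    """Deterministic per-gene RNG substream: reproducible regardless of the
    order or parallelism in which genes are processed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(gene_id.encode())]))


def run_gene_tests(
    inputs: Sequence[GeneTestInput],
    n_permutations: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the gene-specific test over many genes and FDR-adjust the
    p-values of the assessable genes.

    Returns a DataFrame with columns gene_id, n_regions, C, p_value,
    fdr_p, skip_reason.
    """
    results = [
        gene_permutation_test(inp, n_permutations, gene_substream(seed, inp.gene_id))
        for inp in inputs
    ]
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "n_regions": [r.n_regions for r in results],
            "C": [r.C for r in results],
            "p_value": [r.p_value for r in results],
            "skip_reason": [r.skip_reason for r in results],
        }
    )
    tested = df["skip_reason"].isna()
    df["fdr_p"] = np.nan
    if tested.any():
        df.loc[tested, "fdr_p"] = fdr_adjust(df.loc[tested, "p_value"].to_numpy())
    return df
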