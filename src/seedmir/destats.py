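"""Two-library differential abundance of miRNA counts.

Counts per locus are normalized with TMM scaling (weighted trimmed mean of
log2 ratios) and tested twice: a conditional exact test under a negative
binomial model (binomial in the zero-dispersion limit) and the
Audic-Claverie posterior test for digital counts. A locus is called
differentially abundant only when BOTH tests give p <= alpha (default
0.001), with a separate highlight flag for fold changes beyond 2x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from .discover import PrecursorCandidate
from .preprocess import SmallRNATag


# ---------------------------------------------------------------------------
# counting

@dataclass
class QuantLocus:
    """One mature locus used for abundance counting."""

    id: str
    family: str
    precursor_sequence: str
    mature_interval: tuple[int, int]


def loci_from_candidates(candidates: Iterable[PrecursorCandidate],
                         ) -> list[QuantLocus]:
    """Quantifiable loci (one per called arm) of accepted candidates."""
    out = []
    for cand in candidates:
        if not cand.accepted:
            continue
        for locus in cand.loci:
            out.append(QuantLocus(
                id=f"{cand.id}-{locus.arm}", family=cand.category,
                precursor_sequence=cand.sequence,
                mature_interval=locus.interval))
    return out


def count_abundance(tags: Sequence[SmallRNATag], loci: Sequence[QuantLocus],
                    libraries: Sequence[str],
                    isomir_window: int = 3) -> pd.DataFrame:
    """Per-locus count matrix (rows = loci, columns = libraries).

    A tag credits its full count to every locus on whose precursor it
    occurs exactly with both ends within ``isomir_window`` nt of the mature.
    """
    rows = {}
    for locus in loci:
        counts = {lib: 0 for lib in libraries}
        m_start, m_end = locus.mature_interval
        seq = locus.precursor_sequence
        for tag in tags:
            found, start = False, seq.find(tag.sequence)
            while start != -1:
                end = start + len(tag.sequence)
                if (abs(start - m_start) <= isomir_window
                        and abs(end - m_end) <= isomir_window):
                    found = True
                    break
                start = seq.find(tag.sequence, start + 1)
            if found:
                for lib in libraries:
                    counts[lib] += tag.counts.get(lib, 0)
        rows[locus.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(libraries)).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# TMM normalization

def _choose_reference(matrix: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Column whose 75th percentile of nonzero size-scaled counts is
    closest to the mean of those percentiles."""
    q = []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        nz = col[col > 0] / lib_sizes[j]
        q.append(np.percentile(nz, 75) if nz.size else 0.0)
    q = np.asarray(q)
    return int(np.argmin(np.abs(q - q.mean())))


def tmm_factors(matrix: pd.DataFrame | np.ndarray,
                lib_sizes: Sequence[float] | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05,
                reference: int | None = None) -> np.ndarray:
    """TMM scaling factor per library, geometric mean rescaled to 1.

    Rows with a zero in either the library or the reference are excluded;
    the remaining log2 ratios (after library-size division) are trimmed by
    ``trim_m`` on M and ``trim_a`` on A from each tail and averaged with
    inverse-asymptotic-variance weights.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least two libraries")
    if lib_sizes is None:
        lib_sizes = X.sum(axis=0)
    N = np.asarray(lib_sizes, dtype=float)
    if np.any(N <= 0):
        raise ValueError("every library needs a positive size (nonzero column)")
    if reference is None:
        reference = _choose_reference(X, N)
    r = X[:, reference]
    Nr = N[reference]
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == reference:
            continue
        x = X[:, j]
        keep = (x > 0) & (r > 0)
        if not keep.any():
            continue
        xs, rs = x[keep] / N[j], r[keep] / Nr
        M = np.log2(xs / rs)
        A = 0.5 * np.log2(xs * rs)
        w = (N[j] - x[keep]) / (N[j] * x[keep]) + (Nr - r[keep]) / (Nr * r[keep])
        n = M.size
        lo_m, hi_m = math.floor(n * trim_m), n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a), n - math.floor(n * trim_a)
        rank_m = np.argsort(np.argsort(M, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(A, kind="stable"), kind="stable")
        sel = (rank_m >= lo_m) & (rank_m < hi_m) & \
              (rank_a >= lo_a) & (rank_a < hi_a)
        if sel.any() and w[sel].sum() > 0:
            factors[j] = 2.0 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Audic-Claverie test

def ac_pmf_log(y: int, x: int, n1: float, n2: float) -> float:
    """log p(y|x): the AC posterior for observing y in library 2 given x in
    library 1 with sizes n1, n2."""
    r = n2 / n1
    return (y * math.log(r) + gammaln(x + y + 1) - gammaln(x + 1)
            - gammaln(y + 1) - (x + y + 1) * math.log1p(r))


def ac_test(x: int, y: int, n1: float, n2: float) -> tuple[float, float]:
    """(one-sided, two-sided) Audic-Claverie p for counts x, y.

    One-sided p is the smaller tail of p(.|x); two-sided doubles it, capped
    at 1. The posterior p(y|x) is the negative binomial with x+1 successes
    and success probability n1/(n1+n2), so the tails are NB tails.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)
    lower = float(nbinom.cdf(y, x + 1, p))
    upper = float(nbinom.sf(y - 1, x + 1, p))  # includes the observed y
    # clamp away exact zeros from floating-point underflow (p is never 0)
    one_sided = min(1.0, max(min(lower, upper), 1e-300))
    return one_sided, min(1.0, 2.0 * one_sided)


# ---------------------------------------------------------------------------
# NB exact test

def nb_exact_test(x: int, y: int, n1: float, n2: float,
                  dispersion: float = 0.0) -> float:
    """Exact test conditioning on x+y under a negative binomial model.

    The total s = x+y is split between libraries with expected shares
    proportional to the (TMM-adjusted) effective sizes; p sums the
    probabilities of all splits no more likely than the observed one. At
    dispersion 0 this is the two-sided exact binomial test with success
    probability n1/(n1+n2).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s = x + y
    if s == 0:
        return 1.0
    q = n1 / (n1 + n2)
    ks = np.arange(s + 1)
    if dispersion == 0:
        logp = (poisson.logpmf(ks, s * q) + poisson.logpmf(s - ks, s * (1 - q)))
    else:
        size = 1.0 / dispersion
        mu1, mu2 = s * q, s * (1 - q)
        logp = (nbinom.logpmf(ks, size, size / (size + mu1))
                + nbinom.logpmf(s - ks, size, size / (size + mu2)))
    logp -= np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[x]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(max(p, 1e-300), 1.0))


# ---------------------------------------------------------------------------
# DE calling

def call_de(matrix: pd.DataFrame, lib_sizes: Mapping[str, float] | None = None,
            dispersion: float = 0.1, alpha: float = 0.001,
            min_fold: float = 2.0,
            factors: Sequence[float] | None = None) -> pd.DataFrame:
    """Dual-test DE table for a two-library count matrix.

    is_de requires p <= alpha in BOTH the NB exact test and the (two-sided)
    AC test; ``highlight`` additionally marks fold changes beyond
    ``min_fold`` in either direction. Fold change is the ratio of TMM-scaled
    counts-per-million with a pseudocount of 1.
    """
    if matrix.shape[1] != 2:
        raise ValueError("call_de expects exactly two libraries")
    lib_a, lib_b = matrix.columns
    if lib_sizes is None:
        sizes = matrix.sum(axis=0).astype(float)
    else:
        sizes = pd.Series({lib_a: float(lib_sizes[lib_a]),
                           lib_b: float(lib_sizes[lib_b])})
    if factors is None:
        factors = tmm_factors(matrix, lib_sizes=sizes.values)
    eff = sizes.values * np.asarray(factors, dtype=float)
    rows = []
    for locus_id, row in matrix.iterrows():
        x, y = int(row[lib_a]), int(row[lib_b])
        cpm_a = x / eff[0] * 1e6
        cpm_b = y / eff[1] * 1e6
        fold = (cpm_b + 1.0) / (cpm_a + 1.0)
        p_exact = nb_exact_test(x, y, eff[0], eff[1], dispersion)
        _, p_ac = ac_test(x, y, eff[0], eff[1])
        is_de = p_exact <= alpha and p_ac <= alpha
        rows.append({
            "id": locus_id, f"count_{lib_a}": x, f"count_{lib_b}": y,
            f"cpm_{lib_a}": cpm_a, f"cpm_{lib_b}": cpm_b,
            "fold_change": fold, "p_exact": p_exact, "p_ac": p_ac,
            "is_de": is_de,
            "highlight": is_de and (fold > min_fold or fold < 1.0 / min_fold),
        })
    return pd.DataFrame(rows).set_index("id")
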