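"""Bilateral asymmetry indices and population-pattern classification.

A bilateral trait is summarised per specimen by its signed side difference
(R - L).  Three population patterns are distinguished:

* **Fluctuating asymmetry (FA)** — (R - L) has mean zero and is normally
  distributed; only developmental noise separates the sides.
* **Directional asymmetry (DA)** — one side is larger on average;
  mean (R - L) differs from zero.
* **Antisymmetry** — a consistent side difference whose larger side varies
  randomly among individuals; the (R - L) distribution is broadened or
  bimodal and is detected as *platykurtosis*.

Indices
-------
``FA1``  mean |R - L| (biased upward by DA / antisymmetry).
``FA4a`` 0.798 * sqrt(var(R - L)); the constant is E|X|/sd = sqrt(2/pi)
         for a zero-mean normal, so FA4a estimates FA1 under pure FA.
``FA11`` sum over traits of mean |R - L| per individual — a cumulative,
         per-individual measure comparable across samples.

Hypothesis tests use the one-sample t (or Wilcoxon signed-rank) for DA and
large-sample standard-error z tests of the bias-corrected sample skewness
g1 and excess kurtosis g2 for departures from normality; multiple testing
across the six petalia traits is controlled with the Holm step-down
(sequential Bonferroni) procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import TRAITS

__all__ = [
    "FA4A_CONSTANT",
    "BilateralTraitSample",
    "AsymmetryIndices",
    "SideFrequencies",
    "TraitClassification",
    "fa1",
    "fa4a",
    "fa11",
    "asymmetry_indices",
    "test_directional",
    "test_skewness",
    "test_kurtosis",
    "holm_correct",
    "side_frequencies",
    "classify_traits",
]

#: E|X| / sd for a zero-mean normal, sqrt(2/pi), rounded as conventionally used.
FA4A_CONSTANT = 0.798

_MIN_N_MOMENT_TESTS = 8


@dataclass(frozen=True)
class BilateralTraitSample:
    """Signed (R - L) values of one trait across the specimens of a group."""

    trait: str
    values: np.ndarray
    group: str = ""
    size_corrected: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]  # complete-case: missing traits drop out
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AsymmetryIndices:
    mean_signed: float
    fa1: float
    fa4a: float
    n: int
    bias_flag: str = ""  # non-empty when DA/antisymmetry bias FA1/FA4a


@dataclass(frozen=True)
class SideFrequencies:
    """%R / %L over non-zero values; ties reported separately."""

    pct_right: float
    pct_left: float
    n_tied: int
    n: int

    @property
    def pct_tied(self) -> float:
        return 100.0 * self.n_tied / self.n if self.n else float("nan")


@dataclass(frozen=True)
class TraitClassification:
    trait: str
    verdict: str  # "FA" | "DA" | "antisymmetry" | "DA+antisymmetry" | "insufficient n"
    direction: str  # "right" | "left" | "none"
    n: int
    indices: AsymmetryIndices
    p_da: float
    p_da_adj: float
    p_skew: float
    p_skew_adj: float
    p_platy: float
    p_platy_adj: float
    g1: float
    g2: float
    sides: SideFrequencies
    notes: str = ""


def _values(sample) -> np.ndarray:
    if isinstance(sample, BilateralTraitSample):
        return sample.values
    v = np.asarray(sample, dtype=float)
    return v[np.isfinite(v)]


def fa1(sample) -> float:
    """FA1: mean absolute side difference, mean |R - L|."""
    v = _values(sample)
    if v.size == 0:
        raise ValueError("FA1 requires at least one value")
    return float(np.mean(np.abs(v)))


def fa4a(sample) -> float:
    """FA4a: 0.798 * sqrt(sample variance of (R - L)), n-1 denominator."""
    v = _values(sample)
    if v.size < 2:
        raise ValueError("FA4a requires at least two values")
    return float(FA4A_CONSTANT * np.sqrt(np.var(v, ddof=1)))


def fa11(samples: Sequence) -> float:
    """FA11: mean over individuals of the per-individual sum over traits of |R - L|.

    All traits must cover the same individuals (complete-case); algebraically
    FA11 equals the sum of the per-trait FA1 values.
    """
    arrays = [np.asarray(getattr(s, "values", s), dtype=float) for s in samples]
    if not arrays:
        raise ValueError("FA11 requires at least one trait")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("FA11 requires all traits over the same individuals")
    if n == 0:
        raise ValueError("FA11 requires at least one individual")
    per_individual = np.sum([np.abs(a) for a in arrays], axis=0)
    return float(np.mean(per_individual))


def asymmetry_indices(sample, bias_flag: str = "") -> AsymmetryIndices:
    v = _values(sample)
    return AsymmetryIndices(
        mean_signed=float(np.mean(v)) if v.size else float("nan"),
        fa1=fa1(v) if v.size else float("nan"),
        fa4a=fa4a(v) if v.size >= 2 else float("nan"),
        n=int(v.size),
        bias_flag=bias_flag,
    )


def test_directional(sample, alpha: float = 0.05, method: str = "t"):
    """Two-tailed test of mean (R - L) = 0 (directional asymmetry).

    ``method="t"`` is the one-sample t-test; ``method="wilcoxon"`` the
    signed-rank alternative.  Returns ``(statistic, p, direction)`` where
    direction is "right"/"left" when significant at ``alpha``, else "none".
    """
    v = _values(sample)
    if v.size < 3:
        raise ValueError("directional test requires n >= 3")
    if np.ptp(v) == 0:
        raise ValueError("directional test undefined for a zero-variance sample")
    if method == "t":
        res = stats.ttest_1samp(v, 0.0)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        nz = v[v != 0]
        if nz.size == 0:
            return 0.0, 1.0, "none"
        res = stats.wilcoxon(nz)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "none"
    if p < alpha:
        direction = "right" if np.mean(v) > 0 else "left"
    return statistic, p, direction


def _se_g1(n: int) -> float:
    return np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def _se_g2(n: int) -> float:
    return np.sqrt(24.0 * n * (n - 1) ** 2 / ((n - 3) * (n - 2) * (n + 3) * (n + 5)))


def test_skewness(sample):
    """Bias-corrected sample skewness g1 with a two-tailed large-sample z test."""
    v = _values(sample)
    n = v.size
    if n < _MIN_N_MOMENT_TESTS:
        raise ValueError(f"skewness test requires n >= {_MIN_N_MOMENT_TESTS}")
    g1 = float(stats.skew(v, bias=False))
    z = g1 / _se_g1(n)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return g1, p


def test_kurtosis(sample):
    """Excess kurtosis g2 with separate one-tailed tests.

    Returns ``(g2, p_platy, p_lepto)``: the platykurtosis p-value is the
    lower-tail probability of the standardised g2 (antisymmetry broadens or
    bimodalises the distribution, g2 < 0), leptokurtosis the upper tail.
    """
    v = _values(sample)
    n = v.size
    if n < _MIN_N_MOMENT_TESTS:
        raise ValueError(f"kurtosis test requires n >= {_MIN_N_MOMENT_TESTS}")
    g2 = float(stats.kurtosis(v, fisher=True, bias=False))
    z = g2 / _se_g2(n)
    return g2, float(stats.norm.cdf(z)), float(stats.norm.sf(z))


def holm_correct(pvalues: Sequence[float], alpha: float = 0.05):
    """Holm step-down (sequential Bonferroni) correction.

    Returns ``(reject, p_adjusted)`` arrays in the input order; adjusted
    p-values are monotone non-decreasing in the ranked order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return np.asarray(reject, bool), np.asarray(p_adj, float)


def side_frequencies(sample) -> SideFrequencies:
    """Percentages of rightward (>0) and leftward (<0) specimens.

    %R and %L are computed over the non-zero values so that they sum to 100;
    exact ties (R - L = 0) are counted separately.
    """
    v = _values(sample)
    if v.size == 0:
        raise ValueError("side frequencies require at least one value")
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    nz = n_pos + n_neg
    if nz == 0:
        return SideFrequencies(float("nan"), float("nan"), int(v.size), int(v.size))
    return SideFrequencies(
        pct_right=100.0 * n_pos / nz,
        pct_left=100.0 * n_neg / nz,
        n_tied=int(v.size - nz),
        n=int(v.size),
    )


def classify_traits(
    samples: Sequence[BilateralTraitSample],
    alpha: float = 0.05,
    da_method: str = "t",
) -> list[TraitClassification]:
    """Classify each trait's population asymmetry pattern.

    Per trait, the DA test (mean departure from zero) and the platykurtosis
    test (antisymmetry) are run; p-values are Holm-corrected within the
    family of traits separately per test type.  Verdicts:

    * ``DA`` when the adjusted DA p-value < alpha,
    * ``antisymmetry`` when the adjusted platykurtosis p-value < alpha,
    * ``DA+antisymmetry`` when both,
    * ``FA`` otherwise.

    FA1/FA4a are flagged as biased whenever DA or antisymmetry is detected.
    Traits with too few specimens for a test are marked rather than dropped.
    """
    n_traits = len(samples)
    p_da = np.full(n_traits, np.nan)
    stat_da = np.full(n_traits, np.nan)
    g1s = np.full(n_traits, np.nan)
    g2s = np.full(n_traits, np.nan)
    p_skew = np.full(n_traits, np.nan)
    p_platy = np.full(n_traits, np.nan)
    notes = [""] * n_traits

    for i, s in enumerate(samples):
        if s.n >= 3 and np.ptp(s.values) > 0:
            stat_da[i], p_da[i], _ = test_directional(s, alpha=alpha, method=da_method)
        else:
            notes[i] = "insufficient n for tests"
        if s.n >= _MIN_N_MOMENT_TESTS:
            g1s[i], p_skew[i] = test_skewness(s)
            g2s[i], p_platy[i], _ = test_kurtosis(s)
        elif not notes[i]:
            notes[i] = "insufficient n for skewness/kurtosis tests"

    def _holm_with_nans(p):
        adj = np.full_like(p, np.nan)
        rej = np.zeros(p.size, bool)
        mask = np.isfinite(p)
        if mask.any():
            r, a = holm_correct(p[mask], alpha=alpha)
            adj[mask] = a
            rej[mask] = r
        return rej, adj

    rej_da, adj_da = _holm_with_nans(p_da)
    _, adj_skew = _holm_with_nans(p_skew)
    rej_platy, adj_platy = _holm_with_nans(p_platy)

    out = []
    for i, s in enumerate(samples):
        is_da = bool(rej_da[i])
        is_anti = bool(rej_platy[i])
        if not np.isfinite(p_da[i]):
            verdict = "insufficient n"
        elif is_da and is_anti:
            verdict = "DA+antisymmetry"
        elif is_da:
            verdict = "DA"
        elif is_anti:
            verdict = "antisymmetry"
        else:
            verdict = "FA"
        direction = "none"
        if is_da:
            direction = "right" if np.mean(s.values) > 0 else "left"
        bias = "FA1/FA4a biased: " + verdict if (is_da or is_anti) else ""
        out.append(
            TraitClassification(
                trait=s.trait,
                verdict=verdict,
                direction=direction,
                n=s.n,
                indices=asymmetry_indices(s, bias_flag=bias),
                p_da=float(p_da[i]),
                p_da_adj=float(adj_da[i]),
                p_skew=float(p_skew[i]),
                p_skew_adj=float(adj_skew[i]),
                p_platy=float(p_platy[i]),
                p_platy_adj=float(adj_platy[i]),
                g1=float(g1s[i]),
                g2=float(g2s[i]),
                sides=side_frequencies(s.values) if s.n else None,
                notes=notes[i],
            )
        )
    return out
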