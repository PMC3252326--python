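"""Group-level comparative analyses.

Size-association screening (does |R - L| scale with endocranial volume?),
classical multivariate group comparison (Hotelling's two-sample T^2, with
Mardia's multivariate normality statistics and Box's M as assumption
diagnostics), Grubbs outlier screening, fronto-occipital petalial pattern
scoring (RF/LO, LF/RO, RF/RO, LF/LO) and structured per-group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import TRAITS, POLE_POSITIONS
from . import asymmetry as asym

__all__ = [
    "PATTERN_CATEGORIES",
    "size_correlation",
    "hotelling_two_sample",
    "mardia_tests",
    "box_m",
    "grubbs",
    "ap_pattern_category",
    "pattern_frequencies",
    "contralateral_association",
    "group_summary",
]

PATTERN_CATEGORIES = ("RF/LO", "LF/RO", "RF/RO", "LF/LO")

#: Pooled-covariance condition number above which multivariate tests refuse
#: to run (protects tiny fossil-sized groups from spurious results).
MAX_CONDITION_NUMBER = 1e10


class SingularCovarianceError(ValueError):
    """Covariance matrix is singular or too ill-conditioned to invert."""


def size_correlation(abs_asym, EV) -> dict:
    """Association between trait magnitude |R - L| and body/brain size.

    Size enters as the cube root of endocranial volume.  Returns Spearman's
    rho, Kendall's tau and the linear (Pearson/least-squares) fit, each with
    its p-value.
    """
    x = np.asarray(abs_asym, dtype=float)
    ev = np.asarray(EV, dtype=float)
    if x.shape != ev.shape:
        raise ValueError("abs_asym and EV must have the same length")
    mask = np.isfinite(x) & np.isfinite(ev)
    x, ev = x[mask], ev[mask]
    if x.size < 5:
        raise ValueError("size correlation requires n >= 5 complete pairs")
    size = np.cbrt(ev)
    if np.ptp(size) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined for a constant vector")
    sp = stats.spearmanr(size, x)
    kt = stats.kendalltau(size, x)
    lr = stats.linregress(size, x)
    return {
        "n": int(x.size),
        "spearman": {"rho": float(sp.statistic), "p": float(sp.pvalue)},
        "kendall": {"tau": float(kt.statistic), "p": float(kt.pvalue)},
        "linear": {
            "slope": float(lr.slope),
            "intercept": float(lr.intercept),
            "r": float(lr.rvalue),
            "p": float(lr.pvalue),
        },
    }


def _clean_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (specimens x traits) matrix")
    return X[np.all(np.isfinite(X), axis=1)]


def hotelling_two_sample(groupA, groupB):
    """Classical two-sample Hotelling T^2 with pooled covariance.

    Returns ``(T2, F, p)`` where F is the exact F-conversion
    ``F = (nA+nB-p-1) / (p (nA+nB-2)) * T2`` on ``(p, nA+nB-p-1)`` df.
    """
    A, B = _clean_matrix(groupA), _clean_matrix(groupB)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the same trait columns")
    nA, nB, p = A.shape[0], B.shape[0], A.shape[1]
    if nA + nB <= p + 2:
        raise ValueError(f"need nA+nB > p+2 (= {p + 2}), got {nA + nB}")
    S = ((nA - 1) * np.cov(A, rowvar=False) + (nB - 1) * np.cov(B, rowvar=False)) / (
        nA + nB - 2
    )
    S = np.atleast_2d(S)
    if np.linalg.cond(S) > MAX_CONDITION_NUMBER:
        raise SingularCovarianceError(
            "pooled covariance is singular/ill-conditioned; refusing Hotelling T^2"
        )
    d = A.mean(axis=0) - B.mean(axis=0)
    T2 = float(nA * nB / (nA + nB) * d @ np.linalg.solve(S, d))
    dfd = nA + nB - p - 1
    F = T2 * dfd / (p * (nA + nB - 2))
    pval = float(stats.f.sf(F, p, dfd))
    return T2, float(F), pval


def mardia_tests(X):
    """Mardia's multivariate skewness and kurtosis statistics.

    Skewness: ``n/6 * b1p`` ~ chi^2 with p(p+1)(p+2)/6 df.  Kurtosis:
    ``(b2p - p(p+2)) / sqrt(8 p (p+2) / n)`` ~ N(0,1), two-tailed.  Returns
    ``{"skewness": (b1p, p), "kurtosis": (b2p, p)}``.
    """
    X = _clean_matrix(X)
    n, p = X.shape
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    if np.linalg.cond(S) > MAX_CONDITION_NUMBER:
        raise SingularCovarianceError("covariance is singular; Mardia tests undefined")
    Xc = X - X.mean(axis=0)
    D = Xc @ np.linalg.solve(S, Xc.T)  # n x n matrix of Mahalanobis products
    b1p = float(np.mean(D**3))
    b2p = float(np.mean(np.diag(D) ** 2))
    df_skew = p * (p + 1) * (p + 2) / 6.0
    p_skew = float(stats.chi2.sf(n * b1p / 6.0, df_skew))
    z_kurt = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    return {"skewness": (b1p, p_skew), "kurtosis": (b2p, p_kurt)}


def box_m(groupA, groupB):
    """Box's M test of equality of two covariance matrices (chi^2 approximation)."""
    A, B = _clean_matrix(groupA), _clean_matrix(groupB)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the same trait columns")
    p = A.shape[1]
    ns = np.array([A.shape[0], B.shape[0]])
    if np.any(ns <= p):
        raise ValueError("each group needs n > number of traits for Box's M")
    covs = [np.atleast_2d(np.cov(G, rowvar=False)) for G in (A, B)]
    dfs = ns - 1
    Sp = sum(df * C for df, C in zip(dfs, covs)) / dfs.sum()
    if np.linalg.cond(Sp) > MAX_CONDITION_NUMBER:
        raise SingularCovarianceError("pooled covariance singular; Box's M undefined")
    sign, logdet_p = np.linalg.slogdet(Sp)
    if sign <= 0:
        raise SingularCovarianceError("pooled covariance not positive definite")
    M = dfs.sum() * logdet_p
    for df, C in zip(dfs, covs):
        s, ld = np.linalg.slogdet(C)
        if s <= 0:
            raise SingularCovarianceError("group covariance not positive definite")
        M -= df * ld
    k = 2
    c = (
        (2 * p**2 + 3 * p - 1)
        / (6.0 * (p + 1) * (k - 1))
        * (np.sum(1.0 / dfs) - 1.0 / dfs.sum())
    )
    chi2 = M * (1 - c)
    df_chi = p * (p + 1) * (k - 1) / 2.0
    return float(M), float(stats.chi2.sf(chi2, df_chi))


def grubbs(values, alpha: float = 0.05, iterative: bool = False):
    """Two-sided Grubbs test for outliers in a near-normal sample.

    Flags the single most extreme value when its studentised deviation G
    exceeds the exact t-based critical value; with ``iterative=True`` the
    test is repeated on the reduced sample until no further outlier is
    found.  Returns a boolean mask over the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("Grubbs test requires n >= 4")
    flags = np.zeros(x.size, dtype=bool)
    active = np.arange(x.size)
    while True:
        v = x[active]
        n = v.size
        if n < 4:
            break
        s = np.std(v, ddof=1)
        if s == 0:
            raise ValueError("Grubbs test undefined for a zero-variance sample")
        dev = np.abs(v - v.mean())
        i = int(np.argmax(dev))
        G = dev[i] / s
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        G_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        if G > G_crit:
            flags[active[i]] = True
            if not iterative:
                break
            active = np.delete(active, i)
        else:
            break
    return flags


def ap_pattern_category(frontal_ap: float, occipital_ap: float) -> str:
    """Fronto-occipital pattern from the signs of the two AP components.

    RF/LF: right/left frontal petalia (frontal AP > 0 / < 0); RO/LO:
    right/left occipital petalia.  A zero (or missing) component leaves the
    pattern undetermined.
    """
    if not (np.isfinite(frontal_ap) and np.isfinite(occipital_ap)):
        return "undetermined"
    if frontal_ap == 0 or occipital_ap == 0:
        return "undetermined"
    f = "RF" if frontal_ap > 0 else "LF"
    o = "RO" if occipital_ap > 0 else "LO"
    return f"{f}/{o}"


def pattern_frequencies(cohort: pd.DataFrame) -> dict:
    """Percentages of the four fronto-occipital patterns over determined specimens."""
    cats = [
        ap_pattern_category(fa, oa)
        for fa, oa in zip(cohort["frontal_ap"], cohort["occipital_ap"])
    ]
    determined = [c for c in cats if c != "undetermined"]
    n_det = len(determined)
    pct = {
        cat: (100.0 * determined.count(cat) / n_det if n_det else float("nan"))
        for cat in PATTERN_CATEGORIES
    }
    return {
        "pct": pct,
        "n_determined": n_det,
        "n_undetermined": len(cats) - n_det,
    }


def contralateral_association(ap, lat):
    """Percentage of specimens whose AP and lateral asymmetries point to opposite sides.

    Pairs with a zero (or missing) value in either component are excluded
    and counted as ties.  Returns ``(percentage, n_used, n_tied)``.
    """
    a = np.asarray(ap, dtype=float)
    l = np.asarray(lat, dtype=float)
    if a.shape != l.shape:
        raise ValueError("ap and lat must have the same length")
    finite = np.isfinite(a) & np.isfinite(l)
    nonzero = finite & (a != 0) & (l != 0)
    n_used = int(nonzero.sum())
    n_tied = int(finite.sum() - n_used)
    if n_used == 0:
        return float("nan"), 0, n_tied
    pct = 100.0 * np.mean(np.sign(a[nonzero]) != np.sign(l[nonzero]))
    return float(pct), n_used, n_tied


def _trait_samples(sub: pd.DataFrame, group: str, prefix: str = "") -> list:
    return [
        asym.BilateralTraitSample(
            trait=t,
            values=sub[f"{prefix}{t}"].to_numpy(dtype=float),
            group=group,
            size_corrected=bool(prefix),
        )
        for t in TRAITS
    ]


def group_summary(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    size_corrected: bool = True,
    da_method: str = "t",
) -> dict:
    """Structured per-group report over a cohort table.

    For each group (sorted for deterministic output): per-trait asymmetry
    indices and classification (when n allows), FA11 over complete cases,
    fronto-occipital pattern frequencies, the occipital AP-vs-lateral
    contralateral association, and mean pole lateral positions.  When
    ``size_corrected`` and ``rel_*`` columns are present, statistics are run
    on the size-corrected traits; raw-mm indices are always reported.
    """
    prefix = "rel_" if size_corrected and f"rel_{TRAITS[0]}" in cohort.columns else ""
    report: dict = {"alpha": alpha, "size_corrected": bool(prefix), "groups": {}}
    for group in sorted(map(str, cohort["group"].dropna().unique())):
        sub = cohort[cohort["group"].astype(str) == group]
        samples = _trait_samples(sub, group, prefix)
        entry: dict = {"n": int(len(sub))}

        min_n = min(s.n for s in samples)
        if min_n >= 3:
            classifications = asym.classify_traits(samples, alpha=alpha, da_method=da_method)
            entry["traits"] = {c.trait: _classification_dict(c) for c in classifications}
        else:
            entry["traits"] = {
                s.trait: {"n": s.n, "verdict": "insufficient n",
                          "indices": _indices_dict(asym.asymmetry_indices(s))
                          if s.n else None}
                for s in samples
            }

        complete = sub.dropna(subset=[f"{prefix}{t}" for t in TRAITS])
        if len(complete):
            entry["fa11"] = asym.fa11(
                [complete[f"{prefix}{t}"].to_numpy(dtype=float) for t in TRAITS]
            )
            entry["fa11_n"] = int(len(complete))
        else:
            entry["fa11"] = float("nan")
            entry["fa11_n"] = 0

        entry["patterns"] = pattern_frequencies(sub)
        pct, n_used, n_tied = contralateral_association(
            sub["occipital_ap"], sub["occipital_lat"]
        )
        entry["occipital_contralateral"] = {"pct": pct, "n": n_used, "n_tied": n_tied}
        entry["pole_positions"] = {
            k: float(np.nanmean(sub[k].to_numpy(dtype=float)))
            if sub[k].notna().any() else float("nan")
            for k in POLE_POSITIONS
            if k in sub.columns
        }
        report["groups"][group] = entry
    return report


def _indices_dict(ix: asym.AsymmetryIndices) -> dict:
    return {
        "mean_signed": ix.mean_signed,
        "fa1": ix.fa1,
        "fa4a": ix.fa4a,
        "n": ix.n,
        "bias_flag": ix.bias_flag,
    }


def _classification_dict(c: asym.TraitClassification) -> dict:
    return {
        "verdict": c.verdict,
        "direction": c.direction,
        "n": c.n,
        "indices": _indices_dict(c.indices),
        "p_da": c.p_da,
        "p_da_adj": c.p_da_adj,
        "p_skew": c.p_skew,
        "p_skew_adj": c.p_skew_adj,
        "p_platy": c.p_platy,
        "p_platy_adj": c.p_platy_adj,
        "g1": c.g1,
        "g2": c.g2,
        "pct_right": c.sides.pct_right if c.sides else float("nan"),
        "pct_left": c.sides.pct_left if c.sides else float("nan"),
        "n_tied": c.sides.n_tied if c.sides else 0,
        "notes": c.notes,
    }
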