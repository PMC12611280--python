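"""Growth curves, adult-to-old decoupling, mucosal surface area, and the
statistical test battery.

Body and gut lengths follow the von Bertalanffy growth function (vBGF)
L(t) = L_inf * (1 - exp(-k * (t - t0))): fish grow asymptotically toward
L_inf at rate k.  In aging killifish the gut decouples from the body: body
length keeps creeping up while gut length, weight and diameter shrink.  The
mucosal surface area is the smooth-cylinder area times the fold-induced
amplification factor M: area = pi * d * l * M.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.diagnostic import kstest_normal
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "VBGFFit",
    "SurfaceAreaEstimate",
    "vbgf",
    "fit_vbgf",
    "decoupling_test",
    "surface_area",
    "stat_tests",
    "dunn_test",
]

GROWTH_MEASURES = ("body_length", "gut_length", "body_weight", "gut_weight", "gut_diameter")


@dataclass
class VBGFFit:
    l_inf: float  # asymptotic length, mm
    k: float      # growth coefficient, per week
    t0: float     # hypothetical age at zero length, weeks
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.converged and (self.l_inf <= 0 or self.k <= 0):
            raise ValueError("converged vBGF fit must have positive L_inf and k")

    def predict(self, t):
        return vbgf(np.asarray(t, dtype=float), self.l_inf, self.k, self.t0)


@dataclass
class SurfaceAreaEstimate:
    length_mm: float
    diameter_mm: float
    amplification: float
    area_mm2: float


def vbgf(t, l_inf, k, t0):
    return l_inf * (1.0 - np.exp(-k * (t - t0)))


def fit_vbgf(ages: np.ndarray, lengths: np.ndarray) -> VBGFFit:
    """Least-squares vBGF fit.

    Initialisation: L_inf at 1.1x the largest observation, k from a
    log-linearised regression of the early points, t0 = 0.  Non-increasing
    early data is flagged as degenerate but still fitted.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need measurements at >= 4 distinct ages")
    flags = []
    order = np.argsort(t)
    half = max(2, len(t) // 2)
    early = y[order][:half]
    if early[-1] <= early[0]:
        flags.append("degenerate_early_trend")

    linf0 = 1.1 * y.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = 1.0 - y / linf0
        ok = z > 1e-12
        if ok.sum() >= 2:
            slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
            k0 = max(-slope, 1e-3)
        else:
            k0 = 0.1
    p0 = [linf0, k0, 0.0]

    def resid(p):
        return vbgf(t, *p) - y

    sol = optimize.least_squares(
        resid,
        p0,
        bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return VBGFFit(
        l_inf=float(sol.x[0]),
        k=float(sol.x[1]),
        t0=float(sol.x[2]),
        rss=float((sol.fun**2).sum()),
        converged=bool(sol.success),
        flags=tuple(flags),
    )


def decoupling_test(
    body_adult,
    body_old,
    gut_adult,
    gut_old,
    alpha: float = 0.05,
) -> dict:
    """Detect the adult-to-old decoupling of gut size from body growth.

    Welch two-tailed t-tests per measure between age groups; decoupling is
    declared when the body change is non-negative while the gut measure
    decreases significantly (p < alpha).  Groups with n < 3 skip the test.
    """
    body_adult, body_old = np.asarray(body_adult, float), np.asarray(body_old, float)
    gut_adult, gut_old = np.asarray(gut_adult, float), np.asarray(gut_old, float)
    out = {
        "body_delta": float(body_old.mean() - body_adult.mean()),
        "gut_delta": float(gut_old.mean() - gut_adult.mean()),
        "decoupled": False,
        "skipped": False,
    }
    if min(body_adult.size, body_old.size, gut_adult.size, gut_old.size) < 3:
        out.update(skipped=True, body_p=np.nan, gut_p=np.nan)
        return out
    _, bp = stats.ttest_ind(body_adult, body_old, equal_var=False)
    _, gp = stats.ttest_ind(gut_adult, gut_old, equal_var=False)
    out["body_p"] = float(bp)
    out["gut_p"] = float(gp)
    out["decoupled"] = bool(
        out["body_delta"] >= 0 and out["gut_delta"] < 0 and gp < alpha
    )
    return out


def surface_area(length_mm: float, diameter_mm: float, amplification: float) -> SurfaceAreaEstimate:
    """Mucosal surface area of a gut tube: pi * d * l * M."""
    if length_mm <= 0 or diameter_mm <= 0 or amplification <= 0:
        raise ValueError("length, diameter and amplification must be positive")
    if amplification < 1:
        warnings.warn("amplification below 1: less surface than a smooth cylinder")
    return SurfaceAreaEstimate(
        length_mm=length_mm,
        diameter_mm=diameter_mm,
        amplification=amplification,
        area_mm2=float(np.pi * diameter_mm * length_mm * amplification),
    )


def dunn_test(samples: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post-hoc test with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) where
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided p-values are
    Bonferroni-adjusted across the comparisons.
    """
    names = list(samples)
    data = [np.asarray(samples[n], float) for n in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([d.size for d in data])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = {n: rg.mean() for n, rg in zip(names, rank_groups)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        na, nb = samples[a].size if hasattr(samples[a], "size") else len(samples[a]), len(samples[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        rows.append({"group_a": a, "group_b": b, "stat": float(z), "p_value": float(p)})
    return pd.DataFrame(rows)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0:
        return True  # constant samples: the KS machinery degenerates
    _, p = kstest_normal(x)  # Lilliefors: KS against a fitted normal
    return p >= alpha


def stat_tests(samples: dict[str, np.ndarray], design: str = "auto") -> dict:
    """The study's test battery over named samples.

    Designs: ``paired_t`` (two equal-length samples), ``welch_t`` (two
    samples), ``kruskal_dunn`` (global Kruskal-Wallis + Dunn post-hoc,
    Bonferroni), ``anova_tukey`` (one-way ANOVA + Tukey HSD), or ``auto``
    which runs a KS normality pre-check on every group and branches to
    ANOVA+Tukey when all pass, Kruskal-Wallis+Dunn otherwise.
    """
    if not samples or any(len(v) == 0 for v in samples.values()):
        raise ValueError("every group must be non-empty")
    arrays = {k: np.asarray(v, float) for k, v in samples.items()}
    names = list(arrays)

    if design == "auto":
        design = (
            "anova_tukey"
            if all(_is_normal(x) for x in arrays.values())
            else "kruskal_dunn"
        )

    if design == "paired_t":
        if len(arrays) != 2:
            raise ValueError("paired_t needs exactly two samples")
        x, y = arrays[names[0]], arrays[names[1]]
        if x.size != y.size:
            raise ValueError("paired_t needs equal-length samples")
        d = x - y
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(x, y)
        return {"design": design, "stat": float(stat), "p_value": float(p)}

    if design == "welch_t":
        if len(arrays) != 2:
            raise ValueError("welch_t needs exactly two samples")
        stat, p = stats.ttest_ind(arrays[names[0]], arrays[names[1]], equal_var=False)
        return {"design": design, "stat": float(stat), "p_value": float(p)}

    if design == "kruskal_dunn":
        groups = list(arrays.values())
        if np.ptp(np.concatenate(groups)) == 0:
            stat, p = 0.0, 1.0  # all observations identical: H = 0 by definition
        else:
            stat, p = stats.kruskal(*groups)
        return {
            "design": design,
            "stat": float(stat),
            "p_value": float(p),
            "posthoc": dunn_test(arrays),
        }

    if design == "anova_tukey":
        groups = list(arrays.values())
        stat, p = stats.f_oneway(*groups)
        values = np.concatenate(groups)
        labels = np.concatenate([[n] * len(arrays[n]) for n in names])
        tukey = pairwise_tukeyhsd(values, labels)
        posthoc = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return {
            "design": design,
            "stat": float(stat),
            "p_value": float(p),
            "posthoc": posthoc,
        }

    raise ValueError(f"unknown design {design!r}")
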