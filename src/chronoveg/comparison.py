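"""Assumption-gated comparison of per-plot metrics across sites.

The decision flow mirrors common practice for small balanced vegetation
designs: Shapiro-Wilk on the ANOVA residuals and a Brown-Forsythe Levene
test run first; when Levene rejects homoscedasticity at the routing alpha
the omnibus test switches from classic one-way ANOVA (+ Tukey HSD) to
Welch's ANOVA (+ Games-Howell). Normality is reported but never drives the
routing: with four plots per site the Shapiro test has essentially no
power, so acting on it would be noise.

Classic ANOVA, Levene and Shapiro-Wilk are delegated to scipy; Welch's F
and the Games-Howell posthoc are implemented here on scipy's studentized
range distribution, with per-pair Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DomainError
from .diversity import site_diversity
from .importance import basal_area, stem_volume
from .inventory import Chronosequence, PlotInventory
from .vertical import a_index


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float
    df1: float
    df2: float
    pvalue: float
    variant: str  # "classic" | "welch"


@dataclass(frozen=True)
class PosthocPair:
    group_a: str
    group_b: str
    difference: float
    statistic: float
    pvalue: float
    significant: bool


@dataclass
class GroupComparison:
    """Full audit of one metric's comparison across sites."""

    metric: str
    groups: dict[str, list[float]]
    shapiro_w: float
    shapiro_p: float
    levene_f: float
    levene_p: float
    omnibus: OmnibusResult
    posthoc: list[PosthocPair]
    letters: dict[str, str]
    route: str  # "classic+tukey" | "welch+games-howell"


def _validate_groups(groups: list[np.ndarray], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    for g in groups:
        if len(g) < min_n:
            raise DomainError(f"every group needs at least {min_n} values")


def one_way_anova(groups) -> OmnibusResult:
    """Classic fixed-effects one-way ANOVA (F = MSB / MSW)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    f, p = stats.f_oneway(*gs)
    k = len(gs)
    n = sum(len(g) for g in gs)
    return OmnibusResult(float(f), float(k - 1), float(n - k), float(p), "classic")


def welch_anova(groups) -> OmnibusResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Group weights are w_i = n_i / s_i^2; the denominator degrees of freedom
    follow Welch-Satterthwaite and are generally non-integer.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    if any(g.var(ddof=1) == 0 for g in gs):
        raise DomainError(
            "a group has zero variance; Welch's ANOVA is undefined "
            "(classic ANOVA may still apply)"
        )
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = num / (1 + 2 * lam * (k - 2))
    df2 = 1.0 / (3.0 * lam)
    p = stats.f.sf(f, k - 1, df2)
    return OmnibusResult(float(f), float(k - 1), float(df2), float(p), "welch")


def levene_test(groups, center: str = "median") -> tuple[float, float]:
    """Levene homoscedasticity test; median centering (Brown-Forsythe) by
    default, mean centering by flag."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    if all(g.var(ddof=1) == 0 for g in gs):
        raise DomainError("all groups constant; spread comparison degenerate")
    f, p = stats.levene(*gs, center=center)
    return float(f), float(p)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise DomainError(f"Shapiro-Wilk needs 3..5000 values, got {len(x)}")
    if x.var() == 0:
        raise DomainError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _letters(labels: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups not significantly different share a
    letter (insert-and-absorb over maximal non-distinct cliques)."""
    # maximal sets of mutually non-distinct groups, in label order
    cliques: list[set[str]] = []
    for lab in labels:
        placed = False
        for c in cliques:
            if all(tuple(sorted((lab, other))) not in distinct for other in c):
                c.add(lab)
                placed = True
        if not placed:
            cliques.append({lab})
    # absorb cliques contained in others
    cliques = [
        c for i, c in enumerate(cliques)
        if not any(i != j and c < d for j, d in enumerate(cliques))
    ]
    out: dict[str, str] = {lab: "" for lab in labels}
    for letter, c in zip(string.ascii_lowercase, cliques):
        for lab in labels:
            if lab in c:
                out[lab] += letter
    return out


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> list[PosthocPair]:
    """Tukey HSD pairwise comparisons under the pooled-variance model."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    res = stats.tukey_hsd(*gs)
    pairs = []
    for i, j in combinations(range(len(gs)), 2):
        diff = float(gs[i].mean() - gs[j].mean())
        p = float(res.pvalue[i, j])
        pairs.append(
            PosthocPair(labels[i], labels[j], diff, float(res.statistic[i, j]), p, p < alpha)
        )
    return pairs


def games_howell(groups, labels=None, alpha: float = 0.05) -> list[PosthocPair]:
    """Games-Howell pairwise comparisons for unequal variances/sizes.

    For pair (i, j): t = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j), with
    Welch-Satterthwaite df per pair; p comes from the studentized range with
    q = |t| * sqrt(2) and k groups.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    if any(g.var(ddof=1) == 0 for g in gs):
        raise DomainError("a group has zero variance; Games-Howell undefined")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    k = len(gs)
    pairs = []
    for i, j in combinations(range(k), 2):
        a, b = gs[i], gs[j]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = np.sqrt(va + vb)
        t = (a.mean() - b.mean()) / se
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        pairs.append(
            PosthocPair(labels[i], labels[j], float(a.mean() - b.mean()), float(t), p, p < alpha)
        )
    return pairs


def route_comparison(
    groups, labels=None, alpha: float = 0.05, metric: str = "metric"
) -> GroupComparison:
    """Run the full assumption-gated flow on raw per-group values."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    _validate_groups(gs)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    residuals = np.concatenate([g - g.mean() for g in gs])
    w, wp = shapiro_wilk(residuals)
    lf, lp = levene_test(gs)
    if lp < alpha:
        omnibus = welch_anova(gs)
        posthoc = games_howell(gs, labels, alpha)
        route = "welch+games-howell"
    else:
        omnibus = one_way_anova(gs)
        posthoc = tukey_hsd(gs, labels, alpha)
        route = "classic+tukey"
    distinct = {
        tuple(sorted((p.group_a, p.group_b))) for p in posthoc if p.significant
    }
    letters = _letters(labels, distinct if omnibus.pvalue < alpha else set())
    return GroupComparison(
        metric=metric,
        groups={lab: list(map(float, g)) for lab, g in zip(labels, gs)},
        shapiro_w=w,
        shapiro_p=wp,
        levene_f=lf,
        levene_p=lp,
        omnibus=omnibus,
        posthoc=posthoc,
        letters=letters,
        route=route,
    )


METRICS = (
    "richness",
    "effective_species",
    "a_index",
    "abundance",
    "dominance",
    "volume",
)


def _plot_metric(plot: PlotInventory, metric: str) -> float:
    scale = 1e4 / plot.area_m2
    if metric == "abundance":
        return len(plot.records) * scale
    if metric == "dominance":
        return sum(basal_area(r.basal_diameter_cm) for r in plot.records) * scale
    if metric == "volume":
        return (
            sum(
                stem_volume(basal_area(r.basal_diameter_cm), r.height_m)
                for r in plot.records
            )
            * scale
        )
    if metric == "a_index":
        return a_index(plot.records)
    raise DomainError(f"unknown per-plot metric {metric!r}")


def compare_metric(
    chrono: Chronosequence, metric: str, alpha: float = 0.05
) -> GroupComparison:
    """Assumption-gated comparison of a per-plot metric across sites.

    ``metric`` is one of richness, effective_species, a_index, abundance
    (N ha^-1), dominance (m^2 ha^-1), or volume (m^3 ha^-1), each evaluated
    per plot so sites contribute replicate values.
    """
    if metric not in METRICS:
        raise DomainError(f"metric must be one of {METRICS}, got {metric!r}")
    labels = chrono.site_labels
    if metric in ("richness", "effective_species"):
        per_plot = site_diversity(chrono, scope="plot")
        groups = []
        for site in chrono.sites:
            vals = []
            for plot in site.plots:
                scope = f"{site.label}/{plot.plot_id}"
                res = next(r for r in per_plot if r.scope == scope)
                vals.append(
                    float(res.richness)
                    if metric == "richness"
                    else res.effective_species
                )
            groups.append(vals)
    else:
        groups = [
            [_plot_metric(p, metric) for p in site.plots] for site in chrono.sites
        ]
    return route_comparison(groups, labels, alpha, metric=metric)
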