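"""Species richness, Shannon entropy H', and the effective number of species.

The effective number of species (first-order Hill number, ``1D``) is
``exp(H')`` with H' in nats: the number of equally-common species that would
give the same entropy as the observed relative-abundance vector. Proportions
are scale-invariant, so abundance inputs may be raw counts or per-hectare
densities interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .errors import DomainError
from .inventory import Chronosequence, pooled_abundance


@dataclass(frozen=True)
class DiversityResult:
    """Richness, H' (nats) and effective species for one plot or site.

    ``defined`` is False for an empty scope, where H' and 1D are NaN.
    """

    scope: str
    richness: int
    shannon_h: float
    effective_species: float
    defined: bool = True


def species_richness(abund) -> int:
    """Count strictly positive entries of a non-negative abundance vector."""
    x = np.asarray(abund, dtype=float)
    if (x < 0).any():
        raise DomainError("abundances must be non-negative")
    return int((x > 0).sum())


def shannon_index(abund) -> float:
    """Shannon entropy H' = -sum p_i ln p_i (nats) of an abundance vector.

    Proportions are taken over the vector total; zero entries contribute
    nothing. An all-zero vector has undefined proportions and raises.
    """
    x = np.asarray(abund, dtype=float)
    if (x < 0).any():
        raise DomainError("abundances must be non-negative")
    if x.sum() <= 0:
        raise DomainError("Shannon index undefined for an all-zero vector")
    return float(_scipy_entropy(x))


def effective_species(h: float) -> float:
    """First-order Hill number 1D = exp(H'), H' in nats."""
    if h < 0:
        raise DomainError(f"Shannon entropy cannot be negative, got {h!r}")
    return math.exp(h)


def _result(scope: str, abund) -> DiversityResult:
    s = species_richness(abund)
    if s == 0:
        return DiversityResult(scope, 0, float("nan"), float("nan"), defined=False)
    h = shannon_index(abund)
    return DiversityResult(scope, s, h, effective_species(h))


def site_diversity(chrono: Chronosequence, scope: str = "pooled") -> list[DiversityResult]:
    """Diversity per site (scope ``"pooled"``) or per plot (scope ``"plot"``).

    Pooled scope sums each site's abundances over its plots before computing
    indices — the convention that reproduces published per-site effective
    species from per-site density tables. Plot scope yields one result per
    plot (labelled ``site/plot``) and feeds the group-comparison stage.
    """
    if scope == "pooled":
        abund = pooled_abundance(chrono)
        return [
            _result(label, abund.row(label)) for label in abund.site_labels
        ]
    if scope == "plot":
        results = []
        for site in chrono.sites:
            for plot in site.plots:
                counts: dict[str, int] = {}
                for rec in plot.records:
                    key = rec.species.casefold()
                    counts[key] = counts.get(key, 0) + 1
                results.append(
                    _result(f"{site.label}/{plot.plot_id}", list(counts.values()))
                )
        return results
    raise DomainError(f"scope must be 'pooled' or 'plot', got {scope!r}")
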