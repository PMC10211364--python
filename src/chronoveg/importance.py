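"""Species importance values and stand volume for one site.

The importance value index (IVI) of species *i* averages its relative
abundance, relative basal-area dominance, and relative plot frequency:

    IVI_i = (RA_i + Rd_i + Rf_i) / 3

so the IVI column sums to 100 over species, as do each of the three relative
columns. Basal area treats the stem section at 10 cm above ground as a
circle; stand volume applies a morphic coefficient (form factor) of 0.5, the
constant used for Tamaulipan thornscrub, to the cylinder g * h.

Frequency is counted at the plot level (presence/absence per sampling plot),
the only unit that varies within a single site's table under a
four-plots-per-site design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .inventory import CENSUS_MIN_DIAMETER_CM, SiteCondition

logger = logging.getLogger(__name__)

#: Morphic coefficient (form factor) for Tamaulipan thornscrub stems.
DEFAULT_MORPHIC_COEFFICIENT = 0.5


def basal_area(d_cm) -> float | np.ndarray:
    """Basal area g (m^2) of a circular stem section of diameter ``d_cm``.

    g = pi * (d_cm / 200)^2 — the /200 converts a cm diameter to a m radius.
    """
    d = np.asarray(d_cm, dtype=float)
    if (d < CENSUS_MIN_DIAMETER_CM).any():
        raise DomainError(
            f"diameter below the {CENSUS_MIN_DIAMETER_CM} cm census threshold"
        )
    g = math.pi * (d / 200.0) ** 2
    return float(g) if np.isscalar(d_cm) else g


def stem_volume(g: float, h: float, mc: float = DEFAULT_MORPHIC_COEFFICIENT) -> float:
    """Stem volume V = g * h * MC (m^3) from basal area, height and form factor."""
    if g <= 0 or h <= 0:
        raise DomainError("basal area and height must be positive")
    if not 0 < mc <= 1:
        raise DomainError(f"morphic coefficient must be in (0, 1], got {mc!r}")
    return g * h * mc


@dataclass
class ImportanceTable:
    """Per-species importance values for one site, sorted by IVI descending.

    ``table`` columns: ``abundance_ha`` (N ha^-1), ``rel_abundance`` (%),
    ``dominance_m2_ha`` (G ha^-1), ``rel_dominance`` (%), ``frequency``
    (plots occupied), ``rel_frequency`` (%), ``ivi``.
    """

    site_label: str
    table: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        cols = [
            "abundance_ha",
            "rel_abundance",
            "dominance_m2_ha",
            "rel_dominance",
            "frequency",
            "rel_frequency",
            "ivi",
        ]
        return self.table[cols].sum()


@dataclass(frozen=True)
class StandVolume:
    """Above-ground stand volume of one site in m^3 ha^-1."""

    site_label: str
    volume_m3_ha: float
    morphic_coefficient: float = DEFAULT_MORPHIC_COEFFICIENT


def importance_table(site: SiteCondition) -> ImportanceTable:
    """Compute the abundance / dominance / frequency / IVI table for a site."""
    records = site.records
    if not records:
        raise DomainError(f"site {site.label!r} has no records")
    area = site.area_m2
    species = sorted({r.species for r in records}, key=str.casefold)
    idx = {sp: i for i, sp in enumerate(species)}
    n = np.zeros(len(species))
    ba = np.zeros(len(species))
    present = np.zeros((len(site.plots), len(species)), dtype=bool)
    for p, plot in enumerate(site.plots):
        for rec in plot.records:
            j = idx[rec.species]
            n[j] += 1
            ba[j] += basal_area(rec.basal_diameter_cm)
            present[p, j] = True
    abundance = n / area * 1e4
    dominance = ba / area * 1e4
    freq = present.sum(axis=0).astype(float)
    rel = lambda x: x / x.sum() * 100.0
    df = pd.DataFrame(
        {
            "abundance_ha": abundance,
            "rel_abundance": rel(abundance),
            "dominance_m2_ha": dominance,
            "rel_dominance": rel(dominance),
            "frequency": freq,
            "rel_frequency": rel(freq),
        },
        index=pd.Index(species, name="species"),
    )
    df["ivi"] = (df["rel_abundance"] + df["rel_dominance"] + df["rel_frequency"]) / 3.0
    df = df.sort_values("ivi", ascending=False, kind="mergesort")
    return ImportanceTable(site_label=site.label, table=df)


def site_volume(
    site: SiteCondition, mc: float = DEFAULT_MORPHIC_COEFFICIENT
) -> StandVolume:
    """Total stem volume of a site scaled to m^3 ha^-1."""
    records = site.records
    if not records:
        logger.warning("site %s has no records; volume reported as 0", site.label)
        return StandVolume(site.label, 0.0, mc)
    total = sum(
        stem_volume(basal_area(r.basal_diameter_cm), r.height_m, mc) for r in records
    )
    return StandVolume(site.label, total / site.area_m2 * 1e4, mc)
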