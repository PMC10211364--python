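"""Species height profile index (A-index) after Pretzsch.

Individuals are assigned to three relative-height zones defined by the
tallest individual in scope (100%): zone I above 80%, zone II above 50% up
to 80%, zone III at or below 50%. The A-index is the Shannon entropy over
occupied (species, zone) cells, so it grows with both species mixing and
vertical layering; its ceiling is ln(3 S) for S species present.

Zone boundaries use strict inequality upward: a height exactly at 0.8 H* or
0.5 H* falls in the lower zone. Zones are computed per plot against the
plot's own tallest individual, and sites are summarized as the mean +/- SD
of plot-level A values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .errors import DomainError
from .inventory import Chronosequence, StemRecord

logger = logging.getLogger(__name__)

ZONES = ("I", "II", "III")

#: Fixed zone capacity in the a_max ceiling, irrespective of occupancy.
N_ZONES = 3


def assign_zones(records: Sequence[StemRecord]) -> pd.DataFrame:
    """Species x zone occupancy counts for one scope (typically a plot).

    With H* the maximum height in scope: zone I if h > 0.8 H*, zone II if
    0.5 H* < h <= 0.8 H*, zone III otherwise. The tallest individual always
    lands in zone I.
    """
    if not records:
        raise DomainError("cannot assign height zones in an empty scope")
    h_star = max(r.height_m for r in records)
    species = sorted({r.species for r in records})
    counts = pd.DataFrame(0, index=species, columns=list(ZONES))
    for r in records:
        if r.height_m > 0.8 * h_star:
            zone = "I"
        elif r.height_m > 0.5 * h_star:
            zone = "II"
        else:
            zone = "III"
        counts.loc[r.species, zone] += 1
    return counts


def a_index(records: Sequence[StemRecord]) -> float:
    """Shannon entropy (nats) over occupied (species, zone) cells."""
    counts = assign_zones(records).to_numpy().ravel()
    return float(_scipy_entropy(counts[counts > 0]))


@dataclass(frozen=True)
class VerticalProfile:
    """A-index of one plot with its occupancy table and ceiling."""

    scope: str
    zone_counts: pd.DataFrame
    a_index: float
    a_max: float
    reference_height_m: float


def plot_profile(scope: str, records: Sequence[StemRecord]) -> VerticalProfile:
    counts = assign_zones(records)
    occ = counts.to_numpy().ravel()
    a = float(_scipy_entropy(occ[occ > 0]))
    s = int((counts.sum(axis=1) > 0).sum())
    return VerticalProfile(
        scope=scope,
        zone_counts=counts,
        a_index=a,
        a_max=math.log(N_ZONES * s),
        reference_height_m=max(r.height_m for r in records),
    )


def site_a_summary(chrono: Chronosequence) -> pd.DataFrame:
    """Per-site mean and sample SD (n-1) of plot-level A-index values.

    Empty plots are skipped with a log warning; a site with no non-empty
    plots gets NaN summaries. Returns one row per site with columns
    ``n_plots``, ``mean_a``, ``sd_a``.
    """
    rows = []
    for site in chrono.sites:
        values = []
        for plot in site.plots:
            if not plot.records:
                logger.warning(
                    "site %s plot %s is empty; skipped in A-index summary",
                    site.label,
                    plot.plot_id,
                )
                continue
            values.append(a_index(plot.records))
        if values:
            arr = np.asarray(values)
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        else:
            mean = sd = float("nan")
        rows.append(
            {"site": site.label, "n_plots": len(values), "mean_a": mean, "sd_a": sd}
        )
    return pd.DataFrame(rows).set_index("site")
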