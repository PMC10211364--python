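"""Stem-level inventory data model, delimited-table I/O, and per-hectare aggregation.

The census unit is one woody individual with basal diameter ``d_0.10``
(measured 10 cm above ground) of at least 1 cm. Individuals are grouped into
fixed-area plots (40 m x 40 m by default), plots into site conditions labelled
by years since land abandonment, and sites into an ordered chronosequence.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInventoryError, InventoryFormatError

logger = logging.getLogger(__name__)

#: Census inclusion rule: minimum basal diameter in cm at 10 cm above ground.
CENSUS_MIN_DIAMETER_CM = 1.0

#: Default plot area in m^2 (a 40 m x 40 m square).
DEFAULT_PLOT_AREA_M2 = 1600.0

#: Canonical column names of the flat stem-table format.
CANONICAL_COLUMNS = ("site", "plot", "species", "basal_diameter_cm", "height_m")

_WS = re.compile(r"\s+")


def normalize_species(name: str) -> str:
    """Trim and collapse internal whitespace in a species binomial."""
    return _WS.sub(" ", name.strip())


@dataclass(frozen=True)
class StemRecord:
    """One censused woody individual.

    Parameters
    ----------
    species : str
        Binomial name as recorded in the field (no synonym resolution).
    basal_diameter_cm : float
        Basal diameter ``d_0.10`` in cm; must satisfy the 1 cm census rule.
    height_m : float
        Total height in m; strictly positive.
    """

    species: str
    basal_diameter_cm: float
    height_m: float

    def __post_init__(self) -> None:
        name = normalize_species(self.species)
        if not name:
            raise DomainError("species name is empty")
        object.__setattr__(self, "species", name)
        if not self.basal_diameter_cm >= CENSUS_MIN_DIAMETER_CM:
            raise DomainError(
                f"basal diameter {self.basal_diameter_cm!r} cm violates the "
                f">= {CENSUS_MIN_DIAMETER_CM} cm census rule"
            )
        if not self.height_m > 0:
            raise DomainError(f"height {self.height_m!r} m must be positive")


@dataclass
class PlotInventory:
    """A fixed-area sampling plot and its stem records."""

    plot_id: str
    records: list[StemRecord] = field(default_factory=list)
    area_m2: float = DEFAULT_PLOT_AREA_M2

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise DomainError(f"plot area must be positive, got {self.area_m2!r}")
        if not self.records:
            logger.debug("plot %s has no records", self.plot_id)


@dataclass
class SiteCondition:
    """All plots sharing one years-of-abandonment condition."""

    label: str
    plots: list[PlotInventory]

    def __post_init__(self) -> None:
        if not self.plots:
            raise DomainError(f"site {self.label!r} has no plots")
        areas = {p.area_m2 for p in self.plots}
        if len(areas) != 1:
            raise DomainError(f"site {self.label!r} mixes plot areas {sorted(areas)}")
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise DomainError(f"site {self.label!r} has duplicate plot ids")

    @property
    def area_m2(self) -> float:
        """Total sampled area of the site in m^2."""
        return sum(p.area_m2 for p in self.plots)

    @property
    def records(self) -> list[StemRecord]:
        """All stem records pooled across the site's plots."""
        return [r for p in self.plots for r in p.records]


@dataclass
class Chronosequence:
    """Sites ordered by years of abandonment (labels are ordered categories)."""

    sites: list[SiteCondition]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise DomainError("site labels must be unique")

    @property
    def site_labels(self) -> list[str]:
        return [s.label for s in self.sites]

    def site(self, label: str) -> SiteCondition:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass
class AbundanceMatrix:
    """Per-hectare stem density (N ha^-1), sites x species.

    The species axis is the union over sites, zero-filled where a species is
    absent. Rows conserve total density: the row sum equals the site's total
    record count divided by the site area, scaled to one hectare.
    """

    site_labels: list[str]
    species_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_labels), len(self.species_names)):
            raise DomainError("abundance matrix shape does not match labels")
        if (self.values < 0).any():
            raise DomainError("abundance values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.site_labels, columns=self.species_names
        )

    def row(self, label: str) -> np.ndarray:
        return self.values[self.site_labels.index(label)]


def _resolve_columns(
    header: Sequence[str], config: Mapping[str, str] | None
) -> dict[str, str]:
    mapping = {c: c for c in CANONICAL_COLUMNS}
    if config:
        mapping.update({k: v for k, v in config.items() if k in mapping})
    for logical, actual in mapping.items():
        if actual not in header:
            raise InventoryFormatError(
                f"required column {actual!r} (for {logical!r}) missing from header"
            )
    return mapping


def read_inventory(
    path: str | Path,
    config: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> Chronosequence:
    """Read a flat delimited stem table into a validated :class:`Chronosequence`.

    The file must carry a header with site, plot, species, diameter and height
    columns; ``config`` remaps logical names to actual header names. Rows
    below the 1 cm basal-diameter census threshold are dropped with a warning
    carrying the dropped count. Comma and tab delimiters are auto-detected
    when ``delimiter`` is not given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise EmptyInventoryError(f"{path} has no header or data") from None
    mapping = _resolve_columns(list(df.columns), config)
    if df.empty:
        raise EmptyInventoryError(f"{path} contains a header but no records")

    for logical in ("basal_diameter_cm", "height_m"):
        col = mapping[logical]
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise InventoryFormatError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = numeric

    sub = df[mapping["basal_diameter_cm"]] < CENSUS_MIN_DIAMETER_CM
    n_excluded = int(sub.sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} record(s) below the "
            f"{CENSUS_MIN_DIAMETER_CM} cm basal-diameter census threshold",
            stacklevel=2,
        )
        df = df[~sub]
    if df.empty:
        raise EmptyInventoryError(f"{path} has no records passing the census rule")

    sites: list[SiteCondition] = []
    for site_label, site_df in df.groupby(mapping["site"], sort=False):
        plots = []
        for plot_id, plot_df in site_df.groupby(mapping["plot"], sort=False):
            records = [
                StemRecord(
                    species=row[mapping["species"]],
                    basal_diameter_cm=float(row[mapping["basal_diameter_cm"]]),
                    height_m=float(row[mapping["height_m"]]),
                )
                for _, row in plot_df.iterrows()
            ]
            plots.append(PlotInventory(plot_id=str(plot_id), records=records))
        sites.append(SiteCondition(label=str(site_label), plots=plots))
    return Chronosequence(sites=sites)


def write_inventory(
    chrono: Chronosequence, path: str | Path, *, delimiter: str = ","
) -> Path:
    """Write a chronosequence back to the flat delimited stem-table format.

    Round-trip guarantee: reading the written file reproduces the record
    multiset of every plot (row order is not part of the contract).
    """
    path = Path(path)
    rows = [
        {
            "site": site.label,
            "plot": plot.plot_id,
            "species": rec.species,
            "basal_diameter_cm": rec.basal_diameter_cm,
            "height_m": rec.height_m,
        }
        for site in chrono.sites
        for plot in site.plots
        for rec in plot.records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False)
    return path


def pooled_abundance(chrono: Chronosequence) -> AbundanceMatrix:
    """Aggregate a chronosequence into a sites x species N ha^-1 matrix.

    density(site, sp) = records of sp across the site's plots
    / total site plot area (m^2) * 10^4.

    Species are matched case-insensitively after whitespace normalization;
    the first-seen spelling is kept. Columns are sorted alphabetically.
    """
    canonical: dict[str, str] = {}  # casefolded key -> first-seen spelling
    counts: list[Counter] = []
    for site in chrono.sites:
        c: Counter = Counter()
        for rec in site.records:
            key = rec.species.casefold()
            canonical.setdefault(key, rec.species)
            c[key] += 1
        counts.append(c)
    keys = sorted(canonical, key=lambda k: canonical[k].casefold())
    species = [canonical[k] for k in keys]
    values = np.zeros((len(chrono.sites), len(species)))
    for i, (site, c) in enumerate(zip(chrono.sites, counts)):
        scale = 1e4 / site.area_m2
        for j, k in enumerate(keys):
            values[i, j] = c[k] * scale
    return AbundanceMatrix(
        site_labels=list(chrono.site_labels), species_names=species, values=values
    )


def abundance_from_frame(df: pd.DataFrame) -> AbundanceMatrix:
    """Build an :class:`AbundanceMatrix` from a species x site density table.

    ``df`` holds species as rows and site labels as columns with N ha^-1
    values (missing entries are treated as zero). This is the entry point for
    published per-site density tables, which lack stem-level detail but
    support every composition-only stage of the pipeline (diversity,
    similarity, clustering).
    """
    values = df.fillna(0.0).to_numpy(dtype=float).T
    return AbundanceMatrix(
        site_labels=[str(c) for c in df.columns],
        species_names=[normalize_species(str(i)) for i in df.index],
        values=values,
    )
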