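"""Bundled reference dataset: published thornscrub chronosequence densities.

The table holds per-species absolute stem densities (N ha^-1) for four
Tamaulipan thornscrub sites abandoned for 10, 20, 30 and more than 30
years, censused with four 40 m x 40 m plots per site (all woody stems with
basal diameter >= 1 cm at 10 cm above ground). Species names are stored
exactly as published — no synonym or spelling reconciliation is attempted.
Blank cells mean the species was not recorded at the site and are loaded as
zero.

These pooled densities support every composition-only analysis in the
package (richness, Shannon diversity, effective species, Bray-Curtis
similarity, UPGMA clustering); stem-level analyses (vertical structure,
volume, per-plot comparisons) need an individual-level inventory instead.
"""

from __future__ import annotations

import io

import pandas as pd

from .inventory import AbundanceMatrix, abundance_from_frame

SITE_LABELS = ("10", "20", "30", ">30")

_DENSITIES_CSV = """\
species,10,20,30,>30
A. amentacea,70.31,,,215.63
A. farnesiana,1415.63,931.25,459.38,156.25
A. rigidula,,,7.81,
B. myricifolia,,,,1.56
C. boissieri,,20.31,4.69,185.94
C. erecta,,,26.56,4.69
C. hookeri,,,,51.56
C. mexicana,,23.44,,
C. pallida,,29.69,17.19,28.13
D. texana,,,45.31,429.69
E. ebano,,4.69,,31.25
E. polystachya,,,,54.69
F. angustifolia,,15.63,,4.69
G. angustifolium,,1.56,,6.25
H. pallens,9.38,28.13,,434.38
H. parvifolia,,3.13,,31.25
K. spinosa,,,9.38,
L. frutescens,,,,1.56
M. monancistra,,1.56,,
P. aculeata,,,20.31,
P. laevigata,,85.94,90.63,20.31
P. texana,,,31.25,31.25
R. obcordata,,4.69,,3.13
S. celastrinum,,7.81,28.13,78.13
Y. filifera,,,,4.69
Z. fagara,4.69,,21.88,53.13
"""


def survey_densities() -> pd.DataFrame:
    """Species x site table of published densities (N ha^-1), zeros filled."""
    df = pd.read_csv(io.StringIO(_DENSITIES_CSV), index_col="species")
    return df.fillna(0.0)


def survey_abundance() -> AbundanceMatrix:
    """The published density table as a sites x species AbundanceMatrix."""
    return abundance_from_frame(survey_densities())
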