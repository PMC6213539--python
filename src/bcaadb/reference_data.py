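"""Published reference values for a CIQUAL-based BCAA database.

Holds the published method-by-group compilation counts of the
2012-vintage French food table whose amino-acid annexe this package's
compiler reimplements, together with the published content-category
breaks and intake-quartile cut-offs (the latter live in
:mod:`bcaadb.survey` as defaults).  These serve as inputs for summary
arithmetic and as canonical defaults — the underlying item-level tables
are licensed and are not shipped.
"""

from __future__ import annotations

import pandas as pd

from bcaadb.compiler import CompilationReport

#: Method-by-group compilation counts of the published database
#: (columns: methods 1-5 then not compiled; rows: the ten food groups).
PUBLISHED_COMPILATION_COUNTS = {
    "Dairy products and cheese":                 (190, 0, 0,   6,   0,  0),
    "Vegetables, fruits":                        (177, 3, 2,   5,   0, 22),
    "Cereals and pasta":                         (178, 0, 1,  14,   0, 11),
    "Meat, poultry, and fish":                   (248, 4, 3,  13,   0,  5),
    "Sugars and confectioneries":                ( 28, 0, 0,   4,   2,  4),
    "Fats and oils":                             ( 16, 0, 0,   0,  25,  3),
    "Beverages":                                 ( 49, 0, 0,   8, 117, 33),
    "Sauces and condiments":                     ( 38, 0, 0,  13,   7,  7),
    "Mixed dishes and soups":                    ( 67, 0, 0, 111,   0, 16),
    "Items for particular nutritional uses":     (  2, 0, 0,   0,   0,  8),
}

#: Published mean daily total-BCAA intakes (g/day) by sex in the adult
#: multi-country survey the database was evaluated on.
PUBLISHED_MEAN_INTAKE_G_DAY = {"male": 13.84, "female": 12.91}


def published_report() -> CompilationReport:
    """The published compilation counts as a :class:`CompilationReport`."""
    counts = pd.DataFrame.from_dict(
        PUBLISHED_COMPILATION_COUNTS,
        orient="index",
        columns=list(CompilationReport.COLUMNS),
    )
    return CompilationReport.from_counts(counts)
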