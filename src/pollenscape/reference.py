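"""Published reference figures shipped with the package.

The severity percentages reported for the five studied cities (Barcelona,
Montreal, New York City, Paris, Vancouver) across the nine allergenicity
sources are bundled so the worked examples — the high-severity range of a
city, the moderate+low share under one source — can be recomputed without
downloading any municipal inventory.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .tabulation import SeverityTable

__all__ = ["published_percentages", "published_severity_table"]


def published_percentages() -> pd.DataFrame:
    """City × dataset rounded severity percentages, long format.

    Columns: city, severity (high/moderate/low/not_reported), then one
    integer-percent column per source (AAAAI .. RNSA).
    """
    text = (
        resources.files("pollenscape.data")
        .joinpath("published_percentages.csv")
        .read_text(encoding="utf-8")
    )
    return pd.read_csv(io.StringIO(text))


def published_severity_table() -> SeverityTable:
    """The published percentages as a :class:`SeverityTable` (rounded input)."""
    return SeverityTable.from_percent_rows(published_percentages())
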