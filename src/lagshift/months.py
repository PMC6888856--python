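"""Calendar helpers.

All stages exchange dates as integer month indices anchored at January 1982
(month 0), the start of the Landsat 4--8 monitoring era, and serialize them
as ISO ``YYYY-MM`` strings.
"""

from __future__ import annotations

import numpy as np

BASE_YEAR = 1982
#: First month (index) kept after a >=5-year-gap truncation: January 1999.
TRUNCATION_MONTH = (1999 - BASE_YEAR) * 12


def ym_to_index(ym: str) -> int:
    """Convert an ISO ``YYYY-MM`` string to months since Jan 1982."""
    year, month = ym.split("-")
    m = int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return (int(year) - BASE_YEAR) * 12 + (m - 1)


def index_to_ym(idx: int) -> str:
    """Convert a month index back to ``YYYY-MM``."""
    idx = int(idx)
    year, month = divmod(idx, 12)
    return f"{BASE_YEAR + year:04d}-{month + 1:02d}"


def index_to_ym_array(idx) -> np.ndarray:
    return np.array([index_to_ym(i) for i in np.asarray(idx, dtype=int)])
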