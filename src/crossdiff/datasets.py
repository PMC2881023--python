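"""Small reference datasets bundled with the package."""

from __future__ import annotations

from .scoring import TwoWayTable

#: Published 5×5 collective-score table from the four-strain rat TCDD liver
#: study this scoring scheme was developed on: 8605 genes tallied by
#: (resistant-collective score −2..2, sensitive-collective score −2..2) at
#: an adjusted-p threshold of 0.01. Used as a worked example and as ground
#: truth for the derived-count arithmetic.
PUBLISHED_TWO_WAY_GRID = (
    (5, 1, 1, 0, 0),
    (14, 18, 7, 0, 0),
    (26, 177, 8153, 94, 17),
    (0, 0, 30, 12, 26),
    (0, 0, 2, 2, 20),
)

#: The overlap proportions reported alongside the table: 31 of 138
#: resistant-collective responders overlapped within that collective,
#: 108 of 412 in the sensitive collective.
PUBLISHED_OVERLAP_COUNTS = {"resistant": (31, 138), "sensitive": (108, 412)}


def published_two_way_table() -> TwoWayTable:
    """The published 8605-gene two-way score table as a :class:`TwoWayTable`."""
    return TwoWayTable.from_grid(PUBLISHED_TWO_WAY_GRID)
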