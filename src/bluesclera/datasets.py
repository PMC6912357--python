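"""Bundled example data.

The package ships the 2×2 grading counts of a 67-patient pilot cohort of
inpatients with suspected iron deficiency: three physicians independently
graded scleral blueness on anonymized photographs (1 absent … 4 striking;
grade ≥ 3 read as "blue"), cross-classified against serum-marker ID
status.  The consensus table applies the two-of-three rule.  These counts
let the whole metric battery run offline in milliseconds.
"""

from __future__ import annotations

import json
from importlib import resources

from .diagnostics import ContingencyTable2x2

__all__ = ["load_physician_counts"]


def load_physician_counts() -> dict[str, ContingencyTable2x2]:
    """The bundled 2×2 tables, keyed ``r1``, ``r2``, ``r3``, ``consensus``."""
    raw = json.loads(
        resources.files("bluesclera.data").joinpath("physician_counts.json").read_text()
    )
    return {
        rule: ContingencyTable2x2(**counts) for rule, counts in raw["tables"].items()
    }
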