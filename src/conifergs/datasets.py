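"""Bundled worked-example inputs.

Per-generation genetic gains (trait units: mm DBH for the h2 = 0.2 trait,
kg/m^3 wood density for h2 = 0.5) from a full-scale stochastic simulation
of a radiata-pine-style breeding program with a 60K-equivalent SNP panel.
They serve as injected inputs for the per-year and deployment accounting
tables, so the calendar arithmetic can be exercised and regression-tested
without re-running the multi-hour simulation.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_gains"]

_ROWS = [
    # h2, training size, GS gain/generation, FS gain/generation
    (0.2, 800, 4.22, 19.13),
    (0.2, 1000, 10.47, 19.13),
    (0.2, 2000, 14.23, 19.13),
    (0.2, 3000, 16.02, 19.13),
    (0.5, 800, 18.90, 21.30),
    (0.5, 1000, 19.21, 21.30),
    (0.5, 2000, 21.97, 21.30),
    (0.5, 3000, 24.20, 21.30),
]


def example_gains() -> pd.DataFrame:
    """Worked-example per-generation gains by heritability and training size."""
    return pd.DataFrame(_ROWS, columns=["h2", "training_size", "GS", "FS"])
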