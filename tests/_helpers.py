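"""Shared builders for hand-crafted band-power tables."""

import numpy as np
import pandas as pd

from raseeg.bands import BAND_NAMES
from raseeg.montage import MONTAGE_1020
from raseeg.windowing import BandPowerTable


def make_table(values_by_cell, n_rows=2, channels=MONTAGE_1020,
               participants=("p0",)):
    """Normalized band-power table with explicit cell values.

    ``values_by_cell`` maps ``"{channel}_{band}"`` to a scalar or length-
    ``n_rows`` array; unspecified cells are 1.0. Rows are split evenly over
    ``participants``.
    """
    cols = [f"{c}_{b}" for c in channels for b in BAND_NAMES]
    per = n_rows // len(participants)
    pid = np.repeat(list(participants), per)[:n_rows]
    idx = pd.MultiIndex.from_arrays([pid, np.arange(n_rows)],
                                    names=["participant_id", "frame_index"])
    data = pd.DataFrame(1.0, index=idx, columns=cols)
    for col, val in values_by_cell.items():
        data[col] = val
    meta = pd.DataFrame({"timestamp_s": np.arange(n_rows) / 30.0,
                         "error": [False] * n_rows}, index=idx)
    return BandPowerTable(data, meta, tuple(channels), BAND_NAMES,
                          normalized=True)
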