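"""Wide/long reshaping and held-out masking of a wave-item.

The imputation design requires the cohort in long format (one row per
participant per wave) so cross-wave covariance can inform a variable that
is completely missing at one wave.  Masking sets the chosen variable to
missing at the chosen wave and retains the held-out truth in a
:class:`MaskRecord`, so evaluation can run in a separate process from
imputation.

Missing cells are represented by NaN (the column is promoted to float);
ordinal code 0 is a legitimate response and is never overloaded as a
missing sentinel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import columns as C

__all__ = [
    "to_long",
    "to_wide",
    "mask_wave_item",
    "unmask",
    "filter_complete_waves",
    "MaskRecord",
]

log = logging.getLogger(__name__)

_WAVE_SUFFIX = {"W1": "_w1", "W2": "_w2"}


def to_wide(long_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a two-wave long table to one row per participant.

    Wave-varying variables get ``_w1`` / ``_w2`` suffixes; demographics,
    which are time-invariant, keep their names.  Exact inverse of
    :func:`to_long`.
    """
    counts = long_table.groupby(C.PID)[C.WAVE].nunique()
    if (counts != 2).any():
        bad = counts.index[counts != 2][:5].tolist()
        raise ValueError(f"participants missing a wave: {bad}")
    base_cols = [C.PID] + list(C.DEMOGRAPHICS)
    varying = [c for c in long_table.columns if c not in base_cols + [C.WAVE]]

    out = None
    for wave, suffix in _WAVE_SUFFIX.items():
        sub = long_table.loc[long_table[C.WAVE] == wave].set_index(C.PID)
        block = sub[varying].add_suffix(suffix)
        if out is None:
            demo = sub[base_cols[1:]]
            out = pd.concat([demo, block], axis=1)
        else:
            out = out.join(block)
    return out.reset_index().sort_values(C.PID, ignore_index=True)


def to_long(wide_table: pd.DataFrame) -> pd.DataFrame:
    """Append the waves: one row per participant per wave.

    Expects wave-suffixed variable names (``*_w1``, ``*_w2``) plus
    unsuffixed time-invariant columns.  ``to_wide(to_long(x))`` is
    bit-exact.
    """
    suffixed = [c for c in wide_table.columns if c.endswith(("_w1", "_w2"))]
    stems = sorted({c[:-3] for c in suffixed})
    if not stems:
        raise ValueError("no wave-suffixed columns found")
    for stem in stems:
        for sfx in ("_w1", "_w2"):
            if stem + sfx not in wide_table.columns:
                raise ValueError(f"column {stem + sfx} missing from wide table")
    base_cols = [c for c in wide_table.columns if c not in suffixed]

    frames = []
    for wave, suffix in _WAVE_SUFFIX.items():
        block = wide_table[base_cols].copy()
        block.insert(1, C.WAVE, wave)
        for stem in stems:
            block[stem] = wide_table[stem + suffix].to_numpy()
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values([C.PID, C.WAVE], kind="stable", ignore_index=True)
    known = [c for c in C.ALL_VARIABLES if c in out.columns]
    extra = [c for c in out.columns if c not in known]
    return out[known + extra]


def filter_complete_waves(long_table: pd.DataFrame, required=None) -> pd.DataFrame:
    """Drop participants with a wave absent or fully missing.

    A wave counts as fully missing when every ``required`` column (default:
    the 9 depression items) is missing in that row.  The exclusion is
    logged with the participant count, mirroring an explicit cohort-
    eligibility filter.
    """
    required = list(required or C.PHQ_ITEMS)
    counts = long_table.groupby(C.PID)[C.WAVE].nunique()
    incomplete = set(counts.index[counts < 2])
    all_missing = long_table[required].isna().all(axis=1)
    incomplete |= set(long_table.loc[all_missing, C.PID])
    if incomplete:
        log.info("excluding %d participants with a missing wave", len(incomplete))
    keep = ~long_table[C.PID].isin(incomplete)
    return long_table.loc[keep].reset_index(drop=True)


@dataclass
class MaskRecord:
    """Held-out truth for one masked variable at one wave."""

    variable: str
    wave: str
    pids: list
    truth: list

    def __post_init__(self):
        if len(self.pids) != len(self.truth):
            raise ValueError("truth length must equal number of masked rows")

    def truth_series(self) -> pd.Series:
        return pd.Series(self.truth, index=pd.Index(self.pids, name=C.PID))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "variable": self.variable,
                    "wave": self.wave,
                    "pids": list(self.pids),
                    "truth": [None if pd.isna(v) else v for v in self.truth],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "MaskRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["variable"], d["wave"], d["pids"], d["truth"])


def mask_wave_item(
    table: pd.DataFrame, variable: str, wave: str
) -> tuple[pd.DataFrame, MaskRecord]:
    """Set ``variable`` to missing at every row of ``wave``.

    Returns the masked copy (only those cells differ from the input) and a
    :class:`MaskRecord` holding the original values, which restores the
    input exactly via :func:`unmask`.
    """
    if variable not in table.columns:
        raise KeyError(f"variable {variable!r} not in table")
    rows = table[C.WAVE] == wave
    if not rows.any():
        raise ValueError(f"wave {wave!r} not present in table")
    if table.loc[rows, variable].isna().any():
        raise ValueError(f"{variable!r} already missing at wave {wave!r}")
    masked = table.copy()
    truth = table.loc[rows, variable]
    masked[variable] = masked[variable].astype(float)
    masked.loc[rows, variable] = np.nan
    record = MaskRecord(
        variable=variable,
        wave=wave,
        pids=table.loc[rows, C.PID].tolist(),
        truth=[v.item() if hasattr(v, "item") else v for v in truth.tolist()],
    )
    return masked, record


def unmask(masked: pd.DataFrame, record: MaskRecord) -> pd.DataFrame:
    """Reapply the held-out truth, restoring the pre-mask table exactly."""
    out = masked.copy()
    rows = out[C.WAVE] == record.wave
    if int(rows.sum()) != len(record.pids):
        raise ValueError("mask record does not match the table's wave rows")
    if not (out.loc[rows, C.PID].tolist() == list(record.pids)):
        raise ValueError("participant ids do not match the mask record")
    out.loc[rows, record.variable] = record.truth
    col = out[record.variable]
    if not col.isna().any() and np.allclose(np.asarray(col, dtype=float) % 1, 0):
        out[record.variable] = col.astype(np.int64)
    return out
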