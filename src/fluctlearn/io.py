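"""Trial-table input/output.

The canonical on-disk format is a comma-separated, UTF-8 table with a
mandatory header and columns

    participant_id, block, cycle, trial_index, theta_deg, response_deg

one row per trial.  ``block`` is ``baseline`` (cycle 0, trial_index
counting from 1 inside the baseline) or ``main`` (cycle 1..C, trial_index
1..cycle_length).  Angles are written in degrees with 6 decimals; files
written by :func:`write_trials` round-trip byte-identically through
:func:`read_trials`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .protocol import Protocol
from .simulate import Trajectory

__all__ = ["REQUIRED_COLUMNS", "read_trials", "write_trials", "trials_from_run", "validate_trials"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["participant_id", "block", "cycle", "trial_index", "theta_deg", "response_deg"]
_BLOCKS = ("baseline", "main")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate required columns, blocks, indices and finiteness."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) == 0:
        return df
    bad_block = ~df["block"].isin(_BLOCKS)
    if bad_block.any():
        raise FormatError(f"unknown block label {df.loc[bad_block, 'block'].iloc[0]!r}")
    for col in ("theta_deg", "response_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise FormatError(f"non-numeric {col} at line {line}")
        df[col] = vals.astype(float)
    if (df["trial_index"].astype(int) < 1).any():
        raise FormatError("trial_index must be >= 1")
    return df


def read_trials(path) -> pd.DataFrame:
    """Read a trial table; unknown columns are preserved."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    df = validate_trials(df)
    if len(df) == 0:
        logger.warning("trial file %s contains a header but no rows", path)
        return df
    df["participant_id"] = df["participant_id"].astype(str)
    df["cycle"] = df["cycle"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical dialect (angles to 6 decimals)."""
    df = validate_trials(df.copy())
    cols = REQUIRED_COLUMNS + [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df = df[cols]
    df.to_csv(path, index=False, float_format="%.6f")


def trials_from_run(protocol: Protocol, trajectory: Trajectory) -> pd.DataFrame:
    """Tabulate a protocol-aligned trajectory in the canonical trial format."""
    xs = trajectory.responses
    if xs.size != protocol.n_trials:
        raise InvalidInputError(
            f"trajectory length {xs.size} does not match protocol length {protocol.n_trials}"
        )
    nb = protocol.baseline_length
    cl = protocol.cycle_length
    blocks = ["baseline"] * nb + ["main"] * (protocol.n_cycles * cl)
    cycles = [0] * nb + [c for c in range(1, protocol.n_cycles + 1) for _ in range(cl)]
    idx = list(range(1, nb + 1)) + list(range(1, cl + 1)) * protocol.n_cycles
    return pd.DataFrame(
        {
            "participant_id": trajectory.participant_id,
            "block": blocks,
            "cycle": cycles,
            "trial_index": idx,
            "theta_deg": protocol.thetas,
            "response_deg": xs,
        }
    )
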