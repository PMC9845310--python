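"""Hysteresis, adaptation-level summaries, and the randomized control.

Hysteresis is the signature of imperfect (lagging) adaptation: responses
at the same imposed angle differ depending on whether the angle was
reached through the forward or the backward segment.  The table pairs
forward position ``k`` with backward position ``L + 1 - k`` (``L`` the
segment length), which are exposed to the same true angle because the
backward segment replays the forward angles in reverse.

The adaptation fraction is the through-origin regression slope of mean
response on imposed angle over the forward positions, after centring
responses on the participant's bias and angles on the washout reference;
1.0 is full adaptation, 0.0 none, and at least 0.5 (inclusive) marks a
well-adapted participant.

The randomized control destroys the temporal structure that the
fluctuation theorems rely on while preserving each participant's marginal
response distribution: main-block responses are resampled i.i.d. with
replacement within participant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidInputError
from .protocol import Protocol
from .simulate import Trajectory

__all__ = [
    "trajectory_from_trials",
    "hysteresis_table",
    "adaptation_fraction",
    "randomized_control",
]

logger = logging.getLogger(__name__)


def _single_participant(records: pd.DataFrame) -> str:
    ids = records["participant_id"].unique()
    if ids.size != 1:
        raise InvalidInputError(
            f"expected records of a single participant, got {ids.size}; group first"
        )
    return str(ids[0])


def _ordered(records: pd.DataFrame) -> pd.DataFrame:
    key = records["block"].map({"baseline": 0, "main": 1})
    return records.assign(_k=key).sort_values(["_k", "cycle", "trial_index"]).drop(columns="_k")


def trajectory_from_trials(
    records: pd.DataFrame, protocol: Protocol, participant_id: str | None = None
) -> Trajectory:
    """Reassemble a protocol-aligned trajectory from trial records."""
    if participant_id is not None:
        records = records[records["participant_id"] == participant_id]
    pid = _single_participant(records)
    rec = _ordered(records)
    if len(rec) != protocol.n_trials:
        raise InvalidInputError(
            f"{len(rec)} records do not match protocol length {protocol.n_trials}"
        )
    return Trajectory(
        responses=rec["response_deg"].to_numpy(dtype=float),
        source="observed",
        participant_id=pid,
    )


def _complete_cycles(records: pd.DataFrame, protocol: Protocol) -> pd.DataFrame:
    main = records[records["block"] == "main"]
    if len(main) == 0:
        raise DegenerateDataError("no main-block records")
    counts = main.groupby("cycle")["trial_index"].nunique()
    good = counts[counts == protocol.cycle_length].index
    dropped = counts.index.difference(good)
    if len(dropped) > 0:
        logger.warning("skipping incomplete cycles: %s", list(dropped))
    if len(good) == 0:
        raise DegenerateDataError("no complete cycles")
    return main[main["cycle"].isin(good)]


def hysteresis_table(records: pd.DataFrame, protocol: Protocol) -> pd.DataFrame:
    """Mean forward vs mirrored-backward response per forward position.

    Columns: ``position`` (1-based within the forward segment),
    ``theta_deg`` (the true angle at that position), ``forward_mean``,
    ``backward_mean`` (at the mirrored backward position, same true
    angle), and their ``difference``.  Means are taken across all complete
    cycles in ``records`` (single participant or pooled cohort).
    """
    main = _complete_cycles(records, protocol)
    f_lo, f_hi = protocol.forward_range
    b_lo, _ = protocol.backward_range
    L = protocol.segment_length
    mean_by_index = main.groupby("trial_index")["response_deg"].mean()
    rows = []
    for j in range(1, L + 1):
        t_f = f_lo - 1 + j
        t_b = b_lo - 1 + (L + 1 - j)
        theta = protocol.cycle_angles[t_f - 1]
        fm = mean_by_index[t_f]
        bm = mean_by_index[t_b]
        rows.append((j, theta, fm, bm, fm - bm))
    return pd.DataFrame(
        rows, columns=["position", "theta_deg", "forward_mean", "backward_mean", "difference"]
    )


def adaptation_fraction(
    records: pd.DataFrame, protocol: Protocol, bias: float | None = None
) -> float:
    """Fraction of the imposed rotation tracked by the mean response.

    Through-origin least-squares slope of centred mean response on centred
    imposed angle across forward-segment positions.  Responses are centred
    on ``bias`` (baseline mean when absent), angles on the washout
    reference angle, so the measure is invariant under a joint shift of
    all responses and angles.
    """
    pid = _single_participant(records)
    main = _complete_cycles(records, protocol)
    f_lo, f_hi = protocol.forward_range
    b_lo, b_hi = protocol.backward_range
    plateau_idx = [
        i
        for i in range(1, protocol.cycle_length + 1)
        if not (f_lo <= i <= f_hi or b_lo <= i <= b_hi)
    ]
    plat = main[main["trial_index"].isin(plateau_idx)]
    base = records[records["block"] == "baseline"]
    if bias is None:
        if len(base) > 0:
            bias = float(base["response_deg"].mean())
        else:
            bias = float(plat["response_deg"].mean()) if len(plat) else 0.0

    fwd = main[(main["trial_index"] >= f_lo) & (main["trial_index"] <= f_hi)]
    means = fwd.groupby("trial_index")[["theta_deg", "response_deg"]].mean()

    ref_rows = base["theta_deg"] if len(base) else plat["theta_deg"]
    theta_ref = float(ref_rows.mean()) if len(ref_rows) else 0.0
    th = means["theta_deg"].to_numpy() - theta_ref
    resp = means["response_deg"].to_numpy() - bias
    denom = float(np.sum(th * th))
    if denom == 0.0:
        raise DegenerateDataError(
            f"adaptation fraction undefined for participant {pid}: flat protocol"
        )
    return float(np.sum(th * resp) / denom)


def randomized_control(records: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Resample each participant's main-block responses i.i.d. with replacement.

    The imposed-angle sequence and the baseline block are untouched;
    reproducible for a fixed integer seed.
    """
    if len(records) == 0:
        raise InvalidInputError("records must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = records.copy()
    for pid in out["participant_id"].unique():
        mask = (out["participant_id"] == pid) & (out["block"] == "main")
        vals = out.loc[mask, "response_deg"].to_numpy()
        out.loc[mask, "response_deg"] = rng.choice(vals, size=vals.size, replace=True)
    return out
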