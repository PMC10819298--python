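"""From OAA/S observation streams to the binary regained-response dataset.

The Observer's Assessment of Alertness/Sedation (OAA/S) scale scores a
patient 0-5; a score >= 4 means the patient responds (at most lethargically)
to their name spoken in a normal tone.  Regained response (RR) is declared
at the first pair of consecutive observations both scoring >= 4, and loss of
response (LOR) / RR anchor the binary labels used by both predictive models:
rows between LOR and RR are coded 0 (no response), rows from RR through a
post-RR observation window are coded 1 (responsive).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import DataConsistencyError, InvalidInputError, InvalidParameterError
from .pk import ConcentrationTrajectory

__all__ = ["detect_rr", "build_dataset", "LABELED_COLUMNS"]

LABELED_COLUMNS = ["patient_id", "time_min", "cep_ugml", "cer_ngml", "label"]

#: OAA/S score at or above which the patient counts as responsive.
RESPONSIVE_SCORE = 4


def detect_rr(times, scores, convention: str = "first") -> Optional[float]:
    """Time of regained response: two consecutive OAA/S scores >= 4.

    Parameters
    ----------
    times, scores : array-like
        One patient's strictly time-ordered observations; scores integers 0-5.
    convention : {"first", "second"}
        Whether RR is stamped at the first or the second observation of the
        earliest qualifying pair.  The first-of-pair stamp (default) takes
        the earliest evidence of sustained responsiveness.

    Returns
    -------
    float or None
        RR time in minutes, or None if no qualifying pair exists.
    """
    if convention not in ("first", "second"):
        raise InvalidParameterError(f"convention must be 'first' or 'second', got {convention!r}")
    t = np.asarray(times, dtype=float)
    s = np.asarray(scores)
    if t.size != s.size:
        raise InvalidInputError("times and scores must have equal length")
    if t.size == 0:
        raise InvalidInputError("no observations given")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("observations must be strictly time-ordered")
    if not np.all(np.isin(s, np.arange(6))):
        raise InvalidInputError("OAA/S scores must be integers in 0..5")
    ok = s >= RESPONSIVE_SCORE
    pair = np.flatnonzero(ok[:-1] & ok[1:])
    if pair.size == 0:
        return None
    i = int(pair[0])
    return float(t[i] if convention == "first" else t[i + 1])


def build_dataset(
    trajectories: Iterable[ConcentrationTrajectory],
    lor_times: Mapping[str, float],
    rr_times: Mapping[str, Optional[float]],
    post_rr_window: float = 10.0,
    scheme: str = "interval",
) -> pd.DataFrame:
    """Join concentration trajectories to binary response labels.

    For each patient, grid samples from LOR up to (not including) RR are
    labelled 0, samples from RR through ``RR + post_rr_window`` are labelled
    1, and samples outside ``[LOR, RR + window]`` (induction, late recovery)
    are excluded.  A patient with no detected RR contributes only 0-rows from
    LOR onward.

    ``scheme="interval"`` emits every qualifying grid sample (the default
    reconstruction, which on a fine grid yields the tens of thousands of
    concentration sets a per-case record produces); ``scheme="endpoints"``
    emits only the single sample at LOR as the 0 class, plus the post-RR
    1-rows, for an endpoint-anchored dataset.

    Returns a DataFrame with columns ``patient_id, time_min, cep_ugml,
    cer_ngml, label``; per-patient emitted row counts are stored in
    ``df.attrs["rows_per_patient"]``.
    """
    if scheme not in ("interval", "endpoints"):
        raise InvalidParameterError(f"scheme must be 'interval' or 'endpoints', got {scheme!r}")
    if post_rr_window < 0:
        raise InvalidParameterError("post_rr_window must be >= 0")

    frames = []
    counts: dict[str, int] = {}
    for traj in trajectories:
        pid = traj.patient_id
        if pid not in lor_times:
            raise DataConsistencyError(f"no LOR time for patient {pid!r}")
        lor = float(lor_times[pid])
        rr = rr_times.get(pid)
        t = traj.times
        if rr is None:
            mask0 = t >= lor
            mask1 = np.zeros_like(mask0)
        else:
            rr = float(rr)
            if rr <= lor:
                raise DataConsistencyError(
                    f"patient {pid!r}: RR time {rr} is not after LOR time {lor}"
                )
            mask0 = (t >= lor) & (t < rr)
            mask1 = (t >= rr) & (t <= rr + post_rr_window)
        if scheme == "endpoints":
            idx0 = np.flatnonzero(mask0)
            mask0 = np.zeros_like(mask0)
            if idx0.size:
                mask0[idx0[0]] = True
        keep = mask0 | mask1
        counts[pid] = int(keep.sum())
        if not np.any(keep):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "time_min": t[keep],
                    "cep_ugml": traj.cep[keep],
                    "cer_ngml": traj.cer[keep],
                    "label": mask1[keep].astype(int),
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame({c: pd.Series(dtype=float) for c in LABELED_COLUMNS})
        out["patient_id"] = out["patient_id"].astype(object)
        out["label"] = out["label"].astype(int)
    out.attrs["rows_per_patient"] = counts
    return out
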