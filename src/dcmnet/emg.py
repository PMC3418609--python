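"""Silent-period EMG quantification.

Each acquired volume contributes one 600-ms gradient-silent window; the EMG
trace is rectified and integrated over each window, the integrated values
are standardized within subject (interpreted z-normalization), and
per-condition summaries are the mean task score minus the mean rest score.
Multiple channels (e.g. flexor and extensor) are averaged at the
window-value level before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ALL_CONDITIONS, SILENT_WINDOW_S, silent_windows

__all__ = [
    "WindowValues",
    "integrate_windows",
    "normalize_scores",
    "condition_summary",
]


@dataclass(frozen=True)
class WindowValues:
    """Per-window integrated (and optionally normalized) EMG amplitudes."""

    values: np.ndarray
    windows: tuple  # matching SilentWindow sequence
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.windows):
            raise ValueError("one value per window required")
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("integrated rectified values must be non-negative")


def integrate_windows(trace, windows=None) -> WindowValues:
    """Rectify and integrate the trace over each silent window.

    ``trace`` is an :class:`~dcmnet.synthetic.EMGTrace` (or any object with
    ``signal``, ``rate`` and ``session``).  The value per window is
    mean(|signal|) * 0.6 s, i.e. the integral of the rectified signal.
    Multi-channel input (2-D signal, channels in columns) is averaged across
    channels window-wise.
    """
    if windows is None:
        windows = silent_windows(trace.session)
    signal = np.atleast_2d(np.asarray(trace.signal, dtype=float).T).T  # (T, ch)
    rate = float(trace.rate)
    run_offsets = {}
    acc = 0.0
    for ri, run in enumerate(trace.session.runs):
        run_offsets[ri] = acc
        acc += run.duration
    values = np.empty(len(windows))
    for i, w in enumerate(windows):
        t0 = run_offsets[w.run] + w.start
        i0 = int(round(t0 * rate))
        i1 = int(round((t0 + SILENT_WINDOW_S) * rate))
        if i0 < 0 or i1 > signal.shape[0]:
            raise ValueError(f"window {i} lies outside the trace")
        seg = np.abs(signal[i0:i1])
        values[i] = float(np.mean(seg)) * SILENT_WINDOW_S
    return WindowValues(values=values, windows=tuple(windows))


def normalize_scores(wv: WindowValues) -> WindowValues:
    """Within-subject standardization across all windows: (x - mean) / SD."""
    if len(wv.values) < 2:
        raise ValueError("need at least two windows to normalize")
    sd = np.std(wv.values)
    if sd == 0:
        raise ValueError("zero spread across windows")
    scores = (wv.values - np.mean(wv.values)) / sd
    return WindowValues(values=scores, windows=wv.windows, normalized=True)


def condition_summary(
    wv: WindowValues, collapse_direction: bool = False
) -> pd.Series:
    """Per-condition mean score minus mean rest score.

    Returns a Series keyed by condition name (8 conditions, or 4 after
    collapsing the rotation-direction factor).
    """
    rest = [v for v, w in zip(wv.values, wv.windows) if w.kind == "rest"]
    if not rest:
        raise ValueError("no rest windows present")
    rest_mean = float(np.mean(rest))
    out = {}
    for cond in ALL_CONDITIONS:
        vals = [
            v for v, w in zip(wv.values, wv.windows)
            if w.kind == "task" and w.condition == cond
        ]
        if not vals:
            raise ValueError(f"no windows for condition {cond.name}")
        out[cond.name] = float(np.mean(vals)) - rest_mean
    if collapse_direction:
        collapsed = {}
        for cond in ALL_CONDITIONS:
            key = cond.name.rsplit("/", 1)[0]
            collapsed.setdefault(key, []).append(out[cond.name])
        out = {k: float(np.mean(v)) for k, v in collapsed.items()}
    return pd.Series(out)
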