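"""Block-design construction: epoch schedules, boxcar inputs, silent windows.

The default design alternates rest and task epochs (24 s each, starting and
ending with rest, 9 rest + 8 task per run) at TR = 3 s, giving 136 volumes
per run.  A session concatenates six runs; the first ``discard`` volumes of
each run are dropped before analysis.  Three external inputs are modelled:
a task boxcar (on during every task epoch), an execution boxcar and a
hand-observation boxcar, each sampled at microtime resolution
(``bins_per_tr`` bins per TR).

Each 3-s volume ends with a 600-ms gradient-silent window used for EMG
sampling; windows are enumerated over *all* acquired volumes (no discard).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConditionLabel",
    "Epoch",
    "EpochSchedule",
    "SessionDesign",
    "InputMatrix",
    "SilentWindow",
    "ALL_CONDITIONS",
    "DEFAULT_EPOCH_S",
    "DEFAULT_TR",
    "DEFAULT_DISCARD",
    "DEFAULT_BINS_PER_TR",
    "SILENT_WINDOW_S",
    "build_run",
    "build_session",
    "default_session",
    "build_inputs",
    "silent_windows",
    "random_condition_orders",
]

DEFAULT_EPOCH_S = 24.0
DEFAULT_TR = 3.0
DEFAULT_DISCARD = 3
DEFAULT_RUNS = 6
DEFAULT_BINS_PER_TR = 16
SILENT_WINDOW_S = 0.6

INPUT_NAMES = ("task", "exec", "hand")


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One cell of the 2 (Execution) x 2 (Hand) x 2 (direction) crossing."""

    execution: bool
    hand: bool
    direction: str  # "cw" | "ccw"

    def __post_init__(self) -> None:
        if self.direction not in ("cw", "ccw"):
            raise ValueError(f"direction must be 'cw' or 'ccw', got {self.direction!r}")

    @property
    def name(self) -> str:
        return "{}/{}/{}".format(
            "Exec" if self.execution else "Obs",
            "Hand" if self.hand else "NoHand",
            self.direction,
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


#: The eight distinct task conditions, in a fixed canonical order.
ALL_CONDITIONS: tuple[ConditionLabel, ...] = tuple(
    ConditionLabel(execution=e, hand=h, direction=d)
    for e, h, d in itertools.product((True, False), (True, False), ("cw", "ccw"))
)


@dataclass(frozen=True)
class Epoch:
    kind: str  # "rest" | "task"
    condition: ConditionLabel | None
    duration: float  # seconds


@dataclass(frozen=True)
class EpochSchedule:
    """Schedule of one run: alternating rest/task epochs plus timing metadata."""

    epochs: tuple[Epoch, ...]
    tr: float
    discard_volumes: int = 0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        for ep in self.epochs:
            if ep.duration <= 0:
                raise ValueError("epoch durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(ep.duration for ep in self.epochs))

    @property
    def n_volumes(self) -> int:
        n = self.duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("run duration is not an integer number of volumes")
        return int(round(n))

    @property
    def n_retained(self) -> int:
        return self.n_volumes - self.discard_volumes

    def epoch_at(self, t: float) -> Epoch:
        """Epoch containing time ``t`` (seconds from run start, half-open bins)."""
        acc = 0.0
        for ep in self.epochs:
            acc += ep.duration
            if t < acc:
                return ep
        return self.epochs[-1]


@dataclass(frozen=True)
class SessionDesign:
    """Concatenation of several runs sharing one TR."""

    runs: tuple[EpochSchedule, ...]
    discard: int

    @property
    def tr(self) -> float:
        return self.runs[0].tr

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def total_volumes(self) -> int:
        return sum(r.n_volumes for r in self.runs)

    @property
    def retained_volumes(self) -> int:
        return sum(r.n_volumes - self.discard for r in self.runs)


@dataclass(frozen=True)
class InputMatrix:
    """Boxcar inputs at microtime resolution, rows = (task, exec, hand)."""

    u: np.ndarray  # (3, T_micro), values in {0, 1}
    bins_per_tr: int
    tr: float
    input_names: tuple[str, ...] = INPUT_NAMES

    @property
    def n_bins(self) -> int:
        return self.u.shape[1]

    def to_text(self, path) -> None:
        header = "\t".join(self.input_names)
        np.savetxt(path, self.u.T, fmt="%d", delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class SilentWindow:
    run: int
    volume: int  # volume index within run
    start: float  # seconds from run start
    end: float
    kind: str  # "rest" | "task"
    condition: ConditionLabel | None


def build_run(
    condition_order,
    epoch_s: float = DEFAULT_EPOCH_S,
    tr: float = DEFAULT_TR,
) -> EpochSchedule:
    """Build one run: rest/task alternation starting and ending with rest.

    Parameters
    ----------
    condition_order
        The 8 task conditions in presentation order; each of the 8 distinct
        labels must occur exactly once.
    epoch_s
        Epoch duration in seconds; must be an integer multiple of ``tr``.
    tr
        Volume repetition time in seconds.
    """
    order = tuple(condition_order)
    if sorted(order) != sorted(ALL_CONDITIONS):
        raise ValueError(
            f"condition_order must contain each of the {len(ALL_CONDITIONS)} "
            f"labels exactly once (got {len(order)})"
        )
    if epoch_s <= 0 or tr <= 0:
        raise ValueError("epoch_s and tr must be positive")
    if abs(epoch_s / tr - round(epoch_s / tr)) > 1e-9:
        raise ValueError(f"epoch duration {epoch_s} s is not divisible by TR {tr} s")

    epochs: list[Epoch] = [Epoch("rest", None, epoch_s)]
    for cond in order:
        epochs.append(Epoch("task", cond, epoch_s))
        epochs.append(Epoch("rest", None, epoch_s))
    return EpochSchedule(epochs=tuple(epochs), tr=tr)


def build_session(runs, discard: int = DEFAULT_DISCARD) -> SessionDesign:
    """Concatenate runs into a session, discarding leading volumes per run."""
    runs = tuple(runs)
    if not runs:
        raise ValueError("session needs at least one run")
    trs = {r.tr for r in runs}
    if len(trs) != 1:
        raise ValueError(f"inconsistent TR across runs: {sorted(trs)}")
    if discard < 0:
        raise ValueError("discard must be non-negative")
    for i, r in enumerate(runs):
        if discard >= r.n_volumes:
            raise ValueError(
                f"discard={discard} >= {r.n_volumes} volumes in run {i}"
            )
    runs = tuple(
        EpochSchedule(epochs=r.epochs, tr=r.tr, discard_volumes=discard) for r in runs
    )
    return SessionDesign(runs=runs, discard=discard)


def random_condition_orders(n_runs: int, seed: int) -> list[tuple[ConditionLabel, ...]]:
    """Pseudo-randomized per-run condition orders (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    orders = []
    for _ in range(n_runs):
        idx = rng.permutation(len(ALL_CONDITIONS))
        orders.append(tuple(ALL_CONDITIONS[i] for i in idx))
    return orders


def default_session(
    n_runs: int = DEFAULT_RUNS,
    epoch_s: float = DEFAULT_EPOCH_S,
    tr: float = DEFAULT_TR,
    discard: int = DEFAULT_DISCARD,
    seed: int = 0,
) -> SessionDesign:
    """The paper-style session: 6 runs x (9 rest + 8 task) x 24 s at TR 3 s."""
    orders = random_condition_orders(n_runs, seed)
    return build_session(
        [build_run(o, epoch_s=epoch_s, tr=tr) for o in orders], discard=discard
    )


def _run_input_bins(run: EpochSchedule, bins_per_tr: int) -> np.ndarray:
    """(3, n_volumes*bins_per_tr) boxcar matrix for one full run."""
    dt = run.tr / bins_per_tr
    n_bins = run.n_volumes * bins_per_tr
    u = np.zeros((3, n_bins))
    t = (np.arange(n_bins) + 0.5) * dt
    acc = 0.0
    for ep in run.epochs:
        sel = (t >= acc) & (t < acc + ep.duration)
        if ep.kind == "task":
            u[0, sel] = 1.0
            if ep.condition is not None and ep.condition.execution:
                u[1, sel] = 1.0
            if ep.condition is not None and ep.condition.hand:
                u[2, sel] = 1.0
        acc += ep.duration
    return u


def build_inputs(
    session: SessionDesign | EpochSchedule,
    bins_per_tr: int = DEFAULT_BINS_PER_TR,
    drop_discarded: bool = False,
) -> InputMatrix:
    """Microtime boxcar inputs for a session (or single run).

    With ``drop_discarded`` the bins of the discarded leading volumes of each
    run are removed, matching the retained data timeline.
    """
    if bins_per_tr < 1:
        raise ValueError("bins_per_tr must be >= 1")
    if isinstance(session, EpochSchedule):
        session = SessionDesign(runs=(session,), discard=session.discard_volumes)
    blocks = []
    for run in session.runs:
        u = _run_input_bins(run, bins_per_tr)
        if drop_discarded and session.discard:
            u = u[:, session.discard * bins_per_tr:]
        blocks.append(u)
    return InputMatrix(
        u=np.concatenate(blocks, axis=1), bins_per_tr=bins_per_tr, tr=session.tr
    )


def silent_windows(session: SessionDesign) -> list[SilentWindow]:
    """One 600-ms window at the tail of every acquired volume, labelled by epoch."""
    windows: list[SilentWindow] = []
    for ri, run in enumerate(session.runs):
        for vi in range(run.n_volumes):
            end = (vi + 1) * run.tr
            start = end - SILENT_WINDOW_S
            ep = run.epoch_at(start)
            windows.append(
                SilentWindow(
                    run=ri, volume=vi, start=start, end=end,
                    kind=ep.kind, condition=ep.condition,
                )
            )
    return windows


def window_tally(windows) -> dict:
    """Counts of silent windows per condition name, plus the rest count."""
    tally: dict[str, int] = {"rest": 0}
    for c in ALL_CONDITIONS:
        tally[c.name] = 0
    for w in windows:
        key = "rest" if w.kind == "rest" else w.condition.name
        tally[key] += 1
    return tally


def session_to_config(session: SessionDesign) -> dict:
    """JSON-serializable description of a session design."""
    return {
        "tr": session.tr,
        "discard": session.discard,
        "runs": [
            [
                {
                    "kind": ep.kind,
                    "condition": None if ep.condition is None else ep.condition.name,
                    "duration": ep.duration,
                }
                for ep in run.epochs
            ]
            for run in session.runs
        ],
    }


def _condition_from_name(name: str) -> ConditionLabel:
    for c in ALL_CONDITIONS:
        if c.name == name:
            return c
    raise ValueError(f"unknown condition label {name!r}")


def session_from_config(cfg: dict) -> SessionDesign:
    runs = []
    for run_cfg in cfg["runs"]:
        epochs = tuple(
            Epoch(
                kind=e["kind"],
                condition=None if e["condition"] is None else _condition_from_name(e["condition"]),
                duration=float(e["duration"]),
            )
            for e in run_cfg
        )
        runs.append(EpochSchedule(epochs=epochs, tr=float(cfg["tr"])))
    return build_session(runs, discard=int(cfg["discard"]))


def save_session(session: SessionDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(session_to_config(session), fh, indent=1)


def load_session(path) -> SessionDesign:
    with open(path) as fh:
        return session_from_config(json.load(fh))
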