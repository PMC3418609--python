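"""Synthetic group data with the statistical structure the analysis assumes.

The default generating truth places the published group-mean coupling
values on the dual-input, mutual-connection model (model 1): baseline A
couplings, Execution modulations and Hand-observation modulations per
directed edge, with between-subject SD taken as the printed SE scaled by
sqrt(N) for the N = 24 group.  Subject parameter draws are Gaussian around
those means with stability rejection-resampling; BOLD is simulated through
the bilinear/balloon forward model and observed with additive Gaussian
noise at a per-region SNR.  A companion generator produces synthetic EMG
traces with execution/mimicry bursts aligned to the session timeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .design import INPUT_NAMES, SessionDesign, build_inputs
from .generative import (
    A_DIAGONAL,
    DCMParameters,
    HemodynamicParameters,
    ROITimeSeries,
    is_stable,
    simulate_session,
)
from .model_space import REGIONS, ModelSpec, enumerate_models

__all__ = [
    "GroupTruth",
    "EMGTrace",
    "default_truth",
    "draw_subject_parameters",
    "generate_group",
    "generate_evidence",
    "generate_emg",
    "GROUP_N",
    "A_MEANS",
    "B_EXEC_MEANS",
    "B_HAND_MEANS",
]

GROUP_N = 24  # group size behind the printed SEs

# Published group means (SE) per directed connection, (from, to): (mean, se), Hz.
A_MEANS: dict = {
    ("OP", "MT/V5"): (0.387, 0.028),
    ("pSTS", "MT/V5"): (0.169, 0.015),
    ("aIPS", "MT/V5"): (-0.018, 0.012),
    ("IPL", "MT/V5"): (-0.036, 0.014),
    ("MT/V5", "pSTS"): (0.115, 0.032),
    ("aIPS", "pSTS"): (-0.003, 0.014),
    ("IPL", "pSTS"): (-0.021, 0.014),
    ("PMv", "pSTS"): (0.071, 0.020),
    ("MT/V5", "aIPS"): (0.103, 0.022),
    ("pSTS", "aIPS"): (0.122, 0.014),
    ("IPL", "aIPS"): (0.062, 0.018),
    ("PMv", "aIPS"): (0.116, 0.022),
    ("S/M1", "aIPS"): (0.067, 0.018),
    ("MT/V5", "IPL"): (0.011, 0.024),
    ("pSTS", "IPL"): (0.051, 0.012),
    ("aIPS", "IPL"): (0.054, 0.021),
    ("PMv", "IPL"): (0.128, 0.019),
    ("S/M1", "IPL"): (0.087, 0.024),
    ("pSTS", "PMv"): (0.052, 0.017),
    ("aIPS", "PMv"): (0.010, 0.014),
    ("IPL", "PMv"): (-0.008, 0.016),
    ("S/M1", "PMv"): (-0.004, 0.018),
    ("aIPS", "S/M1"): (0.053, 0.020),
    ("IPL", "S/M1"): (0.121, 0.030),
    ("PMv", "S/M1"): (0.229, 0.036),
}

B_EXEC_MEANS: dict = {
    ("OP", "MT/V5"): (0.034, 0.020),
    ("pSTS", "MT/V5"): (0.006, 0.010),
    ("aIPS", "MT/V5"): (-0.012, 0.009),
    ("IPL", "MT/V5"): (-0.009, 0.008),
    ("MT/V5", "pSTS"): (-0.039, 0.016),
    ("aIPS", "pSTS"): (-0.018, 0.015),
    ("IPL", "pSTS"): (0.007, 0.010),
    ("PMv", "pSTS"): (0.077, 0.019),
    ("MT/V5", "aIPS"): (0.022, 0.012),
    ("pSTS", "aIPS"): (0.022, 0.014),
    ("IPL", "aIPS"): (0.039, 0.012),
    ("PMv", "aIPS"): (0.119, 0.024),
    ("S/M1", "aIPS"): (0.055, 0.013),
    ("MT/V5", "IPL"): (0.030, 0.011),
    ("pSTS", "IPL"): (0.031, 0.013),
    ("aIPS", "IPL"): (0.037, 0.011),
    ("PMv", "IPL"): (0.124, 0.022),
    ("S/M1", "IPL"): (0.069, 0.015),
    ("pSTS", "PMv"): (-0.018, 0.012),
    ("aIPS", "PMv"): (-0.008, 0.013),
    ("IPL", "PMv"): (-0.008, 0.014),
    ("S/M1", "PMv"): (0.003, 0.019),
    ("aIPS", "S/M1"): (0.161, 0.018),
    ("IPL", "S/M1"): (0.160, 0.018),
    ("PMv", "S/M1"): (0.274, 0.040),
}

B_HAND_MEANS: dict = {
    ("OP", "MT/V5"): (0.203, 0.018),
    ("pSTS", "MT/V5"): (0.213, 0.020),
    ("aIPS", "MT/V5"): (0.051, 0.011),
    ("IPL", "MT/V5"): (0.030, 0.009),
    ("MT/V5", "pSTS"): (0.002, 0.010),
    ("aIPS", "pSTS"): (-0.016, 0.009),
    ("IPL", "pSTS"): (-0.027, 0.008),
    ("PMv", "pSTS"): (-0.040, 0.010),
    ("MT/V5", "aIPS"): (0.050, 0.015),
    ("pSTS", "aIPS"): (0.123, 0.020),
    ("IPL", "aIPS"): (-0.008, 0.007),
    ("PMv", "aIPS"): (0.013, 0.009),
    ("S/M1", "aIPS"): (-0.029, 0.009),
    ("MT/V5", "IPL"): (0.017, 0.010),
    ("pSTS", "IPL"): (0.056, 0.012),
    ("aIPS", "IPL"): (0.0002, 0.005),
    ("PMv", "IPL"): (0.017, 0.005),
    ("S/M1", "IPL"): (-0.015, 0.005),
    ("pSTS", "PMv"): (0.045, 0.016),
    ("aIPS", "PMv"): (0.003, 0.009),
    ("IPL", "PMv"): (-0.010, 0.008),
    ("S/M1", "PMv"): (-0.021, 0.009),
    ("aIPS", "S/M1"): (0.002, 0.017),
    ("IPL", "S/M1"): (0.037, 0.012),
    ("PMv", "S/M1"): (0.061, 0.018),
}

#: Direct input gains for the generating model (not published; declared).
#: Kept small so neural excursions stay in the physiological range the
#: hemodynamic model is calibrated for (|z| well below 1).
C_DEFAULTS: dict = {
    ("task", "OP"): 0.15,
    ("exec", "PMv"): 0.14,
    ("hand", "pSTS"): 0.14,
}


@dataclass(frozen=True)
class GroupTruth:
    """Population-level generating parameters for a synthetic group."""

    model: ModelSpec
    mean: DCMParameters
    sd: dict  # arrays "A", "B", "C" of between-subject SDs (A diagonal fixed)
    n_subjects: int
    snr: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not is_stable(self.mean):
            raise ValueError("population-mean coupling matrix is unstable")


def _tables_to_matrices(model: ModelSpec, regions=REGIONS):
    ridx = {r: i for i, r in enumerate(regions)}
    n, m = len(regions), len(INPUT_NAMES)
    A_mean = np.zeros((n, n))
    np.fill_diagonal(A_mean, A_DIAGONAL)
    A_sd = np.zeros((n, n))
    B_mean = np.zeros((m, n, n))
    B_sd = np.zeros((m, n, n))
    for (frm, to) in model.a_edges:
        mu, se = A_MEANS[(frm, to)]
        A_mean[ridx[to], ridx[frm]] = mu
        A_sd[ridx[to], ridx[frm]] = se * np.sqrt(GROUP_N)
    tables = {"exec": (B_EXEC_MEANS, 1), "hand": (B_HAND_MEANS, 2)}
    for factor, (table, j) in tables.items():
        for (frm, to) in model.b_edges[factor]:
            mu, se = table[(frm, to)]
            B_mean[j, ridx[to], ridx[frm]] = mu
            B_sd[j, ridx[to], ridx[frm]] = se * np.sqrt(GROUP_N)
    C_mean = np.zeros((n, m))
    C_sd = np.zeros((n, m))
    for (inp, target) in model.c_inputs:
        C_mean[ridx[target], INPUT_NAMES.index(inp)] = C_DEFAULTS[(inp, target)]
        C_sd[ridx[target], INPUT_NAMES.index(inp)] = 0.02
    return A_mean, A_sd, B_mean, B_sd, C_mean, C_sd


def default_truth(
    n_subjects: int = GROUP_N,
    snr: float = 3.0,
    seed: int = 0,
    model: ModelSpec | None = None,
    sd_scale: float = 1.0,
) -> GroupTruth:
    """Published-table means on the dual-input mutual-connection model.

    Between-subject SDs are the printed SEs scaled by sqrt(24); ``sd_scale``
    rescales them (0 gives a homogeneous group).
    """
    if model is None:
        model = enumerate_models()[1]
    A_mean, A_sd, B_mean, B_sd, C_mean, C_sd = _tables_to_matrices(model)
    mean = DCMParameters(A=A_mean, B=B_mean, C=C_mean, regions=REGIONS, inputs=INPUT_NAMES)
    sd = {"A": A_sd * sd_scale, "B": B_sd * sd_scale, "C": C_sd * sd_scale}
    return GroupTruth(
        model=model, mean=mean, sd=sd, n_subjects=n_subjects, snr=snr, seed=seed
    )


Z_PEAK_CAP = 2.0  # reject draws whose neural excursions leave the regime
# the fixed-step integrator resolves accurately


def neural_peak(p: DCMParameters, tr: float = 3.0, epoch_s: float = 24.0) -> float:
    """Peak |z| of the neural subsystem over one canonical run.

    Cheap screen (neural ODE only, coarse RK4): large peaks indicate
    hemodynamic excursions that would need a finer integration step.
    """
    from .design import ALL_CONDITIONS, build_inputs, build_run, SessionDesign

    run = build_run(ALL_CONDITIONS, epoch_s=epoch_s, tr=tr)
    inp = build_inputs(SessionDesign(runs=(run,), discard=0), bins_per_tr=2)
    dt = tr / 2.0
    uniq, inv = np.unique(inp.u.T, axis=0, return_inverse=True)
    Ms = [p.A + np.tensordot(u, p.B, axes=1) for u in uniq]
    ds = [p.C @ u for u in uniq]
    z = np.zeros(p.n_regions)
    peak = 0.0
    for t in range(inp.u.shape[1]):
        M, d = Ms[inv[t]], ds[inv[t]]
        k1 = M @ z + d
        k2 = M @ (z + dt / 2 * k1) + d
        k3 = M @ (z + dt / 2 * k2) + d
        k4 = M @ (z + dt * k3) + d
        z = z + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        peak = max(peak, float(np.max(np.abs(z))))
    return peak


def draw_subject_parameters(
    truth: GroupTruth, rng: np.random.Generator, max_tries: int = 100
) -> DCMParameters:
    """One stable Gaussian draw around the population means.

    Rejection-resamples draws that are dynamically unstable under any
    attainable input combination, or whose neural excursions exceed
    :data:`Z_PEAK_CAP` (integrator-accuracy guard).
    """
    a_sd = np.where(np.eye(len(truth.mean.regions), dtype=bool), 0.0, truth.sd["A"])
    for _ in range(max_tries):
        p = DCMParameters(
            A=truth.mean.A + rng.normal(size=truth.mean.A.shape) * a_sd,
            B=truth.mean.B + rng.normal(size=truth.mean.B.shape) * truth.sd["B"],
            C=truth.mean.C + rng.normal(size=truth.mean.C.shape) * truth.sd["C"],
            regions=truth.mean.regions,
            inputs=truth.mean.inputs,
        )
        combos = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]]
        if is_stable(p, combos) and neural_peak(p) <= Z_PEAK_CAP:
            return p
    raise RuntimeError(f"no stable parameter draw in {max_tries} tries")


def generate_group(
    truth: GroupTruth,
    session: SessionDesign,
    bins_per_tr: int = 16,
    hp: HemodynamicParameters | None = None,
):
    """Per-subject noisy BOLD series plus the underlying truth record.

    Returns ``(list of ROITimeSeries, list of DCMParameters, record)`` where
    ``record`` is a JSON-serializable manifest of seeds and noise levels.
    """
    hp = hp or HemodynamicParameters()
    rng = np.random.default_rng(truth.seed)
    series: list[ROITimeSeries] = []
    params: list[DCMParameters] = []
    noise_record = []
    for _ in range(truth.n_subjects):
        p = draw_subject_parameters(truth, rng)
        clean = simulate_session(p, hp, session, bins_per_tr=bins_per_tr)
        signal_sd = np.std(clean.values, axis=1)
        noise_sd = np.where(signal_sd > 0, signal_sd / truth.snr, 0.0)
        noisy = clean.values + rng.normal(size=clean.values.shape) * noise_sd[:, None]
        series.append(ROITimeSeries(regions=clean.regions, values=noisy, tr=clean.tr))
        params.append(p)
        noise_record.append(noise_sd.tolist())
    record = {
        "seed": truth.seed,
        "snr": truth.snr,
        "n_subjects": truth.n_subjects,
        "model_id": truth.model.model_id,
        "noise_sd": noise_record,
    }
    return series, params, record


def generate_evidence(
    true_model_id: int,
    delta: float,
    n_subjects: int,
    model_ids,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Toy log-evidence matrix: i.i.d. noise + ``delta`` on the true column."""
    from .bms import EvidenceMatrix

    if delta < 0:
        raise ValueError("delta must be non-negative")
    model_ids = tuple(model_ids)
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n_subjects, len(model_ids)))
    values[:, model_ids.index(true_model_id)] += delta
    return EvidenceMatrix(
        values=values,
        subjects=tuple(f"sub-{i + 1:02d}" for i in range(n_subjects)),
        model_ids=model_ids,
    )


@dataclass(frozen=True)
class EMGTrace:
    """Single-channel synthetic EMG aligned to a session timeline."""

    signal: np.ndarray
    rate: float  # Hz
    session: SessionDesign

    def __post_init__(self) -> None:
        expected = int(round(sum(r.duration for r in self.session.runs) * self.rate))
        if len(self.signal) != expected:
            raise ValueError(
                f"signal length {len(self.signal)} != session duration x rate {expected}"
            )

    def save(self, path, meta: dict | None = None) -> None:
        np.savetxt(path, self.signal[:, None], delimiter="\t", header="emg", comments="")
        sidecar = {"rate": self.rate}
        if meta:
            sidecar.update(meta)
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def generate_emg(
    session: SessionDesign,
    a_exec: float,
    a_hand: float,
    baseline_sd: float = 1.0,
    rate: float = 1000.0,
    seed: int = 0,
) -> EMGTrace:
    """Noise plus condition-locked amplitude bursts.

    Baseline is zero-mean Gaussian noise everywhere; during Execution epochs
    the amplitude grows by ``a_exec``, during Hand-observation epochs by
    ``a_hand`` (mimicry), additively for Execution+Hand epochs.
    """
    if not (a_exec >= a_hand >= 0):
        raise ValueError("need a_exec >= a_hand >= 0")
    rng = np.random.default_rng(seed)
    total_s = sum(r.duration for r in session.runs)
    n = int(round(total_s * rate))
    amplitude = np.full(n, baseline_sd, dtype=float)
    offset_s = 0.0
    for run in session.runs:
        acc = offset_s
        for ep in run.epochs:
            if ep.kind == "task" and ep.condition is not None:
                extra = 0.0
                if ep.condition.execution:
                    extra += a_exec
                if ep.condition.hand:
                    extra += a_hand
                i0 = int(round(acc * rate))
                i1 = int(round((acc + ep.duration) * rate))
                amplitude[i0:i1] += extra
            acc += ep.duration
        offset_s += run.duration
    signal = rng.normal(size=n) * amplitude
    return EMGTrace(signal=signal, rate=rate, session=session)
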