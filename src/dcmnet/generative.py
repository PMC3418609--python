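"""Forward model: bilinear neural dynamics, balloon hemodynamics, BOLD.

Neural populations follow dz/dt = (A + sum_j u_j B_j) z + C u, with A the
baseline coupling (Hz), B_j the input-dependent modulation of those
couplings and C the direct input gains.  Each region's activity drives a
four-state balloon model (vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q) whose volume/deoxyhemoglobin states are read out as BOLD:

    y = V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)),
    k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.

Integration is explicit RK4 at microtime resolution (TR / bins_per_tr) with
BOLD sampled at the end of each volume.  All heavy routines accept a leading
batch axis over parameter sets so that finite-difference Jacobians cost one
batched simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .design import InputMatrix, SessionDesign, build_inputs

try:  # compiled integrator core; pure-numpy fallback if unavailable
    import os

    if os.environ.get("DCMNET_NO_NUMBA"):
        raise ImportError("numba disabled by environment")
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised via DCMNET_NO_NUMBA
    _HAVE_NUMBA = False

__all__ = [
    "DCMParameters",
    "HemodynamicParameters",
    "ROITimeSeries",
    "neural_derivative",
    "hemo_derivative",
    "bold_observation",
    "simulate_bold",
    "simulate_session",
    "is_stable",
    "InstabilityError",
]

A_DIAGONAL = -0.5  # fixed self-decay (Hz); off-diagonals are the free couplings


class InstabilityError(RuntimeError):
    """Raised when the simulated states diverge."""


@dataclass(frozen=True)
class DCMParameters:
    """Coupling parameter set: A (n x n), B (m x n x n), C (n x m), in Hz."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    regions: tuple[str, ...]
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        n, m = len(self.regions), len(self.inputs)
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {(n, n)}, got {self.A.shape}")
        if self.B.shape != (m, n, n):
            raise ValueError(f"B must be {(m, n, n)}, got {self.B.shape}")
        if self.C.shape != (n, m):
            raise ValueError(f"C must be {(n, m)}, got {self.C.shape}")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "inputs": list(self.inputs),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMParameters":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            B=np.asarray(d["B"], dtype=float),
            C=np.asarray(d["C"], dtype=float),
            regions=tuple(d["regions"]),
            inputs=tuple(d["inputs"]),
        )


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-model constants, broadcastable per region.

    Defaults are the canonical values of the hemodynamic forward model:
    kappa = 0.65 /s, gamma = 0.41 /s, tau = 0.98 s, alpha = 0.32,
    rho = 0.34, V0 = 0.04, epsilon = 1.
    """

    kappa: float | np.ndarray = 0.65
    gamma: float | np.ndarray = 0.41
    tau: float | np.ndarray = 0.98
    alpha: float | np.ndarray = 0.32
    rho: float | np.ndarray = 0.34
    v0: float | np.ndarray = 0.04
    epsilon: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "v0", "epsilon"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "rho"):
            val = np.asarray(getattr(self, name))
            if np.any(val <= 0) or np.any(val >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def k1(self):
        return 7.0 * np.asarray(self.rho)

    @property
    def k2(self):
        return 2.0

    @property
    def k3(self):
        return 2.0 * np.asarray(self.rho) - 0.2


@dataclass(frozen=True)
class ROITimeSeries:
    """Region x volume BOLD series at a fixed TR."""

    regions: tuple[str, ...]
    values: np.ndarray  # (n_regions, n_volumes)
    tr: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.regions):
            raise ValueError(
                f"values must be (n_regions, n_volumes); got {self.values.shape} "
                f"for {len(self.regions)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    def save(self, path, meta: dict | None = None) -> None:
        """Delimited text (volumes x regions, header row) + JSON sidecar."""
        header = "\t".join(self.regions)
        np.savetxt(path, self.values.T, delimiter="\t", header=header, comments="")
        sidecar = {"tr": self.tr}
        if meta:
            sidecar.update(meta)
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ROITimeSeries":
        with open(path) as fh:
            regions = tuple(fh.readline().strip().split("\t"))
        values = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(regions=regions, values=values.T, tr=float(meta["tr"]))


def neural_derivative(z: np.ndarray, u: np.ndarray, p: DCMParameters) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B_j) z + C u for one state vector."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (p.n_regions,):
        raise ValueError(f"z must have shape ({p.n_regions},), got {z.shape}")
    if u.shape != (p.n_inputs,):
        raise ValueError(f"u must have shape ({p.n_inputs},), got {u.shape}")
    M = p.A + np.tensordot(u, p.B, axes=1)
    return M @ z + p.C @ u


def hemo_derivative(h, z_i, hp: HemodynamicParameters):
    """Balloon-state derivatives (s, f, v, q) for activity ``z_i``.

    ``h`` is a length-4 sequence (s, f, v, q); arrays broadcast.
    """
    s, f, v, q = (np.asarray(x, dtype=float) for x in h)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("f, v and q must stay positive")
    ds = np.asarray(hp.epsilon) * z_i - np.asarray(hp.kappa) * s - np.asarray(hp.gamma) * (f - 1.0)
    df = s
    outflow = v ** (1.0 / np.asarray(hp.alpha))
    dv = (f - outflow) / np.asarray(hp.tau)
    extraction = 1.0 - (1.0 - np.asarray(hp.rho)) ** (1.0 / f)
    dq = (f * extraction / np.asarray(hp.rho) - outflow * q / v) / np.asarray(hp.tau)
    return ds, df, dv, dq


def bold_observation(v, q, hp: HemodynamicParameters):
    """BOLD readout from venous volume and deoxyhemoglobin."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    return np.asarray(hp.v0) * (
        hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v)
    )


def is_stable(p: DCMParameters, input_combos=None) -> bool:
    """True if A (and A + active B sums for the given 0/1 input combos) is stable."""
    mats = [p.A]
    if input_combos is not None:
        for combo in np.unique(np.asarray(input_combos, dtype=float), axis=0):
            mats.append(p.A + np.tensordot(combo, p.B, axes=1))
    return all(np.max(np.real(np.linalg.eigvals(M))) < 0 for M in mats)


# ---------------------------------------------------------------------------
# batched integration core

_Z_DIVERGE = 1e6


def _rk4_kernel(M_tab, d_tab, u_idx, dt, bins_per_sample,
                kappa, gamma, tau, ia, rho, eps, v0, k1, k2, k3,
                euler, state, out):
    """Integrate all batch members; plain loops so numba can compile it.

    M_tab: (U, P, n, n) effective coupling per distinct input column;
    d_tab: (U, P, n) drives; u_idx: (T,) column index per microtime bin;
    state: (P, n, 5) work array (z, s, f, v, q); out: (P, n_vol, n) BOLD.
    """
    U, P, n, _ = M_tab.shape
    T = u_idx.shape[0]
    deriv = np.empty((4, n, 5))  # RK4 slopes for one batch member
    trial = np.empty((n, 5))  # stage trial state
    n_stages = 1 if euler else 4
    vol = 0
    for t in range(T):
        k = u_idx[t]
        for p in range(P):
            M = M_tab[k, p]
            d = d_tab[k, p]
            S = state[p]
            for stage in range(n_stages):
                if stage == 0:
                    for i in range(n):
                        for c in range(5):
                            trial[i, c] = S[i, c]
                else:
                    h = dt * (0.5 if stage < 3 else 1.0)
                    for i in range(n):
                        for c in range(5):
                            trial[i, c] = S[i, c] + h * deriv[stage - 1, i, c]
                for i in range(n):
                    f_i = trial[i, 2] if trial[i, 2] > 1e-3 else 1e-3
                    v_i = trial[i, 3] if trial[i, 3] > 1e-3 else 1e-3
                    q_i = trial[i, 4] if trial[i, 4] > 1e-3 else 1e-3
                    acc = d[i]
                    for jj in range(n):
                        acc += M[i, jj] * trial[jj, 0]
                    deriv[stage, i, 0] = acc
                    deriv[stage, i, 1] = (
                        eps[i] * trial[i, 0] - kappa[i] * trial[i, 1]
                        - gamma[i] * (f_i - 1.0)
                    )
                    deriv[stage, i, 2] = trial[i, 1]
                    outflow = v_i ** ia[i]
                    deriv[stage, i, 3] = (f_i - outflow) / tau[i]
                    ext = -np.expm1(np.log(1.0 - rho[i]) / f_i)
                    deriv[stage, i, 4] = (f_i * ext / rho[i] - outflow * q_i / v_i) / tau[i]
            if euler:
                for i in range(n):
                    for c in range(5):
                        S[i, c] += dt * deriv[0, i, c]
            else:
                w = dt / 6.0
                for i in range(n):
                    for c in range(5):
                        S[i, c] += w * (
                            deriv[0, i, c] + 2.0 * deriv[1, i, c]
                            + 2.0 * deriv[2, i, c] + deriv[3, i, c]
                        )
            for i in range(n):
                if S[i, 2] < 1e-6:
                    S[i, 2] = 1e-6
                if S[i, 3] < 1e-6:
                    S[i, 3] = 1e-6
                if S[i, 4] < 1e-6:
                    S[i, 4] = 1e-6
        if (t + 1) % bins_per_sample == 0:
            for p in range(P):
                for i in range(n):
                    v_i = state[p, i, 3]
                    q_i = state[p, i, 4]
                    out[p, vol, i] = v0[i] * (
                        k1[i] * (1.0 - q_i) + k2 * (1.0 - q_i / v_i) + k3[i] * (1.0 - v_i)
                    )
            vol += 1


def _sens_kernel(M_tab, d_tab, u_vals, u_idx, dt, bins_per_sample,
                 kappa, gamma, tau, ia, rho, eps, v0, k1, k2, k3,
                 par_type, par_j, par_a, par_b,
                 state, sens, out_y, out_jac):
    """Base trajectory plus forward sensitivities for one parameter set.

    The sensitivity systems are linear in the base trajectory, so the
    hemodynamic transcendentals (and their partials) are evaluated once per
    region per stage and shared across all K parameters.

    M_tab: (U, n, n); d_tab: (U, n); u_vals: (U, m) distinct input columns;
    par_type: (K,) 0 = A entry, 1 = B entry, 2 = C entry; par_j: input index
    (B/C); par_a/par_b: target/source region indices.  state: (n, 5) work
    array; sens: (K, n, 5); out_y: (n_vol, n); out_jac: (K, n_vol, n).
    """
    n = state.shape[0]
    K = sens.shape[0]
    T = u_idx.shape[0]
    deriv = np.empty((4, n, 5))
    trial = np.empty((n, 5))
    dsens = np.empty((4, K, n, 5))
    strial = np.empty((K, n, 5))
    dfq = np.empty(n)   # d(dq/dt)/df at stage
    dvq = np.empty(n)   # d(dq/dt)/dv
    dqq = np.empty(n)   # d(dq/dt)/dq
    dvv = np.empty(n)   # d(dv/dt)/dv
    logm = np.empty(n)
    for i in range(n):
        logm[i] = np.log(1.0 - rho[i])
    vol = 0
    for t in range(T):
        k = u_idx[t]
        M = M_tab[k]
        d = d_tab[k]
        u_now = u_vals[k]
        for stage in range(4):
            if stage == 0:
                for i in range(n):
                    for c in range(5):
                        trial[i, c] = state[i, c]
                for kk in range(K):
                    for i in range(n):
                        for c in range(5):
                            strial[kk, i, c] = sens[kk, i, c]
            else:
                h = dt * (0.5 if stage < 3 else 1.0)
                for i in range(n):
                    for c in range(5):
                        trial[i, c] = state[i, c] + h * deriv[stage - 1, i, c]
                for kk in range(K):
                    for i in range(n):
                        for c in range(5):
                            strial[kk, i, c] = sens[kk, i, c] + h * dsens[stage - 1, kk, i, c]
            # base derivatives and hemodynamic partials at this stage
            for i in range(n):
                f_i = trial[i, 2] if trial[i, 2] > 1e-3 else 1e-3
                v_i = trial[i, 3] if trial[i, 3] > 1e-3 else 1e-3
                q_i = trial[i, 4] if trial[i, 4] > 1e-3 else 1e-3
                acc = d[i]
                for jj in range(n):
                    acc += M[i, jj] * trial[jj, 0]
                deriv[stage, i, 0] = acc
                deriv[stage, i, 1] = (
                    eps[i] * trial[i, 0] - kappa[i] * trial[i, 1]
                    - gamma[i] * (f_i - 1.0)
                )
                deriv[stage, i, 2] = trial[i, 1]
                outflow_v = v_i ** (ia[i] - 1.0)  # v^(1/alpha - 1)
                deriv[stage, i, 3] = (f_i - outflow_v * v_i) / tau[i]
                e_exp = np.exp(logm[i] / f_i)
                ext = 1.0 - e_exp
                deriv[stage, i, 4] = (f_i * ext / rho[i] - outflow_v * q_i) / tau[i]
                # partials of (dv/dt, dq/dt)
                dvv[i] = -ia[i] * outflow_v / tau[i]
                dfq[i] = (ext + e_exp * logm[i] / f_i) / (rho[i] * tau[i])
                dvq[i] = -(ia[i] - 1.0) * (v_i ** (ia[i] - 2.0)) * q_i / tau[i]
                dqq[i] = -outflow_v / tau[i]
            # sensitivity derivatives
            for kk in range(K):
                S = strial[kk]
                for i in range(n):
                    acc = 0.0
                    for jj in range(n):
                        acc += M[i, jj] * S[jj, 0]
                    dsens[stage, kk, i, 0] = acc
                    dsens[stage, kk, i, 1] = (
                        eps[i] * S[i, 0] - kappa[i] * S[i, 1] - gamma[i] * S[i, 2]
                    )
                    dsens[stage, kk, i, 2] = S[i, 1]
                    dsens[stage, kk, i, 3] = S[i, 2] / tau[i] + dvv[i] * S[i, 3]
                    dsens[stage, kk, i, 4] = dfq[i] * S[i, 2] + dvq[i] * S[i, 3] + dqq[i] * S[i, 4]
                # parameter-specific forcing on the neural row
                a = par_a[kk]
                if par_type[kk] == 0:  # A entry
                    dsens[stage, kk, a, 0] += trial[par_b[kk], 0]
                elif par_type[kk] == 1:  # B entry
                    dsens[stage, kk, a, 0] += u_now[par_j[kk]] * trial[par_b[kk], 0]
                else:  # C entry
                    dsens[stage, kk, a, 0] += u_now[par_j[kk]]
        w = dt / 6.0
        for i in range(n):
            for c in range(5):
                state[i, c] += w * (
                    deriv[0, i, c] + 2.0 * deriv[1, i, c]
                    + 2.0 * deriv[2, i, c] + deriv[3, i, c]
                )
        for i in range(n):
            if state[i, 2] < 1e-6:
                state[i, 2] = 1e-6
            if state[i, 3] < 1e-6:
                state[i, 3] = 1e-6
            if state[i, 4] < 1e-6:
                state[i, 4] = 1e-6
        for kk in range(K):
            for i in range(n):
                for c in range(5):
                    sens[kk, i, c] += w * (
                        dsens[0, kk, i, c] + 2.0 * dsens[1, kk, i, c]
                        + 2.0 * dsens[2, kk, i, c] + dsens[3, kk, i, c]
                    )
        if (t + 1) % bins_per_sample == 0:
            for i in range(n):
                v_i = state[i, 3]
                q_i = state[i, 4]
                out_y[vol, i] = v0[i] * (
                    k1[i] * (1.0 - q_i) + k2 * (1.0 - q_i / v_i) + k3[i] * (1.0 - v_i)
                )
                dy_dq = v0[i] * (-k1[i] - k2 / v_i)
                dy_dv = v0[i] * (k2 * q_i / (v_i * v_i) - k3[i])
                for kk in range(K):
                    out_jac[kk, vol, i] = (
                        dy_dq * sens[kk, i, 4] + dy_dv * sens[kk, i, 3]
                    )
            vol += 1


if _HAVE_NUMBA:
    _rk4_kernel_jit = _njit(cache=False, fastmath=False)(_rk4_kernel)
    _sens_kernel_jit = _njit(cache=False, fastmath=False)(_sens_kernel)
else:
    _rk4_kernel_jit = None
    _sens_kernel_jit = None


def _deriv_batch(z, s, f, v, q, M, d, kappa, gamma, tau, ia, rho, eps):
    """State derivatives for batched states; all state arrays are (P, n).

    f, v, q are clipped from below so that RK4 trial states of diverging
    parameter sets do not produce overflow; divergence is detected afterwards.
    """
    f = np.maximum(f, 1e-3)
    v = np.maximum(v, 1e-3)
    q = np.maximum(q, 1e-3)
    dz = np.einsum("pij,pj->pi", M, z) + d
    ds = eps * z - kappa * s - gamma * (f - 1.0)
    outflow = v ** ia
    dv = (f - outflow) / tau
    dq = (f * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho - outflow * q / v) / tau
    return dz, ds, s, dv, dq


def _simulate_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    u: np.ndarray,
    dt: float,
    bins_per_sample: int,
    hp: HemodynamicParameters,
    method: str = "rk4",
    raise_on_diverge: bool = True,
) -> np.ndarray:
    """Integrate a batch of parameter sets over one input block.

    A: (P, n, n); B: (P, m, n, n); C: (P, n, m); u: (m, T_micro).
    Returns BOLD samples (P, n_volumes, n) taken after every
    ``bins_per_sample`` microtime bins.  Divergent states raise
    :class:`InstabilityError`, or — with ``raise_on_diverge=False`` — mark
    the offending batch members as NaN so a search can reject them.
    """
    P, n, _ = A.shape
    m, T = u.shape
    if T % bins_per_sample:
        raise ValueError("input length must be a multiple of bins_per_sample")

    # inputs are boxcars: precompute the effective coupling matrix and drive
    # for each distinct input column
    uniq, inv = np.unique(u.T, axis=0, return_inverse=True)
    M_tab = A[None, :, :, :] + np.einsum("uj,pjab->upab", uniq, B)
    d_tab = np.einsum("pam,um->upa", C, uniq)

    kappa = np.broadcast_to(np.asarray(hp.kappa, dtype=float), (n,))
    gamma = np.broadcast_to(np.asarray(hp.gamma, dtype=float), (n,))
    tau = np.broadcast_to(np.asarray(hp.tau, dtype=float), (n,))
    ia = 1.0 / np.broadcast_to(np.asarray(hp.alpha, dtype=float), (n,))
    rho = np.broadcast_to(np.asarray(hp.rho, dtype=float), (n,))
    eps = np.broadcast_to(np.asarray(hp.epsilon, dtype=float), (n,))

    n_vol = T // bins_per_sample
    out = np.empty((P, n_vol, n))

    if _HAVE_NUMBA:
        state = np.zeros((P, n, 5))
        state[:, :, 2:] = 1.0  # f = v = q = 1 at rest
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            _rk4_kernel_jit(
                np.ascontiguousarray(M_tab), np.ascontiguousarray(d_tab),
                inv.astype(np.int64), float(dt), int(bins_per_sample),
                kappa.copy(), gamma.copy(), tau.copy(), ia.copy(), rho.copy(),
                eps.copy(), np.broadcast_to(np.asarray(hp.v0, dtype=float), (n,)).copy(),
                np.broadcast_to(hp.k1, (n,)).astype(float),
                float(hp.k2), np.broadcast_to(hp.k3, (n,)).astype(float),
                method == "euler", state, out,
            )
        z_final = state[:, :, 0]
        ok = np.all(np.isfinite(out), axis=(1, 2)) & (
            np.nan_to_num(np.max(np.abs(z_final), axis=1), nan=np.inf) < _Z_DIVERGE
        )
        if not ok.all():
            if raise_on_diverge:
                raise InstabilityError("simulated states diverged")
            out[~ok] = np.nan
        return out

    z = np.zeros((P, n))
    s = np.zeros((P, n))
    f = np.ones((P, n))
    v = np.ones((P, n))
    q = np.ones((P, n))

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _integrate_loop(
            A, B, C, u, dt, bins_per_sample, hp, method, raise_on_diverge,
            M_tab, d_tab, inv, kappa, gamma, tau, ia, rho, eps,
            z, s, f, v, q, out, T,
        )


def _integrate_loop(
    A, B, C, u, dt, bins_per_sample, hp, method, raise_on_diverge,
    M_tab, d_tab, inv, kappa, gamma, tau, ia, rho, eps,
    z, s, f, v, q, out, T,
):
    vol = 0
    for t in range(T):
        M = M_tab[inv[t]]
        d = d_tab[inv[t]]
        if method == "euler":
            dz, ds, df, dv, dq = _deriv_batch(z, s, f, v, q, M, d, kappa, gamma, tau, ia, rho, eps)
            z = z + dt * dz
            s = s + dt * ds
            f = f + dt * df
            v = v + dt * dv
            q = q + dt * dq
        else:  # rk4
            k1 = _deriv_batch(z, s, f, v, q, M, d, kappa, gamma, tau, ia, rho, eps)
            h2 = dt / 2.0
            k2 = _deriv_batch(
                z + h2 * k1[0], s + h2 * k1[1], f + h2 * k1[2],
                v + h2 * k1[3], q + h2 * k1[4], M, d, kappa, gamma, tau, ia, rho, eps,
            )
            k3 = _deriv_batch(
                z + h2 * k2[0], s + h2 * k2[1], f + h2 * k2[2],
                v + h2 * k2[3], q + h2 * k2[4], M, d, kappa, gamma, tau, ia, rho, eps,
            )
            k4 = _deriv_batch(
                z + dt * k3[0], s + dt * k3[1], f + dt * k3[2],
                v + dt * k3[3], q + dt * k3[4], M, d, kappa, gamma, tau, ia, rho, eps,
            )
            w = dt / 6.0
            z = z + w * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s = s + w * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            f = f + w * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            v = v + w * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            q = q + w * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        # balloon states must remain physical; clip guards tiny excursions
        f = np.maximum(f, 1e-6)
        v = np.maximum(v, 1e-6)
        q = np.maximum(q, 1e-6)

        if (t + 1) % bins_per_sample == 0:
            out[:, vol, :] = hp.v0 * (
                hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v)
            )
            vol += 1

    ok = np.all(np.isfinite(out), axis=(1, 2)) & (np.max(np.abs(z), axis=1) < _Z_DIVERGE)
    if not ok.all():
        if raise_on_diverge:
            raise InstabilityError("simulated states diverged")
        out[~ok] = np.nan
    return out


def simulate_with_sensitivities(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    u: np.ndarray,
    dt: float,
    bins_per_sample: int,
    hp: HemodynamicParameters,
    par_type: np.ndarray,
    par_j: np.ndarray,
    par_a: np.ndarray,
    par_b: np.ndarray,
):
    """Base BOLD plus the Jacobian w.r.t. the indexed parameters.

    Returns ``(y, jac)`` with y (n_vol, n) and jac (K, n_vol, n).  Requires
    the compiled kernel; callers fall back to finite differences otherwise.
    """
    if _sens_kernel_jit is None:
        raise RuntimeError("sensitivity kernel unavailable (numba disabled)")
    n = A.shape[0]
    m, T = u.shape
    uniq, inv = np.unique(u.T, axis=0, return_inverse=True)
    M_tab = A[None] + np.einsum("uj,jab->uab", uniq, B)
    d_tab = uniq @ C.T
    K = len(par_type)
    n_vol = T // bins_per_sample
    state = np.zeros((n, 5))
    state[:, 2:] = 1.0
    sens = np.zeros((K, n, 5))
    out_y = np.empty((n_vol, n))
    out_jac = np.empty((K, n_vol, n))

    def arr(x):
        return np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        _sens_kernel_jit(
            np.ascontiguousarray(M_tab), np.ascontiguousarray(d_tab),
            np.ascontiguousarray(uniq), inv.astype(np.int64),
            float(dt), int(bins_per_sample),
            arr(hp.kappa), arr(hp.gamma), arr(hp.tau),
            1.0 / arr(hp.alpha), arr(hp.rho), arr(hp.epsilon), arr(hp.v0),
            arr(hp.k1), float(hp.k2), arr(hp.k3),
            par_type.astype(np.int64), par_j.astype(np.int64),
            par_a.astype(np.int64), par_b.astype(np.int64),
            state, sens, out_y, out_jac,
        )
    return out_y, out_jac


def simulate_bold(
    p: DCMParameters,
    hp: HemodynamicParameters,
    inputs: InputMatrix,
    noise_sd=0.0,
    seed: int | None = None,
    method: str = "rk4",
    check_stability: bool = True,
) -> ROITimeSeries:
    """Simulate the BOLD series for one input block (e.g. a run).

    ``noise_sd`` is a scalar or per-region array of additive i.i.d. Gaussian
    observation noise at the volume level; 0 gives a deterministic output.
    """
    if check_stability and not is_stable(p, np.unique(inputs.u.T, axis=0)):
        raise InstabilityError("coupling matrix is unstable under the design inputs")
    dt = inputs.tr / inputs.bins_per_tr
    y = _simulate_batch(
        p.A[None], p.B[None], p.C[None], inputs.u, dt,
        inputs.bins_per_tr, hp, method=method,
    )[0]  # (n_vol, n)
    y = y.T.copy()
    noise_sd = np.asarray(noise_sd, dtype=float)
    if np.any(noise_sd > 0):
        rng = np.random.default_rng(seed)
        y = y + rng.normal(size=y.shape) * noise_sd.reshape(-1, 1)
    return ROITimeSeries(regions=p.regions, values=y, tr=inputs.tr)


def simulate_session(
    p: DCMParameters,
    hp: HemodynamicParameters,
    session: SessionDesign,
    bins_per_tr: int = 16,
    noise_sd=0.0,
    seed: int | None = None,
    method: str = "rk4",
) -> ROITimeSeries:
    """Simulate each run from rest, drop discarded volumes, concatenate."""
    rng = np.random.default_rng(seed)
    blocks = []
    for run in session.runs:
        one = SessionDesign(runs=(run,), discard=0)
        y = simulate_bold(p, hp, build_inputs(one, bins_per_tr), method=method).values
        blocks.append(y[:, session.discard:])
    y = np.concatenate(blocks, axis=1)
    noise_sd = np.asarray(noise_sd, dtype=float)
    if np.any(noise_sd > 0):
        y = y + rng.normal(size=y.shape) * noise_sd.reshape(-1, 1)
    return ROITimeSeries(regions=p.regions, values=y, tr=session.tr)
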