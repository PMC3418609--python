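"""Variational-Laplace inversion of one model for one subject.

The free neural parameters (enabled A off-diagonals, enabled B entries per
modulatory factor, enabled C gains) are estimated by a Gauss-Newton scheme
on the posterior mean, alternated with EM updates of per-region noise
precision.  The objective is the Laplace free energy

    F = log p(y | theta_hat) - KL( q(theta) || p(theta) ),

with Gaussian shrinkage priors (mean 0; variance 0.25 Hz^2 on A and B,
1 on C).  Steps are accepted only when F increases, so the accepted-F trace
is non-decreasing; rejected steps are halved.

The data timeline mirrors the preprocessing of the analysis: per run the
discarded leading volumes are dropped, runs are concatenated, and a
discrete-cosine high-pass basis (128-s cutoff, including the per-run
constant) is projected out of both the data and the model prediction.

Jacobians come from forward sensitivity equations integrated alongside the
base trajectory (see :mod:`dcmnet.generative`), so one Gauss-Newton
iteration costs only a handful of forward simulations; without the compiled
kernel the code falls back to batched finite differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import generative
from .design import INPUT_NAMES, SessionDesign, build_inputs
from .generative import DCMParameters, HemodynamicParameters, ROITimeSeries
from .model_space import REGIONS, ModelSpec

__all__ = [
    "Prior",
    "Posterior",
    "ParameterMap",
    "default_priors",
    "invert",
    "free_energy",
    "dct_confounds",
    "InversionOptions",
]

logger = logging.getLogger(__name__)

PRIOR_VAR_AB = 0.25
PRIOR_VAR_C = 1.0
HIGHPASS_CUTOFF_S = 128.0

#: map from model-space modulator factor name to input index
_FACTOR_TO_INPUT = {"exec": 1, "hand": 2}


@dataclass(frozen=True)
class ParameterMap:
    """Vectorization of a model's free parameters.

    ``names`` lists parameters in vector order; the index arrays scatter a
    parameter vector into dense A, B and C arrays.
    """

    model: ModelSpec
    regions: tuple[str, ...]
    names: tuple[str, ...]
    a_idx: np.ndarray  # (n_a, 2) row/col indices into A
    b_idx: dict  # input index -> (n_b, 2)
    c_idx: np.ndarray  # (n_c, 2) row/input indices into C
    slices: dict  # block name -> slice into theta

    @property
    def n_params(self) -> int:
        return len(self.names)

    @classmethod
    def from_model(cls, model: ModelSpec, regions=REGIONS) -> "ParameterMap":
        ridx = {r: i for i, r in enumerate(regions)}
        names: list[str] = []
        a_rows = []
        for frm, to in sorted(model.a_edges):
            a_rows.append((ridx[to], ridx[frm]))
            names.append(f"A:{frm}->{to}")
        slices = {"A": slice(0, len(a_rows))}
        b_idx = {}
        pos = len(a_rows)
        for factor in sorted(model.b_edges):
            rows = []
            for frm, to in sorted(model.b_edges[factor]):
                rows.append((ridx[to], ridx[frm]))
                names.append(f"B_{factor}:{frm}->{to}")
            b_idx[_FACTOR_TO_INPUT[factor]] = np.asarray(rows, dtype=int)
            slices[f"B_{factor}"] = slice(pos, pos + len(rows))
            pos += len(rows)
        c_rows = []
        for inp, target in sorted(model.c_inputs):
            c_rows.append((ridx[target], INPUT_NAMES.index(inp)))
            names.append(f"C:{inp}->{target}")
        slices["C"] = slice(pos, pos + len(c_rows))
        return cls(
            model=model,
            regions=tuple(regions),
            names=tuple(names),
            a_idx=np.asarray(a_rows, dtype=int),
            b_idx=b_idx,
            c_idx=np.asarray(c_rows, dtype=int),
            slices=slices,
        )

    def to_matrices(self, theta: np.ndarray) -> DCMParameters:
        """Scatter one parameter vector into a dense parameter set."""
        A, B, C = self.to_matrices_batch(theta[None])
        return DCMParameters(
            A=A[0], B=B[0], C=C[0], regions=self.regions, inputs=INPUT_NAMES
        )

    def to_matrices_batch(self, thetas: np.ndarray):
        """Scatter (P, n_params) parameter vectors into batched A, B, C."""
        P = thetas.shape[0]
        n, m = len(self.regions), len(INPUT_NAMES)
        A = np.zeros((P, n, n))
        A[:, np.arange(n), np.arange(n)] = generative.A_DIAGONAL
        sl = self.slices["A"]
        A[:, self.a_idx[:, 0], self.a_idx[:, 1]] = thetas[:, sl]
        B = np.zeros((P, m, n, n))
        for j, rows in self.b_idx.items():
            factor = {v: k for k, v in _FACTOR_TO_INPUT.items()}[j]
            sl = self.slices[f"B_{factor}"]
            B[:, j, rows[:, 0], rows[:, 1]] = thetas[:, sl]
        C = np.zeros((P, n, m))
        sl = self.slices["C"]
        C[:, self.c_idx[:, 0], self.c_idx[:, 1]] = thetas[:, sl]
        return A, B, C

    def sensitivity_index(self):
        """(par_type, par_j, par_a, par_b) arrays in parameter-vector order.

        par_type: 0 = A entry, 1 = B entry, 2 = C entry; par_j the input
        index (unused for A); par_a the target row; par_b the source column.
        """
        types, js, aas, bs = [], [], [], []
        for row in self.a_idx:
            types.append(0); js.append(-1); aas.append(row[0]); bs.append(row[1])
        for factor in sorted(self.model.b_edges):
            j = _FACTOR_TO_INPUT[factor]
            for row in self.b_idx[j]:
                types.append(1); js.append(j); aas.append(row[0]); bs.append(row[1])
        for row in self.c_idx:
            types.append(2); js.append(row[1]); aas.append(row[0]); bs.append(-1)
        return (np.asarray(types), np.asarray(js), np.asarray(aas), np.asarray(bs))

    def from_matrices(self, p: DCMParameters) -> np.ndarray:
        """Gather a dense parameter set into a vector (inverse of scatter)."""
        parts = [p.A[self.a_idx[:, 0], self.a_idx[:, 1]]]
        for factor in sorted(self.model.b_edges):
            rows = self.b_idx[_FACTOR_TO_INPUT[factor]]
            parts.append(p.B[_FACTOR_TO_INPUT[factor], rows[:, 0], rows[:, 1]])
        parts.append(p.C[self.c_idx[:, 0], self.c_idx[:, 1]])
        return np.concatenate(parts)


@dataclass(frozen=True)
class Prior:
    """Gaussian prior over the free parameter vector."""

    mean: np.ndarray
    variance: np.ndarray
    pmap: ParameterMap

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")


def default_priors(model: ModelSpec, regions=REGIONS) -> Prior:
    """Shrinkage priors: N(0, 0.25) on A/B entries, N(0, 1) on C gains."""
    pmap = ParameterMap.from_model(model, regions)
    var = np.empty(pmap.n_params)
    for name, sl in pmap.slices.items():
        var[sl] = PRIOR_VAR_C if name == "C" else PRIOR_VAR_AB
    return Prior(mean=np.zeros(pmap.n_params), variance=var, pmap=pmap)


@dataclass
class Posterior:
    """Inversion result: Gaussian posterior, evidence and diagnostics."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    noise_precision: np.ndarray  # per region
    iterations: int
    converged: bool
    names: tuple[str, ...]
    f_trace: tuple[float, ...]
    model_id: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "free_energy": self.free_energy,
            "converged": self.converged,
            "iterations": self.iterations,
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "sd": np.sqrt(np.diag(self.cov)).tolist(),
            "noise_precision": self.noise_precision.tolist(),
            "f_trace": list(self.f_trace),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class InversionOptions:
    tol: float = 0.01  # nats; stop when the F gain drops below this
    max_iter: int = 48
    bins_per_tr: int = 16
    fd_step: float = 1e-3
    em_iters: int = 3
    max_halvings: int = 8
    method: str = "rk4"
    # graduated optimization: noise precision starts at lambda_start / var(y)
    # and may grow at most lambda_growth-fold per iteration, so the likelihood
    # sharpens gradually instead of freezing the search in early local modes
    lambda_start: float = 0.01
    lambda_growth: float = 1.5
    # Levenberg-Marquardt ridge factors tried at each iteration
    lm_ridges: tuple = (0.0, 0.3, 3.0, 30.0)
    # Gaussian temporal smoothing (SD in volumes) applied to data and
    # prediction alike; used by the coarse-to-fine continuation
    smooth_sd: float = 0.0
    # number of preselected trial steps verified with exact simulations
    exact_trials: int = 4
    # extra seeded restarts (best final F wins); 0 = single deterministic run
    n_restarts: int = 0
    restart_sd: float = 0.08


def _gaussian_smoother(n: int, sd: float) -> np.ndarray:
    """Row-normalized Gaussian smoothing matrix over n time points."""
    t = np.arange(n)
    W = np.exp(-0.5 * ((t[:, None] - t[None, :]) / sd) ** 2)
    return W / W.sum(axis=1, keepdims=True)


def dct_confounds(n_volumes: int, tr: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """DCT high-pass basis for one run: constant + cosines below the cutoff."""
    order = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    t = np.arange(n_volumes)
    cols = [np.ones(n_volumes) / np.sqrt(n_volumes)]
    for k in range(1, order + 1):
        c = np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_volumes))
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols)


class _ForwardModel:
    """Confound-projected batched forward prediction for one session."""

    def __init__(self, pmap: ParameterMap, session: SessionDesign,
                 hp: HemodynamicParameters, opts: InversionOptions):
        self.pmap = pmap
        self.session = session
        self.hp = hp
        self.opts = opts
        self.run_inputs = [
            build_inputs(SessionDesign(runs=(run,), discard=0), opts.bins_per_tr)
            for run in session.runs
        ]
        self.run_lengths = [r.n_volumes - session.discard for r in session.runs]
        # per-run projector pieces
        self._X = [dct_confounds(nv, session.tr) for nv in self.run_lengths]
        self._Xp = [np.linalg.pinv(X) for X in self._X]
        self.n_volumes = sum(self.run_lengths)
        self.n_confounds = sum(X.shape[1] for X in self._X)
        self.dof = self.n_volumes - self.n_confounds
        self._S = None
        if opts.smooth_sd > 0:
            self._S = [
                _gaussian_smoother(nv, opts.smooth_sd) for nv in self.run_lengths
            ]

    def project(self, y: np.ndarray) -> np.ndarray:
        """Remove per-run DCT confounds (and optionally smooth in time);
        y is (..., n_volumes, n_regions)."""
        out = np.array(y, dtype=float, copy=True)
        start = 0
        for ri, (X, Xp, nv) in enumerate(zip(self._X, self._Xp, self.run_lengths)):
            seg = out[..., start:start + nv, :]
            seg = seg - np.einsum(
                "tk,...kr->...tr", X, np.einsum("kt,...tr->...kr", Xp, seg)
            )
            if self._S is not None:
                seg = np.einsum("ts,...sr->...tr", self._S[ri], seg)
            out[..., start:start + nv, :] = seg
            start += nv
        return out

    def predict_with_jacobian(self, theta: np.ndarray, fd_step: float):
        """Projected prediction and Jacobian at one parameter vector.

        Uses forward sensitivity equations when the compiled kernel is
        available, otherwise batched finite differences.
        """
        n_par = len(theta)
        if generative._sens_kernel_jit is not None:
            p = self.pmap.to_matrices(theta)
            pt, pj, pa, pb = self.pmap.sensitivity_index()
            y_blocks, j_blocks = [], []
            for inp in self.run_inputs:
                y, jac = generative.simulate_with_sensitivities(
                    p.A, p.B, p.C, inp.u, inp.tr / inp.bins_per_tr,
                    inp.bins_per_tr, self.hp, pt, pj, pa, pb,
                )
                y_blocks.append(y[self.session.discard:, :])
                j_blocks.append(jac[:, self.session.discard:, :])
            g0 = np.concatenate(y_blocks, axis=0)
            J = np.concatenate(j_blocks, axis=1)
            if not np.all(np.isfinite(g0)):
                raise generative.InstabilityError(
                    "forward model diverged at the current posterior mean"
                )
            J[~np.all(np.isfinite(J), axis=(1, 2))] = 0.0
            return self.project(g0), self.project(J)
        eye = np.eye(n_par)
        pred = self.predict(
            np.concatenate([theta[None], theta[None] + fd_step * eye], axis=0)
        )
        if not np.all(np.isfinite(pred[0])):
            raise generative.InstabilityError(
                "forward model diverged at the current posterior mean"
            )
        g0 = pred[0]
        J = (pred[1:] - g0[None]) / fd_step
        J[~np.all(np.isfinite(J), axis=(1, 2))] = 0.0
        return g0, J

    def predict(self, thetas: np.ndarray) -> np.ndarray:
        """(P, n_params) -> projected predictions (P, n_volumes, n_regions).

        Divergent parameter vectors yield NaN rows.
        """
        A, B, C = self.pmap.to_matrices_batch(thetas)
        blocks = []
        for run, inp in zip(self.session.runs, self.run_inputs):
            y = generative._simulate_batch(
                A, B, C, inp.u, inp.tr / inp.bins_per_tr, inp.bins_per_tr,
                self.hp, method=self.opts.method, raise_on_diverge=False,
            )
            blocks.append(y[:, self.session.discard:, :])
        y = np.concatenate(blocks, axis=1)
        ok = np.all(np.isfinite(y), axis=(1, 2))
        out = np.full_like(y, np.nan)
        if ok.any():
            out[ok] = self.project(y[ok])
        return out


def _gaussian_loglik(resid: np.ndarray, lam: np.ndarray, dof: int) -> float:
    """Sum over regions of the projected-Gaussian log-likelihood."""
    rss = np.sum(resid ** 2, axis=0)
    return float(np.sum(0.5 * dof * (np.log(lam) - np.log(2 * np.pi)) - 0.5 * lam * rss))


def _kl_gaussian(mean, cov, prior: Prior, logdet_post: float | None = None) -> float:
    p0 = 1.0 / prior.variance
    d = mean - prior.mean
    if logdet_post is None:
        sign, logdet_post = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior covariance not positive definite")
    logdet_prior = float(np.sum(np.log(prior.variance)))
    n = len(mean)
    return 0.5 * (
        float(np.sum(p0 * np.diag(cov))) + float(np.sum(p0 * d * d))
        - n + logdet_prior - logdet_post
    )


def _posterior_cov(H: np.ndarray, p0: np.ndarray):
    """Covariance and log-determinant from the PD posterior precision.

    Cholesky of (H + diag(p0)) is numerically safer than inverting and
    taking slogdet when the precision is huge; jitter grows until it
    factorizes.
    """
    from scipy.linalg import cho_factor, cho_solve

    A = H + np.diag(p0)
    n = A.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            cf = cho_factor(A + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-8 * np.mean(np.diag(A)))
    else:  # pragma: no cover - pathological curvature
        raise np.linalg.LinAlgError("posterior precision could not be factorized")
    cov = cho_solve(cf, np.eye(n))
    cov = 0.5 * (cov + cov.T)
    logdet_post = -2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cov, logdet_post


def invert(
    model: ModelSpec,
    data: ROITimeSeries,
    session: SessionDesign,
    prior: Prior | None = None,
    hp: HemodynamicParameters | None = None,
    opts: InversionOptions | None = None,
    theta0: np.ndarray | None = None,
) -> Posterior:
    """Estimate the posterior over one model's coupling parameters.

    ``data`` must hold the retained (post-discard) concatenated volumes of
    ``session``; its regions must match the model's region set.  ``theta0``
    overrides the starting point (default: the prior mean).  With
    ``opts.n_restarts > 0`` additional seeded starting points are tried and
    the run with the highest final free energy wins (deterministic).
    """
    opts = opts or InversionOptions()
    hp = hp or HemodynamicParameters()
    if prior is None:
        prior = default_priors(model)
    best: Posterior | None = None
    for s in range(opts.n_restarts + 1):
        if s == 0:
            start = theta0
        else:
            rng = np.random.default_rng(1000 + s)
            start = prior.mean + rng.normal(0.0, opts.restart_sd, prior.pmap.n_params)
        try:
            post = _invert_once(model, data, session, prior, hp, opts, start)
        except generative.InstabilityError:
            if s == 0:
                raise
            continue
        if best is None or post.free_energy > best.free_energy:
            best = post
    assert best is not None
    return best


def _invert_once(
    model: ModelSpec,
    data: ROITimeSeries,
    session: SessionDesign,
    prior: Prior,
    hp: HemodynamicParameters,
    opts: InversionOptions,
    theta0: np.ndarray | None,
) -> Posterior:
    pmap = prior.pmap
    if tuple(data.regions) != tuple(pmap.regions):
        raise ValueError("data regions do not match the model's region set")

    fwd = _ForwardModel(pmap, session, hp, opts)
    if data.n_volumes != fwd.n_volumes:
        raise ValueError(
            f"data has {data.n_volumes} volumes but the design retains {fwd.n_volumes}"
        )

    y = fwd.project(data.values.T)  # (T, n)
    n_regions = y.shape[1]
    p0 = 1.0 / prior.variance  # prior precisions
    theta = prior.mean.copy() if theta0 is None else np.asarray(theta0, dtype=float).copy()
    lam = np.full(n_regions, opts.lambda_start / max(np.mean(np.var(y, axis=0)), 1e-12))

    n_par = pmap.n_params
    eye = np.eye(n_par)
    f_trace: list[float] = []
    converged = False
    cov = np.diag(prior.variance)
    it = 0

    for it in range(1, opts.max_iter + 1):
        g0, J = fwd.predict_with_jacobian(theta, opts.fd_step)  # (T, n), (p, T, n)
        resid = y - g0

        # EM updates of noise precision and posterior covariance; precision
        # growth is rate-limited so the surface sharpens gradually
        lam_cap = lam * opts.lambda_growth
        for _ in range(opts.em_iters):
            H = np.einsum("r,ptr,qtr->pq", lam, J, J)  # J^T Lambda J
            cov, logdet_post = _posterior_cov(H, p0)
            trace_term = np.einsum("ptr,pq,qtr->r", J, cov, J)
            rss = np.sum(resid ** 2, axis=0)
            lam_target = fwd.dof / (rss + trace_term + 1e-12)
            lam = np.minimum(lam_target, lam_cap)
        annealing = bool(np.any(lam_target > lam * 1.01))

        # baseline for step acceptance must use the *current* precision:
        # while annealing, F grows with lambda at fixed theta, so comparing
        # against the previous iteration's F would accept fit-worsening steps
        f_curr = (
            _gaussian_loglik(resid, lam, fwd.dof)
            - _kl_gaussian(theta, cov, prior, logdet_post)
        )
        f_trace.append(f_curr)

        # Gauss-Newton directions under several Levenberg-Marquardt ridges,
        # each tried at halved step lengths; all evaluated in one batch
        grad = np.einsum("r,ptr,tr->p", lam, J, resid) - p0 * (theta - prior.mean)
        scales = 0.5 ** np.arange(opts.max_halvings)
        H_full = H + np.diag(p0)
        diag_h = np.diag(np.diag(H_full))
        steps = []
        for mu in opts.lm_ridges:
            step = np.linalg.solve(H_full + mu * diag_h + 1e-10 * eye, grad)
            steps.append(scales[:, None] * step[None])
        trials = theta[None] + np.concatenate(steps, axis=0)
        # preselect with the linearized objective (free), then verify only
        # the most promising candidates with exact simulations
        d_theta = trials - theta[None]
        lin_resid = resid[None] - np.einsum("kp,ptr->ktr", d_theta, J)
        lin_ll = -0.5 * np.einsum(
            "r,ktr,ktr->k", lam, lin_resid, lin_resid
        )
        dp = trials - prior.mean[None]
        lin_pen = 0.5 * np.einsum("kp,p,kp->k", dp, p0, dp)
        order = np.argsort(-(lin_ll - lin_pen))[: opts.exact_trials]
        tpred = fwd.predict(trials[order])
        best_f, best_theta = -np.inf, None
        for kk, k in enumerate(order):
            if not np.all(np.isfinite(tpred[kk])):
                continue
            tresid = y - tpred[kk]
            f_k = (
                _gaussian_loglik(tresid, lam, fwd.dof)
                - _kl_gaussian(trials[k], cov, prior, logdet_post)
            )
            if f_k > best_f:
                best_f, best_theta = f_k, trials[k]
        if best_theta is None or best_f <= f_curr:
            if not annealing:
                converged = True
                break
            continue  # precision still annealing: re-linearize and retry
        gain = best_f - f_curr
        theta = best_theta
        f_trace[-1] = best_f
        logger.debug("iter %d: F=%.3f (gain %.4f)", it, best_f, gain)
        if gain < opts.tol and not annealing:
            converged = True
            break

    # final curvature at the accepted mean
    g0, J = fwd.predict_with_jacobian(theta, opts.fd_step)
    resid = y - g0
    for _ in range(opts.em_iters):
        H = np.einsum("r,ptr,qtr->pq", lam, J, J)
        cov, logdet_post = _posterior_cov(H, p0)
        trace_term = np.einsum("ptr,pq,qtr->r", J, cov, J)
        lam = fwd.dof / (np.sum(resid ** 2, axis=0) + trace_term + 1e-12)
    f_final = _gaussian_loglik(resid, lam, fwd.dof) - _kl_gaussian(
        theta, cov, prior, logdet_post
    )

    return Posterior(
        mean=theta,
        cov=cov,
        free_energy=float(f_final),
        noise_precision=lam,
        iterations=it,
        converged=converged,
        names=pmap.names,
        f_trace=tuple(f_trace),
        model_id=model.model_id,
    )


def free_energy(
    posterior: Posterior,
    model: ModelSpec,
    data: ROITimeSeries,
    session: SessionDesign,
    prior: Prior | None = None,
    hp: HemodynamicParameters | None = None,
    opts: InversionOptions | None = None,
) -> float:
    """Recompute F = loglik(posterior mean) - KL(posterior || prior)."""
    opts = opts or InversionOptions()
    hp = hp or HemodynamicParameters()
    if prior is None:
        prior = default_priors(model, regions=data.regions)
    fwd = _ForwardModel(prior.pmap, session, hp, opts)
    y = fwd.project(data.values.T)
    g0 = fwd.predict(posterior.mean[None])[0]
    resid = y - g0
    ll = _gaussian_loglik(resid, posterior.noise_precision, fwd.dof)
    return float(ll - _kl_gaussian(posterior.mean, posterior.cov, prior))
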