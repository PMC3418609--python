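"""Random-effects Bayesian model selection over subjects x models.

The group-level model treats each subject's generating model as a draw from
a multinomial whose probabilities follow a Dirichlet distribution.  A
digamma fixed-point iteration estimates the Dirichlet concentrations from
the subjects-by-models log-evidence matrix:

    g_nk  proportional to  exp( ev_nk + psi(alpha_k) - psi(sum alpha) )
    alpha_k = alpha0_k + sum_n g_nk

Exceedance probabilities (probability that a model — or a family of models —
is the most frequent in the population) are Monte-Carlo estimates over
Dirichlet samples; argmax counting makes them sum to 1 exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp

from .model_space import FamilyPartition

__all__ = [
    "EvidenceMatrix",
    "DirichletPosterior",
    "BMSResult",
    "FamilyResult",
    "rfx_bms",
    "exceedance",
    "family_inference",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Log-evidence (nats) per subject (rows) and model (columns)."""

    values: np.ndarray
    subjects: tuple[str, ...]
    model_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.subjects), len(self.model_ids)):
            raise ValueError("evidence shape does not match subject/model labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-evidences must be finite")
        if len(self.model_ids) < 2:
            raise ValueError("need at least two models to compare")
        if len(self.subjects) < 1:
            raise ValueError("need at least one subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject"] + [f"model_{m}" for m in self.model_ids])
            for s, row in zip(self.subjects, self.values):
                w.writerow([s] + list(row))

    @classmethod
    def from_csv(cls, path) -> "EvidenceMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        model_ids = tuple(int(c.removeprefix("model_")) for c in rows[0][1:])
        subjects = tuple(r[0] for r in rows[1:])
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(values=values, subjects=subjects, model_ids=model_ids)


@dataclass(frozen=True)
class DirichletPosterior:
    alpha: np.ndarray
    alpha0: np.ndarray
    responsibilities: np.ndarray  # (n_subjects, n_models), rows sum to 1
    model_ids: tuple[int, ...]
    converged: bool
    iterations: int

    @property
    def expected_probabilities(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


@dataclass(frozen=True)
class BMSResult:
    posterior: DirichletPosterior
    exceedance: np.ndarray
    n_samples: int
    seed: int

    @property
    def expected_probabilities(self) -> np.ndarray:
        return self.posterior.expected_probabilities

    @property
    def model_ids(self) -> tuple[int, ...]:
        return self.posterior.model_ids

    def to_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "alpha": self.posterior.alpha.tolist(),
            "expected_probabilities": self.expected_probabilities.tolist(),
            "exceedance_probabilities": self.exceedance.tolist(),
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def rfx_bms(
    ev: EvidenceMatrix,
    alpha0: float | np.ndarray = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> DirichletPosterior:
    """Dirichlet posterior over model frequencies (digamma fixed point)."""
    K = ev.n_models
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")
    alpha = alpha0.copy() + ev.n_subjects / K
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = ev.values + digamma(alpha)[None, :] - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
    return DirichletPosterior(
        alpha=alpha,
        alpha0=alpha0,
        responsibilities=g,
        model_ids=ev.model_ids,
        converged=converged,
        iterations=it,
    )


def exceedance(alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """P(r_k > r_j for all j != k) under Dirichlet(alpha), by argmax counting."""
    alpha = np.asarray(alpha, dtype=float)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    # sample in manageable blocks to bound memory
    counts = np.zeros(len(alpha), dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        block = min(remaining, 200_000)
        r = rng.gamma(shape=alpha, size=(block, len(alpha)))
        counts += np.bincount(np.argmax(r, axis=1), minlength=len(alpha))
        remaining -= block
    return counts / float(n_samples)


def run_bms(
    ev: EvidenceMatrix,
    alpha0: float | np.ndarray = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Convenience wrapper: Dirichlet posterior + exceedance probabilities."""
    post = rfx_bms(ev, alpha0=alpha0)
    phi = exceedance(post.alpha, n_samples=n_samples, seed=seed)
    return BMSResult(posterior=post, exceedance=phi, n_samples=n_samples, seed=seed)


@dataclass(frozen=True)
class FamilyResult:
    partition_name: str
    families: tuple[str, ...]
    expected_probabilities: np.ndarray
    exceedance: np.ndarray
    posterior: DirichletPosterior
    n_samples: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "partition": self.partition_name,
            "families": list(self.families),
            "expected_probabilities": self.expected_probabilities.tolist(),
            "exceedance_probabilities": self.exceedance.tolist(),
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def family_inference(
    ev: EvidenceMatrix,
    partition: FamilyPartition,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> FamilyResult:
    """Family-level BMS: equal prior mass per family, pooled over members."""
    part = partition.restrict(ev.model_ids)
    if part.model_ids != frozenset(ev.model_ids):
        missing = set(ev.model_ids) - part.model_ids
        raise ValueError(f"partition does not cover models {sorted(missing)}")
    fam_names = tuple(part.families)
    # rebalanced prior: each family receives total prior mass 1
    alpha0 = np.empty(ev.n_models)
    for fam, ids in part.families.items():
        for mid in ids:
            alpha0[ev.model_ids.index(mid)] = 1.0 / len(ids)
    post = rfx_bms(ev, alpha0=alpha0)

    member = np.zeros((len(fam_names), ev.n_models))
    for fi, fam in enumerate(fam_names):
        for mid in part.families[fam]:
            member[fi, ev.model_ids.index(mid)] = 1.0

    expected = member @ post.expected_probabilities

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(fam_names), dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        block = min(remaining, 200_000)
        r = rng.gamma(shape=post.alpha, size=(block, ev.n_models))
        r /= r.sum(axis=1, keepdims=True)
        fam_mass = r @ member.T
        counts += np.bincount(np.argmax(fam_mass, axis=1), minlength=len(fam_names))
        remaining -= block
    phi = counts / float(n_samples)
    return FamilyResult(
        partition_name=part.name,
        families=fam_names,
        expected_probabilities=expected,
        exceedance=phi,
        posterior=post,
        n_samples=n_samples,
        seed=seed,
    )
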