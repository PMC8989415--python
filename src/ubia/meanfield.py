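"""Naive mean-field solution of the indicator Ising system.

The posterior over indicator spins is a pairwise Ising model whose fields
scale as eps and couplings as eps^2, where eps is the inverse regularization
strength of the prior over interaction coefficients.  Magnetizations
m_mu = 2<s_mu> - 1 obey the self-consistent equations

    atanh(m_mu(eps)) = (eps/2) [ h_mu + eps sum_nu J_mu_nu
                                       + eps^2 sum_nu J_mu_nu m_nu(eps) ],

solved by damped fixed-point iteration while eps is swept from 0 (total
ignorance, m = 0) upward in steps of delta_eps = 1/(20 M).  The sweep stops at
eps_max = min(eps1, eps2): eps1 = 1/M keeps the prior narrower than the
likelihood, and eps2 is the largest grid point at which the second-order terms
remain perturbative, mean_mu |h_mu| >= mean_mu |eps h_eff_mu(eps)| with
h_eff_mu = sum_nu J_mu_nu + eps sum_nu J_mu_nu m_nu.

An exact-enumeration oracle over all 2^S indicator states is provided for
small systems; TAP corrections are higher order in eps and are not applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .candidates import IsingSystem

__all__ = [
    "SolverOptions",
    "EpsilonSchedule",
    "MeanFieldTrajectory",
    "mean_field_update",
    "solve_trajectory",
    "perturbative_bound",
    "exact_indicator_marginals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverOptions:
    """Fixed-point iteration controls.

    The map is contractive in practice because fields and couplings enter at
    order eps <= 1/M; damping engages only if the residual grows.
    """

    tol: float = 1e-10
    max_sweeps: int = 1000
    damping: float = 0.5


@dataclass
class EpsilonSchedule:
    """The eps grid: 0, delta, 2*delta, ..., eps1 with delta = 1/(20 M)."""

    M: int

    @property
    def step(self) -> float:
        return 1.0 / (20.0 * self.M)

    @property
    def eps1(self) -> float:
        return 1.0 / self.M

    @property
    def grid(self) -> np.ndarray:
        return self.step * np.arange(1, 21)


@dataclass
class MeanFieldTrajectory:
    """Magnetizations along the eps sweep, with schedule diagnostics."""

    eps_grid: np.ndarray
    m: np.ndarray                    # (n_eps, S) magnetizations
    h_eff: np.ndarray                # (n_eps, S) effective interaction fields
    converged: np.ndarray            # per-eps convergence flags
    eps1: float
    eps2: float | None               # largest grid eps passing the bound; None if never violated
    eps_max: float

    @property
    def final_m(self) -> np.ndarray:
        """Magnetizations at eps_max (the detection statistic)."""
        if self.m.shape[0] == 0:
            return np.zeros(0)
        return self.m[-1]

    def diagnostics(self) -> dict:
        return {
            "eps1": self.eps1,
            "eps2": self.eps2,
            "eps_max": self.eps_max,
            "n_eps": int(self.eps_grid.size),
            "all_converged": bool(self.converged.all()) if self.converged.size else True,
        }


def mean_field_update(system: IsingSystem, m_current: np.ndarray, eps: float,
                      row_sum: np.ndarray | None = None) -> np.ndarray:
    """One sweep of the self-consistent magnetization equations."""
    m_current = np.asarray(m_current, dtype=np.float64)
    if not np.all(np.isfinite(m_current)):
        raise ValueError("non-finite magnetizations passed to mean_field_update")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if row_sum is None:
        row_sum = system.J.sum(axis=1)
    arg = 0.5 * eps * (system.h + eps * row_sum + eps * eps * (system.J @ m_current))
    return np.tanh(arg)


def _effective_field(system: IsingSystem, m: np.ndarray, eps: float,
                     row_sum: np.ndarray | None = None) -> np.ndarray:
    if row_sum is None:
        row_sum = system.J.sum(axis=1)
    return row_sum + eps * (system.J @ m)


def perturbative_bound(system: IsingSystem, m: np.ndarray, eps: float) -> bool:
    """True while second-order terms stay below first order on average:
    mean_mu |h_mu| >= mean_mu |eps * h_eff_mu(eps)|."""
    if system.size == 0:
        return True
    h_eff = _effective_field(system, m, eps)
    return bool(np.mean(np.abs(system.h)) >= np.mean(np.abs(eps * h_eff)))


def _fixed_point(system: IsingSystem, m0: np.ndarray, eps: float,
                 opts: SolverOptions, row_sum: np.ndarray) -> tuple[np.ndarray, bool]:
    m = m0.copy()
    prev_res = np.inf
    damp = 0.0
    for _ in range(opts.max_sweeps):
        m_new = mean_field_update(system, m, eps, row_sum)
        if damp:
            m_new = (1.0 - damp) * m_new + damp * m
        res = float(np.max(np.abs(m_new - m))) if m.size else 0.0
        m = m_new
        if res < opts.tol:
            return m, True
        if res > prev_res and not damp:
            damp = opts.damping  # oscillation detected
        prev_res = res
    return m, False


def solve_trajectory(system: IsingSystem, M: int | None = None,
                     solver_opts: SolverOptions | None = None) -> MeanFieldTrajectory:
    """Sweep eps from 0 to eps_max, warm-starting each fixed point.

    The sweep terminates at the first grid point violating the perturbative
    bound; eps2 is the last grid point satisfying it.  If even the first grid
    point violates the bound, that single step is used (with a warning).
    """
    M = M if M is not None else system.M
    opts = solver_opts or SolverOptions()
    sched = EpsilonSchedule(M)
    row_sum = system.J.sum(axis=1) if system.size else np.zeros(0)

    eps_list: list[float] = []
    m_list: list[np.ndarray] = []
    heff_list: list[np.ndarray] = []
    conv_list: list[bool] = []
    m = np.zeros(system.size)
    eps2: float | None = None
    for eps in sched.grid:
        m_eps, ok = _fixed_point(system, m, eps, opts, row_sum)
        if not ok:
            logger.warning("mean-field iteration did not converge at eps=%g", eps)
        if not perturbative_bound(system, m_eps, eps):
            if not eps_list:
                warnings.warn(
                    "perturbative bound violated at the first eps step; "
                    "using the first step anyway", stacklevel=2,
                )
                eps2 = float(eps)
                eps_list.append(float(eps))
                m_list.append(m_eps)
                heff_list.append(_effective_field(system, m_eps, eps, row_sum))
                conv_list.append(ok)
            else:
                eps2 = eps_list[-1]
            break
        eps_list.append(float(eps))
        m_list.append(m_eps)
        heff_list.append(_effective_field(system, m_eps, eps, row_sum))
        conv_list.append(ok)
        m = m_eps

    eps_max = min(sched.eps1, eps2) if eps2 is not None else sched.eps1
    return MeanFieldTrajectory(
        eps_grid=np.array(eps_list),
        m=np.array(m_list) if m_list else np.zeros((0, system.size)),
        h_eff=np.array(heff_list) if heff_list else np.zeros((0, system.size)),
        converged=np.array(conv_list, dtype=bool),
        eps1=sched.eps1,
        eps2=eps2,
        eps_max=eps_max,
    )


def exact_indicator_marginals(system: IsingSystem, eps: float, limit: int = 20) -> np.ndarray:
    """Exact magnetizations by summing the Boltzmann weights of all 2^S
    indicator states (oracle for small systems; refuses above ``limit``)."""
    S = system.size
    if S > limit:
        raise ValueError(f"exact enumeration refuses S={S} > {limit} candidates")
    if S == 0:
        return np.zeros(0)
    states = ((np.arange(2 ** S)[:, None] >> np.arange(S)[None, :]) & 1).astype(np.float64)
    # ordered-pair double sum over mu != nu: s^T J s counts each pair twice,
    # matching the first-order term eps * sum_nu J_mu_nu of the mean field.
    energy = eps * states @ system.h + eps * eps * np.einsum(
        "ij,jk,ik->i", states, system.J, states
    )
    energy -= energy.max()
    w = np.exp(energy)
    p = w / w.sum()
    s_mean = p @ states
    return 2.0 * s_mean - 1.0
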