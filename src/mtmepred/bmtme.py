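"""Bayesian multi-trait multi-environment mixed model, fitted by Gibbs sampling.

The model, for J lines, I environments and L traits (n = J*I cells):

    Y = X beta + Z1 b1 + Z2 b2 + E

* ``Y`` (n x L): phenotypes, one row per (line, environment) cell;
* ``X`` (n x I), ``beta`` (I x L): environment-by-trait fixed effects;
* ``Z1`` (n x J), ``b1`` (J x L): genotype-by-trait random effects,
  b1 ~ MN(0, G, Sigma_t) with G the genomic relationship matrix and
  Sigma_t the genetic trait covariance;
* ``Z2`` (n x IJ), ``b2`` (IJ x L): genotype-by-environment-by-trait
  effects, b2 ~ MN(0, Sigma_E (x) G, Sigma_t) — optional;
* ``E`` ~ MN(0, I_n, Re): residuals with trait covariance Re.

MN(H, Omega, Sigma) is the matrix-variate normal: vec(M) is multivariate
normal with mean vec(H) and covariance Sigma (x) Omega.

All full conditionals are conjugate: Gaussian for beta, b1, b2 and
inverse-Wishart for Sigma_t, Sigma_E, Re.  The sampler works in the
eigenbasis of G (and, for b2, of Sigma_E (x) G), where each conditional
factorizes into independent L x L blocks; see docs/methods.md for the
derivations.  Unobserved cells are handled by data augmentation: their
rows of Y are redrawn each sweep from N(row mean, Re), which leaves the
posterior over parameters given the observed rows unchanged while
keeping every update in complete-data form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

from .data import MTMEDataset, build_design

__all__ = [
    "BMTMEPriors",
    "BMTMEState",
    "PosteriorChains",
    "BMTMERegressor",
    "matrix_normal_logpdf",
    "sample_matrix_normal",
    "gibbs_step_beta",
    "gibbs_step_b1",
    "gibbs_step_b2",
    "gibbs_step_sigma_t",
    "gibbs_step_sigma_E",
    "gibbs_step_Re",
    "run_gibbs",
    "predict",
]


# ---------------------------------------------------------------------------
# Matrix-variate normal primitives
# ---------------------------------------------------------------------------

def _chol_pd(A: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


def matrix_normal_logpdf(
    M: np.ndarray, H: np.ndarray, Omega: np.ndarray, Sigma: np.ndarray
) -> float:
    """Log-density of M ~ MN(H, Omega, Sigma).

    Equals the multivariate-normal log-density of vec(M) with mean
    vec(H) and covariance ``Sigma (x) Omega`` but never forms the
    np x np Kronecker product: it uses

        -np/2 log(2 pi) - p/2 log|Omega| - n/2 log|Sigma|
        - 1/2 tr(Sigma^-1 (M-H)' Omega^-1 (M-H))
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    n, p = M.shape
    if H.shape != (n, p) or Omega.shape != (n, n) or Sigma.shape != (p, p):
        raise ValueError("dimension mismatch in matrix_normal_logpdf")
    Lo = _chol_pd(Omega, "Omega")
    Ls = _chol_pd(Sigma, "Sigma")
    D = M - H
    # tr(Sigma^-1 D' Omega^-1 D) = ||Lo^-1 D Ls^-T||_F^2
    A = solve_triangular(Lo, D, lower=True)
    B = solve_triangular(Ls, A.T, lower=True)
    quad = float(np.sum(B * B))
    logdet_O = 2.0 * float(np.sum(np.log(np.diag(Lo))))
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(Ls))))
    return -0.5 * (n * p * math.log(2.0 * math.pi) + p * logdet_O + n * logdet_S + quad)


def sample_matrix_normal(
    H: np.ndarray,
    Omega: np.ndarray,
    Sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw M ~ MN(H, Omega, Sigma) as ``H + A Z B'`` with AA' = Omega, BB' = Sigma."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n, p = H.shape
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Omega.shape != (n, n) or Sigma.shape != (p, p):
        raise ValueError("dimension mismatch in sample_matrix_normal")
    A = _psd_factor(Omega)
    B = _psd_factor(Sigma)
    Z = rng.standard_normal((n, p))
    return H + A @ Z @ B.T


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """A factor F with F F' = S; Cholesky when PD, eigen-root otherwise."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(S)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("covariance is not positive semi-definite")
        return V * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# Priors, state, chains
# ---------------------------------------------------------------------------

@dataclass
class BMTMEPriors:
    """Prior settings for the Gibbs sampler.

    The covariance priors are inverse-Wishart IW(nu, S) with density
    proportional to |X|^-(nu+d+1)/2 exp(-tr(S X^-1)/2).  Defaults are
    weakly informative and proper: nu = dim + 2, S = I (prior mean = I).
    ``beta_precision`` is the precision of an independent N(0, 1/tau)
    prior on each fixed effect; 0 gives the flat (improper) prior.
    """

    nu_t: float | None = None
    S_t: np.ndarray | None = None
    nu_E: float | None = None
    S_E: np.ndarray | None = None
    nu_R: float | None = None
    S_R: np.ndarray | None = None
    beta_precision: float = 0.0

    def resolved(self, I: int, L: int) -> "BMTMEPriors":
        """Fill unset hyperparameters with defaults for the given dims."""
        out = BMTMEPriors(
            nu_t=self.nu_t if self.nu_t is not None else L + 2,
            S_t=np.asarray(self.S_t, float) if self.S_t is not None else np.eye(L),
            nu_E=self.nu_E if self.nu_E is not None else I + 2,
            S_E=np.asarray(self.S_E, float) if self.S_E is not None else np.eye(I),
            nu_R=self.nu_R if self.nu_R is not None else L + 2,
            S_R=np.asarray(self.S_R, float) if self.S_R is not None else np.eye(L),
            beta_precision=self.beta_precision,
        )
        for nu, S, d, nm in (
            (out.nu_t, out.S_t, L, "Sigma_t"),
            (out.nu_E, out.S_E, I, "Sigma_E"),
            (out.nu_R, out.S_R, L, "Re"),
        ):
            if nu <= d - 1:
                raise ValueError(f"prior df for {nm} must exceed dim - 1")
            if S.shape != (d, d) or not np.allclose(S, S.T):
                raise ValueError(f"prior scale for {nm} must be symmetric {d}x{d}")
        return out


@dataclass
class BMTMEState:
    """One Gibbs iteration's parameter values."""

    beta: np.ndarray               # (I, L)
    b1: np.ndarray                 # (J, L)
    b2: np.ndarray | None          # (I*J, L) or None without the GxE term
    Sigma_t: np.ndarray            # (L, L)
    Sigma_E: np.ndarray | None     # (I, I) or None without the GxE term
    Re: np.ndarray                 # (L, L)

    def copy(self) -> "BMTMEState":
        return BMTMEState(
            self.beta.copy(), self.b1.copy(),
            None if self.b2 is None else self.b2.copy(),
            self.Sigma_t.copy(),
            None if self.Sigma_E is None else self.Sigma_E.copy(),
            self.Re.copy(),
        )

    def is_finite(self) -> bool:
        arrays = [self.beta, self.b1, self.Sigma_t, self.Re]
        if self.b2 is not None:
            arrays += [self.b2, self.Sigma_E]
        return all(np.isfinite(a).all() for a in arrays)


@dataclass
class PosteriorChains:
    """Retained post-burn-in draws and their posterior means."""

    draws: dict[str, np.ndarray]   # name -> (n_kept, *shape)
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None
    include_gxe: bool
    env_ids: list[str] = field(default_factory=list)
    trait_ids: list[str] = field(default_factory=list)
    line_ids: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=0)

    def posterior_sd(self, name: str) -> np.ndarray:
        return self.draws[name].std(axis=0, ddof=1)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - level) / 2.0
        lo = np.quantile(self.draws[name], a, axis=0)
        hi = np.quantile(self.draws[name], 1.0 - a, axis=0)
        return lo, hi

    def split_rhat(self, name: str) -> np.ndarray:
        """Split-chain potential scale reduction factor per element."""
        x = self.draws[name]
        m = x.shape[0] // 2
        halves = np.stack([x[:m], x[m:2 * m]])        # (2, m, ...)
        mean_h = halves.mean(axis=1)
        var_h = halves.var(axis=1, ddof=1)
        W = var_h.mean(axis=0)
        B = m * mean_h.var(axis=0, ddof=1)
        var_plus = (m - 1) / m * W + B / m
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(var_plus / W)

    def to_frame(self):
        """Flatten retained draws into a tidy table (one row per draw)."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {}
        for name, arr in self.draws.items():
            flat = arr.reshape(arr.shape[0], -1)
            shape = arr.shape[1:]
            for k in range(flat.shape[1]):
                idx = np.unravel_index(k, shape) if shape else ()
                label = name + "[" + ",".join(str(i + 1) for i in idx) + "]" if idx else name
                cols[label] = flat[:, k]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Workspace: precomputed quantities shared by the Gibbs blocks
# ---------------------------------------------------------------------------

class _Workspace:
    """Design matrices, GRM eigendecomposition and index bookkeeping."""

    def __init__(self, ds: MTMEDataset, include_gxe: bool):
        self.ds = ds
        self.include_gxe = include_gxe
        self.J, self.I, self.L = ds.n_lines, ds.n_envs, ds.n_traits
        self.n = ds.n_cells
        design = build_design(ds)
        self.X, self.Z1, self.Z2 = design.X, design.Z1, design.Z2
        G = ds.grm.jittered().values
        self.G = G
        w, U = np.linalg.eigh(G)
        w = np.clip(w, 1e-12, None)
        self.g_eigvals = w            # (J,)
        self.g_eigvecs = U            # (J, J)
        # complete-data crossproduct counts (each cell observed once)
        self.env_counts = self.X.sum(axis=0)          # (I,) = J each
        self.line_counts = self.Z1.sum(axis=0)        # (J,) = I each
        # row index of cell (i, j) is i*J + j in environment-major order
        self.env_of_row = np.repeat(np.arange(self.I), self.J)
        self.line_of_row = np.tile(np.arange(self.J), self.I)

    def fitted(self, state: BMTMEState) -> np.ndarray:
        """Model mean X beta + Z1 b1 (+ Z2 b2) at every cell."""
        M = state.beta[self.env_of_row] + state.b1[self.line_of_row]
        if self.include_gxe and state.b2 is not None:
            M = M + state.b2[self.env_of_row * self.J + self.line_of_row]
        return M


def _workspace(ds: MTMEDataset, include_gxe: bool) -> _Workspace:
    return _Workspace(ds, include_gxe)


def _batched_mvn_draws(
    prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw x_k ~ N(P_k^-1 h_k, P_k^-1) for stacked L x L precisions.

    ``prec`` has shape (K, L, L), ``lin`` shape (K, L).  Uses batched
    Cholesky: x = P^-1 h + L^-T z.
    """
    try:
        C = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular posterior precision; consider jittering the GRM"
        ) from exc
    mean = np.linalg.solve(prec, lin[..., None])[..., 0]
    z = rng.standard_normal(lin.shape)
    # solve L^T x = z  (batched)
    upper = np.swapaxes(C, -1, -2)
    noise = np.linalg.solve(upper, z[..., None])[..., 0]
    return mean + noise


def _require_complete(Y: np.ndarray) -> None:
    if np.isnan(Y).any():
        raise ValueError(
            "Gibbs blocks require complete responses; augment or subset missing rows first"
        )


# ---------------------------------------------------------------------------
# Full-conditional updates (complete-data form)
# ---------------------------------------------------------------------------

def gibbs_step_beta(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
    Y: np.ndarray | None = None,
) -> BMTMEState:
    """Draw beta from its Gaussian full conditional.

    With residual rows iid N(0, Re) and X'X diagonal (one environment per
    row), environments decouple: row i of beta has precision
    ``c_i Re^-1 + tau I`` and mean ``P_i^-1 Re^-1 (X'Yr)_i`` where Yr is
    the partial residual and tau the prior precision (0 = flat).
    """
    work = data if isinstance(data, _Workspace) else _workspace(data, state.b2 is not None)
    Y = work.ds.Y if Y is None else Y
    _require_complete(Y)
    pri = priors.resolved(work.I, work.L)
    Yr = Y - work.fitted(state) + state.beta[work.env_of_row]
    S = work.X.T @ Yr                                     # (I, L)
    Re_inv = np.linalg.inv(state.Re)
    prec = (work.env_counts[:, None, None] * Re_inv[None]
            + pri.beta_precision * np.eye(work.L)[None])
    lin = S @ Re_inv                                      # (I, L): rows (Re^-1 S_i')'
    new = state.copy()
    new.beta = _batched_mvn_draws(prec, lin, rng)
    return new


def gibbs_step_b1(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
    Y: np.ndarray | None = None,
) -> BMTMEState:
    """Draw the genotype-by-trait effects b1 from their full conditional.

    In the eigenbasis G = U diag(d) U' the JL x JL Gaussian conditional
    factorizes into J independent L x L blocks with precision
    ``d_k^-1 Sigma_t^-1 + c Re^-1``.
    """
    work = data if isinstance(data, _Workspace) else _workspace(data, state.b2 is not None)
    Y = work.ds.Y if Y is None else Y
    _require_complete(Y)
    Yr = Y - work.fitted(state) + state.b1[work.line_of_row]
    S = work.Z1.T @ Yr                                    # (J, L)
    U, d = work.g_eigvecs, work.g_eigvals
    S_rot = U.T @ S
    Re_inv = np.linalg.inv(state.Re)
    St_inv = np.linalg.inv(state.Sigma_t)
    c = work.line_counts.mean()                           # = I on the complete grid
    prec = (1.0 / d)[:, None, None] * St_inv[None] + c * Re_inv[None]
    lin = S_rot @ Re_inv
    b_rot = _batched_mvn_draws(prec, lin, rng)
    new = state.copy()
    new.b1 = U @ b_rot
    return new


def gibbs_step_b2(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
    Y: np.ndarray | None = None,
) -> BMTMEState:
    """Draw the genotype-by-environment effects b2 from their full conditional.

    Prior row covariance is ``Sigma_E (x) G``; its eigenbasis is the
    Kronecker product of the two eigenbases, so the IJL-dimensional
    conditional factorizes into IJ blocks of size L with precision
    ``mu_m^-1 Sigma_t^-1 + Re^-1`` (each cell appears once).
    """
    if state.b2 is None or state.Sigma_E is None:
        raise ValueError("the GxE term is not enabled in this state")
    work = data if isinstance(data, _Workspace) else _workspace(data, True)
    Y = work.ds.Y if Y is None else Y
    _require_complete(Y)
    J, I, L = work.J, work.I, work.L
    Yr = Y - work.fitted(state) + state.b2[work.env_of_row * J + work.line_of_row]
    S = work.Z2.T @ Yr                                    # (IJ, L)
    U, d = work.g_eigvecs, work.g_eigvals
    lamE, P = np.linalg.eigh(state.Sigma_E)
    lamE = np.clip(lamE, 1e-12, None)
    S_rot = _rot_kron(S, U.T, P, I, J)
    mu = (lamE[:, None] * d[None, :]).reshape(I * J)      # eigenvalues of Sigma_E (x) G
    Re_inv = np.linalg.inv(state.Re)
    St_inv = np.linalg.inv(state.Sigma_t)
    prec = (1.0 / mu)[:, None, None] * St_inv[None] + Re_inv[None]
    lin = S_rot @ Re_inv
    b_rot = _batched_mvn_draws(prec, lin, rng)
    new = state.copy()
    new.b2 = _rot_kron(b_rot, U, P.T, I, J)
    return new


def _rot_kron(M: np.ndarray, Uc: np.ndarray, Pc: np.ndarray, I: int, J: int) -> np.ndarray:
    """Apply (Pc' (x) Uc) column-wise to an (IJ, L) matrix via reshaping.

    Row index m = i*J + j.  For each trait column v, with V[j, i] =
    v[i*J + j], the product (A (x) B) v equals B V A' in the same
    indexing; the output column is Uc V Pc.  Passing Uc = U', Pc = P
    rotates into the eigenbasis of Sigma_E (x) G; Uc = U, Pc = P'
    rotates back.
    """
    L = M.shape[1]
    out = np.empty_like(M)
    for l in range(L):
        V = M[:, l].reshape(I, J).T                       # (J, I)
        W = Uc @ V @ Pc
        out[:, l] = W.T.reshape(I * J)
    return out


def gibbs_step_sigma_t(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
) -> BMTMEState:
    """Draw Sigma_t ~ IW from its full conditional.

    Pools b1' G^-1 b1 (J pseudo-observations) and, when the GxE term is
    present, b2' (Sigma_E (x) G)^-1 b2 (IJ pseudo-observations).
    """
    work = data if isinstance(data, _Workspace) else _workspace(data, state.b2 is not None)
    pri = priors.resolved(work.I, work.L)
    U, d = work.g_eigvecs, work.g_eigvals
    b1_rot = U.T @ state.b1
    scale = pri.S_t + b1_rot.T @ (b1_rot / d[:, None])
    df = pri.nu_t + work.J
    if state.b2 is not None and state.Sigma_E is not None:
        I, J = work.I, work.J
        lamE, P = np.linalg.eigh(state.Sigma_E)
        lamE = np.clip(lamE, 1e-12, None)
        b2_rot = _rot_kron(state.b2, U.T, P, I, J)
        mu = (lamE[:, None] * d[None, :]).reshape(I * J)
        scale = scale + b2_rot.T @ (b2_rot / mu[:, None])
        df += I * J
    new = state.copy()
    new.Sigma_t = _invwishart_rvs(df, scale, rng)
    return new


def gibbs_step_sigma_E(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
) -> BMTMEState:
    """Draw Sigma_E ~ IW from its full conditional.

    As a function of Sigma_E, the b2 prior contributes J*L
    pseudo-observations with scale Q[i,i'] = sum_{l,l'}
    (Sigma_t^-1)[l,l'] (V_l' G^-1 V_l')[i,i'] where V_l is b2's trait-l
    column folded into a J x I matrix.
    """
    if state.b2 is None or state.Sigma_E is None:
        raise ValueError("the GxE term is not enabled in this state")
    work = data if isinstance(data, _Workspace) else _workspace(data, True)
    pri = priors.resolved(work.I, work.L)
    I, J, L = work.I, work.J, work.L
    U, d = work.g_eigvecs, work.g_eigvals
    # A_l = D^-1/2 U' V_l, so V_l' G^-1 V_l' = A_l' A_l'
    A = np.empty((L, J, I))
    for l in range(L):
        V = state.b2[:, l].reshape(I, J).T
        A[l] = (U.T @ V) / np.sqrt(d)[:, None]
    St_inv = np.linalg.inv(state.Sigma_t)
    Q = np.einsum("lm,lji,mjk->ik", St_inv, A, A)
    new = state.copy()
    new.Sigma_E = _invwishart_rvs(pri.nu_E + J * L, pri.S_E + Q, rng)
    return new


def gibbs_step_Re(
    state: BMTMEState,
    data: MTMEDataset | _Workspace,
    priors: BMTMEPriors,
    rng: np.random.Generator,
    Y: np.ndarray | None = None,
) -> BMTMEState:
    """Draw Re ~ IW(nu + n, S + E'E) with E the current residual matrix."""
    work = data if isinstance(data, _Workspace) else _workspace(data, state.b2 is not None)
    Y = work.ds.Y if Y is None else Y
    _require_complete(Y)
    pri = priors.resolved(work.I, work.L)
    E = Y - work.fitted(state)
    new = state.copy()
    new.Re = _invwishart_rvs(pri.nu_R + Y.shape[0], pri.S_R + E.T @ E, rng)
    return new


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scale = 0.5 * (scale + scale.T)
    try:
        draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    except np.linalg.LinAlgError as exc:
        raise ValueError("inverse-Wishart scale matrix is not positive definite") from exc
    return np.atleast_2d(draw)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def _initial_state(work: _Workspace, include_gxe: bool) -> BMTMEState:
    L, I, J = work.L, work.I, work.J
    Y = work.ds.Y
    beta = np.zeros((I, L))
    for i in range(I):
        rows = Y[work.env_of_row == i]
        with np.errstate(invalid="ignore"):
            m = np.nanmean(rows, axis=0)
        beta[i] = np.where(np.isfinite(m), m, 0.0)
    return BMTMEState(
        beta=beta,
        b1=np.zeros((J, L)),
        b2=np.zeros((I * J, L)) if include_gxe else None,
        Sigma_t=np.eye(L),
        Sigma_E=np.eye(I) if include_gxe else None,
        Re=np.eye(L),
    )


def run_gibbs(
    data: MTMEDataset,
    include_gxe: bool = True,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    thin: int = 2,
    priors: BMTMEPriors | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorChains:
    """Run the Gibbs sampler and return retained post-burn-in draws.

    Cells whose phenotype row is entirely missing are treated as
    prediction targets: each sweep starts by drawing them from their
    conditional N(row mean, Re) (data augmentation), so they contribute
    nothing to the marginal posterior given the observed rows.  With
    ``include_gxe=False`` the Z2 b2 term and Sigma_E are absent from the
    model.  Deterministic given ``seed``.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    work = _workspace(data, include_gxe)
    priors = (priors or BMTMEPriors()).resolved(work.I, work.L)
    if rng is None:
        rng = np.random.default_rng(seed)

    obs = work.ds.observed_mask()
    if not obs.any():
        raise ValueError("no observed cells")
    for i in range(work.I):
        if not obs[work.env_of_row == i].any():
            raise ValueError(f"environment {work.ds.env_ids[i]} has no observed cells")
    partial = obs & np.isnan(work.ds.Y).any(axis=1)
    if partial.any():
        raise ValueError(
            "cells with some but not all traits observed are not supported; "
            "mask whole cells"
        )

    state = _initial_state(work, include_gxe)
    Y = work.ds.Y.copy()
    Y[~obs] = state.beta[work.env_of_row[~obs]]          # initial fill for test cells

    names = ["beta", "b1", "Sigma_t", "Re"] + (["b2", "Sigma_E"] if include_gxe else [])
    kept: dict[str, list[np.ndarray]] = {k: [] for k in names}
    kept["fitted"] = []

    for it in range(n_iter):
        if (~obs).any():
            M = work.fitted(state)
            Lr = _chol_pd(state.Re, "Re")
            z = rng.standard_normal((int((~obs).sum()), work.L))
            Y[~obs] = M[~obs] + z @ Lr.T
        state = gibbs_step_beta(state, work, priors, rng, Y=Y)
        state = gibbs_step_b1(state, work, priors, rng, Y=Y)
        if include_gxe:
            state = gibbs_step_b2(state, work, priors, rng, Y=Y)
        state = gibbs_step_sigma_t(state, work, priors, rng)
        if include_gxe:
            state = gibbs_step_sigma_E(state, work, priors, rng)
        state = gibbs_step_Re(state, work, priors, rng, Y=Y)
        if not state.is_finite():
            raise FloatingPointError(f"sampler diverged at iteration {it}")
        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in names:
                kept[k].append(getattr(state, k).copy())
            kept["fitted"].append(work.fitted(state))

    draws = {k: np.stack(v) for k, v in kept.items()}
    return PosteriorChains(
        draws=draws, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed,
        include_gxe=include_gxe, env_ids=list(data.env_ids),
        trait_ids=list(data.trait_ids), line_ids=list(data.line_ids),
    )


def predict(
    chains: PosteriorChains,
    data: MTMEDataset,
    target_cells: list[tuple[str, str]],
) -> np.ndarray:
    """Posterior-mean prediction for the given (line, env) cells.

    The predictor is the posterior mean of the model mean
    X beta + Z1 b1 (+ Z2 b2) at each cell; unobserved cells borrow
    information through the GRM-structured random effects.
    """
    mean_fitted = chains.posterior_mean("fitted")
    rows = []
    for line, env in target_cells:
        if line not in data.line_ids:
            raise KeyError(f"unknown line id {line!r}")
        if env not in data.env_ids:
            raise KeyError(f"unknown environment id {env!r}")
        rows.append(data.cell_index(line, env))
    return mean_fitted[rows]


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class BMTMERegressor(RegressorMixin, BaseEstimator):
    """Bayesian multi-trait multi-environment genomic predictor.

    Parameters
    ----------
    include_gxe : bool, default True
        Include the genotype-by-environment term Z2 b2 with its
        Kronecker-structured ``Sigma_E (x) G`` covariance.
    n_iter, burn_in, thin : int
        Gibbs chain settings; ``floor((n_iter - burn_in)/thin)`` draws
        are retained.
    priors : BMTMEPriors or None
        Prior hyperparameters; None uses flat beta and IW(dim+2, I).
    random_state : int or None
        Seed for the sampler; fixed seed gives bitwise-identical chains.

    Attributes
    ----------
    chains_ : PosteriorChains
    posterior_mean_ : dict of parameter name -> posterior mean array
    """

    def __init__(
        self,
        include_gxe: bool = True,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 2,
        priors: BMTMEPriors | None = None,
        random_state: int | None = None,
    ):
        self.include_gxe = include_gxe
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.priors = priors
        self.random_state = random_state

    def fit(self, X: MTMEDataset, y=None) -> "BMTMERegressor":
        """Fit on the observed cells of an :class:`MTMEDataset`."""
        if not isinstance(X, MTMEDataset):
            raise TypeError("BMTMERegressor.fit expects an MTMEDataset")
        self.chains_ = run_gibbs(
            X, include_gxe=self.include_gxe, n_iter=self.n_iter,
            burn_in=self.burn_in, thin=self.thin, priors=self.priors,
            seed=self.random_state,
        )
        self.dataset_ = X
        self.posterior_mean_ = {
            k: self.chains_.posterior_mean(k) for k in self.chains_.draws
        }
        return self

    def predict(self, cells: list[tuple[str, str]]) -> np.ndarray:
        if not hasattr(self, "chains_"):
            raise AttributeError("fit the model before predicting")
        return predict(self.chains_, self.dataset_, list(cells))
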