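"""Sampler-correctness diagnostics for the Bayesian engine.

Two heavy-duty checks live here so that both the test suite and the
reproduction script can run them:

* :func:`geweke_test` — the joint-distribution ("getting it right")
  test: statistics of (parameters, data) drawn by forward simulation
  from the prior must match the same statistics from a
  successive-conditional chain that alternates one Gibbs sweep with a
  re-simulation of the data.  Any error in a full conditional shows up
  as a non-zero mean difference; z-scores beyond ~4 flag a bug.

* :func:`recovery_study` — simulate datasets from the generative model,
  fit the sampler, and measure how often the 95% credible intervals for
  the covariance components cover the generating values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bmtme import (
    BMTMEPriors,
    BMTMEState,
    _invwishart_rvs,
    _workspace,
    gibbs_step_b1,
    gibbs_step_b2,
    gibbs_step_beta,
    gibbs_step_Re,
    gibbs_step_sigma_E,
    gibbs_step_sigma_t,
    run_gibbs,
    sample_matrix_normal,
)
from .data import MTMEDataset
from .simulate import SimulationConfig, simulate_dataset, simulate_markers

__all__ = ["geweke_test", "recovery_study"]


def _prior_draw(work, priors: BMTMEPriors, rng, include_gxe: bool) -> BMTMEState:
    I, J, L = work.I, work.J, work.L
    tau = priors.beta_precision
    beta = rng.standard_normal((I, L)) / np.sqrt(tau)
    Sigma_t = _invwishart_rvs(priors.nu_t, priors.S_t, rng)
    Re = _invwishart_rvs(priors.nu_R, priors.S_R, rng)
    b1 = sample_matrix_normal(np.zeros((J, L)), work.G, Sigma_t, rng)
    if include_gxe:
        Sigma_E = _invwishart_rvs(priors.nu_E, priors.S_E, rng)
        K = np.kron(Sigma_E, work.G)
        b2 = sample_matrix_normal(np.zeros((I * J, L)), K, Sigma_t, rng)
    else:
        Sigma_E, b2 = None, None
    return BMTMEState(beta, b1, b2, Sigma_t, Sigma_E, Re)


def _simulate_Y(work, state: BMTMEState, rng) -> np.ndarray:
    M = work.fitted(state)
    Lr = np.linalg.cholesky(state.Re)
    return M + rng.standard_normal(M.shape) @ Lr.T


def _statistics(state: BMTMEState, Y: np.ndarray, include_gxe: bool) -> np.ndarray:
    iu_L = np.triu_indices(state.Sigma_t.shape[0])
    stats_vec = [
        state.beta.ravel(),                      # first moments of beta
        state.beta.ravel() ** 2,                 # second moments of beta
        state.Sigma_t[iu_L],
        state.Re[iu_L],
        [state.b1.mean(), (state.b1 ** 2).mean()],
        [Y.mean(), (Y ** 2).mean()],
    ]
    if include_gxe and state.Sigma_E is not None:
        iu_I = np.triu_indices(state.Sigma_E.shape[0])
        stats_vec.append(state.Sigma_E[iu_I])
        stats_vec.append([(state.b2 ** 2).mean()])
    return np.concatenate([np.asarray(v, float).ravel() for v in stats_vec])


def _stat_names(I: int, L: int, include_gxe: bool) -> list[str]:
    names = [f"beta[{i+1},{l+1}]" for i in range(I) for l in range(L)]
    names += [f"beta^2[{i+1},{l+1}]" for i in range(I) for l in range(L)]
    iu = np.triu_indices(L)
    names += [f"Sigma_t[{a+1},{b+1}]" for a, b in zip(*iu)]
    names += [f"Re[{a+1},{b+1}]" for a, b in zip(*iu)]
    names += ["mean(b1)", "mean(b1^2)", "mean(Y)", "mean(Y^2)"]
    if include_gxe:
        iuI = np.triu_indices(I)
        names += [f"Sigma_E[{a+1},{b+1}]" for a, b in zip(*iuI)]
        names += ["mean(b2^2)"]
    return names


def _batch_se(x: np.ndarray, n_batches: int = 30) -> np.ndarray:
    """Batch-means standard error of the mean for autocorrelated draws."""
    n = x.shape[0]
    m = n // n_batches
    b = x[: m * n_batches].reshape(n_batches, m, -1).mean(axis=1)
    return b.std(axis=0, ddof=1) / np.sqrt(n_batches)


def geweke_test(
    J: int = 5,
    I: int = 2,
    L: int = 2,
    p: int = 30,
    n_sweeps: int = 50_000,
    include_gxe: bool = True,
    seed: int = 0,
    thin: int = 2,
) -> dict:
    """Joint-distribution test of the Gibbs sampler.

    Returns a dict with the statistic names, the marginal-conditional
    and successive-conditional means, and the z-scores of their
    differences.  Uses proper priors throughout (Gaussian beta with unit
    precision, inverse-Wishart with df = dim + 10 so the compared
    moments are finite).
    """
    rng = np.random.default_rng(seed)
    W = simulate_markers(J, p, rng=rng)
    grm_ids = W.line_ids
    from .data import compute_grm

    grm = compute_grm(W).jittered()
    env_ids = [f"Env{i+1}" for i in range(I)]
    trait_ids = [f"T{l+1}" for l in range(L)]
    cells = [(line, env) for env in env_ids for line in grm_ids]
    ds = MTMEDataset(cells, np.zeros((J * I, L)), env_ids, trait_ids, grm, grm_ids)
    work = _workspace(ds, include_gxe)
    priors = BMTMEPriors(
        nu_t=L + 10, S_t=np.eye(L) * (L + 10 - L - 1),
        nu_E=I + 10, S_E=np.eye(I) * (I + 10 - I - 1),
        nu_R=L + 10, S_R=np.eye(L) * (L + 10 - L - 1),
        beta_precision=1.0,
    ).resolved(I, L)

    # marginal-conditional: iid draws from the joint prior-predictive
    n_mc = max(n_sweeps // thin, 1)
    mc = []
    for _ in range(n_mc):
        st = _prior_draw(work, priors, rng, include_gxe)
        Y = _simulate_Y(work, st, rng)
        mc.append(_statistics(st, Y, include_gxe))
    mc = np.asarray(mc)

    # successive-conditional: n_sweeps Gibbs sweeps, each followed by a
    # data re-simulation; record every `thin`-th state
    st = _prior_draw(work, priors, rng, include_gxe)
    Y = _simulate_Y(work, st, rng)
    sc = []
    for s in range(n_sweeps):
        st = gibbs_step_beta(st, work, priors, rng, Y=Y)
        st = gibbs_step_b1(st, work, priors, rng, Y=Y)
        if include_gxe:
            st = gibbs_step_b2(st, work, priors, rng, Y=Y)
        st = gibbs_step_sigma_t(st, work, priors, rng)
        if include_gxe:
            st = gibbs_step_sigma_E(st, work, priors, rng)
        st = gibbs_step_Re(st, work, priors, rng, Y=Y)
        Y = _simulate_Y(work, st, rng)
        if s % thin == 0:
            sc.append(_statistics(st, Y, include_gxe))
    sc = np.asarray(sc)

    se_mc = mc.std(axis=0, ddof=1) / np.sqrt(mc.shape[0])
    se_sc = _batch_se(sc)
    z = (mc.mean(axis=0) - sc.mean(axis=0)) / np.sqrt(se_mc ** 2 + se_sc ** 2)
    return {
        "names": _stat_names(I, L, include_gxe),
        "mc_mean": mc.mean(axis=0),
        "sc_mean": sc.mean(axis=0),
        "z": z,
        "max_abs_z": float(np.abs(z).max()),
        "n_statistics": int(z.size),
    }


def recovery_study(
    n_replicates: int = 20,
    J: int = 100,
    I: int = 3,
    L: int = 2,
    p: int = 200,
    n_iter: int = 6_000,
    burn_in: int = 3_000,
    thin: int = 2,
    include_gxe: bool = True,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Credible-interval coverage for Sigma_t and Re across replicates.

    Each replicate simulates a dataset from the generative model with
    known covariances, runs the sampler, and checks element-wise whether
    the central ``level`` credible interval covers the generating value.
    Returns per-element coverage rates and the overall rates.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_replicates)]
    hits_t, hits_r = [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(J=J, I=I, L=L, p=p, include_gxe=include_gxe,
                               seed=child[r])
        ds, truth = simulate_dataset(cfg)
        chains = run_gibbs(ds, include_gxe=include_gxe, n_iter=n_iter,
                           burn_in=burn_in, thin=thin, seed=child[r] + 1)
        for name, target, store in (
            ("Sigma_t", truth.config.Sigma_t, hits_t),
            ("Re", truth.config.Re, hits_r),
        ):
            lo, hi = chains.credible_interval(name, level)
            store.append((lo <= target) & (target <= hi))
    cov_t = np.mean(hits_t, axis=0)
    cov_r = np.mean(hits_r, axis=0)
    return {
        "coverage_Sigma_t": cov_t,
        "coverage_Re": cov_r,
        "min_coverage": float(min(cov_t.min(), cov_r.min())),
        "overall_coverage": float(np.mean([cov_t.mean(), cov_r.mean()])),
        "n_replicates": n_replicates,
    }
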