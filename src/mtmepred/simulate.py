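"""Synthetic multi-trait multi-environment genomic data.

Data are generated from the same linear model the Bayesian engine fits:

    Y = X beta + Z1 b1 + Z2 b2 + E,
    b1 ~ MN(0, G, Sigma_t),  b2 ~ MN(0, Sigma_E (x) G, Sigma_t),
    E ~ MN(0, I_n, Re),

with G built from simulated biallelic markers.  Markers are drawn under
Hardy-Weinberg proportions at independent loci (no linkage
disequilibrium) with per-locus allele frequencies uniform over a MAF
range — deliberately simple population genetics, sufficient to exercise
every consumer of the data.

The generator keeps the realized effects (``SimulatedTruth``) so that
prediction accuracy can be scored against true genetic values and the
reconstruction identity Y = X beta + Z1 b1 + Z2 b2 + E can be asserted
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bmtme import sample_matrix_normal
from .data import GRM, MarkerMatrix, MTMEDataset, compute_grm, impute_markers

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_markers",
           "simulate_dataset", "mask_cells"]


def _default_beta(I: int, L: int) -> np.ndarray:
    # distinct small integers per environment-trait, so fixed-effect
    # recovery is visually checkable
    return np.arange(1, I * L + 1, dtype=float).reshape(I, L)


@dataclass
class SimulationConfig:
    """Generator settings; defaults give a well-conditioned 2-trait design."""

    J: int = 50
    I: int = 3
    L: int = 2
    p: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    beta: np.ndarray | None = None
    Sigma_t: np.ndarray | None = None
    Sigma_E: np.ndarray | None = None
    Re: np.ndarray | None = None
    include_gxe: bool = True
    missing_marker_rate: float = 0.0
    seed: int | None = None

    def resolved(self) -> "SimulationConfig":
        cfg = SimulationConfig(**{**self.__dict__})
        if cfg.beta is None:
            cfg.beta = _default_beta(cfg.I, cfg.L)
        else:
            cfg.beta = np.asarray(cfg.beta, float)
        # moderate genetic correlation / moderate GxE by default
        if cfg.Sigma_t is None:
            cfg.Sigma_t = np.full((cfg.L, cfg.L), 0.4) + 0.6 * np.eye(cfg.L)
        else:
            cfg.Sigma_t = np.asarray(cfg.Sigma_t, float)
        if cfg.Sigma_E is None:
            cfg.Sigma_E = np.full((cfg.I, cfg.I), 0.2) + 0.8 * np.eye(cfg.I)
        else:
            cfg.Sigma_E = np.asarray(cfg.Sigma_E, float)
        if cfg.Re is None:
            cfg.Re = np.full((cfg.L, cfg.L), 0.1) + 0.4 * np.eye(cfg.L)
        else:
            cfg.Re = np.asarray(cfg.Re, float)
        for name, M in (("Sigma_t", cfg.Sigma_t), ("Sigma_E", cfg.Sigma_E),
                        ("Re", cfg.Re)):
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if not (0.0 <= cfg.missing_marker_rate < 1.0):
            raise ValueError("missing_marker_rate must be in [0, 1)")
        if cfg.beta.shape != (cfg.I, cfg.L):
            raise ValueError("beta must be I x L")
        return cfg


@dataclass
class SimulatedTruth:
    """Realized parameters and effects behind one simulated dataset."""

    beta: np.ndarray
    b1: np.ndarray
    b2: np.ndarray | None
    E: np.ndarray
    genetic_values: np.ndarray     # Z1 b1 (+ Z2 b2), (n, L)
    config: SimulationConfig
    grm: GRM
    grm_jittered: bool = False

    def signal_fraction(self, ds: MTMEDataset) -> np.ndarray:
        """Realized per (environment, trait) share of phenotypic variance
        explained by the genetic value — a calibrated h2 surrogate."""
        I, J = ds.n_envs, ds.n_lines
        out = np.empty((I, ds.n_traits))
        for i in range(I):
            rows = slice(i * J, (i + 1) * J)
            gv = self.genetic_values[rows]
            y = gv + self.E[rows]
            out[i] = gv.var(axis=0) / y.var(axis=0)
        return out


def simulate_markers(
    J: int,
    p: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    missing_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MarkerMatrix:
    """Draw -1/0/1 genotypes at independent loci under Hardy-Weinberg.

    Each locus gets an allele frequency f ~ Uniform(maf_range); genotype
    codes -1/0/1 occur with probabilities (1-f)^2, 2f(1-f), f^2.
    Missing entries are masked completely at random at ``missing_rate``.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    f = rng.uniform(lo, hi, size=p)
    u = rng.random((J, p))
    p_low = (1.0 - f) ** 2
    p_mid = 2.0 * f * (1.0 - f)
    vals = np.where(u < p_low, -1.0, np.where(u < p_low + p_mid, 0.0, 1.0))
    if missing_rate > 0.0:
        mask = rng.random((J, p)) < missing_rate
        vals = np.where(mask, np.nan, vals)
    lines = [f"L{j + 1:04d}" for j in range(J)]
    markers = [f"M{k + 1:05d}" for k in range(p)]
    return MarkerMatrix(vals, lines, markers)


def simulate_dataset(
    cfg: SimulationConfig,
    markers: MarkerMatrix | None = None,
) -> tuple[MTMEDataset, SimulatedTruth]:
    """Simulate one dataset from the generative model.

    Builds the GRM from simulated (or supplied) markers, draws the
    matrix-variate effects, assembles Y in environment-major cell order
    and returns the dataset together with the realized truth.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    if markers is None:
        markers = simulate_markers(cfg.J, cfg.p, cfg.maf_range,
                                   cfg.missing_marker_rate, rng=rng)
    if np.isnan(markers.values).any():
        markers = impute_markers(markers)
    grm = compute_grm(markers)
    grm_j = grm.jittered()
    jittered = grm_j is not grm
    G = grm_j.values
    J, I, L = cfg.J, cfg.I, cfg.L
    n = J * I

    b1 = sample_matrix_normal(np.zeros((J, L)), G, cfg.Sigma_t, rng)
    b2 = None
    if cfg.include_gxe:
        K = np.kron(cfg.Sigma_E, G)
        b2 = sample_matrix_normal(np.zeros((I * J, L)), K, cfg.Sigma_t, rng)
    E = sample_matrix_normal(np.zeros((n, L)), np.eye(n), cfg.Re, rng)

    env_of_row = np.repeat(np.arange(I), J)
    line_of_row = np.tile(np.arange(J), I)
    genetic = b1[line_of_row].copy()
    if b2 is not None:
        genetic += b2[env_of_row * J + line_of_row]
    Y = cfg.beta[env_of_row] + genetic + E

    env_ids = [f"Env{i + 1}" for i in range(I)]
    trait_ids = [f"Trait{l + 1}" for l in range(L)]
    cells = [(line, env) for env in env_ids for line in markers.line_ids]
    ds = MTMEDataset(cells, Y, env_ids, trait_ids, grm_j, list(markers.line_ids))
    truth = SimulatedTruth(beta=cfg.beta, b1=b1, b2=b2, E=E,
                           genetic_values=genetic, config=cfg, grm=grm_j,
                           grm_jittered=jittered)
    return ds, truth


def mask_cells(ds: MTMEDataset, partition) -> MTMEDataset:
    """Return a copy of ``ds`` with the partition's test cells set missing."""
    out = ds.copy()
    for cell in partition.test_cells:
        out.Y[ds.cell_index(*cell)] = np.nan
    return out
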