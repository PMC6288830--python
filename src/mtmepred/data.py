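"""Phenotype/marker containers, quality control, and model design matrices.

This module holds the data layer of the toolkit: marker matrices coded
-1/0/1, the genomic relationship matrix (GRM) ``G = W W'/p``, the aligned
multi-trait multi-environment phenotype table, the incidence matrices of
the linear model ``Y = X beta + Z1 b1 + Z2 b2 + E``, and per-trait
standardization.

Conventions frozen here and relied on everywhere else:

* Missing values are ``numpy.nan`` in float arrays.
* Dataset cells are **environment-major**: all lines of environment 1,
  then environment 2, and so on.  Lines are ordered by first appearance
  in the phenotype input.  ``Z2``'s column for line ``j`` in environment
  ``i`` is ``i * J + j`` — the ordering that makes the genotype-by-
  environment covariance the Kronecker product ``Sigma_E (x) G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MarkerMatrix",
    "GRM",
    "MTMEDataset",
    "DesignMatrices",
    "TraitScaler",
    "filter_markers",
    "impute_markers",
    "compute_grm",
    "build_design",
    "fit_scaler",
    "read_phenotypes",
    "read_markers",
    "read_grm",
    "write_phenotypes",
    "write_markers",
]

_VALID_CODES = (-1.0, 0.0, 1.0)


@dataclass
class MarkerMatrix:
    """Biallelic markers for J lines, coded -1/0/1 with NaN for missing."""

    values: np.ndarray  # (J, p) float
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if self.values.ndim != 2:
            raise ValueError("marker values must be a 2-D array")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"marker matrix shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids in marker matrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, _VALID_CODES).all():
            bad = finite[~np.isin(finite, _VALID_CODES)][:5]
            raise ValueError(f"marker codes must be -1/0/1; found {bad}")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing entries."""
        return np.isnan(self.values).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency.

        Allele dosage of the coded allele is ``(code + 1) / 2``; the MAF
        is the smaller of the two allele frequencies, computed over
        non-missing lines only.  Markers with no non-missing entry get
        NaN.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean((self.values + 1.0) / 2.0, axis=0)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class GRM:
    """Genomic relationship matrix: symmetric PSD, one row per line."""

    values: np.ndarray  # (J, J)
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        J = len(self.line_ids)
        if self.values.shape != (J, J):
            raise ValueError("GRM must be square and match the line ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)
        w = np.linalg.eigvalsh(self.values)
        lam_max = max(w[-1], 0.0)
        if w[0] < -1e-8 * max(lam_max, 1.0):
            raise ValueError(
                f"GRM is not positive semi-definite (min eigenvalue {w[0]:.3g})"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def jittered(self) -> "GRM":
        """Return a strictly PD copy, adding eps*I only if needed.

        eps = 1e-8 * trace / J, the smallest nudge that keeps Cholesky and
        eigen-based solvers downstream stable when G is singular (p < J or
        duplicated genotypes).
        """
        w = np.linalg.eigvalsh(self.values)
        J = self.n_lines
        eps = 1e-8 * np.trace(self.values) / J
        if eps <= 0:
            eps = 1e-8
        if w[0] < eps:
            out = GRM(self.values + (eps - min(w[0], 0.0)) * np.eye(J), self.line_ids)
            return out
        return self


@dataclass
class DesignMatrices:
    """Incidence matrices of the mixed model, rows in dataset cell order."""

    X: np.ndarray   # (n, I)  environment incidence
    Z1: np.ndarray  # (n, J)  line incidence
    Z2: np.ndarray  # (n, I*J) line-within-environment incidence


@dataclass
class MTMEDataset:
    """Aligned multi-trait multi-environment phenotypes plus a GRM.

    ``cells`` is the single source of truth for row indexing: an
    environment-major list of ``(line_id, env_id)`` pairs of length
    ``n = J * I``.  ``Y`` has one row per cell and one column per trait;
    NaN rows mark unobserved (prediction-target) cells.
    """

    cells: list[tuple[str, str]]
    Y: np.ndarray  # (n, L)
    env_ids: list[str]
    trait_ids: list[str]
    grm: GRM
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not self.line_ids:
            # preserve first-appearance order within the first environment
            seen: dict[str, None] = {}
            for line, _ in self.cells:
                seen.setdefault(line, None)
            self.line_ids = list(seen)
        J, I = len(self.line_ids), len(self.env_ids)
        n = J * I
        if len(self.cells) != n:
            raise ValueError(f"expected {n} = J x I cells, got {len(self.cells)}")
        if self.Y.shape != (n, len(self.trait_ids)):
            raise ValueError("Y shape does not match cells x traits")
        if len(set(self.cells)) != n:
            raise ValueError("duplicate (line, env) cells")
        expected = [
            (line, env) for env in self.env_ids for line in self.line_ids
        ]
        if self.cells != expected:
            raise ValueError("cells must be environment-major in the dataset's line order")
        missing = set(self.line_ids) - set(self.grm.line_ids)
        if missing:
            raise ValueError(f"lines absent from GRM: {sorted(missing)}")
        if self.grm.line_ids != self.line_ids:
            idx = [self.grm.line_ids.index(l) for l in self.line_ids]
            self.grm = GRM(self.grm.values[np.ix_(idx, idx)], list(self.line_ids))

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, line_id: str, env_id: str) -> int:
        j = self.line_ids.index(line_id)
        i = self.env_ids.index(env_id)
        return i * self.n_lines + j

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of rows with at least one observed trait."""
        return ~np.isnan(self.Y).all(axis=1)

    def copy(self) -> "MTMEDataset":
        return MTMEDataset(
            list(self.cells), self.Y.copy(), list(self.env_ids),
            list(self.trait_ids), GRM(self.grm.values.copy(), list(self.grm.line_ids)),
            list(self.line_ids),
        )


def filter_markers(
    W: MarkerMatrix,
    max_missing_rate: float = 0.8,
    min_maf: float = 0.05,
    maf_inclusive: bool = True,
) -> MarkerMatrix:
    """Drop markers by missing rate and minor allele frequency.

    A marker is kept when its missing fraction is <= ``max_missing_rate``
    and its MAF clears ``min_maf``.  With ``maf_inclusive=True`` (the
    default) markers with MAF *equal* to the threshold are removed too —
    the "lower than or equal to 0.05" rule used for GBS maize panels; set
    it to False for the strictly-lower wheat rule at 0.01.  MAF is
    computed from allele dosages over non-missing lines.  Column order is
    preserved.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss_ok = W.missing_rate() <= max_missing_rate
    maf = W.maf()
    with np.errstate(invalid="ignore"):
        maf_ok = (maf > min_maf) if maf_inclusive else (maf >= min_maf)
    maf_ok &= np.isfinite(maf)
    keep = miss_ok & maf_ok
    if not keep.any():
        raise ValueError("empty marker set: every marker was filtered out")
    return MarkerMatrix(
        W.values[:, keep],
        list(W.line_ids),
        [m for m, k in zip(W.marker_ids, keep) if k],
    )


def impute_markers(W: MarkerMatrix) -> MarkerMatrix:
    """Replace missing genotypes by the per-marker mean of observed codes.

    Imputed values are real-valued (not rounded back to -1/0/1).
    """
    vals = W.values.copy()
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(W.marker_ids, all_missing) if a]
        raise ValueError(f"markers with no observed genotypes cannot be imputed: {bad}")
    col_means = np.nanmean(vals, axis=0)
    idx = np.where(np.isnan(vals))
    vals[idx] = col_means[idx[1]]
    out = MarkerMatrix.__new__(MarkerMatrix)  # imputed values leave the -1/0/1 code set
    out.values = vals
    out.line_ids = list(W.line_ids)
    out.marker_ids = list(W.marker_ids)
    return out


def compute_grm(W: MarkerMatrix) -> GRM:
    """Genomic relationship matrix ``G = W W' / p``.

    The marker codes are used exactly as given — no centring by allele
    frequency is applied.  (VanRaden's original formulation centres by
    2*p_k; here the cross-product of the raw -1/0/1 codes divided by the
    marker count is taken literally.)  Markers must be imputed first.
    """
    if np.isnan(W.values).any():
        raise ValueError("marker matrix has missing entries; run impute_markers first")
    if W.n_markers < 1:
        raise ValueError("need at least one marker")
    G = W.values @ W.values.T / W.n_markers
    return GRM(G, list(W.line_ids))


def build_design(ds: MTMEDataset) -> DesignMatrices:
    """Incidence matrices X (environments), Z1 (lines), Z2 (line-in-env).

    Row order matches ``ds.cells``; Z2's column for cell (line j, env i)
    is ``i * J + j``, compatible with a Kronecker-structured
    ``Sigma_E (x) G`` covariance over its effects.
    """
    J, I, n = ds.n_lines, ds.n_envs, ds.n_cells
    X = np.zeros((n, I))
    Z1 = np.zeros((n, J))
    Z2 = np.zeros((n, I * J))
    for r, (line, env) in enumerate(ds.cells):
        j = ds.line_ids.index(line)
        i = ds.env_ids.index(env)
        X[r, i] = 1.0
        Z1[r, j] = 1.0
        Z2[r, i * J + j] = 1.0
    return DesignMatrices(X=X, Z1=Z1, Z2=Z2)


class TraitScaler(TransformerMixin, BaseEstimator):
    """Per-trait standardization: subtract mean, divide by sample SD.

    The SD uses the n-1 (sample) denominator.  Fit on training cells
    only; NaNs are ignored during fitting and propagated by transform.

    Attributes
    ----------
    means_ : (L,) per-trait means of the non-missing training values
    sds_ : (L,) per-trait sample standard deviations (ddof=1)
    """

    def fit(self, Y: np.ndarray, y=None) -> "TraitScaler":
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n_obs = (~np.isnan(Y)).sum(axis=0)
        if (n_obs < 2).any():
            raise ValueError(
                f"each trait needs >=2 non-missing training values; counts {n_obs}"
            )
        self.means_ = np.nanmean(Y, axis=0)
        self.sds_ = np.nanstd(Y, axis=0, ddof=1)
        if (self.sds_ <= 0).any():
            bad = int(np.argmin(self.sds_))
            raise ValueError(f"trait column {bad} has zero variance; cannot standardize")
        self.n_features_in_ = Y.shape[1]
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        out = (Y - self.means_) / self.sds_
        return out[:, 0] if squeeze else out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        squeeze = Z.ndim == 1
        if squeeze:
            Z = Z[:, None]
        out = Z * self.sds_ + self.means_
        return out[:, 0] if squeeze else out


def fit_scaler(Y_train: np.ndarray) -> TraitScaler:
    """Fit a :class:`TraitScaler` on training responses (NaNs allowed)."""
    return TraitScaler().fit(Y_train)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype={0: str},
                       comment="#", skip_blank_lines=True)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: columns Line, Env, then one per trait."""
    df = _read_table(path)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "Line" or cols[1] != "Env":
        raise ValueError(
            f"{path}: expected header 'Line', 'Env', <traits...>; got {cols[:3]}"
        )
    df["Line"] = df["Line"].astype(str)
    df["Env"] = df["Env"].astype(str)
    return df


def read_markers(path) -> MarkerMatrix:
    """Read a marker table: first column Line, remaining columns markers."""
    df = _read_table(path)
    if df.columns[0] != "Line":
        raise ValueError(f"{path}: first column must be 'Line'")
    lines = df["Line"].astype(str).tolist()
    vals = df.drop(columns="Line").to_numpy(dtype=float)
    return MarkerMatrix(vals, lines, list(df.columns[1:]))


def read_grm(path) -> GRM:
    """Read a square GRM table whose first row/column hold line ids."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, comment="#")
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise ValueError(f"{path}: GRM row and column ids differ")
    return GRM(df.to_numpy(dtype=float), ids_row)


def write_phenotypes(ds: MTMEDataset, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(ds.cells, columns=["Line", "Env"])
    for l, t in enumerate(ds.trait_ids):
        df[t] = ds.Y[:, l]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_markers(W: MarkerMatrix, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(W.values, columns=W.marker_ids)
    df.insert(0, "Line", W.line_ids)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def dataset_from_tables(
    pheno: pd.DataFrame,
    grm: GRM | None = None,
    markers: MarkerMatrix | None = None,
) -> MTMEDataset:
    """Assemble an :class:`MTMEDataset` from a phenotype table and genotypes.

    Exactly one of ``grm`` / ``markers`` must be given; markers are imputed
    and turned into a GRM with the default pipeline.  Line ids must
    reconcile between the phenotype and genotype inputs; the symmetric
    difference is reported otherwise.  Cells absent from the phenotype
    table are filled with NaN so that the cell grid is complete.
    """
    if (grm is None) == (markers is None):
        raise ValueError("provide exactly one of grm or markers")
    if grm is None:
        assert markers is not None
        grm = compute_grm(impute_markers(markers)).jittered()

    trait_ids = [c for c in pheno.columns if c not in ("Line", "Env")]
    line_ids: list[str] = list(dict.fromkeys(pheno["Line"]))
    env_ids: list[str] = list(dict.fromkeys(pheno["Env"]))

    pheno_lines, geno_lines = set(line_ids), set(grm.line_ids)
    if pheno_lines != geno_lines:
        only_p = sorted(pheno_lines - geno_lines)
        only_g = sorted(geno_lines - pheno_lines)
        raise ValueError(
            "line ids do not reconcile between phenotypes and genotypes; "
            f"phenotype-only: {only_p[:10]}, genotype-only: {only_g[:10]}"
        )

    J, I, L = len(line_ids), len(env_ids), len(trait_ids)
    Y = np.full((J * I, L), np.nan)
    cells = [(line, env) for env in env_ids for line in line_ids]
    pos = {c: r for r, c in enumerate(cells)}
    for _, row in pheno.iterrows():
        key = (row["Line"], row["Env"])
        if key not in pos:
            raise ValueError(f"unknown cell {key}")
        Y[pos[key]] = [row[t] for t in trait_ids]
    return MTMEDataset(cells, Y, env_ids, trait_ids, grm, line_ids)
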