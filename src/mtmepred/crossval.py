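"""CV2 cross-validation and prediction-accuracy summaries.

The CV2 scheme predicts *tested lines in tested environments*: whole
(line, environment) cells — all traits at once — are masked and
predicted from the remaining cells.  One random partition is built as:

1. let N = J*I be the number of cells and m = round(p_testing * N);
2. draw m lines — with replacement when J < m, without otherwise;
3. for each drawn line pick one environment uniformly at random;
4. the distinct (line, environment) pairs so obtained form the test
   set; every other cell is training.

Partitions are drawn independently, so a cell can appear in the test
set of several partitions but never in both sets of one partition.

Accuracy is the Pearson correlation between predictions and observed
values per (trait, environment) stratum and partition; the partition
mean and its standard error (SD across partitions / sqrt(#partitions))
summarize each stratum, and dividing by sqrt(h2) expresses accuracy
relative to the trait-environment heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmtme import BMTMERegressor
from .data import MTMEDataset
from .mtdl import HyperGrid, encode_features, inner_cv_select, train_mtdl

__all__ = [
    "CVPartition",
    "cv2_partition",
    "pearson_by_trait_env",
    "adjust_by_heritability",
    "summarize_accuracy",
    "run_comparison",
    "ENGINE_VARIANTS",
]

ENGINE_VARIANTS = ("bmtme_gxe", "bmtme_no_gxe", "mtdl_gxe", "mtdl_no_gxe")


@dataclass
class CVPartition:
    """One random train/test split at cell granularity."""

    partition_index: int
    test_cells: set
    train_cells: set
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.test_cells & self.train_cells:
            raise ValueError("test and training cells overlap")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def cv2_partition(
    ds: MTMEDataset,
    p_testing: float = 0.2,
    n_partitions: int = 10,
    seed: int | None = None,
) -> list[CVPartition]:
    """Draw independent CV2 partitions of the dataset's observed cells."""
    if not 0.0 < p_testing < 1.0:
        raise ValueError("p_testing must be in (0, 1)")
    obs_mask = ds.observed_mask()
    all_cells = [c for c, o in zip(ds.cells, obs_mask) if o]
    N = len(all_cells)
    J, I = ds.n_lines, ds.n_envs
    m = _round_half_away(p_testing * N)
    if m < 1:
        raise ValueError("p_testing too small: empty test set")
    with_replacement = J < m
    rng = np.random.default_rng(seed)
    lines = np.array(ds.line_ids)
    envs = np.array(ds.env_ids)
    out = []
    for k in range(n_partitions):
        drawn = rng.choice(lines, size=m, replace=with_replacement)
        chosen_envs = rng.choice(envs, size=m, replace=True)
        test = {(l, e) for l, e in zip(drawn, chosen_envs)}
        test &= set(all_cells)
        train = set(all_cells) - test
        for i, env in enumerate(ds.env_ids):
            if not any(e == env for _, e in train):
                warnings.warn(
                    f"partition {k}: environment {env} has no training cells",
                    stacklevel=2,
                )
        out.append(CVPartition(k, test, train, seed=seed))
    return out


def pearson_by_trait_env(
    predictions: np.ndarray,
    truth: np.ndarray,
    cells: list[tuple[str, str]],
    trait_ids: list[str],
    partition_index: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation per (trait, environment) stratum.

    Strata with fewer than two cells, or with zero variance in either
    vector, are reported as NaN (with a warning), never as zero.
    """
    predictions = np.asarray(predictions, float)
    truth = np.asarray(truth, float)
    if predictions.shape != truth.shape or predictions.shape[0] != len(cells):
        raise ValueError("predictions, truth and cells must align")
    env_of = np.array([e for _, e in cells])
    rows = []
    for env in dict.fromkeys(env_of):
        sel = env_of == env
        for l, trait in enumerate(trait_ids):
            p, t = predictions[sel, l], truth[sel, l]
            ok = np.isfinite(p) & np.isfinite(t)
            p, t = p[ok], t[ok]
            if len(p) < 2:
                r = np.nan
            elif p.std() == 0.0 or t.std() == 0.0:
                warnings.warn(
                    f"zero variance in stratum ({trait}, {env}); correlation undefined",
                    stacklevel=2,
                )
                r = np.nan
            else:
                r = float(np.corrcoef(p, t)[0, 1])
            rows.append({"trait": trait, "env": env, "partition": partition_index,
                         "pearson": r, "n": int(len(p))})
    return pd.DataFrame(rows)


def adjust_by_heritability(table: pd.DataFrame, h2: dict | pd.DataFrame) -> pd.DataFrame:
    """Add ``adjusted = pearson / sqrt(h2)`` per (trait, env) stratum.

    ``h2`` maps (trait, env) to a heritability in (0, 1]; strata without
    an entry keep NaN in the adjusted column and are flagged in
    ``h2_supplied``.  Adjusted accuracies may exceed 1 when the raw
    correlation is large relative to sqrt(h2).
    """
    if isinstance(h2, pd.DataFrame):
        h2 = {(r["trait"], r["env"]): r["h2"] for _, r in h2.iterrows()}
    for key, val in h2.items():
        if not 0.0 < val <= 1.0:
            raise ValueError(f"heritability for {key} must be in (0, 1]; got {val}")
    out = table.copy()
    keys = list(zip(out["trait"], out["env"]))
    out["h2"] = [h2.get(k, np.nan) for k in keys]
    out["h2_supplied"] = [k in h2 for k in keys]
    out["adjusted"] = out["pearson"] / np.sqrt(out["h2"])
    return out


def summarize_accuracy(per_partition: pd.DataFrame,
                       value_col: str = "pearson") -> pd.DataFrame:
    """Mean and standard error across partitions per (trait, env) stratum."""
    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        k = len(vals)
        se = vals.std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
        return pd.Series({"mean": vals.mean() if k else np.nan,
                          "se": se, "n_partitions": k})

    cols = [c for c in ("engine", "trait", "env") if c in per_partition.columns]
    return (per_partition.groupby(cols, sort=False)[value_col]
            .apply(_agg).unstack().reset_index())


def run_comparison(
    ds: MTMEDataset,
    truth_Y: np.ndarray | None = None,
    engines: tuple[str, ...] = ENGINE_VARIANTS,
    p_testing: float = 0.2,
    n_partitions: int = 10,
    seed: int | None = None,
    bmtme_opts: dict | None = None,
    mtdl_opts: dict | None = None,
) -> dict:
    """Fit every engine variant across CV2 partitions and score them.

    For each partition, the test cells are masked, each engine is fitted
    on the training cells and its test-cell predictions are scored
    against ``truth_Y`` (defaults to the dataset's own observed values).
    Engine failures are recorded per partition rather than aborting the
    whole comparison.

    Returns a dict with ``per_partition`` scores, the per-stratum
    ``summary`` (mean +/- SE) and ``overall`` cross-stratum averages per
    engine.
    """
    unknown = set(engines) - set(ENGINE_VARIANTS)
    if unknown:
        raise ValueError(f"unknown engines: {sorted(unknown)}")
    from .simulate import mask_cells

    truth_Y = ds.Y if truth_Y is None else np.asarray(truth_Y, float)
    bmtme_opts = dict(bmtme_opts or {})
    mtdl_opts = dict(mtdl_opts or {})
    grid: HyperGrid = mtdl_opts.pop("grid", HyperGrid((50,), (50,), (1,)))
    dropout = mtdl_opts.pop("dropout_rate", 0.3)
    tune = mtdl_opts.pop("tune", True)

    partitions = cv2_partition(ds, p_testing, n_partitions, seed=seed)
    seedseq = np.random.SeedSequence(seed if seed is not None else 0)
    part_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                  seedseq.spawn(n_partitions)]

    tables = []
    failures = []
    for part, pseed in zip(partitions, part_seeds):
        test_cells = sorted(part.test_cells)
        ds_train = mask_cells(ds, part)
        test_rows = [ds.cell_index(*c) for c in test_cells]
        y_true = truth_Y[test_rows]
        for engine in engines:
            try:
                preds = _fit_predict_engine(
                    engine, ds_train, test_cells, pseed,
                    bmtme_opts, grid, dropout, tune, mtdl_opts,
                )
                tab = pearson_by_trait_env(
                    preds, y_true, test_cells, ds.trait_ids,
                    partition_index=part.partition_index,
                )
                tab.insert(0, "engine", engine)
                tables.append(tab)
            except Exception as exc:  # recorded, not fatal
                failures.append({"engine": engine,
                                 "partition": part.partition_index,
                                 "error": str(exc)})
    per_partition = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    summary = summarize_accuracy(per_partition) if len(per_partition) else pd.DataFrame()
    overall = (
        summary.groupby("engine", sort=False)["mean"].mean()
        .rename("cross_stratum_mean").reset_index()
        if len(summary) else pd.DataFrame()
    )
    return {"per_partition": per_partition, "summary": summary,
            "overall": overall, "failures": failures,
            "partitions": partitions}


def _fit_predict_engine(
    engine: str,
    ds_train: MTMEDataset,
    test_cells: list[tuple[str, str]],
    seed: int,
    bmtme_opts: dict,
    grid: HyperGrid,
    dropout: float,
    tune: bool,
    mtdl_opts: dict,
) -> np.ndarray:
    include_gxe = engine.endswith("_gxe") and not engine.endswith("no_gxe")
    if engine.startswith("bmtme"):
        model = BMTMERegressor(include_gxe=include_gxe, random_state=seed,
                               **bmtme_opts)
        model.fit(ds_train)
        return model.predict(test_cells)
    # MTDL: train on observed rows, predict the test-cell rows
    feats = encode_features(ds_train, include_gxe=include_gxe)
    obs = ds_train.observed_mask()
    X_tr, Y_tr = feats.values[obs], ds_train.Y[obs]
    if tune and len(grid) > 1:
        cfg = inner_cv_select(X_tr, Y_tr, grid, dropout_rate=dropout, seed=seed)
    else:
        cfg = grid.configs(dropout_rate=dropout)[0]
    model = train_mtdl(X_tr, Y_tr, cfg, seed=seed, **mtdl_opts)
    test_rows = [ds_train.cell_index(*c) for c in test_cells]
    return model.predict(feats.values[test_rows])
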