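"""Chained-equation multiple imputation of timed-out page-view durations.

The data are arranged in wide format: one row per participant, one
duration column per successive page view (``t_1 .. t_K``). A cell is
*observed* (a duration was logged), *impute* (the view happened but hit
the inactivity time-out, so its duration is missing), or *structural*
(the participant never reached that position; nothing to impute).

Imputation models are normal linear regressions on log duration. Each
position with enough observed cases gets its own model; sparse tail
positions share a pooled model with log position as a covariate. The
predictor set is the participant's baseline covariates, the randomized
arm, the (working) minutes on their first core-content page, and the
target view's page metadata.

Draws are *proper*: the residual variance is drawn from its scaled
chi-square posterior and the coefficients from their conditional
normal before residual noise is added, so between-imputation variance
reflects estimation uncertainty and Rubin's rules are valid.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .weblog import ViewingRecord

logger = logging.getLogger(__name__)

OBSERVED = "observed"
IMPUTE = "impute"
STRUCTURAL = "structural"

DEFAULT_M = 5
DEFAULT_ITERATIONS = 10
DEFAULT_MIN_CASES = 25
DEFAULT_ZERO_FLOOR = 0.005  # minutes; guards log() against zero durations


@dataclass
class WideDataset:
    """One row per participant; page views as successive columns."""

    durations: pd.DataFrame  # float, NaN where missing (either way)
    mask: pd.DataFrame  # OBSERVED / IMPUTE / STRUCTURAL
    page_type: pd.DataFrame  # object, NaN where structural
    content_section: pd.DataFrame
    covariates: pd.DataFrame  # fully observed participant-level columns

    @property
    def n_positions(self) -> int:
        return self.durations.shape[1]

    @property
    def position_columns(self) -> list[str]:
        return list(self.durations.columns)

    def n_impute_cells(self) -> int:
        return int((self.mask.to_numpy() == IMPUTE).sum())


@dataclass
class ImputationModelSpec:
    """Record of one conditional imputation model (for the manifest)."""

    target: str  # column name or "tail"
    positions: list[int]
    predictors: list[str]
    family: str = "normal linear regression on log(duration)"
    n_observed: int = 0


@dataclass
class ImputedDataset:
    """Completed copy of a WideDataset, imputation index m of M."""

    m: int
    durations: pd.DataFrame


@dataclass
class MiceResult:
    imputed: list[ImputedDataset]
    traces: pd.DataFrame  # m, iteration, column, mean_min, sd_min
    model_specs: list[ImputationModelSpec]
    manifest: dict = field(default_factory=dict)


def build_wide(
    records: Sequence[ViewingRecord], participants: pd.DataFrame
) -> WideDataset:
    """Pivot viewing records into the wide layout.

    Every participant in the table gets a row; participants with no
    views are all-structural. A record whose participant is missing
    from the table is an error naming the id.
    """
    if "participant_id" not in participants.columns:
        raise ValueError("participant table needs a participant_id column")
    index = pd.Index(
        participants["participant_id"].astype(str), name="participant_id"
    )
    if index.has_duplicates:
        raise ValueError("participant table has duplicate participant_id values")
    known = set(index)
    for r in records:
        if r.participant_id not in known:
            raise KeyError(
                f"participant {r.participant_id!r} appears in records "
                "but not in the participant table"
            )

    k_max = max((r.position for r in records), default=0)
    cols = [f"t_{k}" for k in range(1, k_max + 1)]
    durations = pd.DataFrame(np.nan, index=index, columns=cols, dtype=float)
    mask = pd.DataFrame(STRUCTURAL, index=index, columns=cols, dtype=object)
    page_type = pd.DataFrame(np.nan, index=index, columns=cols, dtype=object)
    section = pd.DataFrame(np.nan, index=index, columns=cols, dtype=object)

    for r in records:
        col = f"t_{r.position}"
        if r.timed_out:
            mask.loc[r.participant_id, col] = IMPUTE
        else:
            mask.loc[r.participant_id, col] = OBSERVED
            durations.loc[r.participant_id, col] = r.duration_min
        page_type.loc[r.participant_id, col] = r.page_type
        section.loc[r.participant_id, col] = r.content_section

    covariates = (
        participants.astype({"participant_id": str})
        .set_index("participant_id")
        .loc[index]
    )
    return WideDataset(durations, mask, page_type, section, covariates)


def _encode_covariates(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric matrix from the participant table: dummies for non-numeric."""
    pieces, names = [], []
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            pieces.append(series.to_numpy(dtype=float))
            names.append(col)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            for dcol in dummies.columns:
                pieces.append(dummies[dcol].to_numpy(dtype=float))
                names.append(dcol)
    if not pieces:
        return np.empty((len(covariates), 0)), []
    return np.column_stack(pieces), names


def _meta_dummies(values: np.ndarray, prefix: str) -> tuple[np.ndarray, list[str]]:
    cats = sorted({str(v) for v in values if not pd.isna(v)})
    cols, names = [], []
    for cat in cats[1:]:  # drop-first coding
        cols.append((values == cat).astype(float))
        names.append(f"{prefix}_{cat}")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def _posterior_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Proper Bayesian draw from the normal linear model posterior.

    Returns (beta_draw, sigma_draw, beta_hat, df). Uses the standard
    noninformative-prior scheme: sigma^2 ~ SSR / chi2(n - rank), then
    beta | sigma ~ N(beta_hat, sigma^2 (X'X)^-).
    """
    n, p = X.shape
    xtx = X.T @ X
    # tiny relative ridge: keeps near-collinear dummy sets from blowing
    # up the coefficient draw without noticeably biasing the fit
    xtx = xtx + 1e-5 * (np.trace(xtx) / p) * np.eye(p)
    eigval, eigvec = np.linalg.eigh(xtx)
    tol = max(eigval.max(), 0) * p * np.finfo(float).eps
    keep = eigval > tol
    rank = int(keep.sum())
    inv_eig = np.where(keep, 1.0 / np.where(keep, eigval, 1.0), 0.0)
    xtx_inv = (eigvec * inv_eig) @ eigvec.T

    beta_hat = xtx_inv @ (X.T @ y)
    df = n - rank
    resid = y - X @ beta_hat
    ssr = float(resid @ resid)
    if df < 1:
        raise np.linalg.LinAlgError("not enough residual degrees of freedom")
    sigma2 = max(ssr, 1e-12) / rng.chisquare(df)
    half = (eigvec * np.sqrt(inv_eig)) @ eigvec.T  # symmetric sqrt of (X'X)^-
    beta = beta_hat + np.sqrt(sigma2) * (half @ rng.standard_normal(p))
    return beta, float(np.sqrt(sigma2)), beta_hat, df


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop non-intercept columns with no variation (column 0 is intercept)."""
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    return X[:, keep], [names[j] for j in keep]


class _ModelContext:
    """Shared pieces reused by every conditional regression."""

    def __init__(self, wide: WideDataset, zero_floor: float):
        self.wide = wide
        self.cov_matrix, self.cov_names = _encode_covariates(wide.covariates)
        self.mask = wide.mask.to_numpy()
        self.n_rows, self.n_cols = self.mask.shape
        self.page_type = wide.page_type.to_numpy()
        self.section = wide.content_section.to_numpy()

        obs_vals = wide.durations.to_numpy(dtype=float)
        if np.any(obs_vals[~np.isnan(obs_vals)] <= 0):
            n_bad = int((obs_vals[~np.isnan(obs_vals)] <= 0).sum())
            logger.warning(
                "%d non-positive observed durations floored at %g min before log",
                n_bad,
                zero_floor,
            )
        self.log_observed = np.log(np.maximum(obs_vals, zero_floor))

        # first core-content position per row, fallback: first view
        self.first_core = np.full(self.n_rows, -1, dtype=int)
        self.first_view = np.full(self.n_rows, -1, dtype=int)
        for i in range(self.n_rows):
            viewed = np.flatnonzero(self.mask[i] != STRUCTURAL)
            if viewed.size == 0:
                continue
            self.first_view[i] = viewed[0]
            core = [j for j in viewed if str(self.page_type[i, j]) == "core-content"]
            self.first_core[i] = core[0] if core else viewed[0]

    def first_core_predictor(
        self, rows: np.ndarray, target_col: int, working: np.ndarray
    ) -> np.ndarray:
        """Working log-minutes on each row's first core page.

        The target column itself is never used as its own predictor: for
        rows whose first core page *is* the target position, fall back
        to the first view, then to the mean over the other rows.
        """
        out = np.empty(rows.size)
        pending = []
        for idx, i in enumerate(rows):
            j = self.first_core[i]
            if j == target_col:
                j = self.first_view[i]
            if j == target_col or j < 0:
                pending.append(idx)
                out[idx] = np.nan
            else:
                out[idx] = working[i, j]
        if pending:
            usable = out[np.isfinite(out)]
            fill = float(usable.mean()) if usable.size else 0.0
            for idx in pending:
                out[idx] = fill
        return out

    def design(
        self,
        rows: np.ndarray,
        target_col: int,
        working: np.ndarray,
        page_types: np.ndarray,
        sections: np.ndarray,
        positions: Optional[np.ndarray] = None,
        level: int = 0,
    ) -> tuple[np.ndarray, list[str]]:
        """Design matrix at a given shrinkage level.

        level 0: intercept + covariates + first-core minutes + page meta
        level 1: drop page metadata; level 2: drop covariates;
        level 3: intercept only. ``positions`` (tail model) adds
        log(position) at every level below 3.
        """
        n = rows.size
        cols = [np.ones(n)]
        names = ["intercept"]
        if level <= 1:
            cols.append(self.cov_matrix[rows])
            names.extend(self.cov_names)
        if level <= 2:
            cols.append(
                self.first_core_predictor(rows, target_col, working)[:, None]
            )
            names.append("first_core_log_min")
        if level == 0:
            pt, pt_names = _meta_dummies(page_types, "page_type")
            sec, sec_names = _meta_dummies(sections, "content_section")
            cols.extend([pt, sec])
            names.extend(pt_names + sec_names)
        if positions is not None and level <= 2:
            cols.append(np.log(positions.astype(float))[:, None])
            names.append("log_position")
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        return _drop_constant(X, names)


def _fit_and_draw(ctx, rows_obs, rows_imp, target_col, working, rng, *,
                  page_types_obs, sections_obs, page_types_imp, sections_imp,
                  positions_obs=None, positions_imp=None):
    """Fit on observed rows at the widest estimable level, draw imputations.

    The observed and to-impute rows share one design-matrix build so
    the columns (and dummy coding) are identical; columns with no
    variation among the *observed* rows are dropped from both sides.
    """
    y = np.asarray(
        [working[i, c] for i, c in rows_obs]
        if isinstance(rows_obs, list)
        else working[rows_obs, target_col]
    )
    obs_idx = (
        np.array([i for i, _ in rows_obs]) if isinstance(rows_obs, list) else rows_obs
    )
    imp_idx = (
        np.array([i for i, _ in rows_imp]) if isinstance(rows_imp, list) else rows_imp
    )
    n_obs = obs_idx.size
    all_idx = np.concatenate([obs_idx, imp_idx])
    all_pt = np.concatenate([page_types_obs, page_types_imp])
    all_sec = np.concatenate([sections_obs, sections_imp])
    all_pos = (
        np.concatenate([positions_obs, positions_imp])
        if positions_obs is not None
        else None
    )
    for level in range(4):
        X_all, names = ctx.design(
            all_idx, target_col, working, all_pt, all_sec,
            positions=all_pos, level=level,
        )
        keep = [0] + [
            j for j in range(1, X_all.shape[1]) if np.ptp(X_all[:n_obs, j]) > 0
        ]
        X_all = X_all[:, keep]
        names = [names[j] for j in keep]
        # demand real support before trusting a wide design: the
        # exponentiated t-tailed predictive draw from a small-df,
        # high-leverage regression can produce absurd durations
        p_obs = X_all.shape[1]
        enough = n_obs >= p_obs + 10 and n_obs >= 3 * p_obs
        if level == 3:
            enough = n_obs - p_obs >= 3  # last resort: intercept only
        if enough:
            try:
                beta, sigma, _, _ = _posterior_draw(X_all[:n_obs], y, rng)
            except np.linalg.LinAlgError:
                continue
            preds = X_all[n_obs:] @ beta + sigma * rng.standard_normal(imp_idx.size)
            return preds, names
    raise np.linalg.LinAlgError(
        f"no estimable imputation model for target column {target_col}"
    )


def mice_impute(
    wide: WideDataset,
    m: int = DEFAULT_M,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    min_cases: int = DEFAULT_MIN_CASES,
    truncate_at: Optional[float] = None,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> MiceResult:
    """Produce M completed datasets by chained-equation imputation.

    Columns are cycled in ascending order of missing count (ties by
    position); positions with fewer than ``min_cases`` observed values
    share a pooled tail model with log(position) as a covariate.
    Imputation happens on the log scale and results are exponentiated;
    by default imputed durations are NOT truncated at the time-out
    threshold (pass ``truncate_at`` to bound them).

    Observed entries are preserved bit-for-bit in every completed
    dataset; structurally absent entries stay absent.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if iterations < 1:
        raise ValueError("iterations must be at least 1")

    mask = wide.mask.to_numpy()
    cols = wide.position_columns
    n_obs_per_col = (mask == OBSERVED).sum(axis=0)
    n_imp_per_col = (mask == IMPUTE).sum(axis=0)
    impute_cols = [j for j in range(len(cols)) if n_imp_per_col[j] > 0]

    if not impute_cols:
        completed = [
            ImputedDataset(m=i + 1, durations=wide.durations.copy())
            for i in range(m)
        ]
        return MiceResult(
            imputed=completed,
            traces=pd.DataFrame(
                columns=["m", "iteration", "column", "mean_min", "sd_min"]
            ),
            model_specs=[],
            manifest={"m": m, "iterations": iterations, "seed": seed},
        )

    own_cols = [j for j in impute_cols if n_obs_per_col[j] >= min_cases]
    tail_cols = [j for j in impute_cols if n_obs_per_col[j] < min_cases]
    # the tail model trains on every sparse position, imputing or not
    tail_train_cols = [
        j for j in range(len(cols)) if 0 < n_obs_per_col[j] < min_cases
    ]
    if tail_cols:
        tail_obs_total = int(n_obs_per_col[tail_train_cols].sum())
        if tail_obs_total == 0:
            raise ValueError(
                f"column {cols[tail_cols[0]]} has no observed values and no "
                "pooling partner; cannot impute"
            )
    own_cols.sort(key=lambda j: (n_imp_per_col[j], j))

    ctx = _ModelContext(wide, zero_floor)
    log_obs = ctx.log_observed

    # initialization values: observed column median (global fallback)
    global_median = np.nanmedian(log_obs)
    col_medians = np.full(len(cols), global_median)
    for j in range(len(cols)):
        col_vals = log_obs[mask[:, j] == OBSERVED, j]
        if col_vals.size:
            col_medians[j] = np.median(col_vals)

    specs: list[ImputationModelSpec] = []
    completed: list[ImputedDataset] = []
    trace_rows: list[tuple] = []

    for chain in range(m):
        rng = np.random.default_rng([seed, chain])
        working = log_obs.copy()
        for j in impute_cols:
            working[mask[:, j] == IMPUTE, j] = col_medians[j]

        for it in range(1, iterations + 1):
            for j in own_cols:
                obs_rows = np.flatnonzero(mask[:, j] == OBSERVED)
                imp_rows = np.flatnonzero(mask[:, j] == IMPUTE)
                preds, names = _fit_and_draw(
                    ctx, obs_rows, imp_rows, j, working, rng,
                    page_types_obs=ctx.page_type[obs_rows, j],
                    sections_obs=ctx.section[obs_rows, j],
                    page_types_imp=ctx.page_type[imp_rows, j],
                    sections_imp=ctx.section[imp_rows, j],
                )
                working[imp_rows, j] = preds
                if chain == 0 and it == 1:
                    specs.append(
                        ImputationModelSpec(
                            target=cols[j],
                            positions=[j + 1],
                            predictors=names,
                            n_observed=int(n_obs_per_col[j]),
                        )
                    )
            if tail_cols:
                obs_cells = [
                    (i, j)
                    for j in tail_train_cols
                    for i in np.flatnonzero(mask[:, j] == OBSERVED)
                ]
                imp_cells = [
                    (i, j)
                    for j in tail_cols
                    for i in np.flatnonzero(mask[:, j] == IMPUTE)
                ]
                preds, names = _fit_and_draw(
                    ctx,
                    obs_cells,
                    imp_cells,
                    -1,  # no single target column; self-exclusion not needed
                    working,
                    rng,
                    page_types_obs=np.array([ctx.page_type[i, j] for i, j in obs_cells]),
                    sections_obs=np.array([ctx.section[i, j] for i, j in obs_cells]),
                    page_types_imp=np.array([ctx.page_type[i, j] for i, j in imp_cells]),
                    sections_imp=np.array([ctx.section[i, j] for i, j in imp_cells]),
                    positions_obs=np.array([j + 1 for _, j in obs_cells]),
                    positions_imp=np.array([j + 1 for _, j in imp_cells]),
                )
                for (i, j), v in zip(imp_cells, preds):
                    working[i, j] = v
                if chain == 0 and it == 1:
                    specs.append(
                        ImputationModelSpec(
                            target="tail",
                            positions=[j + 1 for j in tail_train_cols],
                            predictors=names,
                            n_observed=int(n_obs_per_col[tail_train_cols].sum()),
                        )
                    )
            for j in impute_cols:
                imp_rows = np.flatnonzero(mask[:, j] == IMPUTE)
                vals = np.exp(working[imp_rows, j])
                trace_rows.append(
                    (chain + 1, it, cols[j], float(vals.mean()),
                     float(vals.std(ddof=0)))
                )

        final = wide.durations.copy()
        arr = final.to_numpy()
        for j in impute_cols:
            imp_rows = np.flatnonzero(mask[:, j] == IMPUTE)
            vals = np.exp(working[imp_rows, j])
            if truncate_at is not None:
                vals = np.minimum(vals, truncate_at)
            arr[imp_rows, j] = vals
        completed.append(
            ImputedDataset(
                m=chain + 1,
                durations=pd.DataFrame(
                    arr, index=final.index, columns=final.columns
                ),
            )
        )

    traces = pd.DataFrame(
        trace_rows, columns=["m", "iteration", "column", "mean_min", "sd_min"]
    )
    manifest = {
        "m": m,
        "iterations": iterations,
        "seed": seed,
        "min_cases": min_cases,
        "truncate_at": truncate_at,
        "zero_floor": zero_floor,
        "n_impute_cells": wide.n_impute_cells(),
        "models": [
            {
                "target": s.target,
                "positions": s.positions,
                "predictors": s.predictors,
                "family": s.family,
                "n_observed": s.n_observed,
            }
            for s in specs
        ],
    }
    return MiceResult(completed, traces, specs, manifest)


def diagnose_convergence(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean/SD of imputed values by iteration (chains averaged)."""
    if traces.empty:
        return pd.DataFrame(columns=["column", "iteration", "mean_min", "sd_min"])
    return (
        traces.groupby(["column", "iteration"])[["mean_min", "sd_min"]]
        .mean()
        .reset_index()
    )


def write_imputed(result: MiceResult, out_dir) -> dict:
    """One delimited-text file per completed dataset plus a manifest."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for ds in result.imputed:
        path = os.path.join(out_dir, f"imputed_{ds.m}.csv")
        frame = ds.durations.reset_index()
        frame.insert(0, "m", ds.m)
        frame.to_csv(path, index=False)
        paths[f"imputed_{ds.m}"] = path
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    paths["manifest"] = manifest_path
    return paths
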