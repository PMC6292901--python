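"""Correlational PPI (cPPI) task-state connectivity.

For two nodes *i*, *j* and a psychological regressor *g* (the
HRF-convolved delay events of one difficulty level), each node's PPI
term is the elementwise product of its demeaned timecourse with the
demeaned regressor.  The cPPI edge is the partial correlation

    rho_{PPI_i, PPI_j . z}

where the removed set *z* holds the psychological regressor, the raw
timecourses of both nodes, the six motion parameters and the WM and CSF
signals.  No deconvolution step is applied: the product is formed
directly from the BOLD timecourse and the convolved regressor.  Edges
are estimated per run and averaged across runs through Fisher's z.

Difficulty is coded two ways, giving eight matrices per subject: the
four titrated set-size levels, and four sorting-steps levels obtained by
within-subject quartile binning of the raw 0-7 step counts so that every
level contributes an equal number of trials.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import HRFModel, convolve_events, DesignError
from .networks import NetworkPartition

__all__ = [
    "ConnectivityError",
    "rebin_steps",
    "build_condition_regressor",
    "ppi_terms",
    "cppi_matrix",
    "condition_tensor",
]

DELAY_DUR = 5.0


class ConnectivityError(ValueError):
    """Raised for degenerate condition definitions or inputs."""


def rebin_steps(table: pd.DataFrame) -> pd.Series:
    """Within-subject quartile levels (1-4) of the sorting-step counts.

    Trials are ordered by (steps, trial order) — a stable tie-break —
    and split into four bins of as-equal-as-possible size, so each
    steps level contributes the same number of trials to connectivity.
    """
    steps = table["steps"].to_numpy()
    if len(steps) < 4:
        raise ConnectivityError("need at least 4 trials to form 4 levels")
    if np.unique(steps).size < 2:
        raise ConnectivityError("all trials share one steps value; "
                                "steps levels are degenerate")
    order = np.argsort(steps, kind="stable")
    levels = np.empty(len(steps), dtype=int)
    for b, chunk in enumerate(np.array_split(order, 4)):
        levels[chunk] = b + 1
    return pd.Series(levels, index=table.index, name="steps_level")


def add_steps_levels(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """Attach per-subject ``steps_level`` to a (multi-subject) trial table."""
    out = cohort_table.copy()
    out["steps_level"] = (
        out.groupby("subject", group_keys=False)[["steps"]]
        .apply(lambda g: rebin_steps(g).to_frame())["steps_level"])
    return out


def build_condition_regressor(
    table_run: pd.DataFrame,
    demand: str,
    level: int,
    hrf: HRFModel | None = None,
    run_duration: float | None = None,
    tr: float = 2.0,
    n_volumes: int = 254,
) -> np.ndarray:
    """Demeaned convolved delay regressor for one difficulty level.

    ``demand`` selects the coding column: ``set_size`` uses the titrated
    ``level`` codes, ``steps`` the quartile ``steps_level`` codes.
    """
    hrf = hrf or HRFModel()
    col = {"set_size": "level", "steps": "steps_level"}.get(demand)
    if col is None:
        raise ConnectivityError(f"unknown demand type {demand!r}")
    if col not in table_run.columns:
        raise ConnectivityError(f"trial table lacks column {col!r}")
    onsets = table_run.loc[table_run[col] == level, "onset_delay"].to_numpy(float)
    if onsets.size == 0:
        raise ConnectivityError(f"no trials at {demand} level {level}")
    if run_duration is None:
        run_duration = n_volumes * tr
    reg = convolve_events([*onsets], DELAY_DUR, hrf, run_duration=run_duration,
                          tr=tr, n_volumes=n_volumes)
    return reg - reg.mean()


def ppi_terms(timecourses: np.ndarray, psych: np.ndarray) -> np.ndarray:
    """PPI term per node: demeaned timecourse x demeaned regressor."""
    tc = timecourses - timecourses.mean(axis=0, keepdims=True)
    g = psych - psych.mean()
    return tc * g[:, None]


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def _run_cppi(signal: np.ndarray, nodes: np.ndarray, psych: np.ndarray,
              confounds: np.ndarray) -> np.ndarray:
    """One run's cPPI matrix over ``nodes`` (NaN-flagged degeneracies)."""
    tc = signal[:, nodes]
    const = tc.std(axis=0) < 1e-12
    if const.any():
        warnings.warn(f"{int(const.sum())} constant node timecourse(s); "
                      "their edges are NaN")
    ppi = ppi_terms(tc, psych)
    common = np.column_stack([np.ones(len(tc)), psych - psych.mean(), confounds])
    tc_r = _residualize(tc - tc.mean(axis=0, keepdims=True), common)
    ppi_r = _residualize(ppi, common)
    # pairwise partial correlation given the two raw timecourses:
    # solve the 2-regressor projection in closed form from Gram blocks
    G = tc_r.T @ tc_r          # G[a, b] = <tc_a, tc_b>
    P = tc_r.T @ ppi_r         # P[a, b] = <tc_a, ppi_b>
    Q = ppi_r.T @ ppi_r
    k = len(nodes)
    iu, ju = np.triu_indices(k, 1)
    gii, gjj, gij = G[iu, iu], G[ju, ju], G[iu, ju]
    det = gii * gjj - gij ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        # projection coefficients of ppi_i and ppi_j on [tc_i, tc_j]
        pi_i, pj_i = P[iu, iu], P[ju, iu]   # <tc_i, ppi_i>, <tc_j, ppi_i>
        pi_j, pj_j = P[iu, ju], P[ju, ju]
        # residual inner products after projecting out the pair block
        def proj(ai, aj, bi, bj):
            return (gjj * ai * bi - gij * (ai * bj + aj * bi) + gii * aj * bj) / det
        var_i = Q[iu, iu] - proj(pi_i, pj_i, pi_i, pj_i)
        var_j = Q[ju, ju] - proj(pi_j, pj_j, pi_j, pj_j)
        cov = Q[iu, ju] - proj(pi_i, pj_i, pi_j, pj_j)
        rho = cov / np.sqrt(var_i * var_j)
    mat = np.full((k, k), np.nan)
    mat[iu, ju] = mat[ju, iu] = np.clip(rho, -1.0, 1.0)
    bad = np.nonzero(const)[0]
    mat[bad, :] = mat[:, bad] = np.nan
    return mat


def cppi_matrix(
    bundle: Mapping[int, dict],
    nodes: Sequence[int],
    psych_by_run: Mapping[int, np.ndarray],
    runs: Sequence[int] | None = None,
) -> np.ndarray:
    """Fisher-z-averaged cPPI matrix across runs.

    ``bundle`` maps run number to ``{"signal", "confounds"}``;
    ``psych_by_run`` supplies the demeaned psychological regressor per
    run.  Runs listed in ``runs`` (default: all in ``psych_by_run``)
    enter the average; order does not matter.
    """
    nodes = np.asarray(list(nodes), dtype=int)
    runs = sorted(psych_by_run) if runs is None else sorted(runs)
    if not runs:
        raise ConnectivityError("no runs to estimate")
    zsum = np.zeros((len(nodes), len(nodes)))
    for run in runs:
        entry = bundle[run]
        conf = entry["confounds"]
        conf = conf.to_numpy(float) if hasattr(conf, "to_numpy") else np.asarray(conf)
        mat = _run_cppi(np.asarray(entry["signal"], float), nodes,
                        np.asarray(psych_by_run[run], float), conf)
        zsum = zsum + np.arctanh(np.clip(mat, -0.999999, 0.999999))
    out = np.tanh(zsum / len(runs))
    np.fill_diagonal(out, np.nan)
    return out


def condition_tensor(
    bundle: Mapping[int, dict],
    partition: NetworkPartition,
    table: pd.DataFrame,
    hrf: HRFModel | None = None,
    tr: float = 2.0,
    n_volumes: int = 254,
) -> dict:
    """All eight condition matrices for one subject.

    Returns ``{"matrices": {(demand, level): matrix}, "manifest": ...}``
    with node order maintenance-block-first.  ``table`` is the
    subject's trial table; steps levels are derived here if absent.
    Runs without any trial at a given level are skipped for that
    condition (the Fisher average uses the remaining runs).
    """
    hrf = hrf or HRFModel()
    if "steps_level" not in table.columns:
        table = table.assign(steps_level=rebin_steps(table))
    nodes = np.asarray(partition.all_nodes, dtype=int)
    matrices: dict[tuple[str, int], np.ndarray] = {}
    manifest: dict[str, dict] = {"trial_counts": {}, "runs_used": {}}
    for demand in ("set_size", "steps"):
        col = {"set_size": "level", "steps": "steps_level"}[demand]
        for level in (1, 2, 3, 4):
            psych: dict[int, np.ndarray] = {}
            for run, t_run in table.groupby("run"):
                try:
                    psych[int(run)] = build_condition_regressor(
                        t_run, demand, level, hrf, tr=tr, n_volumes=n_volumes)
                except ConnectivityError:
                    continue
            if not psych:
                raise ConnectivityError(
                    f"no run has trials at {demand} level {level}")
            matrices[(demand, level)] = cppi_matrix(bundle, nodes, psych)
            key = f"{demand}_{level}"
            manifest["trial_counts"][key] = int((table[col] == level).sum())
            manifest["runs_used"][key] = sorted(psych)
    return {"matrices": matrices, "manifest": manifest, "nodes": nodes}
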