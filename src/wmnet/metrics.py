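"""Segregation, reconfiguration and brain-behaviour statistics.

Within-network connectivity is the signed mean over unordered node
pairs inside a community; between-network connectivity the signed mean
over the full cross block.  Two derived summaries describe system-level
organisation:

* segregation = (Zw - Zb) / Zw — the between-network shortfall as a
  proportion of within-network coupling (0 when equal, 1 when the
  between mean vanishes);
* reconfiguration = 1 - mean pairwise state similarity, where the
  similarity of two difficulty levels is the Spearman correlation of
  their edge vectors over a chosen connection subset (within either
  network, or the between block).  Identical states give 0; unrelated
  states give values near 1.

Node-level segregation (each node's within-edge mean vs between-edge
mean, averaged per network) is reported alongside the network-level
formula.  Brain-behaviour coupling is a Pearson correlation between a
per-subject reconfiguration score and the titrated Criterion, with a
Fisher r-to-z comparison of two correlations on the same sample, and
difficulty trends are tested by a subject-intercept mixed model
likelihood-ratio test on the linear level term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .networks import NetworkPartition

__all__ = [
    "MetricsError",
    "within_between_means",
    "node_level_segregation",
    "segregation",
    "state_vector",
    "reconfiguration",
    "behavior_correlation",
    "compare_correlations",
    "difficulty_trend",
    "metrics_table",
]

SUBSETS = ("within_maintenance", "within_manipulation", "between")


class MetricsError(ValueError):
    """Raised for undefined metric cases (flagged degeneracies)."""


def _blocks(matrix: np.ndarray, partition: NetworkPartition):
    k = partition.size
    n = 2 * k
    M = np.asarray(matrix, float)
    if M.shape != (n, n):
        raise MetricsError(f"matrix shape {M.shape} != ({n}, {n})")
    return M[:k, :k], M[k:, k:], M[:k, k:]


def within_between_means(matrix: np.ndarray, partition: NetworkPartition,
                         magnitudes: bool = False) -> dict[str, float]:
    """Signed mean correlation within each network and between networks.

    The matrix is indexed in partition order (maintenance block first).
    Within means use the upper triangle (diagonal excluded); the between
    mean uses the full cross block.  ``magnitudes=True`` averages
    absolute values instead of signed ones (a reading of "mean
    magnitudes"; signed means are the default, following the defining
    formula).  Missing (NaN) entries are an error.
    """
    if partition.size < 2:
        raise MetricsError("networks need at least 2 nodes for within pairs")
    wm, wn, bt = _blocks(matrix, partition)
    if magnitudes:
        wm, wn, bt = np.abs(wm), np.abs(wn), np.abs(bt)
    iu = np.triu_indices(partition.size, 1)
    vals = {"z_within_maintenance": float(wm[iu].mean()),
            "z_within_manipulation": float(wn[iu].mean()),
            "z_between": float(bt.mean())}
    if any(np.isnan(v) for v in vals.values()):
        raise MetricsError("connectivity matrix has missing entries")
    return vals


def node_level_segregation(matrix: np.ndarray,
                           partition: NetworkPartition) -> dict[str, float]:
    """Per-node (within-mean - between-mean)/within-mean, network-averaged."""
    wm, wn, bt = _blocks(matrix, partition)
    k = partition.size
    out = {}
    for name, within, across in (("maintenance", wm, bt),
                                 ("manipulation", wn, bt.T)):
        off = np.where(np.eye(k, dtype=bool), np.nan, within)
        w = np.nanmean(off, axis=1)  # NaN diagonal excluded
        b = across.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (w - b) / w
        out[f"node_segregation_{name}"] = float(np.nanmean(s))
    return out


def segregation(z_within: float, z_between: float) -> float:
    """(Zw - Zb) / Zw; undefined (raises) when the within mean is 0."""
    if z_within == 0:
        raise MetricsError("segregation undefined for zero within-network mean")
    return (z_within - z_between) / z_within


def state_vector(matrix: np.ndarray, partition: NetworkPartition,
                 subset: str) -> np.ndarray:
    """Edge vector of one connection subset, in a fixed order."""
    wm, wn, bt = _blocks(matrix, partition)
    iu = np.triu_indices(partition.size, 1)
    if subset == "within_maintenance":
        return wm[iu]
    if subset == "within_manipulation":
        return wn[iu]
    if subset == "between":
        return bt.ravel()
    raise MetricsError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


@dataclass(frozen=True)
class ReconfigurationRecord:
    subset: str
    n_states: int
    pairwise_similarity: np.ndarray  # condensed, unordered state pairs
    reconfiguration: float


def reconfiguration(state_matrices: list[np.ndarray],
                    partition: NetworkPartition,
                    subset: str,
                    method: str = "spearman") -> ReconfigurationRecord:
    """1 - mean pairwise state similarity over a connection subset.

    Similarity is the rank (Spearman) correlation of the two states'
    edge vectors by default (``method="pearson"`` optionally).  With the
    ordered-pair average of the defining formula, symmetric similarity
    makes this the unordered-pair mean; all-identical states give 0.
    """
    n = len(state_matrices)
    if n < 2:
        raise MetricsError("reconfiguration needs at least 2 states")
    vecs = [state_vector(m, partition, subset) for m in state_matrices]
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    sims = []
    for x in range(n):
        for y in range(x + 1, n):
            if np.std(vecs[x]) == 0 or np.std(vecs[y]) == 0:
                raise MetricsError(
                    "state has constant edge vector; similarity undefined")
            sims.append(float(corr(vecs[x], vecs[y])[0]))
    sims = np.asarray(sims)
    return ReconfigurationRecord(subset, n, sims, float(1.0 - sims.mean()))


def behavior_correlation(values: np.ndarray, criterion: np.ndarray) -> dict:
    """Pearson correlation of a per-subject score with Criterion."""
    x = np.asarray(values, float)
    y = np.asarray(criterion, float)
    if len(x) != len(y) or len(x) < 4:
        raise MetricsError("need matched scores for at least 4 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricsError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x)}


def compare_correlations(r1: float, r2: float, n: int) -> dict:
    """Fisher r-to-z comparison of two correlations on the same n."""
    if n <= 3:
        raise MetricsError("need n > 3 for the Fisher comparison")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3))
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def difficulty_trend(df: pd.DataFrame, value: str = "value") -> dict:
    """Mixed-model LRT for a linear difficulty-level effect.

    ``df`` holds one row per subject x level with columns ``subject``,
    ``level`` and the metric column.  A linear mixed model with subject
    random intercepts is fitted by maximum likelihood with and without
    the linear level term; the likelihood-ratio chi-square (1 df) tests
    the trend.  Fitting is delegated to statsmodels MixedLM.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    need = {"subject", "level", value}
    if not need.issubset(df.columns):
        raise MetricsError(f"trend table needs columns {sorted(need)}")
    if df.groupby("subject")["level"].nunique().min() < 2:
        raise MetricsError("each subject needs several levels for a trend")
    y = df[value].to_numpy(float)
    groups = df["subject"].to_numpy()
    X_full = np.column_stack([np.ones(len(df)), df["level"].to_numpy(float)])
    X_red = X_full[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = MixedLM(y, X_full, groups).fit(reml=False)
            red = MixedLM(y, X_red, groups).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError) as err:
            return {"chi2": np.nan, "p": np.nan, "slope": np.nan,
                    "converged": False, "message": str(err)}
    chi2 = max(0.0, 2.0 * (full.llf - red.llf))
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1)),
            "slope": float(full.params[1]),
            "converged": bool(full.converged and red.converged)}


def metrics_table(tensors: dict[int, dict], partition: NetworkPartition) -> pd.DataFrame:
    """Tidy per-subject, per-condition summary of all level metrics.

    ``tensors`` maps subject id to a ``condition_tensor`` result.
    Segregation values are NaN-flagged where the within mean is zero.
    """
    rows = []
    for subject, tensor in tensors.items():
        for (demand, level), matrix in tensor["matrices"].items():
            means = within_between_means(matrix, partition)
            row = {"subject": subject, "demand": demand, "level": level, **means}
            for net in ("maintenance", "manipulation"):
                zw = means[f"z_within_{net}"]
                try:
                    row[f"segregation_{net}"] = segregation(zw, means["z_between"])
                except MetricsError:
                    row[f"segregation_{net}"] = np.nan
            row.update(node_level_segregation(matrix, partition))
            rows.append(row)
    return pd.DataFrame(rows)
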