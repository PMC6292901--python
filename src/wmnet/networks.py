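"""Equal-size Maintenance / Manipulation network definition.

The two task networks are read off the group parametric maps: ROIs are
ranked by their group z statistic for each demand effect and the top
fraction (5% of 471 ROIs = 23 nodes) forms each network.  Networks are
kept equal-sized and disjoint so that within- and between-network
summary statistics are comparable; if an ROI ranks in the top set for
both effects it is assigned to the effect where its z is larger and the
other network backfills with its next-ranked ROI.  A subject-level
conjunction utility and a structural (FA) validation of the partition
round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NetworkPartition", "select_top_nodes", "conjunction",
           "validate_structure"]


@dataclass(frozen=True)
class NetworkPartition:
    """Disjoint, equal-size node sets for the two demand networks."""

    maintenance_nodes: tuple[int, ...]
    manipulation_nodes: tuple[int, ...]
    fraction: float

    def __post_init__(self):
        if set(self.maintenance_nodes) & set(self.manipulation_nodes):
            raise ValueError("networks overlap")
        if len(self.maintenance_nodes) != len(self.manipulation_nodes):
            raise ValueError("networks must be equal-sized")

    @property
    def size(self) -> int:
        return len(self.maintenance_nodes)

    @property
    def all_nodes(self) -> tuple[int, ...]:
        """Maintenance nodes then manipulation nodes (matrix order)."""
        return self.maintenance_nodes + self.manipulation_nodes

    def to_dict(self) -> dict:
        return {"fraction": self.fraction,
                "maintenance": list(self.maintenance_nodes),
                "manipulation": list(self.manipulation_nodes)}


def _ranked(pmap: pd.DataFrame, col: str) -> list[int]:
    # descending z, ties broken by ascending ROI id
    order = pmap.sort_values([col, "roi"], ascending=[False, True],
                             kind="mergesort")
    return order["roi"].astype(int).tolist()


def select_top_nodes(pmap: pd.DataFrame, fraction: float = 0.05) -> NetworkPartition:
    """Top-``fraction`` ROIs per demand effect, kept disjoint.

    ``pmap`` has columns ``roi``, ``z_set_size``, ``z_steps``.  The
    per-network node count is ``floor(fraction * n_rois)`` (5% of 471
    gives exactly 23).  Contested ROIs go to the effect with the larger
    z (ties to set size) and the loser backfills from its ranking.
    """
    if not 0 < fraction <= 0.2:
        raise ValueError("fraction must lie in (0, 0.2]")
    n_rois = len(pmap)
    k = int(np.floor(fraction * n_rois))
    if k == 0:
        raise ValueError(f"fraction {fraction} selects zero nodes of {n_rois}")
    if 2 * k > n_rois:
        raise ValueError("not enough ROIs for two disjoint networks")
    rank_set = _ranked(pmap, "z_set_size")
    rank_steps = _ranked(pmap, "z_steps")
    z_set = dict(zip(pmap["roi"].astype(int), pmap["z_set_size"]))
    z_steps = dict(zip(pmap["roi"].astype(int), pmap["z_steps"]))
    maint: list[int] = []
    manip: list[int] = []
    assigned: set[int] = set()
    while len(maint) < k or len(manip) < k:
        cand_m = [r for r in rank_set if r not in assigned][: k - len(maint)]
        cand_n = [r for r in rank_steps if r not in assigned][: k - len(manip)]
        contested = set(cand_m) & set(cand_n)
        for r in cand_m:
            if r not in contested and len(maint) < k:
                maint.append(r)
                assigned.add(r)
        for r in cand_n:
            if r not in contested and r not in assigned and len(manip) < k:
                manip.append(r)
                assigned.add(r)
        # contested ROIs go to the larger-z effect (ties to set size);
        # the loser backfills on the next pass
        for r in sorted(contested, key=lambda r: (-max(z_set[r], z_steps[r]), r)):
            prefer_manip = z_steps[r] > z_set[r]
            if prefer_manip and len(manip) < k:
                manip.append(r)
            elif not prefer_manip and len(maint) < k:
                maint.append(r)
            elif len(manip) < k:
                manip.append(r)
            elif len(maint) < k:
                maint.append(r)
            else:
                continue
            assigned.add(r)
    return NetworkPartition(tuple(sorted(maint)), tuple(sorted(manip)), fraction)


def conjunction(pmap: pd.DataFrame, threshold: float = 2.576) -> tuple[int, ...]:
    """ROIs suprathreshold for *both* demand effects."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hit = np.minimum(pmap["z_set_size"], pmap["z_steps"]) > threshold
    return tuple(pmap.loc[hit, "roi"].astype(int).tolist())


def validate_structure(fa_matrices: list[np.ndarray] | np.ndarray,
                       partition: NetworkPartition) -> dict:
    """Within- vs between-network mean FA and paired t across subjects.

    ``fa_matrices`` holds one symmetric matrix per subject, indexed in
    partition node order (maintenance block first).  Returns per-subject
    means, pooled summaries and a paired t per network (within vs
    between); with a single subject the t statistics are ``nan`` and
    flagged.
    """
    mats = [np.asarray(m, float) for m in (
        [fa_matrices] if isinstance(fa_matrices, np.ndarray) else fa_matrices)]
    k = partition.size
    n = 2 * k
    for m in mats:
        if m.shape != (n, n):
            raise ValueError(f"FA matrix shape {m.shape} != ({n}, {n})")
    iu = np.triu_indices(k, 1)
    w_maint = np.array([m[:k, :k][iu].mean() for m in mats])
    w_manip = np.array([m[k:, k:][iu].mean() for m in mats])
    between = np.array([m[:k, k:].mean() for m in mats])
    out = {
        "within_maintenance": w_maint, "within_manipulation": w_manip,
        "between": between,
        "mean_within_maintenance": float(w_maint.mean()),
        "mean_within_manipulation": float(w_manip.mean()),
        "mean_between": float(between.mean()),
        "single_subject": len(mats) < 2,
    }
    if len(mats) >= 2:
        for name, w in (("maintenance", w_maint), ("manipulation", w_manip)):
            d = w - between
            if np.allclose(d.std(ddof=1), 0.0):
                # no paired variability: t is 0 for identical means,
                # +/-inf for a deterministic offset
                m = d.mean()
                t = 0.0 if np.isclose(m, 0.0) else float(np.sign(m) * np.inf)
                p = 1.0 if t == 0.0 else 0.0
            else:
                t, p = (float(v) for v in stats.ttest_rel(w, between))
            out[f"t_{name}"], out[f"p_{name}"] = t, p
    else:
        out["t_maintenance"] = out["t_manipulation"] = float("nan")
    return out
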