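"""Leave-one-out robustness statistics for cluster-permutation results.

The cluster-based permutation test is rerun once per subject with that
subject excluded; each iteration records the T_sum and the number of
significant voxels of the largest significant cluster of the expected
sign, together with the relative T_sum (T_sum divided by the number of
significant voxels — a per-voxel cluster-strength statistic).  Groups
are then compared on these per-iteration statistics with Mann-Whitney
U tests, either dropping iterations without significant clusters
("missing") or scoring them as zero ("zero-penalty", the more
conservative option).

Note that the leave-one-out samples overlap heavily, so the group
comparisons treat dependent observations as independent; the procedure
is reproduced as published and no correction for this dependence is
attempted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clusterperm import Adjacency, ClusterSet, permutation_test


@dataclass
class LOORecord:
    left_out_subject: int
    band: str | tuple[float, float] | None
    cluster_found: bool
    t_sum: float | None = None
    n_sig_voxels: int | None = None

    @property
    def relative_t_sum(self) -> float | None:
        if not self.cluster_found or not self.n_sig_voxels:
            return None
        return self.t_sum / self.n_sig_voxels


@dataclass
class GroupComparison:
    statistic: str               # which LOO statistic was compared
    handling: str                # "missing" | "zero-penalty"
    U: float
    Z: float
    p: float
    r: float
    n_a: int
    n_b: int
    band: str | tuple[float, float] | None = None


def relative_tsum(t_sum: float, n_voxels: int) -> float:
    """T_sum per significant voxel; NaN when no voxels are significant."""
    if n_voxels < 0:
        raise ValueError("voxel count cannot be negative")
    if n_voxels == 0:
        return math.nan
    return t_sum / n_voxels


def loo_iterate(
    values_a: np.ndarray,
    values_b: np.ndarray,
    adjacency: Adjacency,
    band=None,
    sign: int = 1,
    R: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_neighbors: int = 0,
    aggregate: str = "largest",
    **perm_kwargs,
) -> list[LOORecord]:
    """One dependent-design permutation test per left-out subject.

    ``values_a``/``values_b`` are (subjects, nodes) condition arrays of
    one group.  Each iteration uses a seed fixed by the iteration index
    (``seed + index``) for reproducibility.  ``aggregate`` selects what
    is recorded when several clusters of the expected sign are
    significant: the largest one (default, mirroring one reported
    cluster per band/group) or their sum ("sum").
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least three subjects")
    records: list[LOORecord] = []
    for i in range(n):
        keep = np.arange(n) != i
        cs: ClusterSet = permutation_test(
            a[keep], b[keep], "dependent", adjacency,
            R=R, alpha=alpha, seed=seed + i, min_neighbors=min_neighbors,
            **perm_kwargs,
        )
        sig = [c for c in cs.significant() if c.sign == sign]
        if not sig:
            records.append(LOORecord(left_out_subject=i, band=band, cluster_found=False))
        elif aggregate == "sum":
            records.append(
                LOORecord(
                    left_out_subject=i, band=band, cluster_found=True,
                    t_sum=float(sum(c.t_sum for c in sig)),
                    n_sig_voxels=int(sum(len(c.nodes) for c in sig)),
                )
            )
        else:
            best = max(sig, key=lambda c: abs(c.t_sum))
            records.append(
                LOORecord(
                    left_out_subject=i, band=band, cluster_found=True,
                    t_sum=float(best.t_sum), n_sig_voxels=int(len(best.nodes)),
                )
            )
    return records


def _extract(records, statistic: str, handling: str) -> np.ndarray:
    def value(rec: LOORecord) -> float | None:
        if not rec.cluster_found:
            return None
        if statistic == "t_sum":
            return rec.t_sum
        if statistic == "n_voxels":
            return float(rec.n_sig_voxels)
        if statistic == "relative_t_sum":
            return rec.relative_t_sum
        raise ValueError(f"unknown statistic {statistic!r}")

    vals = [value(r) for r in records]
    if handling == "missing":
        return np.array([v for v in vals if v is not None], float)
    if handling == "zero-penalty":
        return np.array([0.0 if v is None else v for v in vals], float)
    raise ValueError(f"unknown handling {handling!r}")


def effect_size_r(z: float, n: int) -> float:
    """Rank-test effect size r = Z / sqrt(n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return z / math.sqrt(n)


def compare_groups(
    records_a,
    records_b,
    statistic: str = "relative_t_sum",
    handling: str = "missing",
    n_convention: str = "per_group",
) -> GroupComparison:
    """Mann-Whitney U comparison of a LOO statistic between groups.

    The effect size follows the published convention r = Z / sqrt(n)
    with n the per-group iteration count; ``n_convention="total"``
    uses the combined sample size instead.
    """
    if not records_a or not records_b:
        raise ValueError("both record lists must be non-empty")
    from .behavstats import mann_whitney  # local import to avoid a cycle

    va = _extract(records_a, statistic, handling)
    vb = _extract(records_b, statistic, handling)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("fewer than two usable observations in a group")
    res = mann_whitney(va, vb)
    if n_convention == "per_group":
        n_eff = max(len(records_a), len(records_b))
    elif n_convention == "total":
        n_eff = len(va) + len(vb)
    else:
        raise ValueError(f"unknown n convention {n_convention!r}")
    band = records_a[0].band
    return GroupComparison(
        statistic=statistic, handling=handling,
        U=res.statistic, Z=res.z, p=res.p,
        r=effect_size_r(res.z, n_eff),
        n_a=len(va), n_b=len(vb), band=band,
    )
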