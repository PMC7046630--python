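"""Omics relationship matrices, their principal components, and windowed
group-ORM arithmetic.

The ORM is the methylation analogue of a genomic relationship matrix:
``A = W W' / m`` over standardized probe values, so the diagonal averages 1
and the matrix is positive semi-definite by construction.  The windowed
variants support multi-component association engines that exclude probes in
a genomic window around the tested probe to avoid proximal contamination;
they are computed by downdating a precomputed full ORM (subtracting the
excluded probes' outer products and rescaling), which matches a rebuild
from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ValidationError


@dataclass
class ORM:
    """An n x n relationship matrix with the probe list that built it."""

    A: np.ndarray
    m: int
    probe_ids: list[str] = field(default_factory=list)
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValidationError("ORM must be square")
        if np.abs(self.A - self.A.T).max() > 1e-10:
            raise ValidationError("ORM must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]


def compute_orm(
    W: MethylationMatrix | np.ndarray,
    probe_subset: list[str] | None = None,
    group_label: str | None = None,
) -> ORM:
    """Build ``A = W W' / m`` from standardized probe values.

    ``W`` may be a standardized/residualized :class:`MethylationMatrix` or a
    plain array (assumed pre-standardized).  ``probe_subset`` restricts to
    the named probes.
    """
    if isinstance(W, MethylationMatrix):
        if W.scale_state == "beta":
            raise ValidationError("compute_orm expects standardized values")
        probe_ids = list(W.probe_ids)
        vals = W.values
        if probe_subset is not None:
            sub = W.subset_probes(list(probe_subset))
            vals, probe_ids = sub.values, list(sub.probe_ids)
    else:
        vals = np.asarray(W, dtype=float)
        probe_ids = [f"p{j}" for j in range(vals.shape[1])]
        if probe_subset is not None:
            raise ValidationError("probe_subset needs a MethylationMatrix")
    m = vals.shape[1]
    if m == 0:
        raise ValidationError("cannot build an ORM from zero probes")
    A = (vals @ vals.T) / m
    A = (A + A.T) / 2.0
    return ORM(A=A, m=m, probe_ids=probe_ids, group_label=group_label)


def orm_pca(A: ORM, k: int) -> np.ndarray:
    """Top-k principal component scores of a relationship matrix.

    Eigenvectors are scaled by the square root of their eigenvalue and
    ordered by descending eigenvalue; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if k > A.n:
        raise ValidationError(f"k={k} exceeds n={A.n}")
    if k == 0:
        return np.empty((A.n, 0))
    w, V = np.linalg.eigh(A.A)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(k):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V * np.sqrt(w)


def window_mask(
    probe_annot: pd.DataFrame, target_probe: str, window_bp: int
) -> np.ndarray:
    """Boolean mask of probes excluded for a target: the target itself plus
    probes on its chromosome within ``window_bp / 2`` of its position
    (inclusive) — i.e. the ``window_bp`` region centred at the probe."""
    pid = probe_annot["probe_id"].to_numpy()
    hit = pid == target_probe
    if not hit.any():
        raise ValidationError(f"target probe {target_probe!r} not found")
    t = np.flatnonzero(hit)[0]
    chrom = probe_annot["chr"].to_numpy()
    bp = probe_annot["bp"].to_numpy(np.int64)
    half = window_bp // 2
    mask = (chrom == chrom[t]) & (np.abs(bp - bp[t]) <= half)
    mask[t] = True
    return mask


def downdate_orm(
    orm: ORM, W_excl: np.ndarray, excl_ids: list[str]
) -> ORM:
    """Remove probes from an ORM without rebuilding.

    ``A_new = (m A - W_excl W_excl') / (m - k)``; raises when the group
    would be left empty.
    """
    k = W_excl.shape[1]
    if k == 0:
        return orm
    if orm.m - k <= 0:
        raise ValidationError(
            f"group {orm.group_label!r} empty after window exclusion"
        )
    A = (orm.m * orm.A - W_excl @ W_excl.T) / (orm.m - k)
    kept = [p for p in orm.probe_ids if p not in set(excl_ids)]
    return ORM(A=(A + A.T) / 2.0, m=orm.m - k, probe_ids=kept,
               group_label=orm.group_label)


def windowed_group_orm(
    W: MethylationMatrix,
    groups: dict[str, int] | np.ndarray,
    target_probe: str,
    window_bp: int = 100_000,
    full_orms: dict[int, ORM] | None = None,
) -> list[ORM]:
    """Group-wise ORMs excluding the window around a target probe.

    ``groups`` maps probe id (or a per-probe integer array) to group label
    1 or 2.  Probes within ``window_bp / 2`` of the target (same
    chromosome), and the target itself, are excluded from *both* groups.
    Precomputed full group ORMs may be passed to enable downdating; they
    are computed here otherwise.
    """
    pid = W.probe_ids
    if isinstance(groups, dict):
        gvec = np.array([groups[p] for p in pid])
    else:
        gvec = np.asarray(groups)
        if gvec.shape[0] != len(pid):
            raise ValidationError("group vector length mismatch")
    labels = sorted(set(gvec.tolist()))
    if full_orms is None:
        full_orms = {
            g: compute_orm(
                W.values[:, gvec == g], group_label=str(g)
            )
            for g in labels
        }
        for g in labels:
            full_orms[g].probe_ids = [p for p, gg in zip(pid, gvec) if gg == g]
    excl = window_mask(W.probe_annot, target_probe, window_bp)
    out = []
    for g in labels:
        in_group = gvec == g
        drop = in_group & excl
        W_excl = W.values[:, drop]
        out.append(
            downdate_orm(full_orms[g], W_excl, [p for p in pid[drop]])
        )
    return out
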