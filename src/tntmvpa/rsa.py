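"""Cross-phase representational similarity and the reinstatement index.

Memory-specific reinstatement is quantified by correlating (Pearson,
over ROI voxels) each item's pre-test pattern with every item's
post-test pattern. The similarity of an item with itself (same-item) is
compared with its average similarity to the other items of the same
condition (different-item); restricting the different-item pool to the
same condition ensures condition-level mean shifts cannot masquerade as
item-specific reinstatement. Correlations are Fisher-z transformed
before averaging, and the reinstatement index is

    R = z_same - z_diff            (per condition, per subject)

with the suppression-induced reduction exported as R_baseline -
R_suppress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import TrialPatternSet
from .synthetic import ROIMask

logger = logging.getLogger(__name__)

#: clipping bound applied before atanh so |r| = 1 stays finite
FISHER_EPS = 1e-7


def fisher_z(r, eps: float = FISHER_EPS):
    """Variance-stabilising Fisher transform z = atanh(r).

    Values at the boundary |r| = 1 are clipped to 1 - eps (the event is
    logged); |r| > 1 is rejected.
    """
    r = np.asarray(r, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = finite & (np.abs(r) > 1 - eps)
    if clipped.any():
        logger.info("fisher_z: clipped %d boundary correlation(s)", int(clipped.sum()))
    z = np.where(finite, np.arctanh(np.clip(r, -1 + eps, 1 - eps)), np.nan)
    return z if z.ndim else float(z)


@dataclass
class CrossPhaseSimilarity:
    """Pre-by-post item similarity matrix over one ROI.

    ``matrix[i, j]`` is the Pearson correlation of item i's pre-test
    pattern with item j's post-test pattern; generally non-symmetric.
    """

    matrix: np.ndarray
    items: list[str]
    condition: dict[str, str]
    roi: str
    n_undefined: int = 0


def _pairwise_pearson(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix with pairwise exclusion of NaN voxels."""
    n_pre, n_post = pre.shape[0], post.shape[0]
    if np.all(np.isfinite(pre)) and np.all(np.isfinite(post)):
        pc = pre - pre.mean(axis=1, keepdims=True)
        qc = post - post.mean(axis=1, keepdims=True)
        pn = np.linalg.norm(pc, axis=1)
        qn = np.linalg.norm(qc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (pc @ qc.T) / np.outer(pn, qn)
        out[pn == 0, :] = np.nan
        out[:, qn == 0] = np.nan
        return np.clip(out, -1.0, 1.0, out=out)
    out = np.full((n_pre, n_post), np.nan)
    for i in range(n_pre):
        for j in range(n_post):
            mask = np.isfinite(pre[i]) & np.isfinite(post[j])
            if mask.sum() < 3:
                continue
            x, y = pre[i, mask], post[j, mask]
            xs, ys = x.std(), y.std()
            if xs == 0 or ys == 0:
                continue
            out[i, j] = np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0)
    return out


def cross_phase_similarity(
    pre: TrialPatternSet, post: TrialPatternSet, roi: ROIMask
) -> CrossPhaseSimilarity:
    """Pearson similarity of every pre-test item pattern with every
    post-test item pattern over the ROI voxels.

    Items must match across phases (each critical item occurs exactly
    once per test phase, so item-level equals trial-level here);
    constant (zero-variance) patterns yield undefined similarities,
    which are reported and propagate as NaN.
    """
    roi.validate(pre.n_voxels)
    if roi.indices.size < 3:
        raise ValueError("similarity requires an ROI of at least 3 voxels")
    pre_items = pre.meta["item_id"].tolist()
    post_items = post.meta["item_id"].tolist()
    if sorted(pre_items) != sorted(post_items):
        raise ValueError("pre- and post-test pattern sets must cover identical items")
    items = pre_items
    post_order = [post_items.index(i) for i in items]
    P = pre.patterns[:, roi.indices]
    Q = post.patterns[np.asarray(post_order)][:, roi.indices]
    mat = _pairwise_pearson(P, Q)
    n_undef = int(np.isnan(mat).sum())
    if n_undef:
        logger.warning("cross_phase_similarity[%s]: %d undefined similarities", roi.name, n_undef)
    condition = dict(zip(items, pre.meta["condition"].tolist()))
    return CrossPhaseSimilarity(
        matrix=mat, items=list(items), condition=condition, roi=roi.name, n_undefined=n_undef
    )


@dataclass
class SimilarityResult:
    """Per-item Fisher-z similarities and per-condition reinstatement."""

    per_item: pd.DataFrame  # item_id, condition, z_same, z_diff
    per_condition: pd.DataFrame  # condition, z_same, z_diff, reinstatement
    roi: str

    def reduction(self) -> float:
        """Suppression-induced reduction R_baseline - R_suppress."""
        r = self.per_condition.set_index("condition")["reinstatement"]
        return float(r["baseline"] - r["suppress"])


def reinstatement_index(
    sim: CrossPhaseSimilarity, symmetric: bool = False
) -> SimilarityResult:
    """Same-item minus different-item Fisher-z similarity per condition.

    For item i, z_same = fisher(r(i, i)) and z_diff averages
    fisher(r(i, j)) over the other items j of the same condition,
    using the pre(i) x post(j) direction (``symmetric=True`` additionally
    averages in the post(i) x pre(j) direction, i.e. r(j, i)).

    Raises
    ------
    ValueError
        If any condition has fewer than 2 items (the different-item mean
        would be undefined).
    """
    items = sim.items
    conds = np.array([sim.condition[i] for i in items])
    for c in np.unique(conds):
        if (conds == c).sum() < 2:
            raise ValueError(f"condition '{c}' has fewer than 2 items")
    Z = fisher_z(sim.matrix)
    rows = []
    for i, item in enumerate(items):
        same_cond = np.flatnonzero((conds == conds[i]))
        others = same_cond[same_cond != i]
        z_same = Z[i, i]
        if symmetric:
            z_same = np.nanmean([Z[i, i], Z[i, i]])  # diagonal is its own mirror
            zd = np.nanmean(np.concatenate([Z[i, others], Z[others, i]]))
        else:
            zd = np.nanmean(Z[i, others])
        rows.append(
            {"item_id": item, "condition": conds[i], "z_same": z_same, "z_diff": zd}
        )
    per_item = pd.DataFrame(rows)
    per_condition = (
        per_item.groupby("condition", as_index=False)[["z_same", "z_diff"]].mean()
    )
    per_condition["reinstatement"] = per_condition["z_same"] - per_condition["z_diff"]
    return SimilarityResult(per_item=per_item, per_condition=per_condition, roi=sim.roi)
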