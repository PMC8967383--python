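"""Single-trial and block-wise GLM pattern estimation.

Implements the least-squares-single (LSS) strategy for estimating one
activity pattern per trial: each trial gets its own GLM with a regressor
for that trial and a second regressor collapsing all other trials, plus
nuisance regressors, a discrete-cosine high-pass set and run intercepts.
Parameter estimates are converted to voxelwise t-values through the
contrast target-minus-others; the resulting t-maps are the substrate for
all downstream multivoxel analyses.

Boxcar regressors are convolved with the canonical double-gamma
haemodynamic response function on a fine time grid before being sampled
at the scan times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: fine time grid (s) used to build regressors before TR sampling
HRF_DT = 0.1
#: canonical HRF support (s)
HRF_LENGTH = 32.0
#: conventional high-pass cutoff (s)
DEFAULT_HP_CUTOFF = 128.0

# ---------------------------------------------------------------------------
# canonical HRF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HRFKernel:
    """Canonical haemodynamic response sampled on a uniform grid."""

    samples: np.ndarray
    dt: float
    length: float = HRF_LENGTH

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def canonical_hrf(dt: float = HRF_DT) -> HRFKernel:
    """Double-gamma canonical HRF.

    Difference of two gamma densities with peak delay 6 s, undershoot
    delay 16 s, unit dispersions and a peak:undershoot ratio of 6,
    evaluated on ``[0, 32]`` s and normalised to peak amplitude 1.

    Parameters
    ----------
    dt : float
        Grid spacing in seconds, ``0 < dt <= 1``.
    """
    if not (0 < dt <= 1):
        raise ValueError(f"dt must be in (0, 1], got {dt}")
    t = np.arange(int(round(HRF_LENGTH / dt)) + 1) * dt
    h = sps.gamma.pdf(t, a=6.0, scale=1.0) - sps.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    h = h / h.max()
    return HRFKernel(samples=h, dt=dt)


def sample_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    dt: float = HRF_DT,
    hrf: HRFKernel | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the TR grid.

    The boxcar is built on a grid of spacing ``dt``, convolved with the
    canonical HRF, and read out at scan times ``0, TR, 2 TR, ...``
    (microtime onset at 0).
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.atleast_1d(np.asarray(durations, dtype=float)), onsets.shape
    )
    if hrf is None:
        hrf = canonical_hrf(dt)
    elif hrf.dt != dt:
        raise ValueError("hrf grid spacing does not match dt")
    total = n_scans * tr
    if np.any(onsets + durations > total + 1e-9):
        raise ValueError("events extend beyond the acquired time series")
    n_fine = int(np.ceil(total / dt)) + 1
    box = np.zeros(n_fine)
    for on, dur in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        box[i0:i1] = 1.0
    # dt factor approximates the continuous convolution integral, making
    # the regressor scale independent of the fine-grid resolution
    conv = np.convolve(box, hrf.samples)[:n_fine] * dt
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


# ---------------------------------------------------------------------------
# high-pass basis and design matrix
# ---------------------------------------------------------------------------


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = DEFAULT_HP_CUTOFF) -> np.ndarray:
    """Discrete-cosine high-pass set with cutoff expressed in seconds.

    Order ``K = floor(2 * n_scans * TR / cutoff)``; columns are the unit
    DCT-II basis vectors of order 1..K (the constant term is left to the
    intercept).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive (seconds)")
    K = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_scans))
        for k in range(1, K + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def highpass_project(data: np.ndarray, tr: float, cutoff: float = DEFAULT_HP_CUTOFF) -> np.ndarray:
    """Residual-forming projection removing the DCT set plus intercept.

    Operates on the last axis (time). Including the DCT set as regressors
    in a GLM is equivalent to applying this projection to both the data
    and the model, which is why the LSS estimator simply appends the
    basis to each design.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    C = np.column_stack([np.ones(n), dct_highpass_basis(n, tr, cutoff)])
    coef, *_ = np.linalg.lstsq(C, data.reshape(-1, n).T, rcond=None)
    resid = data.reshape(-1, n).T - C @ coef
    return resid.T.reshape(data.shape)


@dataclass
class DesignMatrix:
    """Labelled GLM design at the TR grid."""

    matrix: np.ndarray
    names: list[str]
    tr: float
    hp_cutoff: float

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")


def _name_rank_deficient(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of earlier ones."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        coef, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
        resid = X[:, j] - prev @ coef
        scale = max(np.linalg.norm(X[:, j]), 1e-12)
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(names[j])
    return bad


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    nuisance: np.ndarray | None = None,
    hp_cutoff: float = DEFAULT_HP_CUTOFF,
    dt: float = HRF_DT,
) -> DesignMatrix:
    """Assemble a GLM design: one convolved regressor per event row, the
    DCT high-pass set, nuisance columns (appended unchanged) and an
    intercept.

    Raises
    ------
    ValueError
        If events extend beyond ``n_scans * tr`` or the assembled matrix
        is rank deficient (the offending columns are named).
    """
    hrf = canonical_hrf(dt)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for i, row in enumerate(events.itertuples(index=False)):
        cols.append(
            sample_regressor(row.onset, row.duration, n_scans, tr, dt=dt, hrf=hrf)
        )
        names.append(f"trial_{i:03d}")
    hp = dct_highpass_basis(n_scans, tr, hp_cutoff)
    for k in range(hp.shape[1]):
        cols.append(hp[:, k])
        names.append(f"dct_{k + 1:02d}")
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance row count must equal n_scans")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k:02d}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _name_rank_deficient(X, names)
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    return DesignMatrix(matrix=X, names=names, tr=tr, hp_cutoff=hp_cutoff)


# ---------------------------------------------------------------------------
# trial pattern container
# ---------------------------------------------------------------------------

META_COLUMNS = ["trial_id", "phase", "condition", "item_id", "block"]


@dataclass
class TrialPatternSet:
    """Trials-by-voxels t-value patterns with per-trial metadata.

    ``patterns[i]`` is the voxelwise t-map of trial ``meta.iloc[i]``;
    undefined voxels (zero residual variance) are NaN and are excluded
    pairwise downstream.
    """

    patterns: np.ndarray
    meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.meta):
            raise ValueError("one metadata row per pattern required")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def select(self, mask: np.ndarray) -> "TrialPatternSet":
        """Row subset by boolean mask or index array."""
        return TrialPatternSet(
            patterns=self.patterns[mask],
            meta=self.meta.iloc[np.atleast_1d(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype != bool
            else self.meta.loc[mask].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def to_files(self, pattern_path, meta_path) -> None:
        np.savetxt(pattern_path, self.patterns, delimiter="\t")
        self.meta.to_csv(meta_path, sep="\t", index=False, na_rep="n/a")

    @classmethod
    def from_files(cls, pattern_path, meta_path) -> "TrialPatternSet":
        patterns = np.loadtxt(pattern_path, delimiter="\t", ndmin=2)
        meta = pd.read_csv(meta_path, sep="\t", na_values=["n/a"])
        return cls(patterns=patterns, meta=meta)


# ---------------------------------------------------------------------------
# LSS estimation
# ---------------------------------------------------------------------------


def _ols_tmap(
    X: np.ndarray, data: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of ``data`` (time x voxels) on ``X``; returns (betas, t).

    t = c'b / sqrt(s2 * c'(X'X)^- c) with s2 the residual variance at
    residual dof = n - rank(X). Voxels with (numerically) zero residual
    variance get NaN t-values rather than infinities.
    """
    n = X.shape[0]
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ data)
    resid = data - X @ beta
    rank = np.linalg.matrix_rank(X)
    dof = n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = np.einsum("ij,ij->j", resid, resid) / dof
    cvar = float(contrast @ XtX_inv @ contrast)
    cb = contrast @ beta
    scale = np.mean(data * data) if data.size else 0.0
    undefined = s2 <= 1e-20 * max(scale, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / np.sqrt(s2 * cvar)
    t[undefined] = np.nan
    return beta, t


def lss_estimate(
    ts,
    events: pd.DataFrame,
    hp_cutoff: float = DEFAULT_HP_CUTOFF,
    group_by: str = "trial",
    dt: float = HRF_DT,
    return_betas: bool = False,
):
    """Least-squares-single trial pattern estimation.

    For each target unit (a single trial, or all repetitions of one item
    when ``group_by='item'``), fits an OLS model with a target regressor,
    a collapsed all-other-trials regressor, the nuisance columns carried
    by ``ts``, the DCT high-pass set and an intercept, and converts the
    fit to a voxelwise t-map via the target-minus-others contrast.

    Parameters
    ----------
    ts : VoxelTimeSeries
        Single-run series (voxels x timepoints) with nuisance columns.
    events : DataFrame
        Columns onset, duration, phase, condition, item_id, block.
    group_by : {'trial', 'item'}
        Unit receiving its own GLM. 'item' collapses repeated
        presentations of the same item into one target regressor (the
        Think/No-Think phase model).

    Returns
    -------
    TrialPatternSet
        One t-map per unit; ``provenance['n_undefined_voxels']`` counts
        NaN-flagged voxels.
    """
    data = np.asarray(ts.data, dtype=float).T  # time x voxels
    n_scans = data.shape[0]
    tr = ts.tr
    events = events.reset_index(drop=True)
    if group_by == "trial":
        groups = [[i] for i in range(len(events))]
    elif group_by == "item":
        groups = [list(idx) for _, idx in events.groupby("item_id", sort=False).groups.items()]
    else:
        raise ValueError(f"unknown group_by: {group_by}")
    if not groups:
        raise ValueError("no events to estimate")

    hrf = canonical_hrf(dt)
    regs = np.column_stack(
        [
            sample_regressor(row.onset, row.duration, n_scans, tr, dt=dt, hrf=hrf)
            for row in events.itertuples(index=False)
        ]
    )  # scans x trials
    total_reg = regs.sum(axis=1)
    base_cols = [dct_highpass_basis(n_scans, tr, hp_cutoff)]
    nuis = getattr(ts, "nuisance", None)
    if nuis is not None and np.size(nuis):
        nuis = np.asarray(nuis, dtype=float)
        if nuis.shape[0] != n_scans:
            raise ValueError("nuisance row count must equal timepoint count")
        base_cols.append(nuis)
    base_cols.append(np.ones((n_scans, 1)))
    base = np.column_stack(base_cols)

    patterns = np.empty((len(groups), data.shape[1]))
    betas = np.empty_like(patterns)
    meta_rows = []
    n_undefined = 0
    for g, idx in enumerate(groups):
        target = regs[:, idx].sum(axis=1)
        others = total_reg - target
        single_unit = len(groups) == 1
        if single_unit:
            X = np.column_stack([target, base])
            contrast = np.zeros(X.shape[1])
            contrast[0] = 1.0
        else:
            X = np.column_stack([target, others, base])
            contrast = np.zeros(X.shape[1])
            contrast[0], contrast[1] = 1.0, -1.0
        beta, t = _ols_tmap(X, data, contrast)
        patterns[g] = t
        betas[g] = beta[0]
        n_undefined += int(np.isnan(t).sum())
        row = events.iloc[idx[0]]
        meta_rows.append(
            {
                "trial_id": g,
                "phase": row.get("phase", "n/a"),
                "condition": row.get("condition", "n/a"),
                "item_id": row.get("item_id", "n/a"),
                "block": row.get("block", -1),
            }
        )
    if n_undefined:
        logger.info("lss_estimate: %d voxel t-values undefined (zero residual variance)", n_undefined)
    out = TrialPatternSet(
        patterns=patterns,
        meta=pd.DataFrame(meta_rows, columns=META_COLUMNS),
        provenance={
            "estimator": "lss",
            "group_by": group_by,
            "hp_cutoff": hp_cutoff,
            "n_undefined_voxels": n_undefined,
        },
    )
    if return_betas:
        return out, betas
    return out


def block_estimate(ts, events: pd.DataFrame, hp_cutoff: float = DEFAULT_HP_CUTOFF, **kw):
    """Block-wise pattern estimation for the localizer.

    Identical to :func:`lss_estimate` with one GLM per block-duration
    boxcar; each event row is one block, labelled with its class
    (intact/morphed) and block index.
    """
    out = lss_estimate(ts, events, hp_cutoff=hp_cutoff, group_by="trial", **kw)
    prov = dict(out.provenance) if isinstance(out, TrialPatternSet) else dict(out[0].provenance)
    prov["estimator"] = "block"
    if isinstance(out, TrialPatternSet):
        out.provenance = prov
    else:
        out[0].provenance = prov
    return out
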