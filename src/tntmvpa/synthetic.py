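"""Seeded synthetic Think/No-Think fMRI experiments with known ground truth.

Emulates the design of a retrieval-suppression study: a pre-test and a
post-test of cued recall over three item conditions (baseline, suppress,
recall) with 1-5 vividness ratings, a five-block Think/No-Think phase in
which recall and suppress items each appear twice per block while
baseline items are withheld, and a twelve-block two-class localizer
(intact vs morphed aversive scenes).

Voxel time series follow the forward model the downstream GLM assumes:
each trial contributes HRF-convolved boxcar responses of two additive
components — a category (scene) template scaled by a per-(phase,
condition) amplitude, and an item-unique template scaled by the item
amplitude — on top of low-frequency drift, AR(1) Gaussian noise and
nuisance-regressor leakage. A per-subject suppression effect delta
reduces the category amplitude of suppress items at post-test only, and
the same latent amplitude drives the simulated vividness ratings, so
both the neural and the behavioural suppression effects share one
plantable ground truth.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import signal as ssig
from scipy.optimize import brentq

from .glm import HRF_DT, canonical_hrf, sample_regressor

PHASES = ("pretest", "tnt", "posttest", "localizer")
CONDITIONS = ("baseline", "suppress", "recall")
LOCALIZER_CLASSES = ("intact", "morphed")
#: ROI compartments; graymatter is their union
COMPARTMENTS = ("phc_left", "phc_right", "other")

EVENT_COLUMNS = ["onset", "duration", "phase", "condition", "item_id", "block", "run"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters of one simulated experiment.

    Defaults reproduce the study design: 16 items per condition, TR 2 s,
    3 s recall trials with a long 14 s ITI (plus a 3 s rating period),
    five Think/No-Think blocks with two presentations per item per block
    and 2-8.5 s jittered ITIs of mean 3 s, and six 16 s localizer blocks
    per class with 10 s between blocks.
    """

    n_items_per_condition: int = 16
    n_voxels: int = 60  # per compartment (phc_left, phc_right, other)
    tr: float = 2.0
    trial_duration_test: float = 3.0
    rating_duration: float = 3.0
    iti_test: float = 14.0
    tnt_blocks: int = 5
    tnt_repeats_per_block: int = 2
    tnt_trial_duration: float = 3.0
    tnt_iti_min: float = 2.0
    tnt_iti_max: float = 8.5
    tnt_iti_mean: float = 3.0
    tnt_block_gap: float = 10.0
    localizer_blocks_per_class: int = 6
    localizer_block_duration: float = 16.0
    localizer_inter_block: float = 10.0
    n_nuisance: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_items_per_condition": self.n_items_per_condition,
            "n_voxels": self.n_voxels,
            "tnt_blocks": self.tnt_blocks,
            "tnt_repeats_per_block": self.tnt_repeats_per_block,
            "localizer_blocks_per_class": self.localizer_blocks_per_class,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v} (zero items make an empty design)")
        durations = {
            "tr": self.tr,
            "trial_duration_test": self.trial_duration_test,
            "iti_test": self.iti_test,
            "tnt_trial_duration": self.tnt_trial_duration,
            "localizer_block_duration": self.localizer_block_duration,
        }
        for name, v in durations.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not (0 < self.tnt_iti_min <= self.tnt_iti_mean <= self.tnt_iti_max):
            raise ValueError("require 0 < tnt_iti_min <= tnt_iti_mean <= tnt_iti_max")

    @property
    def n_items(self) -> int:
        return 3 * self.n_items_per_condition

    @property
    def n_total_voxels(self) -> int:
        return len(COMPARTMENTS) * self.n_voxels

    @property
    def item_ids(self) -> list[str]:
        return [f"item{i:03d}" for i in range(self.n_items)]

    def item_condition_map(self) -> dict[str, str]:
        """Deterministic, seed-shuffled assignment of items to conditions."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
        ids = np.array(self.item_ids)
        rng.shuffle(ids)
        out = {}
        for c, cond in enumerate(CONDITIONS):
            for iid in ids[c * self.n_items_per_condition : (c + 1) * self.n_items_per_condition]:
                out[str(iid)] = cond
        return out


@dataclass(frozen=True)
class ROIMask:
    """Named set of voxel indices; masks may overlap (PhC within graymatter)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"ROI '{self.name}' is empty")
        object.__setattr__(self, "indices", idx)

    def validate(self, n_voxels: int) -> None:
        if self.indices.min() < 0 or self.indices.max() >= n_voxels:
            raise ValueError(f"ROI '{self.name}' has indices outside [0, {n_voxels})")


def default_rois(config: ExperimentConfig) -> dict[str, ROIMask]:
    """phc_left, phc_right, other compartments plus the graymatter union."""
    n = config.n_voxels
    rois = {
        name: ROIMask(name, np.arange(i * n, (i + 1) * n))
        for i, name in enumerate(COMPARTMENTS)
    }
    rois["graymatter"] = ROIMask("graymatter", np.arange(config.n_total_voxels))
    return rois


def save_rois(rois: dict[str, ROIMask], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.indices.tolist() for k, v in rois.items()}, fh)


def load_rois(path) -> dict[str, ROIMask]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: ROIMask(k, np.asarray(v, dtype=int)) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _default_category_amplitude() -> dict:
    # recall-like retrieval carries full scene signal; active suppression
    # transiently reduces it; the two localizer classes drive their own
    # templates at equal strength
    amp = {}
    for phase in ("pretest", "posttest"):
        for cond in CONDITIONS:
            amp[(phase, cond)] = 1.0
    amp[("tnt", "recall")] = 1.0
    amp[("tnt", "suppress")] = 0.4
    amp[("localizer", "intact")] = 1.0
    amp[("localizer", "morphed")] = 1.0
    return amp


@dataclass
class SimulationTruth:
    """Generative parameters and templates for one simulated subject.

    ``subject_delta`` is the suppression-induced reduction of the
    category amplitude, applied only to suppress items at post-test.
    Templates are stored so recovery checks can compare estimates
    against the planted signal.
    """

    category_amplitude: dict = field(default_factory=_default_category_amplitude)
    item_amplitude: float = 0.6
    subject_delta: float = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    vividness_intercept: float = 1.0
    vividness_slope: float = 2.0
    vividness_noise_sd: float = 0.8
    scene_template: np.ndarray | None = None
    morphed_template: np.ndarray | None = None
    item_templates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must be in [0, 1)")


def generate_templates(config: ExperimentConfig, seed: int) -> dict:
    """Unit-norm category and item template vectors.

    The scene (intact) and morphed category templates are concentrated in
    the PhC compartments (their loadings there are drawn with three times
    the standard deviation of the rest), emulating the preferential
    engagement of scene-selective cortex; item templates are isotropic
    and mutually uncorrelated in expectation.
    """
    if config.n_voxels < 2:
        raise ValueError("need at least 2 voxels per compartment")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    V = config.n_total_voxels
    phc = np.zeros(V, dtype=bool)
    phc[: 2 * config.n_voxels] = True  # phc_left + phc_right

    def category_vec() -> np.ndarray:
        v = rng.normal(size=V)
        v[phc] *= 3.0
        return v / np.linalg.norm(v)

    scene = category_vec()
    morphed = category_vec()
    items = {}
    for iid in config.item_ids:
        v = rng.normal(size=V)
        items[iid] = v / np.linalg.norm(v)
    return {"scene": scene, "morphed": morphed, "items": items}


def default_truth(
    config: ExperimentConfig,
    seed: int | None = None,
    subject_delta: float = 0.0,
    **overrides,
) -> SimulationTruth:
    """Truth with freshly generated templates for ``config``."""
    if seed is None:
        seed = config.seed
    tpl = generate_templates(config, seed)
    return SimulationTruth(
        subject_delta=subject_delta,
        scene_template=tpl["scene"],
        morphed_template=tpl["morphed"],
        item_templates=tpl["items"],
        **overrides,
    )


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------


def _shuffle_max_run(labels: list, rng: np.random.Generator, max_run: int, key=lambda x: x) -> list:
    """Shuffle with at most ``max_run`` consecutive equal keys (retry loop)."""
    labels = list(labels)
    for _ in range(2000):
        rng.shuffle(labels)
        run, prev, ok = 0, object(), True
        for lab in labels:
            k = key(lab)
            run = run + 1 if k == prev else 1
            prev = k
            if run > max_run:
                ok = False
                break
        if ok:
            return labels
    return labels  # degenerate tiny designs may not admit the constraint


def _truncexp_rate(a: float, b: float, mean: float) -> float:
    """Rate of an exponential truncated to [a, b] with the given mean."""

    def m(lam: float) -> float:
        if lam < 1e-9:
            return (a + b) / 2.0
        ea, eb = np.exp(-lam * a), np.exp(-lam * b)
        num = (a + 1 / lam) * ea - (b + 1 / lam) * eb
        return num / (ea - eb)

    lo, hi = 1e-6, 200.0
    if not (m(hi) <= mean <= m(lo)):
        raise ValueError("requested ITI mean not attainable on the given range")
    return brentq(lambda l: m(l) - mean, lo, hi)


def sample_truncexp_itis(
    n: int, a: float, b: float, mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered ITIs from a truncated exponential on [a, b] with target mean."""
    if a == b:
        return np.full(n, a)
    lam = _truncexp_rate(a, b, mean)
    u = rng.uniform(size=n)
    ea, eb = np.exp(-lam * a), np.exp(-lam * b)
    return -np.log(ea - u * (ea - eb)) / lam


def generate_design(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Event tables for every phase, keyed pretest/tnt/posttest/localizer.

    Pre- and post-test each present every critical item exactly once in a
    pseudorandom order (at most three same-condition items in a row);
    Think/No-Think blocks present every recall and suppress item
    ``tnt_repeats_per_block`` times with truncated-exponential ITI
    jitter, and never a baseline item; the localizer alternates intact
    and morphed blocks pseudorandomly (at most two of a class in a row).
    """
    cond_of = config.item_condition_map()
    items = config.item_ids
    tables: dict[str, pd.DataFrame] = {}

    run_index = {"pretest": 0, "tnt": 1, "posttest": 2, "localizer": 3}
    spacing = config.trial_duration_test + config.rating_duration + config.iti_test

    for phase in ("pretest", "posttest"):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31, run_index[phase]]))
        order = _shuffle_max_run(list(items), rng, max_run=3, key=lambda i: cond_of[i])
        rows = [
            {
                "onset": k * spacing,
                "duration": config.trial_duration_test,
                "phase": phase,
                "condition": cond_of[iid],
                "item_id": iid,
                "block": 0,
                "run": run_index[phase],
            }
            for k, iid in enumerate(order)
        ]
        tables[phase] = pd.DataFrame(rows, columns=EVENT_COLUMNS)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31, run_index["tnt"]]))
    tnt_items = [i for i in items if cond_of[i] != "baseline"]
    rows = []
    t = 0.0
    for b in range(config.tnt_blocks):
        order = list(tnt_items) * config.tnt_repeats_per_block
        order = _shuffle_max_run(order, rng, max_run=2)
        itis = sample_truncexp_itis(
            len(order), config.tnt_iti_min, config.tnt_iti_max, config.tnt_iti_mean, rng
        )
        for iid, iti in zip(order, itis):
            rows.append(
                {
                    "onset": t,
                    "duration": config.tnt_trial_duration,
                    "phase": "tnt",
                    "condition": cond_of[iid],
                    "item_id": iid,
                    "block": b,
                    "run": run_index["tnt"],
                }
            )
            t += config.tnt_trial_duration + iti
        t += config.tnt_block_gap
    tables["tnt"] = pd.DataFrame(rows, columns=EVENT_COLUMNS)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31, run_index["localizer"]]))
    classes = list(LOCALIZER_CLASSES) * config.localizer_blocks_per_class
    classes = _shuffle_max_run(classes, rng, max_run=2)
    rows = []
    t = 0.0
    for b, cls in enumerate(classes):
        rows.append(
            {
                "onset": t,
                "duration": config.localizer_block_duration,
                "phase": "localizer",
                "condition": cls,
                "item_id": "n/a",
                "block": b,
                "run": run_index["localizer"],
            }
        )
        t += config.localizer_block_duration + config.localizer_inter_block
    tables["localizer"] = pd.DataFrame(rows, columns=EVENT_COLUMNS)

    for phase, df in tables.items():
        _validate_events(df, phase)
    return tables


def _validate_events(df: pd.DataFrame, phase: str) -> None:
    onsets = df["onset"].to_numpy()
    ends = onsets + df["duration"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise ValueError(f"{phase}: onsets must be strictly increasing within a run")
    if not np.all(ends[:-1] <= onsets[1:] + 1e-9):
        raise ValueError(f"{phase}: overlapping trials")
    if phase == "tnt" and (df["condition"] == "baseline").any():
        raise ValueError("baseline items must never appear in the tnt phase")


# ---------------------------------------------------------------------------
# events TSV (BIDS dialect)
# ---------------------------------------------------------------------------


def events_to_tsv(df: pd.DataFrame, path) -> None:
    """Write a BIDS-dialect events table (trial_type carries the phase)."""
    out = df.rename(columns={"phase": "trial_type"})
    out = out[["onset", "duration", "trial_type", "condition", "item_id", "block", "run"]]
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def events_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    df = df.rename(columns={"trial_type": "phase"})
    return df[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


@dataclass
class VoxelTimeSeries:
    """Single- or multi-run voxels-by-timepoints series with nuisance columns."""

    data: np.ndarray
    tr: float
    run_boundaries: list[int] = field(default_factory=list)
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.nuisance is not None and self.nuisance.shape[0] != self.data.shape[1]:
            raise ValueError("nuisance row count must equal timepoint count")

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path, nuisance_path=None) -> None:
        np.savetxt(path, self.data, delimiter="\t")
        if nuisance_path is not None and self.nuisance is not None:
            np.savetxt(nuisance_path, self.nuisance, delimiter="\t")

    @classmethod
    def from_tsv(cls, path, tr: float, nuisance_path=None) -> "VoxelTimeSeries":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        nuis = None
        if nuisance_path is not None:
            nuis = np.loadtxt(nuisance_path, delimiter="\t", ndmin=2)
        return cls(data=data, tr=tr, nuisance=nuis)

    def to_nifti(self, path) -> None:
        """Optional 4D NIfTI export (voxels laid out along one axis)."""
        import nibabel as nib

        img = nib.Nifti1Image(
            self.data[:, None, None, :].astype(np.float32), affine=np.eye(4)
        )
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr))
        nib.save(img, str(path))


def trial_amplitudes(events: pd.DataFrame, truth: SimulationTruth) -> np.ndarray:
    """Scalar ground-truth amplitude per trial.

    amplitude = category_amplitude(phase, condition) + item_amplitude
    - delta * [condition == suppress and phase == posttest]. Localizer
    blocks carry no item component.
    """
    amps = np.empty(len(events))
    for k, row in enumerate(events.itertuples(index=False)):
        a = truth.category_amplitude[(row.phase, row.condition)]
        if row.phase != "localizer":
            a += truth.item_amplitude
        if row.phase == "posttest" and row.condition == "suppress":
            a -= truth.subject_delta
        amps[k] = a
    return amps


def _n_scans_for(events: pd.DataFrame, tr: float, tail: float = 20.0) -> int:
    end = float((events["onset"] + events["duration"]).max()) + tail
    return int(np.ceil(end / tr))


def ar1_noise(
    shape: tuple[int, int], sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd`` and lag-1 autocorr ``phi``."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.normal(scale=sd * np.sqrt(1.0 - phi**2), size=shape)
    x0 = rng.normal(scale=sd, size=(shape[0], 1))
    zi = (phi * x0)[:, 0][:, None]
    out, _ = ssig.lfilter([1.0], [1.0, -phi], innov, axis=1, zi=zi)
    return out


def simulate_timeseries(
    events: pd.DataFrame,
    truth: SimulationTruth,
    config: ExperimentConfig,
    seed: int,
    n_scans: int | None = None,
) -> VoxelTimeSeries:
    """Forward-simulate one run of voxel data for the given events.

    data = sum over trials of amplitude-weighted, HRF-convolved boxcar
    responses of the trial's category and item templates, plus cosine
    drift, AR(1) Gaussian noise and nuisance-regressor leakage. Drift,
    noise and nuisance terms all scale with the truth's noise/drift
    parameters, so a zero-noise, zero-drift truth yields the exact
    noiseless forward model.
    """
    if truth.scene_template is None:
        raise ValueError("truth must carry templates (use default_truth)")
    tr = config.tr
    if n_scans is None:
        n_scans = _n_scans_for(events, tr)
    if float((events["onset"] + events["duration"]).max()) > n_scans * tr:
        raise ValueError("events extend beyond the requested series length")
    V = truth.scene_template.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
    hrf = canonical_hrf(HRF_DT)

    # template index: 0 scene, 1 morphed, then items
    item_ids = list(truth.item_templates)
    tpl_index = {"__scene__": 0, "__morphed__": 1}
    U_cols = [truth.scene_template, truth.morphed_template]
    for iid in item_ids:
        tpl_index[iid] = len(U_cols)
        U_cols.append(truth.item_templates[iid])
    U = np.column_stack(U_cols)  # voxels x templates
    W = np.zeros((U.shape[1], n_scans))  # template weights over scans

    amps = trial_amplitudes(events, truth)
    for k, row in enumerate(events.itertuples(index=False)):
        reg = sample_regressor(row.onset, row.duration, n_scans, tr, dt=HRF_DT, hrf=hrf)
        if row.phase == "localizer":
            cat_tpl = "__morphed__" if row.condition == "morphed" else "__scene__"
            W[tpl_index[cat_tpl]] += amps[k] * reg
        else:
            cat_amp = amps[k] - truth.item_amplitude
            W[0] += cat_amp * reg
            W[tpl_index[row.item_id]] += truth.item_amplitude * reg
    data = U @ W

    # low-frequency drift: first 3 cosines with random voxelwise loadings
    if truth.drift_amplitude > 0:
        t = np.arange(n_scans) / max(n_scans - 1, 1)
        basis = np.stack([np.cos(np.pi * k * t) for k in (1, 2, 3)])
        load = rng.normal(scale=truth.drift_amplitude / np.sqrt(3), size=(V, 3))
        data = data + load @ basis

    data = data + ar1_noise((V, n_scans), truth.noise_sd, truth.ar1_coef, rng)

    # nuisance stand-ins (slow random walks) leak into the data with small
    # voxelwise loadings tied to the noise scale
    k = config.n_nuisance
    nuis = np.cumsum(rng.normal(size=(n_scans, k)), axis=0)
    nuis = (nuis - nuis.mean(axis=0)) / np.maximum(nuis.std(axis=0), 1e-12)
    if truth.noise_sd > 0:
        load = rng.normal(scale=0.3 * truth.noise_sd, size=(V, k))
        data = data + load @ nuis.T

    return VoxelTimeSeries(data=data, tr=tr, run_boundaries=[n_scans], nuisance=nuis)


def simulate_vividness(
    truth: SimulationTruth, amplitudes: np.ndarray, seed: int
) -> np.ndarray:
    """Integer vividness ratings in 1..5 per test trial.

    rating = clip(round(a + b * amplitude + noise), 1, 5); a positive
    slope b yields a positive amplitude-rating association.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 59]))
    amplitudes = np.asarray(amplitudes, dtype=float)
    latent = (
        truth.vividness_intercept
        + truth.vividness_slope * amplitudes
        + rng.normal(scale=truth.vividness_noise_sd, size=amplitudes.shape)
        if truth.vividness_noise_sd > 0
        else truth.vividness_intercept + truth.vividness_slope * amplitudes
    )
    return np.clip(np.round(latent), 1, 5).astype(int)
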