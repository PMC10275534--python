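"""Synthetic multi-subject fMRI cohort with known intrinsic connectivity.

Each simulated subject has a subject-specific *intrinsic* correlation
structure (a 7-network block matrix perturbed by idiosyncratic jitter —
the ground-truth "connectivity fingerprint"), realized as an AR(1)
process with that cross-parcel covariance.  Task runs add a trial-locked
evoked response on task-responsive parcels, and every run is contaminated
by confound signals, white noise and occasional motion spikes.  The
design mirrors a slow event-related study: an 8-min rest run plus four
3.67-min passive-viewing runs, trials every 12 s (2 s stimulus + 10 s
fixation) after a 4-s initial fixation, 18 trials per run, TR 2 s.

The observed signal is the sum of intrinsic, evoked, confound and noise
components — the linear-superposition assumption that motivates removing
the evoked part to recover rest-like "background" connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (
    AtlasLabels,
    ConfoundSet,
    ParcelTimeSeries,
    SEVEN_NETWORKS,
    default_parcel_ids,
)

__all__ = [
    "GroundTruthSpec",
    "SimulatedRun",
    "SyntheticSubject",
    "nearest_psd_correlation",
    "make_intrinsic_covariance",
    "make_onsets",
    "simulate_subject",
    "simulate_cohort",
    "default_atlas",
]

#: Default 7-network split of 100 parcels (Visual, Somatomotor, DorsalAttention,
#: VentralAttention, Limbic, FrontoparietalControl, Default).
DEFAULT_NETWORK_SIZES = (17, 16, 13, 12, 10, 13, 19)

#: Networks that respond to the passive-viewing task by default.
DEFAULT_RESPONSIVE_NETWORKS = ("Visual", "DorsalAttention")

#: Per-TR evoked response template within the 12-s trial window
#: (discretized double-gamma-like shape, peak normalized to 1).
DEFAULT_EVOKED_SHAPE = (0.0, 0.6, 1.0, 0.7, 0.3, 0.1)


@dataclass
class GroundTruthSpec:
    """Generative parameters for one synthetic cohort.

    Defaults emulate the slow event-related study design: 56 subjects,
    one 480-s rest run and four task runs of 4 + 18*12 = 220 s each at
    TR 2 s.
    """

    n_subjects: int = 56
    n_parcels: int = 100
    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    network_names: tuple[str, ...] = SEVEN_NETWORKS
    r_within: float = 0.5
    r_between: float = 0.1
    subject_jitter_sd: float = 0.05
    ar_coefficient: float = 0.4
    tr_s: float = 2.0
    rest_duration_s: float = 480.0
    n_task_runs: int = 4
    initial_fixation_s: float = 4.0
    trial_spacing_s: float = 12.0
    n_trials_per_run: int = 18
    task_amplitude: np.ndarray | float | None = None
    evoked_shape: tuple[float, ...] = DEFAULT_EVOKED_SHAPE
    baseline: float = 1000.0
    confound_sd: float = 1.0
    confound_loading_sd: float = 0.15
    noise_sd: float = 0.5
    spike_prob: float = 0.02
    spike_magnitude_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.network_sizes = tuple(int(s) for s in self.network_sizes)
        if sum(self.network_sizes) != self.n_parcels:
            raise ValueError(
                f"network_sizes sum to {sum(self.network_sizes)}, "
                f"expected n_parcels={self.n_parcels}"
            )
        if len(self.network_names) != len(self.network_sizes):
            raise ValueError("network_names and network_sizes length mismatch")
        if not (0 <= self.r_within < 1):
            raise ValueError("r_within must be in [0, 1)")
        if not (-1 < self.r_between < 1):
            raise ValueError("r_between must be in (-1, 1)")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.trial_spacing_s <= 0 or self.initial_fixation_s < 0:
            raise ValueError("trial spacing must be positive, fixation non-negative")
        if self.n_trials_per_run < 1 or self.n_task_runs < 1:
            raise ValueError("need at least one trial and one task run")
        for name in ("rest_duration_s",):
            val = getattr(self, name)
            if abs(val / self.tr_s - round(val / self.tr_s)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of tr_s")
        needed = self.initial_fixation_s + self.n_trials_per_run * self.trial_spacing_s
        if needed > self.task_duration_s + 1e-9:
            raise ValueError("trials do not fit in the task run")
        if self.task_amplitude is None:
            self.task_amplitude = self._default_amplitude()
        else:
            amp = np.asarray(self.task_amplitude, dtype=float)
            if amp.ndim == 0:
                amp = np.full(self.n_parcels, float(amp))
            if amp.shape != (self.n_parcels,):
                raise ValueError("task_amplitude must be scalar or length n_parcels")
            self.task_amplitude = amp
        self.evoked_shape = tuple(float(v) for v in self.evoked_shape)

    def _default_amplitude(self) -> np.ndarray:
        amp = np.zeros(self.n_parcels)
        start = 0
        for name, size in zip(self.network_names, self.network_sizes):
            if name in DEFAULT_RESPONSIVE_NETWORKS:
                amp[start : start + size] = 1.5
            start += size
        return amp

    # -- derived design quantities -------------------------------------
    @property
    def task_duration_s(self) -> float:
        """Task run length: fixation plus the full trial train (220 s at
        defaults, i.e. 3.67 min)."""
        return self.initial_fixation_s + self.n_trials_per_run * self.trial_spacing_s

    @property
    def n_rest_volumes(self) -> int:
        return int(round(self.rest_duration_s / self.tr_s))

    @property
    def n_task_volumes(self) -> int:
        return int(round(self.task_duration_s / self.tr_s))

    @property
    def parcel_ids(self) -> tuple[str, ...]:
        return default_parcel_ids(self.n_parcels)

    def network_vector(self) -> np.ndarray:
        return np.repeat(list(self.network_names), list(self.network_sizes))

    def subject_seed(self, subject_index: int) -> int:
        # one master seed; per-subject streams derived by offset
        return int(self.seed) + int(subject_index)


@dataclass
class SimulatedRun:
    """One simulated run: signal block, confounds, and ground-truth audit
    fields (trial onsets for task runs, indices of injected motion spikes)."""

    ts: ParcelTimeSeries
    confounds: ConfoundSet
    onsets_s: tuple[float, ...] | None
    spike_volumes: tuple[int, ...]


@dataclass
class SyntheticSubject:
    subject_id: str
    true_covariance: np.ndarray  # unit-diagonal intrinsic correlation matrix
    rest_run: SimulatedRun
    task_runs: list[SimulatedRun]

    def __post_init__(self) -> None:
        c = np.asarray(self.true_covariance, dtype=float)
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("true_covariance must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("true_covariance must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("true_covariance must be positive semidefinite")


def default_atlas(spec: GroundTruthSpec | None = None) -> AtlasLabels:
    """Parcel -> network lookup matching the generator's block layout."""
    spec = spec or GroundTruthSpec()
    return AtlasLabels.from_sequences(spec.parcel_ids, spec.network_vector())


def nearest_psd_correlation(mat: np.ndarray, min_eig: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue
    clipping) and rescale to unit diagonal.

    Raises ``ValueError`` when the clipped matrix has a (numerically) zero
    diagonal entry, i.e. a parcel's variance is entirely carried by negative
    eigenvalues and no unit-diagonal rescaling exists.
    """
    mat = np.asarray(mat, dtype=float)
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    clipped = np.clip(vals, min_eig, None)
    repaired = (vecs * clipped) @ vecs.T
    d = np.diag(repaired).copy()
    if np.any(d <= 1e-12):
        raise ValueError(
            "matrix is not repairable to a correlation matrix: "
            "zero diagonal after PSD projection"
        )
    scale = 1.0 / np.sqrt(d)
    out = repaired * np.outer(scale, scale)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def make_intrinsic_covariance(
    spec: GroundTruthSpec, subject_index: int
) -> np.ndarray:
    """Subject-specific intrinsic correlation matrix.

    A block matrix (``r_within`` inside network blocks, ``r_between``
    elsewhere) is perturbed symmetrically off-diagonal with Gaussian noise
    of sd ``subject_jitter_sd`` — the subject's idiosyncratic fingerprint —
    then projected to the nearest PSD correlation matrix.  Deterministic
    given ``(spec.seed, subject_index)``.
    """
    p = spec.n_parcels
    block = np.full((p, p), spec.r_between)
    start = 0
    for size in spec.network_sizes:
        block[start : start + size, start : start + size] = spec.r_within
        start += size
    np.fill_diagonal(block, 1.0)

    if spec.subject_jitter_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.subject_seed(subject_index), 11])
        )
        noise = rng.normal(0.0, spec.subject_jitter_sd, size=(p, p))
        noise = np.triu(noise, k=1)
        block = block + noise + noise.T

    return nearest_psd_correlation(block)


def make_onsets(spec: GroundTruthSpec) -> list[float]:
    """Trial onsets (seconds): ``initial_fixation_s + k * trial_spacing_s``."""
    onsets = [
        spec.initial_fixation_s + k * spec.trial_spacing_s
        for k in range(spec.n_trials_per_run)
    ]
    if onsets and onsets[-1] >= spec.task_duration_s:
        raise ValueError("last onset falls beyond the end of the run")
    return onsets


def _ar1_series(
    rng: np.random.Generator, n: int, phi: float, sd: float, ncols: int = 1
) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sd``; columns independent."""
    innov_sd = sd * np.sqrt(1.0 - phi**2) if phi > 0 else sd
    e = rng.normal(0.0, 1.0, size=(n, ncols))
    x = np.empty((n, ncols))
    x[0] = sd * e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov_sd * e[t]
    return x


def _intrinsic_signal(
    rng: np.random.Generator, n_volumes: int, root: np.ndarray, phi: float
) -> np.ndarray:
    """AR(1) process whose stationary cross-parcel covariance is root@root.T."""
    p = root.shape[0]
    e = rng.normal(0.0, 1.0, size=(n_volumes, p))
    corr_e = e @ root.T
    x = np.empty_like(corr_e)
    x[0] = corr_e[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n_volumes):
        x[t] = phi * x[t - 1] + scale * corr_e[t]
    return x


def _covariance_root(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _evoked_timecourse(
    n_volumes: int, onsets_s: Sequence[float], tr_s: float, shape: Sequence[float]
) -> np.ndarray:
    """Per-volume evoked template: ``shape`` placed at each onset (unit peak)."""
    tc = np.zeros(n_volumes)
    for onset in onsets_s:
        v0 = int(round(onset / tr_s))
        for k, val in enumerate(shape):
            if v0 + k < n_volumes:
                tc[v0 + k] += val
    return tc


def _simulate_confounds(
    rng: np.random.Generator,
    n_volumes: int,
    spec: GroundTruthSpec,
    spike_volumes: Sequence[int],
) -> ConfoundSet:
    # drifting motion: translations in mm, rotations in radians
    trans = _ar1_series(rng, n_volumes, 0.95, 0.05, 3)
    rot = _ar1_series(rng, n_volumes, 0.95, 0.0005, 3)
    motion = np.column_stack([trans, rot])
    # a spike is a sustained step in the translations so that framewise
    # displacement exceeds threshold only at the spike volume itself
    for v in spike_volumes:
        motion[v:, :3] += spec.spike_magnitude_mm / 3.0
    physio = _ar1_series(rng, n_volumes, 0.5, spec.confound_sd, 3)
    return ConfoundSet(
        motion=motion,
        csf=physio[:, 0],
        white_matter=physio[:, 1],
        global_signal=physio[:, 2],
    )


def _simulate_run(
    spec: GroundTruthSpec,
    root: np.ndarray,
    loadings: np.ndarray,
    rng: np.random.Generator,
    *,
    task: bool,
    run_id: str,
) -> SimulatedRun:
    n_volumes = spec.n_task_volumes if task else spec.n_rest_volumes
    p = spec.n_parcels

    spike_volumes: tuple[int, ...] = ()
    if spec.spike_prob > 0:
        hits = rng.random(n_volumes) < spec.spike_prob
        hits[0] = False
        spike_volumes = tuple(int(i) for i in np.flatnonzero(hits))

    confounds = _simulate_confounds(rng, n_volumes, spec, spike_volumes)

    signal = _intrinsic_signal(rng, n_volumes, root, spec.ar_coefficient)

    onsets: tuple[float, ...] | None = None
    if task:
        onset_list = make_onsets(spec)
        onsets = tuple(onset_list)
        tc = _evoked_timecourse(n_volumes, onset_list, spec.tr_s, spec.evoked_shape)
        signal = signal + np.outer(tc, spec.task_amplitude)

    signal = signal + confounds.signals() @ loadings
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=(n_volumes, p))
    # transient per-parcel corruption of the spiked volume only; the volume
    # is censored by scrubbing, so the artifact does not leak into
    # connectivity of the retained series
    for v in spike_volumes:
        signal[v] += rng.normal(0.0, 3.0 * spec.spike_magnitude_mm, size=p)
    signal = signal + spec.baseline

    ts = ParcelTimeSeries(
        data=signal,
        tr_s=spec.tr_s,
        parcel_ids=spec.parcel_ids,
        run_id=run_id,
        task="task" if task else "rest",
    )
    return SimulatedRun(
        ts=ts, confounds=confounds, onsets_s=onsets, spike_volumes=spike_volumes
    )


def simulate_subject(spec: GroundTruthSpec, subject_index: int) -> SyntheticSubject:
    """Simulate one subject: a rest run plus ``n_task_runs`` task runs.

    Each run's signal is intrinsic AR(1) activity with the subject's true
    cross-parcel covariance, plus (task runs only) the evoked response at
    each trial onset, plus confound contamination, white noise and a
    constant baseline.  Fully reproducible from ``(spec.seed, subject_index)``.
    """
    cov = make_intrinsic_covariance(spec, subject_index)
    root = _covariance_root(cov)
    sseed = spec.subject_seed(subject_index)

    load_rng = np.random.default_rng(np.random.SeedSequence([sseed, 21]))
    loadings = (
        load_rng.normal(0.0, spec.confound_loading_sd, size=(9, spec.n_parcels))
        if spec.confound_loading_sd > 0
        else np.zeros((9, spec.n_parcels))
    )

    rest_rng = np.random.default_rng(np.random.SeedSequence([sseed, 31]))
    rest = _simulate_run(
        spec, root, loadings, rest_rng, task=False, run_id="rest_run-1"
    )
    task_runs = []
    for r in range(spec.n_task_runs):
        rng = np.random.default_rng(np.random.SeedSequence([sseed, 41 + r]))
        task_runs.append(
            _simulate_run(
                spec, root, loadings, rng, task=True, run_id=f"task_run-{r + 1}"
            )
        )
    return SyntheticSubject(
        subject_id=f"sub-{subject_index + 1:02d}",
        true_covariance=cov,
        rest_run=rest,
        task_runs=task_runs,
    )


def simulate_cohort(spec: GroundTruthSpec) -> list[SyntheticSubject]:
    """All ``spec.n_subjects`` subjects, in index order."""
    return [simulate_subject(spec, i) for i in range(spec.n_subjects)]
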