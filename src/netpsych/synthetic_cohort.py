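"""Synthetic two-group task-fMRI cohort generator.

Emulates a cohort in which task-evoked activation statistics are identical
across groups while inter-voxel coupling — especially long-range,
inter-hemispheric coupling — differs.  Each voxel's signal is

    y_v(t) = baseline + a_v * (s ⊛ h)(t) + Σ_f L_{v,f}(group) * z_f(t) + ε_v(t)

where ``s`` are condition indicator trains convolved with the canonical
hemodynamic response ``h``, ``z_f`` are AR(1) latent series shared by all
voxels in factor f's spatial support (the "hidden brain process" that couples
voxels beyond the task), and ε is white Gaussian noise.  The activation
amplitude a_v is drawn from the same distribution for both groups; only the
factor loadings L differ, so any group difference lives purely in the
covariance structure, never in the univariate task response.

The default configuration is *variance matched*: the coupling power patients
lose in the bilateral factor is returned to them through within-hemisphere
factors of equal total power, so per-voxel signal variances (and hence GLM
residual variances and activation t-statistics) are group-identical in
expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "Paradigm",
    "BoldRun",
    "SubjectRecord",
    "LatentFactor",
    "CohortConfig",
    "default_config",
    "acquisition_scale_config",
    "generate_paradigm",
    "generate_motion",
    "generate_cohort",
    "write_cohort",
]

CONDITIONS = ("FrenchNative", "Foreign", "Silence")

# Trial envelope (seconds): attention tone, mean sentence length, pause before
# the two-syllable probe, probe itself; inter-trial jitter is drawn uniformly.
TONE_S = 0.2
SENTENCE_S = 3.5
PAUSE_S = 0.75
PROBE_S = 0.5
JITTER_MIN_S = 0.5
JITTER_MAX_S = 3.5
TRIAL_FIXED_S = TONE_S + SENTENCE_S + PAUSE_S + PROBE_S

# Stream codes for per-(subject, run, component) child seeds.  Seeds are
# derived from the master seed with numpy SeedSequence spawn keys, so adding
# subjects or runs never perturbs existing streams.
_STREAM_AMPLITUDE = 0
_STREAM_PARADIGM = 1
_STREAM_LATENT = 2
_STREAM_NOISE = 3
_STREAM_MOTION = 4


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass(frozen=True)
class Paradigm:
    """Event list for one run: (onset s, duration s, condition) triples."""

    events: tuple[tuple[float, float, str], ...]
    tr: float
    n_volumes: int

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        total = self.tr * self.n_volumes
        for onset, duration, condition in self.events:
            if condition not in CONDITIONS:
                raise ValueError(f"unknown condition {condition!r}")
            if onset + duration > total:
                raise ValueError("event extends beyond the run")
        counts = self.condition_counts()
        if len(set(counts.values())) > 1:
            raise ValueError(f"unbalanced condition counts: {counts}")

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for _, _, condition in self.events:
            counts[condition] += 1
        return counts

    def onsets(self, condition: str) -> np.ndarray:
        return np.array([e[0] for e in self.events if e[2] == condition])

    def durations(self, condition: str) -> np.ndarray:
        return np.array([e[1] for e in self.events if e[2] == condition])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"onset": o, "duration": d, "trial_type": c} for o, d, c in self.events]
        )


@dataclass
class BoldRun:
    """A single 4D acquisition with its mask and voxel→mm affine."""

    data: np.ndarray  # X x Y x Z x T
    mask: np.ndarray  # X x Y x Z bool
    affine: np.ndarray  # 4 x 4
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("data must be 4D with T >= 2")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if int(self.mask.sum()) < 2:
            raise ValueError("mask must contain at least 2 voxels")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("masked values must be finite")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def masked_series(self) -> np.ndarray:
        """V x T array of masked voxel time series (C-order voxel indexing)."""
        return self.data[self.mask]

    def voxel_coords_mm(self) -> np.ndarray:
        """V x 3 mm coordinates of masked voxel centers."""
        idx = np.argwhere(self.mask)
        homog = np.c_[idx, np.ones(len(idx))]
        return (homog @ self.affine.T)[:, :3]

    def voxel_coords_vox(self) -> np.ndarray:
        return np.argwhere(self.mask).astype(float)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    runs: tuple[BoldRun, BoldRun]
    motion: tuple[np.ndarray, np.ndarray]
    paradigms: tuple[Paradigm, Paradigm]

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if len(self.runs) != 2:
            raise ValueError("exactly two runs per subject")
        r0, r1 = self.runs
        if not np.array_equal(r0.mask, r1.mask) or not np.allclose(r0.affine, r1.affine):
            raise ValueError("both runs must share mask and affine")
        for run, mot in zip(self.runs, self.motion):
            if mot.shape != (run.n_volumes, 6):
                raise ValueError("motion rows must match run length")


@dataclass(frozen=True)
class LatentFactor:
    """A hidden process loading onto a spatial support.

    ``loading_control``/``loading_patient`` scale the shared AR(1) series for
    the respective group; a support spanning both hemispheres with unequal
    loadings is what injects a pure-connectivity group difference.
    """

    name: str
    support: np.ndarray  # 3D bool
    loading_control: float
    loading_patient: float
    ar_coef: float = 0.3

    def __post_init__(self) -> None:
        if not self.support.any():
            raise ValueError(f"factor {self.name!r} has empty support")
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValueError("AR coefficient must lie in [0, 1)")


@dataclass
class CohortConfig:
    n_per_group: int
    grid: tuple[int, int, int]
    mask: np.ndarray
    affine: np.ndarray
    n_volumes: int
    tr: float
    n_per_condition: int
    activation_region: np.ndarray  # 3D bool
    activation_amplitude: float  # mean of a_v, same for both groups
    factors: tuple[LatentFactor, ...]
    noise_sd: float
    seed: int
    baseline: float = 100.0
    motion_artifact_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for f in self.factors:
            if f.support.shape != self.grid:
                raise ValueError(f"factor {f.name!r} support off-grid")


def _ellipsoid(grid, center_vox, semi_axes_vox) -> np.ndarray:
    idx = np.indices(grid).astype(float)
    d2 = sum(
        ((idx[a] - center_vox[a]) / semi_axes_vox[a]) ** 2 for a in range(3)
    )
    return d2 <= 1.0


def _sphere_mm(grid, affine, center_mm, radius_mm) -> np.ndarray:
    idx = np.indices(grid).reshape(3, -1).T.astype(float)
    homog = np.c_[idx, np.ones(len(idx))]
    mm = (homog @ affine.T)[:, :3]
    d = np.linalg.norm(mm - np.asarray(center_mm), axis=1)
    return (d <= radius_mm).reshape(grid)


def two_lobe_geometry(grid=(16, 16, 12), voxel_mm=10.0):
    """Two ellipsoidal 'hemisphere' lobes separated at x = 0 mm.

    The affine centers the grid so no voxel center sits exactly on x = 0;
    voxels at negative mm x belong to the left lobe.
    """
    nx, ny, nz = grid
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(grid) - 1) / 2.0
    left = _ellipsoid(grid, ((nx - 1) / 2.0 - 3.8, (ny - 1) / 2.0, (nz - 1) / 2.0),
                      (3.6, 6.5, 4.8))
    right = _ellipsoid(grid, ((nx - 1) / 2.0 + 3.8, (ny - 1) / 2.0, (nz - 1) / 2.0),
                       (3.6, 6.5, 4.8))
    # keep the lobes strictly on their side of x = 0 mm
    idx = np.indices(grid).astype(float)
    xs_mm = idx[0] * voxel_mm + affine[0, 3]
    left &= xs_mm < 0
    right &= xs_mm > 0
    return (left | right), affine


def default_config(
    seed: int,
    n_per_group: int = 11,
    n_volumes: int = 200,
    tr: float = 2.0,
    n_per_condition: int | None = None,
    loading_control: float = 1.6,
    loading_patient: float = 0.4,
    local_loading: float = 1.6,
    noise_sd: float = 1.0,
    activation_amplitude: float = 1.0,
    variance_matched: bool = True,
) -> CohortConfig:
    """Default study conditions.

    A bilateral "auditory" factor couples homologous temporal blobs in both
    hemispheres strongly in controls and weakly in patients; two
    group-identical within-hemisphere factors give both groups comparable
    local network structure (and anchor the map-normalization maximum so that
    spatial normalization does not create spurious group differences).  With
    ``variance_matched`` (the default) the patients' lost bilateral power is
    restored by per-hemisphere factors on the same supports, equalizing
    per-voxel marginal variances across groups.
    """
    grid = (16, 16, 12)
    mask, affine = two_lobe_geometry(grid)

    left_audio = _sphere_mm(grid, affine, (-40, 25, 5), 20.0) & mask
    right_audio = _sphere_mm(grid, affine, (40, 25, 5), 20.0) & mask
    bilateral = left_audio | right_audio
    # the left local blob is deliberately the largest coupled set: it anchors
    # the maximum degree (hence the normalization denominator) identically in
    # both groups, so spatial normalization cannot manufacture group
    # differences at group-identical factors
    left_local = _sphere_mm(grid, affine, (-38, -30, 0), 29.0) & mask
    right_local = _sphere_mm(grid, affine, (38, -30, 0), 20.0) & mask
    left_local &= ~bilateral
    right_local &= ~bilateral

    factors = [
        LatentFactor("bilateral_auditory", bilateral, loading_control, loading_patient),
        LatentFactor("left_local", left_local, local_loading, local_loading),
        LatentFactor("right_local", right_local, local_loading, local_loading),
    ]
    if variance_matched:
        # restore Σ_f L² for patients within each hemisphere half
        comp = float(np.sqrt(loading_control**2 - loading_patient**2))
        factors.append(LatentFactor("left_auditory_patient", left_audio, 0.0, comp))
        factors.append(LatentFactor("right_auditory_patient", right_audio, 0.0, comp))

    if n_per_condition is None:
        n_per_condition = _max_trials_per_condition(tr, n_volumes)

    return CohortConfig(
        n_per_group=n_per_group,
        grid=grid,
        mask=mask,
        affine=affine,
        n_volumes=n_volumes,
        tr=tr,
        n_per_condition=n_per_condition,
        activation_region=bilateral,
        activation_amplitude=activation_amplitude,
        factors=tuple(factors),
        noise_sd=noise_sd,
        seed=seed,
    )


def acquisition_scale_config(seed: int, **kwargs) -> CohortConfig:
    """Preset at the emulated acquisition's native scale: 416 retained
    volumes at TR 2.0 s and 32 trials per condition."""
    kwargs.setdefault("n_volumes", 416)
    kwargs.setdefault("n_per_condition", 32)
    return default_config(seed, **kwargs)


# mean trial-to-trial spacing of the emulated acquisition (two 14-minute runs
# of 96 trials give ~8.7 s per trial)
TRIAL_TARGET_SPACING_S = 8.7


def _max_trials_per_condition(tr: float, n_volumes: int) -> int:
    total = tr * n_volumes
    return max(1, int(total // TRIAL_TARGET_SPACING_S) // 3)


def generate_paradigm(
    seed: int, n_per_condition: int, tr: float, n_volumes: int
) -> Paradigm:
    """Seeded, balanced three-condition event sequence.

    Each trial occupies tone + sentence + pause + probe plus a uniform
    inter-trial jitter; the per-trial condition order is a seeded permutation.
    The recorded event onset is the sentence onset (after the attention tone)
    and its duration the sentence length; for Silence trials the "sentence"
    slot is an equally long silent interval.
    """
    n_trials = 3 * n_per_condition
    total = tr * n_volumes
    min_required = n_trials * (TRIAL_FIXED_S + JITTER_MIN_S)
    if min_required > total:
        raise ValueError(
            f"run too short for {n_trials} trials: needs at least "
            f"{min_required:.1f} s, run is {total:.1f} s"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(3), n_per_condition))
    # scale the jitter budget so trials spread over the whole run
    slack = total - n_trials * TRIAL_FIXED_S
    jitter_hi = min(JITTER_MAX_S, max(JITTER_MIN_S, slack / n_trials))
    jitters = rng.uniform(JITTER_MIN_S, jitter_hi, size=n_trials)

    events = []
    t = 0.0
    for k, cond_idx in enumerate(order):
        onset = t + TONE_S
        events.append((round(onset, 3), SENTENCE_S, CONDITIONS[cond_idx]))
        t += TRIAL_FIXED_S + jitters[k]
    return Paradigm(events=tuple(events), tr=tr, n_volumes=n_volumes)


def generate_motion(seed: int, n_volumes: int) -> np.ndarray:
    """Six seeded AR(1) head-motion traces (3 translations mm, 3 rotations rad).

    Drawn from a stream independent of every BOLD component.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(seed)
    scales = np.array([0.05, 0.05, 0.05, 0.001, 0.001, 0.001])
    return _ar1(rng, 0.8, (n_volumes, 6)) * scales


def _ar1(rng: np.random.Generator, coef: float, shape) -> np.ndarray:
    """Stationary AR(1) innovations-variance-1 series along axis 0."""
    t = shape[0]
    out = np.empty(shape)
    out[0] = rng.standard_normal(shape[1:]) / np.sqrt(1.0 - coef**2)
    for i in range(1, t):
        out[i] = coef * out[i - 1] + rng.standard_normal(shape[1:])
    return out


def _condition_regressors(paradigm: Paradigm, tr: float, n_volumes: int) -> np.ndarray:
    # local import: glm_activation owns the HRF; cohort generation reuses it so
    # the simulated response matches the analysis model
    from .glm_activation import hrf_convolved_regressor

    return np.column_stack(
        [hrf_convolved_regressor(paradigm, c, tr, n_volumes) for c in CONDITIONS]
    )


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate ``2 * n_per_group`` subjects (patients first), two runs each.

    Deterministic given ``config.seed``; every random component draws from its
    own child stream keyed by (subject index, run index, component code).
    """
    mask = config.mask
    v_support = {f.name: f.support[mask] for f in config.factors}
    act_v = config.activation_region[mask]
    n_vox = int(mask.sum())
    records: list[SubjectRecord] = []

    # condition amplitudes relative to a_v: both auditory conditions activate,
    # silence does not; identical for both groups by construction
    cond_gain = np.array([1.0, 0.8, 0.0])

    for s_idx in range(2 * config.n_per_group):
        group = "patient" if s_idx < config.n_per_group else "control"
        amp_rng = _rng(config.seed, s_idx, 0, _STREAM_AMPLITUDE)
        a_v = np.zeros(n_vox)
        a_v[act_v] = amp_rng.normal(
            config.activation_amplitude, 0.1 * config.activation_amplitude,
            size=int(act_v.sum()),
        )

        runs, motions, paradigms = [], [], []
        for r_idx in range(2):
            par_seed = int(
                _rng(config.seed, s_idx, r_idx, _STREAM_PARADIGM).integers(2**31)
            )
            paradigm = generate_paradigm(
                par_seed, config.n_per_condition, config.tr, config.n_volumes
            )
            regressors = _condition_regressors(paradigm, config.tr, config.n_volumes)
            task = regressors @ cond_gain  # T

            signal = np.full((n_vox, config.n_volumes), config.baseline)
            signal += a_v[:, None] * task[None, :]

            latent_rng = _rng(config.seed, s_idx, r_idx, _STREAM_LATENT)
            for f in config.factors:
                z = _ar1(latent_rng, f.ar_coef, (config.n_volumes,))
                loading = (
                    f.loading_patient if group == "patient" else f.loading_control
                )
                if loading != 0.0:
                    signal[v_support[f.name]] += loading * z[None, :]

            noise_rng = _rng(config.seed, s_idx, r_idx, _STREAM_NOISE)
            signal += config.noise_sd * noise_rng.standard_normal(
                (n_vox, config.n_volumes)
            )

            motion_seed = int(
                _rng(config.seed, s_idx, r_idx, _STREAM_MOTION).integers(2**31)
            )
            motion = generate_motion(motion_seed, config.n_volumes)
            if config.motion_artifact_gain > 0.0:
                signal += config.motion_artifact_gain * motion[:, 0][None, :]

            data = np.zeros(config.grid + (config.n_volumes,))
            data[mask] = signal
            runs.append(BoldRun(data=data, mask=mask.copy(),
                                affine=config.affine.copy(), tr=config.tr))
            motions.append(motion)
            paradigms.append(paradigm)

        records.append(
            SubjectRecord(
                subject_id=f"sub-{s_idx + 1:02d}",
                group=group,
                runs=(runs[0], runs[1]),
                motion=(motions[0], motions[1]),
                paradigms=(paradigms[0], paradigms[1]),
            )
        )
    return records


def write_cohort(records: list[SubjectRecord], outdir: str | Path, seed: int | None = None) -> Path:
    """Write runs as 4D NIfTI-1, mask as uint8 NIfTI-1, paradigms as BIDS-style
    events TSV, motion as 6-column text, plus a JSON manifest."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "subjects": []}
    mask_img = nib.Nifti1Image(
        records[0].runs[0].mask.astype(np.uint8), records[0].runs[0].affine
    )
    mask_path = outdir / "mask.nii.gz"
    nib.save(mask_img, mask_path)
    for rec in records:
        entry = {"subject_id": rec.subject_id, "group": rec.group, "runs": []}
        for r_idx, (run, motion, paradigm) in enumerate(
            zip(rec.runs, rec.motion, rec.paradigms), start=1
        ):
            stem = f"{rec.subject_id}_run-{r_idx}"
            bold_path = outdir / f"{stem}_bold.nii.gz"
            nib.save(nib.Nifti1Image(run.data, run.affine), bold_path)
            events_path = outdir / f"{stem}_events.tsv"
            paradigm.to_frame().to_csv(events_path, sep="\t", index=False)
            motion_path = outdir / f"{stem}_motion.txt"
            np.savetxt(motion_path, motion, fmt="%.6f")
            entry["runs"].append(
                {
                    "bold": bold_path.name,
                    "events": events_path.name,
                    "motion": motion_path.name,
                    "mask": mask_path.name,
                    "tr": run.tr,
                }
            )
        manifest["subjects"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"
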