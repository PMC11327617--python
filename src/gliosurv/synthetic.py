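"""Synthetic multimodal glioblastoma cohorts with known ground truth.

Generates the three ingredients the survival model consumes — a clinical /
molecular covariate table, small 4-channel MR-like volumes whose lesion
geometry carries survival signal, and discrete-time survival outcomes with
independent right censoring — together with the true per-subject hazards, so
that oracle quantities (e.g. the Bayes-optimal time-dependent concordance)
can be computed exactly.

The clinical marginals emulate a typical multicenter glioblastoma cohort:
age ~ N(63, 12) truncated to 18–90, ~60% male, ~57% gross total resection,
MGMT methylation ~50% with a substantial missing fraction, ~90% IDH
wild-type, KPS >= 80 in ~60% with missingness.  Missing categorical values
are generated missing-completely-at-random.

The data-generating hazard model is exactly the model class of the survival
head: per-bin hazard h_m = logistic(b_m + lp) with linear predictor
lp = β_clin · x + β_img · (lesion volume fraction), continuous event times
uniform within the sampled bin, and censoring uniform on [0, horizon] with
the horizon tuned by bisection to the target censored fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discrete_survival import TimeGrid
from .metrics import ctd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "CLINICAL_COLUMNS",
    "generate_clinical",
    "generate_tabular",
    "generate_volume",
    "sample_survival",
    "true_cif",
    "bayes_optimal_ctd",
    "make_cohort",
    "write_cohort",
    "DEFAULT_CUT_POINTS",
    "DEFAULT_BASELINE_LOGITS",
]

# encoded covariate order produced by generate_clinical
CLINICAL_COLUMNS = ("age_z", "sex_male", "gtr", "mgmt_methylated", "idh_wildtype", "kps_ge80")

# default grid: bins ending at ~4, 8, 12, 18, 24 months (days); baseline
# logit-hazards chosen so the median survival sits near 12 months, matching
# a typical glioblastoma cohort
DEFAULT_CUT_POINTS = (120.0, 240.0, 365.0, 540.0, 730.0)
DEFAULT_BASELINE_LOGITS = (-2.0, -1.4, -1.0, -0.8, -0.6)


@dataclass
class SyntheticConfig:
    n_subjects: int = 200
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_channels: int = 4
    beta_clinical: tuple[float, ...] = (0.4, 0.1, -0.5, -0.5, 0.5, -0.3)
    beta_imaging: float = 0.0
    baseline_logit_hazard: tuple[float, ...] = DEFAULT_BASELINE_LOGITS
    cut_points: tuple[float, ...] = DEFAULT_CUT_POINTS
    censoring_rate: float = 0.3
    imaging_feature_range: tuple[float, float] = (0.01, 0.15)
    channel_contrasts: tuple[float, ...] = (0.5, 1.5, 1.0, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if len(self.baseline_logit_hazard) != len(self.cut_points):
            raise ValueError("need one baseline logit per time bin")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.cut_points)


@dataclass
class GroundTruth:
    true_risk: np.ndarray  # linear predictor per subject
    true_hazard: np.ndarray  # (n, n_bins), entries in (0, 1)
    imaging_feature: np.ndarray  # lesion volume fraction per subject
    censoring_time: np.ndarray | None = None  # latent, for independence checks

    def __post_init__(self):
        if np.any((self.true_hazard <= 0) | (self.true_hazard >= 1)):
            raise ValueError("true hazards must lie in (0, 1)")
        if np.any(self.imaging_feature < 0):
            raise ValueError("imaging feature must be nonnegative")


@dataclass
class Cohort:
    clinical: pd.DataFrame  # id, raw covariates, time_days, event
    covariates: np.ndarray  # encoded covariate matrix used in the hazard
    volumes: dict[str, np.ndarray] | None  # id -> (C, X, Y, Z) array
    ground_truth: GroundTruth
    grid: TimeGrid
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def times(self) -> np.ndarray:
        return self.clinical["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)


# ----------------------------------------------------------------- clinical


def generate_clinical(n: int, effects, seed) -> tuple[pd.DataFrame, np.ndarray]:
    """Clinical/molecular covariate table plus the resulting linear predictor.

    ``effects`` is the log-hazard-ratio per encoded covariate in the order
    of :data:`CLINICAL_COLUMNS`; missing values contribute 0 to the linear
    predictor.  Returns (table, linear_predictor).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (len(CLINICAL_COLUMNS),):
        raise ValueError(
            f"effects must have length {len(CLINICAL_COLUMNS)} "
            f"(one per encoded covariate {CLINICAL_COLUMNS})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    age = np.clip(rng.normal(63.0, 12.0, size=n), 18.0, 90.0)
    sex_male = rng.binomial(1, 0.6, size=n).astype(float)
    gtr = rng.binomial(1, 0.57, size=n).astype(float)
    mgmt = rng.binomial(1, 0.5, size=n).astype(float)
    mgmt[rng.random(n) < 0.2] = np.nan
    idh_wt = rng.binomial(1, 0.9, size=n).astype(float)
    kps = rng.binomial(1, 0.6, size=n).astype(float)
    kps[rng.random(n) < 0.3] = np.nan

    df = pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(sex_male == 1, "M", "F"),
            "gtr": gtr,
            "mgmt": mgmt,
            "idh": np.where(idh_wt == 1, "wildtype", "mutant"),
            "kps": kps,
        }
    )
    encoded = np.column_stack(
        [(age - 63.0) / 12.0, sex_male, gtr, mgmt, idh_wt, kps]
    )
    lp = np.nansum(encoded * effects[None, :], axis=1)
    return df, lp


def generate_tabular(n: int, effects, seed) -> tuple[np.ndarray, np.ndarray]:
    """Generic tabular cohort: independent standard-normal covariates with
    the given log-hazard-ratio effects.  Returns (X, linear_predictor)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    effects = np.asarray(effects, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.normal(size=(n, effects.size))
    return X, X @ effects


# ------------------------------------------------------------------ imaging


def _brain_mask(shape) -> np.ndarray:
    """Ellipsoidal brain with semi-axes at 45% of each dimension."""
    grids = np.indices(shape).astype(float)
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    return r2 <= 1.0


def generate_volume(
    imaging_feature_target: float,
    shape=(32, 32, 32),
    channel_contrasts=(0.5, 1.5, 1.0, 1.2),
    seed=0,
    noise_sd: float = 0.1,
) -> tuple[np.ndarray, float]:
    """A 4-channel volume: noisy ellipsoidal "brain" on a zero exterior, with
    a spherical lesion whose volume fraction (lesion voxels / brain voxels)
    approximates ``imaging_feature_target``.

    The lesion raises intensity by ``channel_contrasts[c]`` per channel — the
    same geometry, different conspicuity per MR contrast.  Returns
    (volume (C, X, Y, Z), achieved_fraction).
    """
    if not (0.0 <= imaging_feature_target <= 0.2):
        raise ValueError("imaging_feature_target must be in [0, 0.2]")
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError("each axis must be >= 16 voxels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _brain_mask(shape)
    n_brain = int(mask.sum())
    C = len(channel_contrasts)
    vol = np.zeros((C,) + shape, dtype=np.float32)
    base = rng.normal(1.0, noise_sd, size=shape).astype(np.float32)
    for c in range(C):
        vol[c][mask] = base[mask] * (1.0 + 0.1 * c)

    achieved = 0.0
    if imaging_feature_target > 0:
        target_vox = imaging_feature_target * n_brain
        # radius from the continuous-sphere volume, then refined over a
        # small neighbourhood to the closest achievable voxel count
        r0 = (3.0 * target_vox / (4.0 * np.pi)) ** (1.0 / 3.0)
        max_r = 0.45 * min(shape) * 0.8
        if r0 > max_r:
            raise ValueError("lesion radius exceeds the brain ellipsoid")
        # center placed randomly but far enough from the ellipsoid border
        centers = np.array([(s - 1) / 2.0 for s in shape])
        offset = rng.uniform(-0.15, 0.15, size=3) * np.array(shape)
        center = centers + offset
        grids = np.indices(shape).astype(float)
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        best_r, best_err = r0, np.inf
        for r in np.linspace(max(r0 - 2, 0.5), r0 + 2, 41):
            cnt = int(((dist2 <= r * r) & mask).sum())
            err = abs(cnt - target_vox)
            if err < best_err:
                best_err, best_r = err, r
        lesion = (dist2 <= best_r * best_r) & mask
        achieved = float(lesion.sum()) / n_brain
        for c in range(C):
            vol[c][lesion] += channel_contrasts[c]
    return vol, achieved


# ----------------------------------------------------------------- survival


def _hazards(linear_predictor, baseline_logits) -> np.ndarray:
    lp = np.asarray(linear_predictor, dtype=float)[:, None]
    b = np.asarray(baseline_logits, dtype=float)[None, :]
    return 1.0 / (1.0 + np.exp(-(b + lp)))


def sample_survival(
    linear_predictor,
    grid: TimeGrid,
    censoring_rate: float,
    seed,
    baseline_logits=DEFAULT_BASELINE_LOGITS,
    imaging_feature=None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Sample (time_days, event) under the discrete-time hazard model.

    The event bin is drawn sequentially — a subject at risk in bin m dies
    there with probability h_m = logistic(b_m + lp) — and the continuous
    event time is uniform within the bin.  Subjects surviving all bins get a
    time beyond the horizon.  Censoring times are uniform on [0, horizon],
    with the horizon found by bisection so the expected censored fraction
    matches ``censoring_rate``; censoring is independent of risk.

    Holding the generator's random draws fixed, raising a subject's linear
    predictor can only move its event to an earlier bin (hazard
    monotonicity), which is relied on by tests.
    """
    if not (0 <= censoring_rate < 1):
        raise ValueError("censoring_rate must be in [0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)
    if len(baseline_logits) != grid.n_bins:
        raise ValueError("need one baseline logit per bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = lp.size
    M = grid.n_bins
    h = _hazards(lp, baseline_logits)

    u = rng.random((n, M))
    dies = u < h  # compare one uniform per bin against the hazard
    first = np.argmax(dies, axis=1)
    any_death = dies.any(axis=1)
    edges = np.concatenate([[0.0], np.asarray(grid.cut_points)])
    w = rng.random(n)
    event_time = np.empty(n)
    in_bin = first[any_death]
    event_time[any_death] = edges[in_bin] + w[any_death] * (
        edges[in_bin + 1] - edges[in_bin]
    )
    # survivors of the whole grid: uniform in one extra bin beyond the horizon
    beyond_width = edges[-1] - edges[-2]
    event_time[~any_death] = edges[-1] + w[~any_death] * beyond_width

    if censoring_rate > 0:
        uc = rng.random(n)

        def censored_fraction(horizon):
            # P(C < t) with C ~ U[0, horizon]
            return float(np.mean(np.minimum(event_time / horizon, 1.0)))

        lo, hi = 1e-6, 10.0 * event_time.max()
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_fraction(mid) > censoring_rate:
                lo = mid  # longer horizon -> less censoring
            else:
                hi = mid
        horizon = 0.5 * (lo + hi)
        cens_time = uc * horizon
        event = (event_time <= cens_time).astype(int)
        time = np.minimum(event_time, cens_time)
    else:
        event = np.ones(n, dtype=int)
        time = event_time
        cens_time = None

    gt = GroundTruth(
        true_risk=lp,
        true_hazard=h,
        imaging_feature=(
            np.asarray(imaging_feature, dtype=float)
            if imaging_feature is not None
            else np.zeros(n)
        ),
        censoring_time=cens_time,
    )
    return time, event, gt


def true_cif(gt: GroundTruth) -> np.ndarray:
    """Exact per-subject CIF over the grid bins: F(m) = 1 − Π_{j≤m}(1 − h_j)."""
    return 1.0 - np.cumprod(1.0 - gt.true_hazard, axis=1)


def bayes_optimal_ctd(gt: GroundTruth, times, events, grid: TimeGrid) -> float:
    """Ctd achieved by the true CIF in place of model predictions — an oracle
    upper reference for any predictor built from the observed covariates.
    Uses the same pair rules as :func:`gliosurv.metrics.ctd`."""
    from .discrete_survival import discretize_time

    F = true_cif(gt)
    bins = np.minimum(np.asarray(discretize_time(times, grid)), grid.n_bins - 1)
    cif_matrix = F[:, bins].T  # entry [i, j] = F_j(bin_i)
    return ctd(cif_matrix, times, events)


# ------------------------------------------------------------------- cohort


def make_cohort(config: SyntheticConfig, with_volumes: bool | None = None) -> Cohort:
    """Generate a full multimodal cohort per the config (seeded, deterministic)."""
    rng = np.random.default_rng(config.seed)
    df, lp_clin = generate_clinical(config.n_subjects, config.beta_clinical, rng)

    volumes = None
    feature = np.zeros(config.n_subjects)
    if with_volumes is None:
        with_volumes = config.beta_imaging != 0.0
    if with_volumes:
        lo, hi = config.imaging_feature_range
        targets = rng.uniform(lo, hi, size=config.n_subjects)
        volumes = {}
        for i, sid in enumerate(df["id"]):
            vol, achieved = generate_volume(
                targets[i], config.volume_shape, config.channel_contrasts, rng
            )
            volumes[sid] = vol
            feature[i] = achieved

    img_signal = feature - feature.mean() if with_volumes else feature
    lp = lp_clin + config.beta_imaging * img_signal
    grid = config.grid
    time, event, gt = sample_survival(
        lp,
        grid,
        config.censoring_rate,
        rng,
        baseline_logits=config.baseline_logit_hazard,
        imaging_feature=feature,
    )
    df = df.assign(time_days=time, event=event)
    encoded = np.column_stack(
        [
            (df["age"].to_numpy() - 63.0) / 12.0,
            (df["sex"] == "M").to_numpy(float),
            df["gtr"].to_numpy(float),
            df["mgmt"].to_numpy(float),
            (df["idh"] == "wildtype").to_numpy(float),
            df["kps"].to_numpy(float),
        ]
    )
    return Cohort(
        clinical=df,
        covariates=encoded,
        volumes=volumes,
        ground_truth=gt,
        grid=grid,
        config=config,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Persist a cohort: clinical.csv, ground_truth.csv, and one NIfTI file
    per channel per subject (``<id>_{t1,t1c,t2,flair}.nii.gz``)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    gt = cohort.ground_truth
    gt_df = pd.DataFrame(
        {
            "id": cohort.clinical["id"],
            "true_risk": gt.true_risk,
            "imaging_feature": gt.imaging_feature,
        }
    )
    for m in range(gt.true_hazard.shape[1]):
        gt_df[f"hazard_bin{m + 1}"] = gt.true_hazard[:, m]
    gt_df.to_csv(out / "ground_truth.csv", index=False)
    if cohort.volumes is not None:
        channels = ("t1", "t1c", "t2", "flair")
        for sid, vol in cohort.volumes.items():
            for c, name in enumerate(channels[: vol.shape[0]]):
                img = nib.Nifti1Image(vol[c].astype(np.float32), affine=np.eye(4))
                nib.save(img, str(out / f"{sid}_{name}.nii.gz"))
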