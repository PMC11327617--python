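"""Imaging and covariate preprocessing.

Imaging: the four morphological MR contrasts (T1, T1 post-contrast, T2,
FLAIR) are stacked in the channel dimension, intensity-aligned by
histogram standardization (Nyúl-style decile landmarks fitted on the
training split), and z-normalized within the brain mask.

Covariates: continuous variables are min–max scaled to [−1, 1] using ranges
learned on the training split (test values outside the range are clipped);
categorical variables are one-hot encoded with an explicit "missing" level
rather than imputed.

All fitting statistics derive from the training split only; the fitted
objects carry a frozen flag and refuse to re-fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeStack",
    "stack_modalities",
    "znorm_volume",
    "HistogramStandardizer",
    "scale_continuous",
    "one_hot",
    "CovariateEncoder",
    "load_nifti_channel",
]

CHANNEL_ORDER = ("t1", "t1c", "t2", "flair")


@dataclass
class VolumeStack:
    """Multi-channel 3D volume with voxel spacing and a brain mask.

    ``data`` is (channels, X, Y, Z); the mask marks in-brain voxels shared
    by all channels (defaults to the union of nonzero voxels).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (channels, X, Y, Z)")
        if self.brain_mask is None:
            self.brain_mask = np.any(self.data != 0, axis=0)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match the spatial dimensions")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def load_nifti_channel(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read one single-channel NIfTI volume; returns (array, spacing mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asanyarray(img.dataobj, dtype=np.float32), tuple(img.header.get_zooms()[:3])


def stack_modalities(t2, flair, t1, t1c, spacing=None) -> VolumeStack:
    """Stack the four morphological volumes in the channel dimension.

    Inputs may be arrays (sharing ``spacing``) or (array, spacing) pairs.
    The channel order of the output is fixed as (T1, T1c, T2, FLAIR).
    """
    vols, spacings = [], []
    for v in (t1, t1c, t2, flair):
        if isinstance(v, tuple):
            vols.append(np.asarray(v[0]))
            spacings.append(tuple(float(s) for s in v[1]))
        else:
            vols.append(np.asarray(v))
            spacings.append(tuple(float(s) for s in (spacing or (1.0, 1.0, 1.0))))
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"modalities have mismatched shapes: {shapes}")
    if len(set(spacings)) != 1:
        raise ValueError(f"modalities have mismatched spacing: {set(spacings)}")
    return VolumeStack(data=np.stack(vols, axis=0), spacing=spacings[0])


def znorm_volume(stack: VolumeStack, tol: float = 1e-12) -> VolumeStack:
    """Per-channel z-normalization within the brain mask (population SD);
    voxels outside the mask are set to 0."""
    mask = stack.brain_mask
    if mask.sum() < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    out = np.zeros_like(stack.data, dtype=float)
    for c in range(stack.n_channels):
        vals = stack.data[c][mask]
        sd = vals.std()
        if sd < tol:
            raise ValueError(f"channel {c} has zero within-mask variance")
        out[c][mask] = (vals - vals.mean()) / sd
    return VolumeStack(data=out, spacing=stack.spacing, brain_mask=mask)


class HistogramStandardizer:
    """Nyúl-style piecewise-linear intensity standardization.

    Fitting averages the within-mask decile landmarks {10, 20, ..., 90} (plus
    the min/max tails) over the training volumes, per channel.  Transforming
    maps a subject's own landmarks onto the training average by linear
    interpolation — a monotone map that is the identity for a subject whose
    landmarks already equal the training ones.
    """

    PERCENTILES = np.array([0.0] + [10.0 * k for k in range(1, 10)] + [100.0])

    def __init__(self):
        self.landmarks_: np.ndarray | None = None  # (channels, len(PERCENTILES))
        self.frozen = False

    @property
    def fitted(self) -> bool:
        return self.landmarks_ is not None

    def fit(self, stacks) -> "HistogramStandardizer":
        if self.frozen:
            raise RuntimeError("standardizer is frozen; refusing to re-fit")
        stacks = list(stacks)
        if not stacks:
            raise ValueError("need at least one training volume")
        n_ch = stacks[0].n_channels
        acc = np.zeros((n_ch, self.PERCENTILES.size))
        for s in stacks:
            for c in range(n_ch):
                acc[c] += np.percentile(s.data[c][s.brain_mask], self.PERCENTILES)
        self.landmarks_ = acc / len(stacks)
        self.frozen = True
        return self

    def transform(self, stack: VolumeStack) -> VolumeStack:
        if not self.fitted:
            raise RuntimeError("standardizer has not been fitted")
        out = np.zeros_like(stack.data, dtype=float)
        mask = stack.brain_mask
        for c in range(stack.n_channels):
            vals = stack.data[c][mask]
            own = np.percentile(vals, self.PERCENTILES)
            own, idx = np.unique(own, return_index=True)
            out[c][mask] = np.interp(vals, own, self.landmarks_[c][idx])
        return VolumeStack(data=out, spacing=stack.spacing, brain_mask=mask)


def scale_continuous(values, fitted_range) -> np.ndarray:
    """Min–max scale to [−1, 1] with the training-split range; out-of-range
    values are clipped so the output contract holds on test data."""
    lo, hi = fitted_range
    if not hi > lo:
        raise ValueError("degenerate range: max must exceed min")
    x = np.asarray(values, dtype=float)
    return np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)


def one_hot(value, category_map) -> np.ndarray:
    """Indicator vector over an ordered category list ending in "missing".

    ``None``/NaN map to the missing level; an unseen category maps to
    missing with a warning (the training-fitted map is never extended).
    """
    cats = list(category_map)
    if "missing" not in cats:
        raise ValueError('category_map must include an explicit "missing" level')
    vec = np.zeros(len(cats))
    if value is None or (isinstance(value, float) and np.isnan(value)):
        vec[cats.index("missing")] = 1.0
        return vec
    if value not in cats:
        warnings.warn(f"unseen category {value!r}; mapped to 'missing'", stacklevel=2)
        vec[cats.index("missing")] = 1.0
        return vec
    vec[cats.index(value)] = 1.0
    return vec


@dataclass
class CovariateEncoder:
    """Fit-on-train covariate encoding: [−1, 1] scaling for continuous
    variables, one-hot with a "missing" level for categorical ones."""

    continuous: tuple[str, ...] = ("age",)
    categorical: tuple[str, ...] = ("sex", "gtr", "mgmt", "idh", "kps")
    ranges_: dict = field(default_factory=dict)
    category_maps_: dict = field(default_factory=dict)
    frozen: bool = False

    @property
    def fitted(self) -> bool:
        return bool(self.ranges_) or bool(self.category_maps_)

    def fit(self, df) -> "CovariateEncoder":
        if self.frozen:
            raise RuntimeError("encoder is frozen; refusing to re-fit")
        for col in self.continuous:
            lo, hi = float(df[col].min()), float(df[col].max())
            if not hi > lo:
                raise ValueError(f"degenerate range for {col}")
            self.ranges_[col] = (lo, hi)
        for col in self.categorical:
            seen = sorted(
                {v for v in df[col] if not (isinstance(v, float) and np.isnan(v))},
                key=str,
            )
            self.category_maps_[col] = [*seen, "missing"]
        self.frozen = True
        return self

    def transform(self, df) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("encoder has not been fitted")
        parts = []
        for col in self.continuous:
            parts.append(scale_continuous(df[col].to_numpy(), self.ranges_[col])[:, None])
        for col in self.categorical:
            cats = self.category_maps_[col]
            block = np.stack([one_hot(v, cats) for v in df[col]], axis=0)
            parts.append(block)
        return np.concatenate(parts, axis=1)

    @property
    def dim(self) -> int:
        return len(self.continuous) + sum(len(v) for v in self.category_maps_.values())

    def to_dict(self) -> dict:
        return {
            "continuous": list(self.continuous),
            "categorical": list(self.categorical),
            "ranges": {k: list(v) for k, v in self.ranges_.items()},
            "category_maps": {k: list(v) for k, v in self.category_maps_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateEncoder":
        enc = cls(
            continuous=tuple(d["continuous"]), categorical=tuple(d["categorical"])
        )
        enc.ranges_ = {k: tuple(v) for k, v in d["ranges"].items()}
        enc.category_maps_ = {k: list(v) for k, v in d["category_maps"].items()}
        enc.frozen = True
        return enc
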