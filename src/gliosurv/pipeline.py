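"""Experiment orchestration: splits, training loop, evaluation protocol.

Implements the two-stage workflow — self-supervised pretraining of the image
encoder, then survival training with the encoder frozen — under a stratified
70/15/15 train/validation/test split (stratification cells: event indicator
× survival-time tertile, so censoring and survival times stay consistent
across splits).  The held-out test split is evaluated exactly once per
experiment; a second evaluation attempt raises.

All randomness flows from two explicit seeds (data, model); identical
configuration and seeds reproduce identical predictions bitwise.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import discrete_survival as ds
from . import metrics as mx
from .autodiff import Tensor, no_grad
from .fusion import FusionConfig, SurvivalTransformer
from .nn import Adam
from .preprocessing import HistogramStandardizer, VolumeStack, znorm_volume
from .ssl_encoder import ViTConfig, pretrain
from .synthetic import Cohort, SyntheticConfig, make_cohort

__all__ = [
    "ExperimentConfig",
    "SplitAssignment",
    "stratified_split",
    "train_survival",
    "predict_survival",
    "evaluate_predictions",
    "Experiment",
    "run_experiment",
    "ablation_suite",
]


# ------------------------------------------------------------------- splits


@dataclass
class SplitAssignment:
    labels: pd.Series  # subject id -> {"train", "val", "test"}
    audit: dict

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero((self.labels == split).to_numpy())

    def hash(self) -> str:
        payload = json.dumps(sorted(self.labels.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _largest_remainder(n: int, fractions) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    for k in np.argsort(-rem)[: n - base.sum()]:
        base[k] += 1
    return base


def stratified_split(times, events, ids=None, fractions=(0.70, 0.15, 0.15), seed=0) -> SplitAssignment:
    """Stratified train/val/test partition.

    Stratification cells are event indicator × survival-time tertile;
    subjects are allocated proportionally within each cell and the global
    split sizes are exact (largest-remainder rounding).  If any cell is
    empty the split falls back to event-only stratification with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = times.size
    if n < 20:
        raise ValueError("need at least 20 subjects to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(ids) if ids is not None else list(range(n))
    rng = np.random.default_rng(seed)

    tert = np.searchsorted(np.quantile(times, [1 / 3, 2 / 3]), times, side="right")
    cells = events * 3 + tert
    cell_ids = [np.flatnonzero(cells == c) for c in range(6)]
    if min(len(c) for c in cell_ids) == 0:
        warnings.warn("empty stratification cell; falling back to event-only strata")
        cell_ids = [np.flatnonzero(events == e) for e in (0, 1)]
        cell_ids = [c for c in cell_ids if len(c)]

    targets = _largest_remainder(n, fractions)
    labels = np.empty(n, dtype=object)
    counts = np.zeros(3, dtype=int)
    for members in cell_ids:
        members = rng.permutation(members)
        alloc = _largest_remainder(len(members), fractions)
        idx = 0
        for s, k in enumerate(alloc):
            labels[members[idx : idx + k]] = ("train", "val", "test")[s]
            counts[s] += k
            idx += k
    # repair any global drift from per-cell rounding
    names = ("train", "val", "test")
    for s_over in range(3):
        while counts[s_over] > targets[s_over]:
            s_under = int(np.argmin(counts - targets))
            pool = np.flatnonzero(labels == names[s_over])
            pick = rng.choice(pool)
            labels[pick] = names[s_under]
            counts[s_over] -= 1
            counts[s_under] += 1

    series = pd.Series(labels, index=ids)
    audit = {}
    for s in names:
        m = labels == s
        audit[s] = {
            "n": int(m.sum()),
            "event_fraction": float(events[m].mean()),
            "median_time": float(np.median(times[m])),
        }
    return SplitAssignment(labels=series, audit=audit)


# ----------------------------------------------------------------- training


def _forward_probabilities(model: SurvivalTransformer, img_feats, X, idx) -> Tensor:
    img = None if img_feats is None else img_feats[idx]
    logits = model(img, X[idx])
    return logits.softmax(axis=-1)


def train_survival(
    model: SurvivalTransformer,
    img_feats,
    X,
    times,
    events,
    grid: ds.TimeGrid,
    train_idx,
    val_idx,
    epochs: int = 200,
    batch_size: int = 32,
    lr: float = 1e-3,
    lambda_rank: float = 0.5,
    sigma: float = 0.1,
    patience: int = 10,
    seed: int = 0,
    history: list | None = None,
) -> SurvivalTransformer:
    """Minibatch Adam training of the two-part survival objective with early
    stopping on the validation likelihood term (patience in epochs); the best
    validation state is restored before returning."""
    rng = np.random.default_rng(seed)
    bins = np.asarray(ds.discretize_time(times, grid))
    opt = Adam(model.parameters(), lr=lr)
    best_val, best_state, since_best = np.inf, None, 0
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)

    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 2:
                continue
            y = _forward_probabilities(model, img_feats, X, idx)
            l1 = ds.likelihood_loss(y, bins[idx], events[idx], grid)
            l2 = ds.ranking_loss(y, bins[idx], events[idx], grid, sigma)
            loss = ds.total_loss(l1, l2, lambda_rank)
            opt.zero_grad()
            loss.backward()
            opt.step()
        with no_grad():
            y_val = _forward_probabilities(model, img_feats, X, val_idx)
            val_l1 = float(
                ds.likelihood_loss(y_val, bins[val_idx], events[val_idx], grid).item()
            )
        if history is not None:
            history.append({"epoch": epoch, "val_likelihood": val_l1})
        if val_l1 < best_val - 1e-6:
            best_val, best_state, since_best = val_l1, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def predict_survival(model, img_feats, X, grid: ds.TimeGrid, idx=None) -> ds.DiscreteSurvivalOutput:
    idx = np.arange(X.shape[0]) if idx is None else np.asarray(idx)
    img = None if img_feats is None else img_feats[idx]
    logits = model.predict(img, X[idx])
    return ds.softmax_probabilities(logits, grid)


def evaluate_predictions(
    out: ds.DiscreteSurvivalOutput,
    times,
    events,
    censor_train_times=None,
    censor_train_events=None,
    dichotomize_at: float = 12.0,
) -> mx.MetricReport:
    """Full metric report for one split: time-dependent concordance, Brier
    scores on the monthly grid with censoring weights fitted on the training
    split (or this split if none given), integrated Brier score, and the
    log-rank test between predicted favorable/unfavorable groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = out.grid
    bins = np.minimum(np.asarray(ds.discretize_time(times, grid)), grid.n_bins - 1)
    F = ds.cif(out)
    cif_matrix = F[:, bins].T
    c_td = mx.ctd(cif_matrix, times, events)

    if censor_train_times is None:
        censor_train_times, censor_train_events = times, events
    G = mx.censoring_km(censor_train_times, censor_train_events)
    curve = ds.survival_function(out)
    months = grid.months() * grid.month_days
    briers = []
    used_t = []
    for j, t in enumerate(months):
        try:
            briers.append(mx.brier_score(curve.monthly[:, j], times, events, t, G))
            used_t.append(t)
        except ZeroDivisionError:
            break
    ibs = mx.integrated_brier(briers, used_t) if len(briers) >= 2 else np.nan

    groups = mx.dichotomize(curve.monthly, dichotomize_at)
    if 0 < groups.sum() < len(groups):
        chi2, p = mx.logrank_test(groups, times, events)
    else:
        chi2, p = None, None
    return mx.MetricReport(
        ctd=c_td,
        ibs=float(ibs),
        brier_times=np.asarray(used_t),
        brier_values=np.asarray(briers),
        logrank_chi2=chi2,
        logrank_p=p,
    )


# -------------------------------------------------------------- experiments


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    modality: str = "multimodal"
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed_data: int = 0
    seed_model: int = 0
    # survival training
    epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-3
    lambda_rank: float = 0.5
    sigma: float = 0.1
    patience: int = 10
    embed_dim: int = 32
    clin_tokens: int = 4
    # self-supervised pretraining
    ssl: ViTConfig = field(default_factory=ViTConfig)
    ssl_epochs: int = 20
    ssl_batch_size: int = 8
    ssl_lr: float = 1e-3

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Experiment:
    config: ExperimentConfig
    cohort: Cohort
    split: SplitAssignment
    model: SurvivalTransformer
    encoder: object | None
    predictions: ds.DiscreteSurvivalOutput  # all subjects, row order = cohort
    reports: dict
    _test_consumed: bool = False

    def evaluate_test(self) -> mx.MetricReport:
        """Held-out evaluation; callable exactly once per experiment."""
        if self._test_consumed:
            raise RuntimeError("test split already evaluated for this experiment")
        self._test_consumed = True
        te = self.split.indices("test")
        tr = self.split.indices("train")
        out = ds.DiscreteSurvivalOutput(self.predictions.y[te], self.predictions.grid)
        return evaluate_predictions(
            out,
            self.cohort.times[te],
            self.cohort.events[te],
            censor_train_times=self.cohort.times[tr],
            censor_train_events=self.cohort.events[tr],
        )


def _preprocess_volumes(cohort: Cohort, train_ids) -> dict[str, VolumeStack]:
    """Histogram standardization (fitted on the training split) followed by
    within-mask z-normalization, per subject."""
    stacks = {
        sid: VolumeStack(data=np.asarray(v, dtype=float)) for sid, v in cohort.volumes.items()
    }
    standardizer = HistogramStandardizer().fit([stacks[s] for s in train_ids])
    return {sid: znorm_volume(standardizer.transform(s)) for sid, s in stacks.items()}


def run_experiment(config: ExperimentConfig) -> Experiment:
    """Execute the full two-stage workflow on a synthetic cohort.

    Pretrains the image encoder on the training-split volumes (imaging
    modalities only), freezes it, trains the survival model with early
    stopping on the validation likelihood, and evaluates the test split
    exactly once.  Returns the experiment with per-split metric reports
    under ``reports`` ("train", "val", "test").
    """
    needs_imaging = config.modality in ("multimodal", "imaging")
    cohort = make_cohort(config.synthetic, with_volumes=needs_imaging)
    ids = list(cohort.clinical["id"])
    split = stratified_split(
        cohort.times, cohort.events, ids=ids, fractions=config.fractions, seed=config.seed_data
    )
    tr = split.indices("train")
    va = split.indices("val")

    grid = ds.build_time_grid(cohort.times[tr])

    # covariates: encoded matrix with missing-as-zero (the clinical encoder
    # requires finite input; the synthetic covariates are already on a
    # bounded scale)
    X = np.nan_to_num(cohort.covariates, nan=0.0)

    encoder = None
    img_feats = None
    if needs_imaging:
        train_ids = [ids[i] for i in tr]
        prepped = _preprocess_volumes(cohort, train_ids)
        vols_train = np.stack([prepped[s].data for s in train_ids]).astype(np.float32)
        encoder = pretrain(
            vols_train,
            config.ssl,
            epochs=config.ssl_epochs,
            batch_size=config.ssl_batch_size,
            lr=config.ssl_lr,
            seed=config.seed_model,
        )
        encoder.freeze()
        img_feats = np.stack([encoder.encode(prepped[s].data) for s in ids])

    d_clin = X.shape[1]
    fusion_cfg = FusionConfig(
        embed_dim=config.embed_dim,
        clin_tokens=config.clin_tokens,
        img_dim=config.ssl.embed_dim,
        n_img_tokens=0 if img_feats is None else img_feats.shape[1],
        n_bins=grid.n_bins,
        modality=config.modality,
    )
    model = SurvivalTransformer(fusion_cfg, d_clin, seed=config.seed_model)
    train_survival(
        model,
        img_feats,
        X,
        cohort.times,
        cohort.events,
        grid,
        tr,
        va,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        lambda_rank=config.lambda_rank,
        sigma=config.sigma,
        patience=config.patience,
        seed=config.seed_model,
    )

    predictions = predict_survival(model, img_feats, X, grid)
    reports = {}
    for name in ("train", "val"):
        idx = split.indices(name)
        out = ds.DiscreteSurvivalOutput(predictions.y[idx], grid)
        reports[name] = evaluate_predictions(
            out,
            cohort.times[idx],
            cohort.events[idx],
            censor_train_times=cohort.times[tr],
            censor_train_events=cohort.events[tr],
        )
    exp = Experiment(
        config=config,
        cohort=cohort,
        split=split,
        model=model,
        encoder=encoder,
        predictions=predictions,
        reports=reports,
    )
    reports["test"] = exp.evaluate_test()
    return exp


def ablation_suite(config: ExperimentConfig, modes) -> pd.DataFrame:
    """Run the experiment once per mode with shared data seed and splits.

    A mode is either a modality ("clinical", "imaging", "multimodal") or an
    SSL loss mode ("additive", "product_regularized", ...).  Returns one row
    per mode with test Ctd and IBS plus the shared split hash.
    """
    modes = list(modes)
    if len(modes) < 2:
        raise ValueError("need at least 2 modes to compare")
    rows = []
    modalities = {"clinical", "imaging", "multimodal"}
    for mode in modes:
        if mode in modalities:
            cfg = replace(config, modality=mode)
        else:
            cfg = replace(config, ssl=replace(config.ssl, loss_mode=mode))
        exp = run_experiment(cfg)
        rows.append(
            {
                "mode": mode,
                "ctd": exp.reports["test"].ctd,
                "ibs": exp.reports["test"].ibs,
                "split_hash": exp.split.hash(),
            }
        )
    return pd.DataFrame(rows)
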