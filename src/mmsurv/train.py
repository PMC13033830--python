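"""Cox partial-likelihood training, cohort splitting, CV, and ablation runs.

The loss is the negative log partial likelihood under proportional hazards,
Breslow convention for tied event times:

    L(r) = - sum_{i: event_i = 1} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]

It depends on risks only through differences (shift-invariant) and is convex.
The trainer minimizes the per-event mean of L with Adam (weight decay 4e-6 by
default), full-cohort risk sets by default, and optional event-stratified
large-batch risk sets for cohorts too large to fit in one likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .features import (
    ClinicalSchema,
    PATHOLOGY_STREAMS,
    PatientRecord,
    ULTRASOUND_STREAMS,
    cohort_to_batch,
)
from .fusion import FusionConfig, MultimodalRiskModel, _QUERY_ALIAS
from .metrics import concordance_index
from .simulate import inject_missingness

logger = logging.getLogger("mmsurv")


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def _risk_set_mask(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows = event subjects, columns = cohort; mask[i, j] = t_j >= t_i."""
    ev_idx = np.flatnonzero(events == 1)
    mask = times[None, :] >= times[ev_idx, None]
    return ev_idx, mask.astype(np.float64)


def cox_loss_graph(risks: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Summed negative log partial likelihood as an autodiff graph node."""
    ev_idx, mask = _risk_set_mask(times, events)
    if ev_idx.size == 0:
        return Tensor(0.0)
    shift = float(risks.data.max())
    exp_r = (risks - shift).exp()  # n
    denom = Tensor(mask).matmul(exp_r.reshape(-1, 1)).reshape(-1)  # per-event sums
    log_denom = denom.log() + shift
    r_events = Tensor(np.eye(len(times))[ev_idx]).matmul(risks.reshape(-1, 1)).reshape(-1)
    return (log_denom - r_events).sum()


def cox_loss(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Negative log Cox partial likelihood (Breslow ties); 0 when no events."""
    risks = np.asarray(risks, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if risks.size == 0:
        raise ValueError("empty input")
    if risks.shape != times.shape or risks.shape != events.shape:
        raise ValueError("risks, times, events must have equal length")
    return float(cox_loss_graph(Tensor(risks), times, events).data)


def cox_loss_grad(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`cox_loss` with respect to the risks."""
    r = Tensor(np.asarray(risks, dtype=np.float64), requires_grad=True)
    loss = cox_loss_graph(r, np.asarray(times, float), np.asarray(events, int))
    loss.backward()
    return r.grad


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    train_fraction: float = 5 / 6
    stratify_on: str = "event"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split_indices(
    events: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified train/test indices.

    Train size is round(fraction * n); each stratum contributes its
    proportional share (largest-remainder rounding), so the event fraction of
    each part is within one patient of the cohort's.
    """
    events = np.asarray(events, dtype=int)
    n = len(events)
    n_train = round(train_fraction * n)
    if n - n_train < 2:
        raise ValueError("split leaves fewer than 2 test patients")
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(events == 1), np.flatnonzero(events == 0)]
    targets = [train_fraction * len(s) for s in strata]
    base = [math.floor(t) for t in targets]
    remainder = n_train - sum(base)
    order = sorted(range(len(strata)), key=lambda i: targets[i] - base[i], reverse=True)
    for i in order[:remainder]:
        base[i] += 1
    train_idx, test_idx = [], []
    for s, k in zip(strata, base):
        s = s.copy()
        rng.shuffle(s)
        train_idx.append(s[:k])
        test_idx.append(s[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def split_cohort(
    cohort: list[PatientRecord], spec: SplitSpec
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    events = np.array([r.outcome.event for r in cohort])
    if events.sum() < 2:
        raise ValueError("cohort must contain at least 2 events to stratify")
    tr, te = stratified_split_indices(events, spec.train_fraction, spec.seed)
    return [cohort[i] for i in tr], [cohort[i] for i in te]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 4e-6
    max_epochs: int = 100
    risk_set_batching: str = "full_cohort"  # or "large_batch"
    batch_size: int = 256
    min_events_per_batch: int = 1
    early_stop_patience: int = 0  # 0 disables early stopping
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")
        if self.risk_set_batching not in ("full_cohort", "large_batch"):
            raise ValueError("risk_set_batching must be full_cohort or large_batch")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    val_c_index: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)
    stopped_epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.loss) + 1),
                "loss": self.loss,
                "val_c_index": self.val_c_index,
            }
        )


def _event_balanced_batches(
    times: np.ndarray, events: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled batches, events dealt round-robin so each batch keeps >= 1
    event whenever enough events exist."""
    n = len(times)
    n_batches = max(1, n // batch_size)
    ev = np.flatnonzero(events == 1)
    ce = np.flatnonzero(events == 0)
    rng.shuffle(ev)
    rng.shuffle(ce)
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for i, idx in enumerate(np.concatenate([ev, ce])):
        batches[i % n_batches].append(idx)
    return [np.sort(np.array(b)) for b in batches if len(b) >= 2]


def train_model(
    train_records: list[PatientRecord],
    fusion_config: FusionConfig,
    train_config: TrainConfig,
    schema: ClinicalSchema,
    val_records: list[PatientRecord] | None = None,
) -> tuple[MultimodalRiskModel, TrainingHistory]:
    """End-to-end training: fusion stages, clinical encoder and compensation
    embeddings optimized jointly on the Cox objective.  Fully reproducible for
    a fixed seed."""
    batch = cohort_to_batch(train_records, schema)
    stream_dims = {s: v.shape[2] for s, v in batch["streams"].items()}
    model = MultimodalRiskModel(
        fusion_config, schema, stream_dims, seed=train_config.seed
    )
    params = model.named_parameters()
    opt = Adam(
        params, lr=train_config.learning_rate, weight_decay=train_config.weight_decay
    )
    drop_rng = np.random.default_rng([train_config.seed, 271828])
    batch_rng = np.random.default_rng([train_config.seed, 314159])

    val_batch = cohort_to_batch(val_records, schema) if val_records else None
    history = TrainingHistory(seed=train_config.seed, config=model.config_snapshot())
    best_c, best_state, since_best = -np.inf, None, 0

    times, events = batch["time"], batch["event"]
    n_events = max(int(events.sum()), 1)

    for epoch in range(train_config.max_epochs):
        if train_config.risk_set_batching == "full_cohort":
            sub_batches = [np.arange(len(train_records))]
        else:
            sub_batches = _event_balanced_batches(
                times, events, train_config.batch_size, batch_rng
            )
        epoch_loss = 0.0
        epoch_risks, epoch_idx = [], []
        for idx in sub_batches:
            sub = _subset_batch(batch, idx)
            out = model.forward_batch(sub, training=True, rng=drop_rng)
            n_ev = max(int(sub["event"].sum()), 1)
            loss = cox_loss_graph(out["risk"], sub["time"], sub["event"]) * (1.0 / n_ev)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}: {float(loss.data)}; "
                    f"risk range [{out['risk'].data.min()}, {out['risk'].data.max()}]"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * max(int(sub["event"].sum()), 1)
            epoch_risks.append(out["risk"].data.copy())
            epoch_idx.append(idx)
        history.loss.append(epoch_loss / n_events)

        if val_batch is not None:
            risks = model.predict_risk(val_batch)
            c = concordance_index(risks, val_batch["time"], val_batch["event"])
        else:
            # no validation set: track concordance of the (pre-step,
            # dropout-mode) training risks instead of re-running a forward
            idx_all = np.concatenate(epoch_idx)
            r_all = np.concatenate(epoch_risks)
            c = concordance_index(r_all, times[idx_all], events[idx_all])
        history.val_c_index.append(c)

        if train_config.early_stop_patience > 0:
            if c > best_c + 1e-9:
                best_c, since_best = c, 0
                best_state = {k: p.data.copy() for k, p in params.items()}
            else:
                since_best += 1
                if since_best >= train_config.early_stop_patience:
                    history.stopped_epoch = epoch + 1
                    break
    if best_state is not None and train_config.early_stop_patience > 0:
        for k, p in params.items():
            p.data = best_state[k]
    return model, history


def _subset_batch(batch: dict, idx: np.ndarray) -> dict:
    return {
        "patient_ids": [batch["patient_ids"][i] for i in idx],
        "streams": {s: v[idx] for s, v in batch["streams"].items()},
        "clinical_continuous": batch["clinical_continuous"][idx],
        "clinical_categorical": batch["clinical_categorical"][idx],
        "time": batch["time"][idx],
        "event": batch["event"][idx],
        "availability": {m: v[idx] for m, v in batch["availability"].items()},
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(
    events: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    ev = np.flatnonzero(events == 1)
    ce = np.flatnonzero(events == 0)
    rng.shuffle(ev)
    rng.shuffle(ce)
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, idx in enumerate(ev):
        folds[i % k].append(idx)
    for i, idx in enumerate(ce):
        folds[(k - 1 - i % k)].append(idx)
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(
    cohort: list[PatientRecord],
    fusion_config: FusionConfig,
    train_config: TrainConfig,
    schema: ClinicalSchema,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    max_redraws: int = 5,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV; returns per-fold held-out C-index."""
    if k < 2:
        raise ValueError("k must be >= 2")
    events = np.array([r.outcome.event for r in cohort])
    rows = []
    for rep in range(repeats):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
        rng = np.random.default_rng(rep_seed)
        for attempt in range(max_redraws):
            folds = stratified_folds(events, k, rng)
            if all(events[f].sum() >= 1 for f in folds):
                break
        else:
            raise ValueError("could not draw folds with events in every fold")
        for fold_i, test_idx in enumerate(folds):
            test_set = set(test_idx.tolist())
            train = [r for i, r in enumerate(cohort) if i not in test_set]
            test = [cohort[i] for i in test_idx]
            tc = replace(train_config, seed=rep_seed + fold_i)
            model, _ = train_model(train, fusion_config, tc, schema)
            tb = cohort_to_batch(test, schema)
            c = concordance_index(model.predict_risk(tb), tb["time"], tb["event"])
            rows.append({"repeat": rep, "fold": fold_i, "c_index": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------


def apply_config_delta(base: FusionConfig, delta: dict) -> FusionConfig:
    """Build an ablated configuration from a delta dict.

    Supported keys: ``drop_modality``, ``drop_stream`` (query auto-reassigned
    to the next enabled stream in declared order), plus any FusionConfig field
    override (``wsi_query``, ``intermodal_strategy``, ...).
    """
    from dataclasses import asdict

    fields = asdict(base)
    delta = dict(delta)
    if "drop_modality" in delta:
        m = delta.pop("drop_modality")
        if m not in fields["enabled_modalities"]:
            raise ValueError(f"modality {m} not enabled")
        fields["enabled_modalities"] = tuple(
            x for x in fields["enabled_modalities"] if x != m
        )
    if "drop_stream" in delta:
        drops = delta.pop("drop_stream")
        if isinstance(drops, str):
            drops = [drops]
        fields["enabled_streams"] = tuple(
            s for s in fields["enabled_streams"] if s not in set(drops)
        )
        # reassign queries if their stream was dropped; drop a modality whose
        # streams are all gone
        for modality, attr, order in (
            ("pathology", "wsi_query", PATHOLOGY_STREAMS),
            ("ultrasound", "us_query", ULTRASOUND_STREAMS),
        ):
            if modality not in fields["enabled_modalities"]:
                continue
            alias = _QUERY_ALIAS[modality]
            remaining = tuple(s for s in order if s in fields["enabled_streams"])
            if not remaining:
                fields["enabled_modalities"] = tuple(
                    x for x in fields["enabled_modalities"] if x != modality
                )
            elif alias[fields[attr]] not in remaining:
                fields[attr] = {v: k for k, v in alias.items()}[remaining[0]]
    fields.update(delta)
    return FusionConfig(**fields)


def run_ablation_grid(
    cohort: list[PatientRecord],
    base_config: FusionConfig,
    cells: list[dict],
    train_config: TrainConfig,
    split_spec: SplitSpec,
    schema: ClinicalSchema,
    missing_seed: int = 12345,
) -> pd.DataFrame:
    """Train/evaluate one run per grid cell on a shared split and seed.

    Each cell: ``{"name": str, "delta": {...}, "missing_rates": {...}}``.
    Cells that request missingness share one injected mask (controlled
    comparison).  The base configuration is always evaluated as the
    reference row; ``delta_c_index`` is relative to it.
    """
    if not cells:
        raise ValueError("empty ablation grid")
    train, test = split_cohort(cohort, split_spec)

    masked_cache: dict[tuple, tuple[list, list]] = {}

    def with_missingness(rates: dict | None) -> tuple[list, list]:
        if not rates:
            return train, test
        key = tuple(sorted(rates.items()))
        if key not in masked_cache:
            masked_cache[key] = (
                inject_missingness(train, rates, seed=missing_seed),
                inject_missingness(test, rates, seed=missing_seed + 1),
            )
        return masked_cache[key]

    def run_cell(cfg: FusionConfig, rates: dict | None) -> float:
        tr, te = with_missingness(rates)
        model, _ = train_model(tr, cfg, train_config, schema)
        tb = cohort_to_batch(te, schema)
        return concordance_index(model.predict_risk(tb), tb["time"], tb["event"])

    rows = [{"name": "full", "c_index": run_cell(base_config, None)}]
    c_ref = rows[0]["c_index"]
    for cell in cells:
        name = cell.get("name", str(cell.get("delta", {})))
        try:
            cfg = apply_config_delta(base_config, cell.get("delta", {}))
        except ValueError as err:
            logger.warning("skipping invalid ablation cell %s: %s", name, err)
            continue
        c = run_cell(cfg, cell.get("missing_rates"))
        rows.append({"name": name, "c_index": c})
    df = pd.DataFrame(rows)
    df["delta_c_index"] = df["c_index"] - c_ref
    return df
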