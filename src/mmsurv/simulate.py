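"""Synthetic multimodal survival cohorts with planted latent risk.

Each modality m (pathology, ultrasound, clinical) carries an i.i.d. standard
normal latent factor vector f_m per patient; its unit-scaled score
s_m = sum(f_m)/sqrt(latent_dim) ~ N(0,1) contributes w_m * s_m to the true
log-relative-hazard z.  Event times are exponential given z
(T = -log(U) / (h0 * exp(z))), censoring is uniform up to an administrative
cutoff, and the cutoff can be calibrated analytically so a target fraction of
patients experiences the event (default 16.2%, the event rate typical of
HR+/HER2- early breast cancer cohorts over ~10 years of follow-up).

Feature streams are linear read-outs of their modality's latent factor:
token t of stream s is A_s f_m + noise, with a fixed seeded mixing map A_s,
so every stream is informative of exactly one modality.  Clinical variables
are noisy copies of the clinical score (continuous) or quantile-binned noisy
copies (categorical).  Times are in months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import roots_hermitenorm
from scipy.stats import norm

from .features import (
    MODALITIES,
    STREAM_MODALITY,
    STREAM_NAMES,
    ClinicalProfile,
    ClinicalSchema,
    PatientRecord,
    SurvivalOutcome,
    TokenMatrix,
    default_clinical_schema,
)

DEFAULT_SIGNAL_WEIGHTS = {"pathology": 1.0, "ultrasound": 0.4, "clinical": 0.4}
DEFAULT_STREAM_DIMS = {
    "wsi_deep": 64,
    "wsi_morph": 32,
    "wsi_top": 32,
    "us_deep": 64,
    "us_omic": 32,
    "us_text": 32,
}


@dataclass
class CohortSimConfig:
    n_patients: int = 768
    latent_dim: int = 4
    signal_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_WEIGHTS)
    )
    stream_dims: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STREAM_DIMS)
    )
    n_wsi_patches: int = 32
    n_us_tokens: int = 16
    noise_sd: float = 0.5
    baseline_hazard: float = 0.002  # events per month at z = 0
    admin_censor_time: float | None = None  # None -> calibrate to target
    target_event_fraction: float = 0.162
    stream_offset_scale: float = 1.0  # sd of the fixed per-stream mean offset
    missing_rates: dict[str, float] = field(default_factory=dict)
    clinical_schema: ClinicalSchema = field(default_factory=default_clinical_schema)
    clinical_signal: float = 0.8  # correlation of clinical variables with s_clin
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.n_wsi_patches < 1 or self.n_us_tokens < 1:
            raise ValueError("token counts must be positive")
        for s, d in self.stream_dims.items():
            if s not in STREAM_NAMES:
                raise ValueError(f"unknown stream {s}")
            if d < 1:
                raise ValueError(f"stream {s}: dim must be positive")
        for m, w in self.signal_weights.items():
            if m not in MODALITIES:
                raise ValueError(f"unknown modality in signal_weights: {m}")
            if w < 0:
                raise ValueError("signal weights must be nonnegative")
        for m, r in self.missing_rates.items():
            if m not in MODALITIES:
                raise ValueError(f"unknown modality in missing_rates: {m}")
            if not 0 <= r <= 1:
                raise ValueError("missing rates must be in [0, 1]")
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must be in (0, 1)")
        if self.noise_sd < 0 or self.baseline_hazard <= 0:
            raise ValueError("noise_sd >= 0 and baseline_hazard > 0 required")


@dataclass
class GroundTruth:
    true_log_risk: np.ndarray  # planted z per patient
    latent_factors: dict[str, np.ndarray]  # modality -> n x latent_dim


# ---------------------------------------------------------------------------
# censoring calibration
# ---------------------------------------------------------------------------


def event_probability(admin_time: float, baseline_hazard: float, risk_sd: float) -> float:
    """P(T < C) with T | z ~ Exp(h0 e^z), z ~ N(0, risk_sd^2), C ~ U(0, a).

    Closed form inner integral: P(T < C | z) = 1 - (1 - e^{-lam a})/(lam a);
    the outer normal expectation uses Gauss-Hermite quadrature.
    """
    if admin_time <= 0:
        return 0.0
    nodes, weights = roots_hermitenorm(64)
    lam = baseline_hazard * np.exp(risk_sd * nodes)
    x = lam * admin_time
    inner = 1.0 - (1.0 - np.exp(-x)) / x
    return float(np.sum(weights * inner) / np.sqrt(2 * np.pi))


def calibrate_admin_censor_time(config: CohortSimConfig) -> float:
    """Bisection on the analytic event-probability integral so the expected
    event fraction equals ``target_event_fraction``."""
    sd = float(np.sqrt(sum(w**2 for w in config.signal_weights.values())))
    target = config.target_event_fraction
    lo, hi = 1e-6, 1.0
    while event_probability(hi, config.baseline_hazard, sd) < target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("cannot reach target event fraction; hazard too low")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if event_probability(mid, config.baseline_hazard, sd) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _mixing_maps(
    config: CohortSimConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Fixed per-stream mixing maps A_s and mean offsets mu_s, seeded
    independently of patient randomness so the feature geometry is a property
    of the config.  The nonzero offsets mirror real extracted features (deep
    embeddings, radiomics), which are not centered at zero — so substituting
    zeros for a missing modality lands off the feature manifold, as it would
    on real data."""
    rng = np.random.default_rng([config.seed, 7919])
    maps = {
        s: rng.standard_normal((config.latent_dim, d)) / np.sqrt(config.latent_dim)
        for s, d in config.stream_dims.items()
    }
    offsets = {
        s: config.stream_offset_scale * rng.standard_normal(d)
        for s, d in config.stream_dims.items()
    }
    return maps, offsets


def simulate_cohort(config: CohortSimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    rng = np.random.default_rng(config.seed)
    n, k = config.n_patients, config.latent_dim

    factors = {m: rng.standard_normal((n, k)) for m in MODALITIES}
    scores = {m: factors[m].sum(axis=1) / np.sqrt(k) for m in MODALITIES}
    z = sum(
        config.signal_weights.get(m, 0.0) * scores[m] for m in MODALITIES
    ) + np.zeros(n)

    # outcomes: exponential given z, uniform-to-administrative censoring
    admin = (
        config.admin_censor_time
        if config.admin_censor_time is not None
        else calibrate_admin_censor_time(config)
    )
    u = rng.random(n)
    t_event = -np.log(u) / (config.baseline_hazard * np.exp(z))
    t_cens = admin * rng.random(n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    event = (t_event <= t_cens).astype(int)

    # feature streams
    maps, offsets = _mixing_maps(config)
    n_tokens = {
        "wsi_deep": config.n_wsi_patches,
        "wsi_morph": 1,
        "wsi_top": 1,
        "us_deep": config.n_us_tokens,
        "us_omic": 1,
        "us_text": 1,
    }
    stream_values: dict[str, np.ndarray] = {}
    for s, d in config.stream_dims.items():
        f = factors[STREAM_MODALITY[s]]  # n x k
        signal = f @ maps[s] + offsets[s]  # n x d
        noise = config.noise_sd * rng.standard_normal((n, n_tokens[s], d))
        stream_values[s] = signal[:, None, :] + noise

    # clinical variables from the clinical score
    schema = config.clinical_schema
    a = config.clinical_signal
    s_clin = scores["clinical"]
    cont_cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(schema.continuous_names):
        v = a * s_clin + np.sqrt(max(1 - a**2, 0.0)) * rng.standard_normal(n)
        if name == "age_years":
            cont_cols[name] = 47.0 + 12.0 * v
        elif name == "tumor_size_cm":
            cont_cols[name] = np.maximum(2.2 + 0.8 * v, 0.1)
        else:
            cont_cols[name] = v
    cat_cols: dict[str, np.ndarray] = {}
    for v_def in schema.categorical:
        u_v = a * s_clin + np.sqrt(max(1 - a**2, 0.0) + 0.25) * rng.standard_normal(n)
        sd_u = np.sqrt(a**2 + max(1 - a**2, 0.0) + 0.25)
        edges = norm.ppf(
            np.linspace(0, 1, v_def.n_categories + 1)[1:-1], scale=sd_u
        )
        cat_cols[v_def.name] = np.digitize(u_v, edges)

    records: list[PatientRecord] = []
    for i in range(n):
        streams = {
            s: TokenMatrix(stream_values[s][i], s) for s in config.stream_dims
        }
        profile = ClinicalProfile(
            continuous={k_: float(v[i]) for k_, v in cont_cols.items()},
            categorical={k_: int(v[i]) for k_, v in cat_cols.items()},
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                streams=streams,
                clinical=profile,
                outcome=SurvivalOutcome(float(time[i]), int(event[i])),
                availability={m: True for m in MODALITIES},
            )
        )

    truth = GroundTruth(true_log_risk=z, latent_factors=factors)
    cohort = records
    if any(r > 0 for r in config.missing_rates.values()):
        cohort = inject_missingness(
            cohort, config.missing_rates, seed=int(rng.integers(2**31))
        )
    return cohort, truth


def inject_missingness(
    cohort: list[PatientRecord], missing_rates: dict[str, float], seed: int
) -> list[PatientRecord]:
    """Flip availability masks to unavailable, independently per patient and
    modality.  Stream content is retained (only flagged).  Clinical data are
    always available in this artifact."""
    for m, r in missing_rates.items():
        if m not in MODALITIES:
            raise ValueError(f"unknown modality: {m}")
        if m == "clinical" and r > 0:
            raise ValueError("clinical modality is always available")
        if not 0 <= r <= 1:
            raise ValueError("missing rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec in cohort:
        avail = dict(rec.availability)
        for m, r in missing_rates.items():
            if r > 0 and rng.random() < r:
                avail[m] = False
        out.append(replace(rec, availability=avail))
    return out


# ---------------------------------------------------------------------------
# tabular serialization (one delimited file per stream)
# ---------------------------------------------------------------------------


def save_cohort(
    cohort: list[PatientRecord],
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    schema: ClinicalSchema | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [r.patient_id for r in cohort]
    schema = schema or default_clinical_schema()

    stream_names = sorted(cohort[0].streams)
    for s in stream_names:
        mats = np.stack([r.streams[s].values for r in cohort])  # n x t x d
        n, t, d = mats.shape
        cols = [f"t{ti}_f{fi}" for ti in range(t) for fi in range(d)]
        df = pd.DataFrame(mats.reshape(n, t * d), columns=cols)
        df.insert(0, "patient_id", ids)
        df.to_csv(out / f"stream_{s}.tsv", sep="\t", index=False)

    clin_rows = []
    for r in cohort:
        row: dict = {"patient_id": r.patient_id}
        row.update(r.clinical.continuous)
        row.update(r.clinical.categorical)
        clin_rows.append(row)
    pd.DataFrame(clin_rows).to_csv(out / "clinical.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "patient_id": ids,
            "time_months": [r.outcome.time_months for r in cohort],
            "event": [r.outcome.event for r in cohort],
        }
    ).to_csv(out / "outcomes.tsv", sep="\t", index=False)

    mask_rows = [
        {"patient_id": r.patient_id, "modality": m, "available": int(av)}
        for r in cohort
        for m, av in r.availability.items()
    ]
    pd.DataFrame(mask_rows).to_csv(out / "masks.tsv", sep="\t", index=False)

    if truth is not None:
        df = pd.DataFrame({"patient_id": ids, "true_log_risk": truth.true_log_risk})
        for m, f in truth.latent_factors.items():
            for k in range(f.shape[1]):
                df[f"latent_{m}_{k}"] = f[:, k]
        df.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    meta = {
        "streams": {
            s: {
                "n_tokens": cohort[0].streams[s].n_tokens,
                "dim": cohort[0].streams[s].dim,
            }
            for s in stream_names
        },
        "clinical_schema": schema.to_dict(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_cohort(
    in_dir: str | Path,
) -> tuple[list[PatientRecord], GroundTruth | None, ClinicalSchema]:
    src = Path(in_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in {src}")
    meta = json.loads(meta_path.read_text())
    schema = ClinicalSchema.from_dict(meta["clinical_schema"])

    try:
        outcomes = pd.read_csv(src / "outcomes.tsv", sep="\t")
    except FileNotFoundError:
        raise FileNotFoundError(f"missing outcomes table in {src}")
    for col in ("patient_id", "time_months", "event"):
        if col not in outcomes.columns:
            raise ValueError(f"outcomes table missing column '{col}'")
    ids = outcomes["patient_id"].astype(str).tolist()

    streams: dict[str, np.ndarray] = {}
    for s, info in meta["streams"].items():
        path = src / f"stream_{s}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing stream file for '{s}': {path}")
        df = pd.read_csv(path, sep="\t").set_index("patient_id")
        t, d = info["n_tokens"], info["dim"]
        streams[s] = df.loc[ids].to_numpy(dtype=np.float64).reshape(len(ids), t, d)

    clin = pd.read_csv(src / "clinical.tsv", sep="\t").set_index("patient_id").loc[ids]
    masks = pd.read_csv(src / "masks.tsv", sep="\t")
    avail_map: dict[str, dict[str, bool]] = {pid: {} for pid in ids}
    for _, row in masks.iterrows():
        avail_map[str(row["patient_id"])][row["modality"]] = bool(row["available"])

    records = []
    for i, pid in enumerate(ids):
        profile = ClinicalProfile(
            continuous={n: float(clin.loc[pid, n]) for n in schema.continuous_names},
            categorical={v.name: int(clin.loc[pid, v.name]) for v in schema.categorical},
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                streams={s: TokenMatrix(streams[s][i], s) for s in streams},
                clinical=profile,
                outcome=SurvivalOutcome(
                    float(outcomes.iloc[i]["time_months"]), int(outcomes.iloc[i]["event"])
                ),
                availability={m: avail_map[pid].get(m, True) for m in MODALITIES},
            )
        )

    truth = None
    gt_path = src / "ground_truth.tsv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t").set_index("patient_id").loc[ids]
        factors: dict[str, np.ndarray] = {}
        for m in MODALITIES:
            cols = sorted(
                (c for c in gt.columns if c.startswith(f"latent_{m}_")),
                key=lambda c: int(c.rsplit("_", 1)[1]),
            )
            if cols:
                factors[m] = gt[cols].to_numpy(dtype=np.float64)
        truth = GroundTruth(
            true_log_risk=gt["true_log_risk"].to_numpy(dtype=np.float64),
            latent_factors=factors,
        )
    return records, truth, schema
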