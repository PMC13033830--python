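"""Domain containers and feature-level encoders.

A patient is a bundle of numeric feature *streams* (pre-extracted, one token
matrix per stream), a structured clinical profile, a right-censored outcome,
and per-modality availability flags.  Three modalities group the streams:

* pathology   — ``wsi_deep`` (patch tokens), ``wsi_morph``, ``wsi_top``
                (patient-level summary vectors)
* ultrasound  — ``us_deep`` (image tokens), ``us_omic`` (radiomics),
                ``us_text`` (report embedding)
* clinical    — structured variables, encoded to tokens by
                :class:`ClinicalEncoder` (one token per variable)

The clinical modality is assumed always available; availability masks only
ever disable the two imaging modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, embedding_lookup

MODALITIES = ("pathology", "ultrasound", "clinical")

PATHOLOGY_STREAMS = ("wsi_deep", "wsi_morph", "wsi_top")
ULTRASOUND_STREAMS = ("us_deep", "us_omic", "us_text")
STREAM_NAMES = PATHOLOGY_STREAMS + ULTRASOUND_STREAMS

STREAM_MODALITY = {s: "pathology" for s in PATHOLOGY_STREAMS}
STREAM_MODALITY.update({s: "ultrasound" for s in ULTRASOUND_STREAMS})


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TokenMatrix:
    """An ``n_tokens x dim`` feature stream for one modality feature type."""

    values: np.ndarray
    stream_name: str

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError(f"{self.stream_name}: token matrix must be 2-D, n_tokens >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.stream_name}: non-finite entries")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalOutcome:
    """Right-censored follow-up: months from surgery, event = 1 for
    recurrence / metastasis / disease-related death."""

    time_months: float
    event: int

    def __post_init__(self):
        if self.time_months <= 0:
            raise ValueError("time_months must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class ClinicalProfile:
    continuous: dict[str, float]
    categorical: dict[str, int]


@dataclass
class PatientRecord:
    patient_id: str
    streams: dict[str, TokenMatrix]
    clinical: ClinicalProfile
    outcome: SurvivalOutcome
    availability: dict[str, bool] = field(
        default_factory=lambda: {m: True for m in MODALITIES}
    )


# ---------------------------------------------------------------------------
# clinical schema / encoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalVariable:
    name: str
    kind: str  # "continuous" | "categorical"
    n_categories: int = 0  # categorical only


@dataclass(frozen=True)
class ClinicalSchema:
    """Ordered variable list; order fixes the clinical token order."""

    variables: tuple[ClinicalVariable, ...]

    def __post_init__(self):
        for v in self.variables:
            if v.kind not in ("continuous", "categorical"):
                raise ValueError(f"unknown kind for {v.name}: {v.kind}")
            if v.kind == "categorical" and v.n_categories < 2:
                raise ValueError(f"{v.name}: categorical needs >= 2 categories")

    @property
    def continuous_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "continuous"]

    @property
    def categorical(self) -> list[ClinicalVariable]:
        return [v for v in self.variables if v.kind == "categorical"]

    @property
    def n_tokens(self) -> int:
        return len(self.variables)

    def to_dict(self) -> list[dict]:
        return [
            {"name": v.name, "kind": v.kind, "n_categories": v.n_categories}
            for v in self.variables
        ]

    @staticmethod
    def from_dict(items: list[dict]) -> "ClinicalSchema":
        return ClinicalSchema(
            tuple(
                ClinicalVariable(d["name"], d["kind"], d.get("n_categories", 0))
                for d in items
            )
        )


def default_clinical_schema() -> ClinicalSchema:
    """Schema mirroring routine breast-cancer clinicopathologic variables:
    two continuous, seven categorical (Ki67 as a low/high band)."""
    return ClinicalSchema(
        (
            ClinicalVariable("age_years", "continuous"),
            ClinicalVariable("tumor_size_cm", "continuous"),
            ClinicalVariable("lymph_node_status", "categorical", 3),
            ClinicalVariable("histologic_grade", "categorical", 3),
            ClinicalVariable("er_status", "categorical", 2),
            ClinicalVariable("pr_status", "categorical", 2),
            ClinicalVariable("her2_status", "categorical", 2),
            ClinicalVariable("ki67_band", "categorical", 2),
            ClinicalVariable("molecular_subtype", "categorical", 2),
        )
    )


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Affine map applied along the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(_xavier(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = Tensor.as_tensor(x).matmul(self.W)
        return y + self.b if self.b is not None else y

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.W": self.W}
        if self.b is not None:
            out[f"{prefix}.b"] = self.b
        return out


class ClinicalEncoder:
    """Encode structured clinical variables into one token per variable.

    Continuous variables go through a learnable affine map ``1 -> embed_dim``;
    categorical ones through a learnable lookup table.  Tokens are stacked in
    schema order, giving an ``n_vars x embed_dim`` matrix per patient (batched:
    ``B x n_vars x embed_dim``).
    """

    def __init__(self, schema: ClinicalSchema, embed_dim: int, rng: np.random.Generator):
        self.schema = schema
        self.embed_dim = embed_dim
        self.affine = {
            name: Linear(1, embed_dim, rng) for name in schema.continuous_names
        }
        self.tables = {
            v.name: Tensor(
                _xavier(rng, v.n_categories, embed_dim, (v.n_categories, embed_dim)),
                requires_grad=True,
            )
            for v in schema.categorical
        }

    def encode_batch(self, continuous: np.ndarray, categorical: np.ndarray) -> Tensor:
        """``continuous``: B x n_cont floats; ``categorical``: B x n_cat codes.
        Columns follow schema order within each kind."""
        from .autodiff import concat

        continuous = np.atleast_2d(np.asarray(continuous, dtype=np.float64))
        categorical = np.atleast_2d(np.asarray(categorical))
        self._check_codes(categorical)
        tokens: list[Tensor] = []
        i_cont = i_cat = 0
        for v in self.schema.variables:
            if v.kind == "continuous":
                x = Tensor(continuous[:, i_cont : i_cont + 1])  # B x 1
                tok = self.affine[v.name](x)  # B x d
                i_cont += 1
            else:
                codes = categorical[:, i_cat].astype(np.intp)
                tok = embedding_lookup(self.tables[v.name], codes)  # B x d
                i_cat += 1
            tokens.append(tok.reshape(-1, 1, self.embed_dim))
        return concat(tokens, axis=1)  # B x n_vars x d

    def encode_profile(self, profile: ClinicalProfile) -> Tensor:
        cont = np.array(
            [[profile.continuous[n] for n in self.schema.continuous_names]]
        )
        cat = np.array([[profile.categorical[v.name] for v in self.schema.categorical]])
        return self.encode_batch(cont, cat)

    def _check_codes(self, categorical: np.ndarray) -> None:
        for j, v in enumerate(self.schema.categorical):
            codes = categorical[:, j]
            bad = (codes < 0) | (codes >= v.n_categories)
            if np.any(bad):
                code = int(np.asarray(codes)[bad][0])
                raise ValueError(
                    f"out-of-vocabulary code {code} for clinical variable "
                    f"'{v.name}' (vocabulary size {v.n_categories})"
                )

    def parameters(self, prefix: str = "clinical") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, lin in self.affine.items():
            out.update(lin.parameters(f"{prefix}.affine.{name}"))
        for name, tab in self.tables.items():
            out[f"{prefix}.table.{name}"] = tab
        return out


def encode_clinical(profile: ClinicalProfile, encoder: ClinicalEncoder) -> TokenMatrix:
    """Functional wrapper: one profile -> n_vars x embed_dim token matrix."""
    toks = encoder.encode_profile(profile)
    return TokenMatrix(toks.data[0], "clinical")


def project_stream(tokens: TokenMatrix, projector: Linear) -> TokenMatrix:
    """Per-token learnable affine dimension alignment; token count preserved."""
    out = projector(Tensor(tokens.values))
    return TokenMatrix(out.data, tokens.stream_name)


# ---------------------------------------------------------------------------
# missing-modality compensation
# ---------------------------------------------------------------------------


class MissingCompensation:
    """Learnable per-modality embeddings substituted for absent fusion inputs.

    One vector per imaging modality, shaped like that modality's fused
    representation and initialized to zeros.  Selection by the availability
    mask is a convex blend ``a*f + (1-a)*e``, so the embedding receives
    gradient exactly from patients whose modality is missing.
    """

    def __init__(self, embed_dim: int, trainable: bool = True):
        self.trainable = trainable
        self.embeddings = {
            m: Tensor(np.zeros(embed_dim), requires_grad=trainable)
            for m in ("pathology", "ultrasound")
        }

    def apply(self, modality: str, fused: Tensor, avail: np.ndarray) -> Tensor:
        """``fused``: B x d modality representation; ``avail``: B floats in {0,1}."""
        emb = self.embeddings[modality]
        if emb.data.shape[-1] != fused.data.shape[-1]:
            raise ValueError(
                f"compensation embedding for {modality} has width "
                f"{emb.data.shape[-1]}, fused input has {fused.data.shape[-1]}"
            )
        a = Tensor(np.asarray(avail, dtype=np.float64).reshape(-1, 1))
        return a * fused + (Tensor(1.0) - a) * emb

    def parameters(self, prefix: str = "missing") -> dict[str, Tensor]:
        if not self.trainable:
            return {}
        return {f"{prefix}.{m}": t for m, t in self.embeddings.items()}


def apply_missing_compensation(
    fused_inputs: dict[str, Tensor],
    availability: dict[str, np.ndarray],
    comp: MissingCompensation,
) -> dict[str, Tensor]:
    """Replace unavailable modalities' fused inputs with learnable embeddings.

    Available modalities pass through unchanged (bitwise).
    """
    out: dict[str, Tensor] = {}
    for modality, fused in fused_inputs.items():
        avail = np.asarray(availability.get(modality, np.ones(fused.data.shape[0])))
        if modality in comp.embeddings and np.any(avail == 0):
            out[modality] = comp.apply(modality, fused, avail)
        else:
            out[modality] = fused
    return out


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


def cohort_to_batch(records: list[PatientRecord], schema: ClinicalSchema) -> dict:
    """Stack a cohort into dense batch arrays for the fusion network.

    Requires equal token counts per stream across patients (true for the
    synthetic generator; real cohorts would pad or bag upstream).
    """
    streams = {
        s: np.stack([r.streams[s].values for r in records])
        for s in records[0].streams
    }
    cont = np.array(
        [[r.clinical.continuous[n] for n in schema.continuous_names] for r in records]
    )
    cat = np.array(
        [[r.clinical.categorical[v.name] for v in schema.categorical] for r in records],
        dtype=np.intp,
    )
    return {
        "patient_ids": [r.patient_id for r in records],
        "streams": streams,
        "clinical_continuous": cont,
        "clinical_categorical": cat,
        "time": np.array([r.outcome.time_months for r in records]),
        "event": np.array([r.outcome.event for r in records], dtype=int),
        "availability": {
            m: np.array([float(r.availability.get(m, True)) for r in records])
            for m in MODALITIES
        },
    }
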