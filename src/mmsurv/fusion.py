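"""Hierarchical cross-attention fusion network for multimodal risk prediction.

The architecture fuses three data modalities into a scalar log-relative-hazard:

1. *Intramodality fusion* — within pathology, the query stream (patch-level
   deep features by default) attends separately to the morphological and
   topological summary streams; the two attention outputs are element-wise
   summed with the query tokens (a residual), then pooled to the modality
   vector ``f_path``.  Ultrasound is fused symmetrically (deep-feature tokens
   attending to radiomics and report-text embeddings) into ``f_us``.
2. *Intermodality fusion* — ``f_path`` and ``f_us`` are combined into
   ``f_inter`` by one of four strategies: bidirectional single-token
   cross-attention (default), affine-aligned concatenation, element-wise
   addition, or multiplication.  Dropout is applied here during training.
3. *Clinical residual fusion* — ``f_inter`` serves as a single query over the
   per-variable clinical tokens; the attention output is added back through a
   residual connection, giving ``f_final`` and (via an affine head) the risk.

Missing imaging modalities are handled either by zeroing their contribution
("ignore" baseline) or by substituting a learnable, zero-initialized
compensation embedding selected by the availability mask.

All cross-attention stages use a single head by default and record their
softmax weight matrices for interpretability export.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor, concat
from .features import (
    ClinicalEncoder,
    ClinicalSchema,
    Linear,
    MissingCompensation,
    PatientRecord,
    PATHOLOGY_STREAMS,
    ULTRASOUND_STREAMS,
    cohort_to_batch,
)

INTERMODAL_STRATEGIES = ("concat", "add", "multiply", "cross_attention")

_QUERY_ALIAS = {
    "pathology": {"deep": "wsi_deep", "morph": "wsi_morph", "top": "wsi_top"},
    "ultrasound": {"deep": "us_deep", "omic": "us_omic", "text": "us_text"},
}


@dataclass
class FusionConfig:
    """Architecture hyperparameters.

    ``wsi_query`` / ``us_query`` select which stream supplies the attention
    queries inside each modality (the remaining enabled streams serve as
    key-value pairs).  ``intermodal_strategy`` selects how the two imaging
    modality vectors are combined; ``cross_attention`` is the full model,
    the others are fusion-strategy baselines.
    """

    embed_dim: int = 1024
    n_heads: int = 1
    dropout: float = 0.2
    wsi_query: str = "deep"
    us_query: str = "deep"
    intermodal_strategy: str = "cross_attention"
    enabled_streams: tuple[str, ...] = PATHOLOGY_STREAMS + ULTRASOUND_STREAMS
    enabled_modalities: tuple[str, ...] = ("pathology", "ultrasound", "clinical")
    use_missing_compensation: bool = False
    token_pooling: str = "mean"

    def __post_init__(self):
        self.enabled_streams = tuple(self.enabled_streams)
        self.enabled_modalities = tuple(self.enabled_modalities)
        if self.embed_dim < 1 or self.n_heads < 1:
            raise ValueError("embed_dim and n_heads must be positive")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.intermodal_strategy not in INTERMODAL_STRATEGIES:
            raise ValueError(f"unknown intermodal strategy: {self.intermodal_strategy}")
        if self.token_pooling not in ("mean", "attention"):
            raise ValueError("token_pooling must be 'mean' or 'attention'")
        if not self.enabled_modalities:
            raise ValueError("at least one modality must be enabled")
        for m in self.enabled_modalities:
            if m not in ("pathology", "ultrasound", "clinical"):
                raise ValueError(f"unknown modality: {m}")
        for m, alias, query in (
            ("pathology", _QUERY_ALIAS["pathology"], self.wsi_query),
            ("ultrasound", _QUERY_ALIAS["ultrasound"], self.us_query),
        ):
            if query not in alias:
                raise ValueError(f"invalid {m} query: {query}")
            if m in self.enabled_modalities:
                q_stream = alias[query]
                enabled = self.modality_streams(m)
                if not enabled:
                    raise ValueError(f"{m} enabled but all its streams disabled")
                if q_stream not in enabled:
                    raise ValueError(
                        f"{m} query stream '{q_stream}' is disabled; "
                        "reassign the query or drop the modality"
                    )

    def modality_streams(self, modality: str) -> tuple[str, ...]:
        base = PATHOLOGY_STREAMS if modality == "pathology" else ULTRASOUND_STREAMS
        return tuple(s for s in base if s in self.enabled_streams)

    def query_stream(self, modality: str) -> str:
        q = self.wsi_query if modality == "pathology" else self.us_query
        return _QUERY_ALIAS[modality][q]


@dataclass
class FusedRepresentation:
    f_path: np.ndarray | None
    f_us: np.ndarray | None
    f_inter: np.ndarray
    f_final: np.ndarray
    risk: float
    attention_records: list[tuple[str, np.ndarray]] = field(default_factory=list)


class CrossAttention:
    """Scaled dot-product cross-attention with learnable Q/K/V/output maps."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.dim = dim
        self.n_heads = n_heads
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, queries: Tensor, keys_values: Tensor) -> Tensor:
        if queries.shape[-1] != self.dim or keys_values.shape[-1] != self.dim:
            raise ValueError(
                f"cross-attention expects width {self.dim}, got "
                f"{queries.shape[-1]} / {keys_values.shape[-1]}"
            )
        q, k, v = self.Wq(queries), self.Wk(keys_values), self.Wv(keys_values)
        dh = self.dim // self.n_heads
        outs, weights = [], []
        for h in range(self.n_heads):
            qh = q.slice_last(h * dh, (h + 1) * dh)
            kh = k.slice_last(h * dh, (h + 1) * dh)
            vh = v.slice_last(h * dh, (h + 1) * dh)
            scores = qh.matmul(kh.transpose_last()) * (1.0 / np.sqrt(dh))
            attn = scores.softmax(axis=-1)
            weights.append(attn.data)
            outs.append(attn.matmul(vh))
        self.last_weights = np.mean(weights, axis=0)
        merged = outs[0] if self.n_heads == 1 else concat(outs, axis=-1)
        return self.Wo(merged)

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, lin in (("Wq", self.Wq), ("Wk", self.Wk), ("Wv", self.Wv), ("Wo", self.Wo)):
            out.update(lin.parameters(f"{prefix}.{name}"))
        return out


def cross_attention_block(
    queries: np.ndarray, keys_values: np.ndarray, block: CrossAttention
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: run one attention block on plain arrays.

    Returns (output tokens, attention weights); weights rows sum to 1.
    """
    q = Tensor(np.asarray(queries, dtype=np.float64))
    kv = Tensor(np.asarray(keys_values, dtype=np.float64))
    out = block(q, kv)
    return out.data, block.last_weights


class MultimodalRiskModel:
    """End-to-end trainable fusion network mapping patient feature bundles to
    a scalar log-relative-hazard."""

    def __init__(
        self,
        config: FusionConfig,
        schema: ClinicalSchema,
        stream_dims: dict[str, int],
        seed: int = 0,
    ):
        config.__post_init__()  # re-validate in case of mutation
        self.config = config
        self.schema = schema
        self.stream_dims = dict(stream_dims)
        self.seed = seed
        rng = np.random.default_rng([seed, 104729])
        d = config.embed_dim

        # per-stream dimension alignment (token count preserved)
        self.projectors = {
            s: Linear(stream_dims[s], d, rng)
            for s in sorted(stream_dims)
            if s in config.enabled_streams
        }

        # intramodality cross-attention, keyed by the key-value stream so the
        # same module serves any query assignment
        self.intra_ca: dict[str, CrossAttention] = {}
        for modality in ("pathology", "ultrasound"):
            for s in (PATHOLOGY_STREAMS if modality == "pathology" else ULTRASOUND_STREAMS):
                if s in config.enabled_streams:
                    self.intra_ca[s] = CrossAttention(d, config.n_heads, rng)

        # attention pooling scores (used only when token_pooling == "attention")
        self.pool_score = {
            m: Linear(d, 1, rng, bias=False) for m in ("pathology", "ultrasound")
        }

        # intermodality fusion
        self.align_path = Linear(d, d, rng)
        self.align_us = Linear(d, d, rng)
        self.concat_proj = Linear(2 * d, d, rng)
        self.ca_path_to_us = CrossAttention(d, config.n_heads, rng)
        self.ca_us_to_path = CrossAttention(d, config.n_heads, rng)

        # clinical
        self.clinical_encoder = ClinicalEncoder(schema, d, rng)
        self.ca_clinical = CrossAttention(d, config.n_heads, rng)

        self.compensation = MissingCompensation(
            d, trainable=config.use_missing_compensation
        )
        self.risk_head = Linear(d, 1, rng)

    # -- parameters ---------------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for s, lin in self.projectors.items():
            out.update(lin.parameters(f"proj.{s}"))
        for s, ca in self.intra_ca.items():
            out.update(ca.parameters(f"intra.{s}"))
        for m, lin in self.pool_score.items():
            out.update(lin.parameters(f"pool.{m}"))
        out.update(self.align_path.parameters("inter.align_path"))
        out.update(self.align_us.parameters("inter.align_us"))
        out.update(self.concat_proj.parameters("inter.concat_proj"))
        out.update(self.ca_path_to_us.parameters("inter.ca_path_to_us"))
        out.update(self.ca_us_to_path.parameters("inter.ca_us_to_path"))
        out.update(self.clinical_encoder.parameters("clinical"))
        out.update(self.ca_clinical.parameters("clinical.ca"))
        out.update(self.compensation.parameters("missing"))
        out.update(self.risk_head.parameters("risk_head"))
        return out

    # -- stages -------------------------------------------------------------
    def _pool(self, tokens: Tensor, modality: str) -> Tensor:
        if self.config.token_pooling == "mean":
            return tokens.mean(axis=1)
        scores = self.pool_score[modality](tokens)  # B x n x 1
        alpha = scores.softmax(axis=1)
        return (alpha * tokens).sum(axis=1)

    def _fuse_modality(
        self, modality: str, streams: dict[str, np.ndarray], records: list | None
    ) -> Tensor:
        enabled = self.config.modality_streams(modality)
        q_name = self.config.query_stream(modality)
        q_tokens = self.projectors[q_name](Tensor(streams[q_name]))
        out = q_tokens
        for kv_name in enabled:
            if kv_name == q_name:
                continue
            kv_tokens = self.projectors[kv_name](Tensor(streams[kv_name]))
            ca = self.intra_ca[kv_name]
            out = out + ca(q_tokens, kv_tokens)
            if records is not None:
                records.append((f"intra.{modality}.{kv_name}", ca.last_weights))
        return self._pool(out, modality)

    def fuse_pathology(self, streams, records=None) -> Tensor:
        """Query stream + sum of its cross-attention views, pooled to f_path."""
        return self._fuse_modality("pathology", streams, records)

    def fuse_ultrasound(self, streams, records=None) -> Tensor:
        return self._fuse_modality("ultrasound", streams, records)

    def fuse_intermodal(
        self,
        f_path: Tensor | None,
        f_us: Tensor | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        records: list | None = None,
    ) -> Tensor:
        cfg = self.config
        if f_path is not None and f_us is not None:
            if cfg.intermodal_strategy == "cross_attention":
                p_tok = f_path.reshape(-1, 1, cfg.embed_dim)
                u_tok = f_us.reshape(-1, 1, cfg.embed_dim)
                a = self.ca_path_to_us(p_tok, u_tok)
                if records is not None:
                    records.append(("inter.path_to_us", self.ca_path_to_us.last_weights))
                b = self.ca_us_to_path(u_tok, p_tok)
                if records is not None:
                    records.append(("inter.us_to_path", self.ca_us_to_path.last_weights))
                f_inter = (a + b).reshape(-1, cfg.embed_dim)
            else:
                fp = self.align_path(f_path)
                fu = self.align_us(f_us)
                if cfg.intermodal_strategy == "concat":
                    f_inter = self.concat_proj(concat([fp, fu], axis=-1))
                elif cfg.intermodal_strategy == "add":
                    f_inter = fp + fu
                else:  # multiply
                    f_inter = fp * fu
        elif f_path is not None:
            f_inter = self.align_path(f_path)
        elif f_us is not None:
            f_inter = self.align_us(f_us)
        else:
            raise ValueError("intermodal fusion needs at least one imaging modality")
        if training and cfg.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            f_inter = f_inter.dropout(cfg.dropout, rng, training=True)
        return f_inter

    def fuse_clinical_residual(
        self, f_inter: Tensor, clinical_tokens: Tensor, records: list | None = None
    ) -> Tensor:
        q = f_inter.reshape(-1, 1, self.config.embed_dim)
        attended = self.ca_clinical(q, clinical_tokens)
        if records is not None:
            records.append(("clinical", self.ca_clinical.last_weights))
        return f_inter + attended.reshape(-1, self.config.embed_dim)

    # -- full forward --------------------------------------------------------
    def forward_batch(
        self,
        batch: dict,
        training: bool = False,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> dict:
        cfg = self.config
        records: list | None = [] if collect_attention else None
        avail = batch["availability"]

        f_path = f_us = None
        if "pathology" in cfg.enabled_modalities:
            f_path = self.fuse_pathology(batch["streams"], records)
            f_path = self._mask_or_compensate("pathology", f_path, avail["pathology"])
        if "ultrasound" in cfg.enabled_modalities:
            f_us = self.fuse_ultrasound(batch["streams"], records)
            f_us = self._mask_or_compensate("ultrasound", f_us, avail["ultrasound"])

        clinical_tokens = None
        if "clinical" in cfg.enabled_modalities:
            clinical_tokens = self.clinical_encoder.encode_batch(
                batch["clinical_continuous"], batch["clinical_categorical"]
            )

        if f_path is None and f_us is None:
            # clinical-only baseline: pooled clinical tokens drive the head
            f_inter = clinical_tokens.mean(axis=1)
            f_final = f_inter
        else:
            f_inter = self.fuse_intermodal(f_path, f_us, training, rng, records)
            if clinical_tokens is not None:
                f_final = self.fuse_clinical_residual(f_inter, clinical_tokens, records)
            else:
                f_final = f_inter

        risk = self.risk_head(f_final).reshape(-1)
        return {
            "risk": risk,
            "f_path": f_path,
            "f_us": f_us,
            "f_inter": f_inter,
            "f_final": f_final,
            "attention_records": records or [],
        }

    def _mask_or_compensate(self, modality: str, fused: Tensor, avail) -> Tensor:
        avail = np.asarray(avail, dtype=np.float64)
        if np.all(avail == 1.0):
            return fused
        a = Tensor(avail.reshape(-1, 1))
        if self.config.use_missing_compensation:
            return self.compensation.apply(modality, fused, avail)
        return a * fused  # ignore baseline: missing contribution zeroed

    def forward(self, record: PatientRecord, collect_attention: bool = True) -> FusedRepresentation:
        batch = cohort_to_batch([record], self.schema)
        out = self.forward_batch(batch, training=False, collect_attention=collect_attention)
        return FusedRepresentation(
            f_path=None if out["f_path"] is None else out["f_path"].data[0],
            f_us=None if out["f_us"] is None else out["f_us"].data[0],
            f_inter=out["f_inter"].data[0],
            f_final=out["f_final"].data[0],
            risk=float(out["risk"].data[0]),
            attention_records=[(s, w[0]) for s, w in out["attention_records"]],
        )

    def predict_risk(self, batch: dict) -> np.ndarray:
        """Evaluation-mode risks for a stacked batch (deterministic)."""
        return self.forward_batch(batch, training=False)["risk"].data.copy()

    # -- attention export -----------------------------------------------------
    def export_attention(self, batch: dict) -> pd.DataFrame:
        """Long-format attention table (patient_id, stage, token, weight).

        For the clinical stage the token column carries variable names, giving
        an attention-based variable-importance ranking.
        """
        out = self.forward_batch(batch, collect_attention=True)
        var_names = [v.name for v in self.schema.variables]
        rows = []
        for stage, weights in out["attention_records"]:
            w = np.asarray(weights)  # B x nq x nk
            mean_over_queries = w.mean(axis=1)  # B x nk
            for i, pid in enumerate(batch["patient_ids"]):
                for j in range(mean_over_queries.shape[1]):
                    token = var_names[j] if stage == "clinical" else str(j)
                    rows.append(
                        {
                            "patient_id": pid,
                            "stage": stage,
                            "token": token,
                            "weight": mean_over_queries[i, j],
                        }
                    )
        return pd.DataFrame(rows)

    # -- checkpointing ---------------------------------------------------------
    def config_snapshot(self) -> dict:
        return {
            "fusion_config": asdict(self.config),
            "stream_dims": self.stream_dims,
            "clinical_schema": self.schema.to_dict(),
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        params = {k: v.data for k, v in self.named_parameters().items()}
        snap = json.dumps(self.config_snapshot()).encode()
        np.savez(path, __config__=np.frombuffer(snap, dtype=np.uint8), **params)

    @classmethod
    def load(cls, path: str | Path) -> "MultimodalRiskModel":
        with np.load(path) as archive:
            snap = json.loads(bytes(archive["__config__"].tobytes()).decode())
            params = {k: archive[k] for k in archive.files if k != "__config__"}
        cfg = FusionConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in snap["fusion_config"].items()
        })
        model = cls(
            cfg,
            ClinicalSchema.from_dict(snap["clinical_schema"]),
            snap["stream_dims"],
            seed=snap["seed"],
        )
        own = model.named_parameters()
        if set(own) != set(params):
            raise ValueError("checkpoint parameter names do not match architecture")
        for k, v in params.items():
            own[k].data = np.array(v, dtype=np.float64)
        return model
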