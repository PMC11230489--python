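"""Inference-cost budgeting: closed-form FLOPs and GPU-time projection.

The per-sentence inference cost of a decoder-only transformer is
estimated with the standard forward-pass approximation

    FLOPs = n_tokens_out × (2·N + 2·n_layer·n_ctx·d_attn)

where ``N`` is the total parameter count, ``n_layer`` the number of
layers, ``n_ctx`` the input context length in tokens (estimated from
the rendered prompt template), ``d_attn`` the attention output
dimension, and ``n_tokens_out`` the number of generated tokens.  Total
GPU time for a large corpus is projected by ordinary least squares on
(number of notes, GPU seconds) timing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_DOWN
from typing import Sequence

import numpy as np

from .corpus_io import regex_tokenize

__all__ = [
    "ModelProfile",
    "TimingSample",
    "flops_per_sentence",
    "format_flops",
    "estimate_ctx_tokens",
    "project_gpu_time",
]


@dataclass(frozen=True)
class ModelProfile:
    """Architecture constants entering the FLOPs estimate."""

    n_params: int
    n_layer: int
    n_ctx: int
    d_attn: int
    n_tokens_out: int

    def __post_init__(self) -> None:
        for name in ("n_params", "n_layer", "n_ctx", "d_attn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_tokens_out < 0:
            raise ValueError("n_tokens_out must be non-negative")


@dataclass(frozen=True)
class TimingSample:
    n_notes: int
    gpu_seconds: float

    def __post_init__(self) -> None:
        if self.n_notes < 0 or self.gpu_seconds < 0:
            raise ValueError("timing samples must be non-negative")


def flops_per_sentence(profile: ModelProfile) -> int:
    """Exact integer FLOPs for generating one sentence's output."""
    return profile.n_tokens_out * (
        2 * profile.n_params
        + 2 * profile.n_layer * profile.n_ctx * profile.d_attn
    )


def format_flops(flops: int, sig: int = 4) -> str:
    """Scientific rendering at *sig* significant digits, truncated toward
    zero (3348838481920 → ``3.348e+12``)."""
    if flops == 0:
        return f"{0:.{sig - 1}e}"
    d = Decimal(flops)
    exp = d.adjusted()
    mantissa = d.scaleb(-exp).quantize(
        Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_DOWN
    )
    sign = "+" if exp >= 0 else "-"
    return f"{mantissa}e{sign}{abs(exp):02d}"


def estimate_ctx_tokens(rendered_prompt: str) -> int:
    """Estimate the context length of a rendered prompt in tokens using the
    package word tokenizer (a proxy for the model's subword count)."""
    return len(regex_tokenize(rendered_prompt))


def project_gpu_time(
    samples: Sequence[TimingSample], target_notes: int
) -> tuple[float, float, float]:
    """OLS line through (n_notes, gpu_seconds); returns
    ``(slope, intercept, predicted_seconds_at_target)``."""
    if len(samples) < 2:
        raise ValueError("need at least two timing samples")
    x = np.array([s.n_notes for s in samples], dtype=float)
    y = np.array([s.gpu_seconds for s in samples], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("timing samples must vary in n_notes")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), float(slope * target_notes + intercept)
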