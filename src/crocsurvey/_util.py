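"""Small shared helpers: reporting-grade rounding and seed derivation."""
from __future__ import annotations

import decimal

import numpy as np

__all__ = ["round_half_up", "child_seed", "sigmoid", "logit"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used in all report tables.

    Python's built-in ``round`` is banker's rounding; report tables follow
    the usual field convention (0.125 -> 0.13 at 2 decimals).
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def child_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from one master seed.

    The derivation spawns a ``SeedSequence`` keyed on the stage name so each
    pipeline stage is independently reproducible: the stage name is hashed
    to a bounded integer and combined with the master seed.
    """
    stage_key = int.from_bytes(stage.encode("utf-8"), "big") % (2**31)
    return np.random.SeedSequence([int(master_seed) % (2**31), stage_key])


def sigmoid(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)
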