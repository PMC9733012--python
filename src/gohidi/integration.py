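"""Combine subjective (FAHP) and objective (EWM) weights.

The integrated weight is the convex combination

    W_int = beta * W_subj + (1 - beta) * W_obj,   beta in [0, 1],

where beta is chosen to minimize the sum of squared deviations of the
integrated weight from each component:

    Z(beta) = sum_k [ (W_int,k - W_subj,k)^2 + (W_int,k - W_obj,k)^2 ].

Since W_int - W_subj = (beta - 1) d_k and W_int - W_obj = beta d_k with
d_k = W_subj,k - W_obj,k, Z(beta) = [(1-beta)^2 + beta^2] * sum d_k^2, so
the minimizer is beta = 0.5 whenever the two vectors differ at all; when
they coincide the objective is flat and 0.5 is returned by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import AlignmentError
from .fahp import WeightVector


class BetaResult(NamedTuple):
    """Outcome of the squared-deviation minimization."""

    beta: float
    objective_value: float
    flat_objective: bool

    def __float__(self) -> float:
        return self.beta


@dataclass
class IntegratedWeights:
    """Per-group integrated weights with their two parents."""

    group_code: str
    indicators: list[str]
    beta: float
    subjective: np.ndarray   # FAHP weights
    objective: np.ndarray    # EWM weights
    integrated: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fahp_weight": self.subjective,
                "ewm_weight": self.objective,
                "integrated_weight": self.integrated,
            },
            index=self.indicators,
        )


def _coerce(w, name: str) -> tuple[np.ndarray, list[str] | None, str | None]:
    if isinstance(w, WeightVector):
        return np.asarray(w.weights, dtype=float), list(w.indicators), w.group_code
    if isinstance(w, pd.Series):
        return w.to_numpy(dtype=float), [str(i) for i in w.index], None
    arr = np.asarray(w, dtype=float)
    if arr.ndim != 1:
        raise AlignmentError(f"{name} must be a 1-D weight vector")
    return arr, None, None


def integrate_weights(
    subjective,
    objective,
    beta: float = 0.5,
    normalized_tol: float = 1e-6,
) -> IntegratedWeights:
    """Elementwise convex combination of two aligned weight vectors.

    Accepts :class:`~gohidi.fahp.WeightVector`, pandas Series or plain
    arrays; when both sides carry indicator labels they must agree. With
    the default beta = 0.5 the result is the arithmetic mean of the two
    vectors, and it sums to 1 whenever both inputs do.
    """
    ws, idx_s, group_s = _coerce(subjective, "subjective")
    wo, idx_o, group_o = _coerce(objective, "objective")
    if len(ws) != len(wo):
        raise AlignmentError(f"length mismatch: {len(ws)} vs {len(wo)}")
    if idx_s is not None and idx_o is not None and idx_s != idx_o:
        raise AlignmentError(
            f"indicator order mismatch: {idx_s} vs {idx_o}"
        )
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    for name, w in (("subjective", ws), ("objective", wo)):
        if abs(w.sum() - 1.0) > normalized_tol:
            raise ValueError(f"{name} weights sum to {w.sum():.6f}, expected 1")
    indicators = idx_s or idx_o or [str(k) for k in range(len(ws))]
    return IntegratedWeights(
        group_code=group_s or group_o or "",
        indicators=indicators,
        beta=beta,
        subjective=ws,
        objective=wo,
        integrated=beta * ws + (1.0 - beta) * wo,
    )


def deviation_objective(beta: float, subjective, objective) -> float:
    """Z(beta): summed squared deviations of the blend from both parents."""
    ws, _, _ = _coerce(subjective, "subjective")
    wo, _, _ = _coerce(objective, "objective")
    blend = beta * ws + (1.0 - beta) * wo
    return float(((blend - ws) ** 2).sum() + ((blend - wo) ** 2).sum())


def optimal_beta(subjective, objective) -> BetaResult:
    """Minimize Z(beta) over [0, 1] numerically.

    Returns 0.5 for any pair of distinct normalized weight vectors; for
    identical vectors the objective is identically zero and 0.5 is returned
    with ``flat_objective=True``.
    """
    ws, idx_s, _ = _coerce(subjective, "subjective")
    wo, idx_o, _ = _coerce(objective, "objective")
    if len(ws) != len(wo):
        raise AlignmentError(f"length mismatch: {len(ws)} vs {len(wo)}")
    if idx_s is not None and idx_o is not None and idx_s != idx_o:
        raise AlignmentError(f"indicator order mismatch: {idx_s} vs {idx_o}")
    if np.allclose(ws, wo):
        return BetaResult(beta=0.5, objective_value=0.0, flat_objective=True)
    res = minimize_scalar(
        deviation_objective,
        bounds=(0.0, 1.0),
        args=(ws, wo),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return BetaResult(
        beta=float(res.x), objective_value=float(res.fun), flat_objective=False
    )


# ---------------------------------------------------------------------------
# Report-table helpers


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    scale = 10**decimals
    return np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)


def integrate_table(
    table: pd.DataFrame,
    beta: float = 0.5,
    fahp_col: str = "fahp_weight",
    ewm_col: str = "ewm_weight",
    out_col: str = "integrated_weight",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Add an integrated-weight column to a weight table (percent scale).

    Mirrors the published framework-table layout: per-row convex
    combination of the FAHP and EWM percentage columns. With ``group_col``
    set (or codes like ``"1.2"`` in a ``code`` column), rows are treated
    group by group; the combination itself is row-local either way.
    """
    for col in (fahp_col, ewm_col):
        if col not in table.columns:
            raise AlignmentError(f"table is missing column {col!r}")
    out = table.copy()
    out[out_col] = beta * out[fahp_col].astype(float) + (1.0 - beta) * out[
        ewm_col
    ].astype(float)
    return out


def sibling_groups_from_codes(codes: Sequence[str]) -> dict[str, list[str]]:
    """Group dotted codes by their parent prefix (e.g. "1.2" -> parent "1")."""
    groups: dict[str, list[str]] = {}
    for code in codes:
        parent = ".".join(str(code).split(".")[:-1])
        groups.setdefault(parent, []).append(str(code))
    return groups
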