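"""Subjective weighting from expert pairwise comparisons (fuzzy AHP).

Each expert compares every unordered pair of second-level indicators within
one first-level group, yielding an a x a judgment matrix R = (r_ie) where
r_ie is the importance of indicator i relative to indicator e. Two matrix
conventions are supported:

* ``reciprocal`` — ratio judgments on the Saaty 1–9 scale, r_ie * r_ei = 1,
  diagonal 1;
* ``complementary`` — fuzzy 0.1–0.9 preference degrees, r_ie + r_ei = 1,
  diagonal 0.5 (converted to ratio form b_ie = r_ie / r_ei before weighting).

The priority vector is the vector of row geometric means, normalized:

    omega_i = (prod_e r_ie)^(1/a) / sum_k (prod_e r_ke)^(1/a)
    W_i     = omega_i / sum_e omega_e

(the second normalization is idempotent after the first, and is kept for
fidelity to the published procedure). Panel consensus is taken by pooling
the expert matrices element-wise — geometric mean on the reciprocal scale
(preserves reciprocity), arithmetic mean on the complementary scale
(preserves complementarity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    CompletenessError,
    FormatError,
    ScaleError,
)

RECIPROCAL = "reciprocal"
COMPLEMENTARY = "complementary"

#: Saaty scale bounds for ratio judgments.
RECIPROCAL_BOUNDS = (1.0 / 9.0, 9.0)
#: Fuzzy preference-degree bounds.
COMPLEMENTARY_BOUNDS = (0.1, 0.9)

#: Random consistency index (Saaty) by matrix order; order <= 2 is always
#: consistent.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56,
    14: 1.57, 15: 1.59,
}

_CLIP = (1e-6, 1e6)


@dataclass(frozen=True)
class ComparisonResponse:
    """One questionnaire answer: indicator ``first`` vs ``second``.

    ``value`` is the stated importance of ``first`` relative to ``second``
    on the chosen scale.
    """

    expert_id: str
    group_code: str
    first: str
    second: str
    value: float


@dataclass
class JudgmentMatrix:
    """Pairwise-comparison matrix for one sibling group and one expert."""

    group_code: str
    indicators: list[str]
    values: np.ndarray
    scale: str = RECIPROCAL
    expert_id: str = "consensus"

    @property
    def order(self) -> int:
        return len(self.indicators)

    def check(self, atol: float = 1e-8) -> None:
        a = self.order
        v = self.values
        if v.shape != (a, a):
            raise ScaleError(f"matrix shape {v.shape} != ({a}, {a})")
        if self.scale == RECIPROCAL:
            if np.any(v <= 0):
                raise ScaleError("reciprocal matrix entries must be positive")
            if not np.allclose(v * v.T, 1.0, atol=atol):
                raise ScaleError("reciprocity r_ie * r_ei = 1 violated")
            if not np.allclose(np.diag(v), 1.0, atol=atol):
                raise ScaleError("reciprocal diagonal must be 1")
        elif self.scale == COMPLEMENTARY:
            if not np.allclose(v + v.T, 1.0, atol=atol):
                raise ScaleError("complementarity r_ie + r_ei = 1 violated")
            if not np.allclose(np.diag(v), 0.5, atol=atol):
                raise ScaleError("complementary diagonal must be 0.5")
            lo, hi = COMPLEMENTARY_BOUNDS
            if np.any(v < lo - atol) or np.any(v > hi + atol):
                raise ScaleError(f"entries outside [{lo}, {hi}]")
        else:
            raise ScaleError(f"unknown scale {self.scale!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.indicators, columns=self.indicators)


@dataclass
class WeightVector:
    """Normalized priority vector W for one sibling group."""

    group_code: str
    indicators: list[str]
    raw: np.ndarray        # omega_i, already normalized by construction
    weights: np.ndarray    # W_i

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.indicators, name=self.group_code)


def _scale_bounds(scale: str) -> tuple[float, float]:
    if scale == RECIPROCAL:
        return RECIPROCAL_BOUNDS
    if scale == COMPLEMENTARY:
        return COMPLEMENTARY_BOUNDS
    raise ScaleError(f"unknown scale {scale!r}")


def build_judgment_matrix(
    responses: Iterable[ComparisonResponse],
    indicators: Sequence[str] | None = None,
    scale: str = RECIPROCAL,
) -> JudgmentMatrix:
    """Assemble one expert's judgment matrix from questionnaire responses.

    ``responses`` must belong to a single expert and group and cover every
    unordered indicator pair exactly once; the mirror entry and the diagonal
    are filled by the scale law. ``indicators`` fixes column order (defaults
    to first-appearance order).
    """
    responses = list(responses)
    if not responses:
        raise CompletenessError("no responses supplied")
    experts = {r.expert_id for r in responses}
    groups = {r.group_code for r in responses}
    if len(experts) != 1 or len(groups) != 1:
        raise CompletenessError(
            f"responses span experts {sorted(experts)} and groups {sorted(groups)}; "
            "expected exactly one of each"
        )
    lo, hi = _scale_bounds(scale)

    if indicators is None:
        seen: dict[str, None] = {}
        for r in responses:
            seen.setdefault(r.first)
            seen.setdefault(r.second)
        indicators = list(seen)
    index = {code: k for k, code in enumerate(indicators)}
    a = len(indicators)

    values = np.full((a, a), np.nan)
    np.fill_diagonal(values, 1.0 if scale == RECIPROCAL else 0.5)
    for r in responses:
        if r.first == r.second:
            raise CompletenessError(f"self-comparison {r.first!r}")
        if r.first not in index or r.second not in index:
            raise CompletenessError(f"unknown indicator in pair ({r.first}, {r.second})")
        if not lo - 1e-12 <= r.value <= hi + 1e-12:
            raise ValueError(
                f"value {r.value} outside {scale} scale bounds [{lo}, {hi}]"
            )
        i, e = index[r.first], index[r.second]
        if not np.isnan(values[i, e]):
            raise CompletenessError(f"duplicate pair ({r.first}, {r.second})")
        values[i, e] = r.value
        values[e, i] = 1.0 / r.value if scale == RECIPROCAL else 1.0 - r.value
    if np.isnan(values).any():
        missing = [
            f"({indicators[i]}, {indicators[e]})"
            for i in range(a)
            for e in range(i + 1, a)
            if np.isnan(values[i, e])
        ]
        raise CompletenessError(f"missing pairs: {', '.join(missing)}")

    matrix = JudgmentMatrix(
        group_code=responses[0].group_code,
        indicators=list(indicators),
        values=values,
        scale=scale,
        expert_id=responses[0].expert_id,
    )
    matrix.check()
    return matrix


def aggregate_judgments(matrices: Sequence[JudgmentMatrix]) -> JudgmentMatrix:
    """Pool expert matrices into one consensus matrix.

    Element-wise geometric mean on the reciprocal scale, arithmetic mean on
    the complementary scale; either preserves its scale's pairing law.
    """
    if not matrices:
        raise AggregationError("no matrices to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if (
            m.group_code != first.group_code
            or m.indicators != first.indicators
            or m.scale != first.scale
            or m.values.shape != first.values.shape
        ):
            raise AggregationError(
                "matrices disagree on group, indicator order, scale or size"
            )
    stack = np.stack([m.values for m in matrices])
    if first.scale == RECIPROCAL:
        consensus = np.exp(np.mean(np.log(stack), axis=0))
    else:
        consensus = np.mean(stack, axis=0)
    out = JudgmentMatrix(
        group_code=first.group_code,
        indicators=list(first.indicators),
        values=consensus,
        scale=first.scale,
        expert_id="consensus",
    )
    out.check()
    return out


def fahp_weights(matrix: JudgmentMatrix) -> WeightVector:
    """Priority vector by normalized row geometric means.

    Complementary-scale matrices are first converted to ratio form via
    b_ie = r_ie / r_ei. Entries are clipped to [1e-6, 1e6] before the log
    transform (with a warning) to guard against degenerate inputs.
    """
    v = matrix.values.astype(float)
    if matrix.scale == COMPLEMENTARY:
        v = v / v.T
    elif matrix.scale != RECIPROCAL:
        raise ScaleError(f"unknown scale {matrix.scale!r}")
    if np.any(v <= 0):
        raise ValueError("judgment matrix entries must be positive")
    if np.any(v < _CLIP[0]) or np.any(v > _CLIP[1]):
        warnings.warn("extreme judgment values clipped before weighting", stacklevel=2)
        v = np.clip(v, *_CLIP)

    row_gm = np.exp(np.mean(np.log(v), axis=1))
    omega = row_gm / row_gm.sum()
    weights = omega / omega.sum()  # idempotent renormalization, kept as stated
    return WeightVector(
        group_code=matrix.group_code,
        indicators=list(matrix.indicators),
        raw=omega,
        weights=weights,
    )


def consistency_ratio(matrix: JudgmentMatrix) -> float:
    """Eigenvalue consistency ratio CR = CI / RI of a reciprocal matrix.

    CI = (lambda_max - a) / (a - 1); RI is the tabulated random index for
    order a. Perfectly consistent matrices (r_ie = w_i / w_e) give 0;
    matrices of order <= 2 are always consistent.
    """
    if matrix.scale != RECIPROCAL:
        raise ScaleError("consistency ratio is defined for reciprocal matrices only")
    matrix.check()
    a = matrix.order
    if a <= 2:
        return 0.0
    lam = float(np.max(np.linalg.eigvals(matrix.values).real))
    ci = (lam - a) / (a - 1)
    ri = RANDOM_INDEX.get(a)
    if ri is None:
        raise ValueError(f"no random index tabulated for order {a}")
    return max(ci, 0.0) / ri


# ---------------------------------------------------------------------------
# Questionnaire I/O

QUESTIONNAIRE_COLUMNS = ["expert_id", "group_code", "indicator_i", "indicator_e", "value"]


def read_questionnaire(path: str | Path) -> list[ComparisonResponse]:
    """Read a long-format questionnaire CSV.

    Columns: ``expert_id, group_code, indicator_i, indicator_e, value``; one
    row per expert per unordered pair.
    """
    try:
        df = pd.read_csv(path, dtype={"expert_id": str, "group_code": str})
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read questionnaire {path}: {exc}") from exc
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"questionnaire missing columns: {missing}")
    return [
        ComparisonResponse(
            expert_id=str(row.expert_id),
            group_code=str(row.group_code),
            first=str(row.indicator_i),
            second=str(row.indicator_e),
            value=float(row.value),
        )
        for row in df.itertuples()
    ]


def write_questionnaire(
    responses: Iterable[ComparisonResponse], path: str | Path
) -> Path:
    df = pd.DataFrame(
        [
            (r.expert_id, r.group_code, r.first, r.second, r.value)
            for r in responses
        ],
        columns=QUESTIONNAIRE_COLUMNS,
    )
    df.to_csv(path, index=False)
    return Path(path)


def panel_weights(
    responses: Iterable[ComparisonResponse],
    scale: str = RECIPROCAL,
    indicators_by_group: dict[str, Sequence[str]] | None = None,
    per_expert_average: bool = False,
) -> dict[str, WeightVector]:
    """Full questionnaire -> per-group consensus weights.

    Default route: pool each group's expert matrices (geometric mean), then
    weight the consensus. With ``per_expert_average=True``, weight each
    expert's matrix and arithmetically average the weight vectors instead —
    a sensitivity-check mode.
    """
    by_group: dict[str, dict[str, list[ComparisonResponse]]] = {}
    for r in responses:
        by_group.setdefault(r.group_code, {}).setdefault(r.expert_id, []).append(r)

    out: dict[str, WeightVector] = {}
    for group_code in sorted(by_group):
        order = None
        if indicators_by_group and group_code in indicators_by_group:
            order = list(indicators_by_group[group_code])
        matrices = [
            build_judgment_matrix(rs, indicators=order, scale=scale)
            for _, rs in sorted(by_group[group_code].items())
        ]
        order = matrices[0].indicators
        for m in matrices:
            if m.indicators != order:
                raise AggregationError(
                    f"group {group_code}: experts disagree on indicator order; "
                    "pass indicators_by_group to fix it"
                )
        if per_expert_average:
            ws = np.mean([fahp_weights(m).weights for m in matrices], axis=0)
            ws = ws / ws.sum()
            out[group_code] = WeightVector(group_code, list(order), ws, ws)
        else:
            out[group_code] = fahp_weights(aggregate_judgments(matrices))
    return out
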