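"""Objective weighting by the entropy weight method (EWM).

Given m evaluated entities (countries, regions, ...) and n indicators, the
raw matrix X = (x_ij) is min–max standardized per indicator, respecting its
orientation (benefit: larger is better; cost: smaller is better):

    benefit:  r_ij = (x_ij - x_jmin) / (x_jmax - x_jmin)
    cost:     r_ij = (x_jmax - x_ij) / (x_jmax - x_jmin)

Each standardized column is turned into a share distribution
P_ij = r_ij / sum_i r_ij, whose Shannon entropy (normalized by ln m)

    e_j = -(1 / ln m) * sum_i P_ij ln P_ij        (0 * ln 0 := 0)

measures how uniform the indicator is across entities. Indicators that vary
more carry more information and receive larger weights:

    W_j = (1 - e_j) / sum_k (1 - e_k)

Entropies are bounded by construction: 0 <= e_j <= 1. Weights are computed
independently within each sibling group of the framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

BENEFIT = "benefit"
COST = "cost"


@dataclass
class IndicatorDataMatrix:
    """m entities x n indicators of raw values plus per-indicator orientation.

    ``values`` is a DataFrame indexed by entity id with indicator codes as
    columns; ``orientations`` maps every column to ``"benefit"`` or
    ``"cost"``.
    """

    values: pd.DataFrame
    orientations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = self.values.copy()
        missing = [c for c in self.values.columns if c not in self.orientations]
        if missing:
            # default orientation is benefit; state it explicitly
            for c in missing:
                self.orientations[c] = BENEFIT
        bad = {c: o for c, o in self.orientations.items() if o not in (BENEFIT, COST)}
        if bad:
            raise ValueError(f"unknown orientations: {bad}")

    @property
    def n_entities(self) -> int:
        return len(self.values)

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    def check(self) -> None:
        if self.n_entities < 2:
            raise ValueError("need at least 2 entities to standardize")
        non_numeric = [
            c for c in self.values.columns
            if not pd.api.types.is_numeric_dtype(self.values[c])
        ]
        if non_numeric:
            raise FormatError(f"non-numeric indicator columns: {non_numeric}")
        if self.values.isna().any().any():
            raise FormatError("data matrix contains missing values")


@dataclass
class EntropyResult:
    """All EWM intermediates for one indicator group."""

    standardized: pd.DataFrame   # r_ij in [0, 1]
    proportions: pd.DataFrame    # P_ij, columns sum to 1
    entropies: pd.Series         # e_j in [0, 1]
    weights: pd.Series           # W_j, sums to 1


def standardize(data: IndicatorDataMatrix) -> pd.DataFrame:
    """Min–max standardize each column by its orientation; output in [0, 1].

    A constant column has no spread to scale and is mapped to 0.5
    everywhere — downstream it yields a uniform share distribution, e_j = 1
    and weight 0, the "no variation, no information" convention.
    """
    data.check()
    out = {}
    for col in data.values.columns:
        x = data.values[col].astype(float)
        lo, hi = x.min(), x.max()
        if np.isclose(hi, lo):
            out[col] = pd.Series(0.5, index=x.index)
        elif data.orientations[col] == BENEFIT:
            out[col] = (x - lo) / (hi - lo)
        else:
            out[col] = (hi - x) / (hi - lo)
    return pd.DataFrame(out, index=data.values.index)


def proportions(standardized: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    """Column share distributions P_ij = r_ij / sum_i r_ij.

    An all-zero column carries no signal and is assigned the uniform
    distribution (with a warning), so its entropy is maximal. A nonzero
    ``epsilon`` (conventionally 1e-12) is added to every standardized value
    before forming shares — an alternative zero-handling mode for
    comparison with the exact 0*ln 0 := 0 convention.
    """
    r = standardized.astype(float) + epsilon
    if (r.values < -1e-12).any() or (r.values > 1 + 1e-12).any():
        raise ValueError("standardized values must lie in [0, 1]")
    sums = r.sum(axis=0)
    dead = sums[sums <= 0].index.tolist()
    if dead:
        warnings.warn(
            f"all-zero standardized columns treated as uniform: {dead}",
            stacklevel=2,
        )
    p = r.div(sums.replace(0, np.nan), axis=1)
    for col in dead:
        p[col] = 1.0 / len(r)
    return p


def indicator_entropy(
    standardized: pd.DataFrame, epsilon: float = 0.0
) -> pd.Series:
    """Normalized Shannon entropy e_j of each column's share distribution.

    e_j = -(1/ln m) sum_i P_ij ln P_ij with 0 * ln 0 := 0; always in [0, 1]
    (1 for uniform columns, 0 when a single entity holds all the mass).
    ``epsilon`` switches the zero-handling mode (see :func:`proportions`).
    """
    p = proportions(standardized, epsilon=epsilon)
    m = len(p)
    if m < 2:
        raise ValueError("entropy needs at least 2 entities")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p.values > 0, p.values * np.log(p.values), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    # clamp the tiny float excursions around the exact bounds
    e = np.clip(e, 0.0, 1.0)
    return pd.Series(e, index=standardized.columns, name="entropy")


def entropy_weight_vector(entropies: pd.Series | Sequence[float]) -> pd.Series:
    """Entropy weights W_j = (1 - e_j) / sum_k (1 - e_k).

    Lower entropy (more cross-entity variation) earns a larger weight. If
    every entropy equals 1 the numerator vanishes everywhere; the guard
    returns uniform weights with a warning.

    Accepts any entropy vector, including values above 1 as found in some
    published tables: the formula is a simple normalization of (1 - e_j)
    and remains well defined as long as the denominator is nonzero.
    """
    e = pd.Series(np.asarray(entropies, dtype=float))
    if isinstance(entropies, pd.Series):
        e.index = entropies.index
    info = 1.0 - e
    total = info.sum()
    if np.isclose(total, 0.0):
        warnings.warn(
            "all entropies equal 1 (no information); returning uniform weights",
            stacklevel=2,
        )
        return pd.Series(1.0 / len(e), index=e.index, name="ewm_weight")
    w = info / total
    w.name = "ewm_weight"
    return w


def entropy_weights(data: IndicatorDataMatrix) -> EntropyResult:
    """Full EWM pipeline: standardize -> shares -> entropies -> weights."""
    r = standardize(data)
    p = proportions(r)
    e = indicator_entropy(r)
    w = entropy_weight_vector(e)
    return EntropyResult(standardized=r, proportions=p, entropies=e, weights=w)


def groupwise_entropy_weights(
    data: IndicatorDataMatrix, groups: Mapping[str, Sequence[str]]
) -> dict[str, EntropyResult]:
    """Apply EWM independently within each sibling group.

    ``groups`` maps a group code to the ordered indicator codes it contains;
    each group's weights sum to 1 on their own.
    """
    out = {}
    for group_code, cols in groups.items():
        missing = [c for c in cols if c not in data.values.columns]
        if missing:
            raise FormatError(f"group {group_code}: missing columns {missing}")
        sub = IndicatorDataMatrix(
            values=data.values[list(cols)],
            orientations={c: data.orientations[c] for c in cols},
        )
        out[group_code] = entropy_weights(sub)
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def read_data_matrix(
    path: str | Path,
    orientations: Mapping[str, str] | str | Path | None = None,
    orientation_row: bool = False,
) -> IndicatorDataMatrix:
    """Read an entity x indicator CSV (first column = entity id).

    Orientations come either from a mapping / sidecar CSV with columns
    ``indicator,orientation``, or — with ``orientation_row=True`` — from a
    second header line holding ``benefit``/``cost`` per column. Unlisted
    indicators default to benefit.
    """
    path = Path(path)
    try:
        if orientation_row:
            head = pd.read_csv(path, nrows=1, index_col=0)
            orient = {c: str(head[c].iloc[0]).strip() for c in head.columns}
            df = pd.read_csv(path, skiprows=[1], index_col=0)
            return IndicatorDataMatrix(df, orient)
        df = pd.read_csv(path, index_col=0)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read data matrix {path}: {exc}") from exc
    if orientations is None:
        orient = {}
    elif isinstance(orientations, (str, Path)):
        side = pd.read_csv(orientations)
        if not {"indicator", "orientation"} <= set(side.columns):
            raise FormatError(
                "orientation sidecar needs columns indicator,orientation"
            )
        orient = dict(zip(side["indicator"].astype(str), side["orientation"]))
    else:
        orient = dict(orientations)
    return IndicatorDataMatrix(df, orient)
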