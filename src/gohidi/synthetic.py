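"""Synthetic expert panels and indicator data with known ground truth.

The generator mirrors the study geometry behind the published weights: a
panel of 42 experts each compares every pair of second-level indicators
within the three first-level groups (of sizes 6, 4 and 5), and an
entity x indicator matrix of country-style data with controllable
per-indicator dispersion.

Expert judgments follow the standard multiplicative AHP error model: for
true group priorities w, expert b reports

    r_ie = (w_i / w_e) * exp(eps),   eps ~ Normal(0, noise_sd^2),

mirrored reciprocally so each matrix stays exactly reciprocal. At
noise_sd = 0 the consensus matrix is perfectly consistent and the true
priorities are recovered to machine precision.

Default true priorities are the published second-level FAHP weights
(renormalized within each group), so simulations run under realistic
magnitudes; default noise_sd = 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ewm import BENEFIT, COST, IndicatorDataMatrix
from .fahp import RECIPROCAL_BOUNDS, ComparisonResponse

#: Published second-level FAHP weights (percent), renormalized per group —
#: the default "true" subjective priorities for simulation.
DEFAULT_GROUP_PRIORITIES: dict[str, list[float]] = {
    "1": [20.63, 19.53, 15.88, 13.49, 17.47, 13.01],
    "2": [31.87, 24.66, 17.36, 26.11],
    "3": [23.82, 19.55, 20.68, 17.52, 18.42],
}


def _normalized(v: Sequence[float]) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("priority vector needs length >= 2")
    if np.any(arr <= 0):
        raise ValueError("priorities must be positive")
    return arr / arr.sum()


@dataclass
class ExpertPanelSpec:
    """Geometry and noise model of a simulated expert panel."""

    group_sizes: tuple[int, ...] = (6, 4, 5)
    n_experts: int = 42
    priorities: dict[str, Sequence[float]] | None = None
    noise_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("every group needs at least 2 indicators")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def resolved_priorities(self) -> dict[str, np.ndarray]:
        """Group code -> normalized true priority vector, sizes checked."""
        if self.priorities is not None:
            out = {g: _normalized(v) for g, v in self.priorities.items()}
        else:
            defaults = DEFAULT_GROUP_PRIORITIES
            out = {}
            for k, size in enumerate(self.group_sizes, start=1):
                code = str(k)
                if code in defaults and len(defaults[code]) == size:
                    out[code] = _normalized(defaults[code])
                else:
                    # fall back to a fixed mildly-uneven profile
                    out[code] = _normalized(np.arange(size, 0, -1, dtype=float))
        for g, v in out.items():
            if self.group_sizes and g in {str(k + 1) for k in range(len(self.group_sizes))}:
                size = self.group_sizes[int(g) - 1]
                if len(v) != size:
                    raise ValueError(
                        f"group {g}: priority length {len(v)} != size {size}"
                    )
        return out

    def indicator_codes(self) -> dict[str, list[str]]:
        return {
            str(k): [f"{k}.{j}" for j in range(1, size + 1)]
            for k, size in enumerate(self.group_sizes, start=1)
        }


def simulate_expert_responses(
    spec: ExpertPanelSpec, seed: int | None = None
) -> list[ComparisonResponse]:
    """Draw a full questionnaire: every expert, every group, every pair.

    Values are clipped into the reciprocal 1/9–9 scale bounds (noise at the
    default level essentially never reaches them). Deterministic given
    ``seed`` (argument overrides ``spec.seed``).
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    priorities = spec.resolved_priorities()
    codes = spec.indicator_codes()
    lo, hi = RECIPROCAL_BOUNDS

    responses: list[ComparisonResponse] = []
    for b in range(1, spec.n_experts + 1):
        expert = f"E{b:03d}"
        for group, w in priorities.items():
            names = codes[group]
            for i in range(len(w)):
                for e in range(i + 1, len(w)):
                    eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                    value = float(np.clip((w[i] / w[e]) * np.exp(eps), lo, hi))
                    responses.append(
                        ComparisonResponse(
                            expert_id=expert,
                            group_code=group,
                            first=names[i],
                            second=names[e],
                            value=value,
                        )
                    )
    return responses


@dataclass
class IndicatorDataSpec:
    """Synthetic entity x indicator matrix: one distribution per indicator.

    ``indicators`` maps an indicator code to a spec dict with keys
    ``family`` ("normal" or "lognormal"), ``loc``, ``scale`` and
    ``orientation``. Dispersion (``scale``) is the lever that drives
    entropy weights: more cross-entity spread, more weight.
    """

    n_entities: int = 50
    indicators: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.n_entities < 2:
            raise ValueError("need at least 2 entities")
        if not self.indicators:
            # a small default battery spanning both families and orientations
            self.indicators = {
                "x1": {"family": "lognormal", "loc": 1.0, "scale": 0.6,
                       "orientation": BENEFIT},
                "x2": {"family": "normal", "loc": 50.0, "scale": 12.0,
                       "orientation": BENEFIT},
                "x3": {"family": "normal", "loc": 20.0, "scale": 4.0,
                       "orientation": COST},
            }
        for code, cfg in self.indicators.items():
            if cfg.get("scale", 1.0) < 0:
                raise ValueError(f"{code}: dispersion must be nonnegative")
            if cfg.get("family", "normal") not in ("normal", "lognormal"):
                raise ValueError(f"{code}: unknown family {cfg.get('family')!r}")


def simulate_indicator_data(
    spec: IndicatorDataSpec, seed: int | None = None
) -> IndicatorDataMatrix:
    """Draw the raw data matrix; deterministic given ``seed``."""
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    entities = [f"C{k:03d}" for k in range(1, spec.n_entities + 1)]
    cols = {}
    orient = {}
    for code, cfg in spec.indicators.items():
        family = cfg.get("family", "normal")
        loc = float(cfg.get("loc", 0.0))
        scale = float(cfg.get("scale", 1.0))
        if family == "lognormal":
            draw = rng.lognormal(mean=loc, sigma=scale, size=spec.n_entities)
        else:
            draw = rng.normal(loc=loc, scale=scale, size=spec.n_entities)
        cols[code] = draw
        orient[code] = cfg.get("orientation", BENEFIT)
    return IndicatorDataMatrix(
        values=pd.DataFrame(cols, index=entities), orientations=orient
    )


def write_truth(spec: ExpertPanelSpec, path: str | Path) -> Path:
    """Dump the panel's true priorities as JSON for test harnesses."""
    doc = {
        "group_sizes": list(spec.group_sizes),
        "n_experts": spec.n_experts,
        "noise_sd": spec.noise_sd,
        "priorities": {
            g: [float(x) for x in v] for g, v in spec.resolved_priorities().items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path
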