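"""Maps quantitative measurements onto 0-5 index scores via monotone bins.

Each quantitative index (D1 cellular density, D2 cell-less %, C2 GFAP %, E1
positive-control SD ratio, B1 size, B2 growth slope) carries five ordered cut
points partitioning its measurement axis into scores 0..5.  Boundary values
resolve to the higher score (ties favor quality).  B1/B2 are batch-relative:
the mapped quantity is the absolute deviation from the batch median in units
of the batch MAD, because absolute size expectations depend on seeding
density.  The default edges shipped with the package are declared,
uncalibrated anchors and should be replaced by a lab-calibrated rubric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scheme_engine import NOT_ASSESSED, default_config

__all__ = [
    "ScoreBins",
    "map_measurement",
    "batch_relative_deviations",
    "score_indices",
    "default_bins",
]

#: Quantitative indices and the metric feeding each one.
INDEX_METRICS = {
    "D1": "cell_density",
    "D2": "cellless_fraction",
    "C2": "gfap_fraction",
    "E1": "positive_control_ratio",
    "B1": "size",
    "B2": "slope",
}


@dataclass(frozen=True)
class ScoreBins:
    """Monotone step mapping from a measurement to a 0-5 score."""

    index_id: str
    direction: str  # "higher" (higher is better) | "lower"
    edges: tuple[float, ...]
    units: str = ""
    relative: str | None = None  # "batch" for batch-relative measurements

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"{self.index_id}: direction must be 'higher' or 'lower'")
        if len(self.edges) != 5:
            raise ValueError(f"{self.index_id}: need exactly 5 bin edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"{self.index_id}: edges must be strictly increasing")


def map_measurement(value: float, bins: ScoreBins) -> int:
    """Score a measurement through its bins.

    For higher-is-better bins the score is the number of edges at or below
    the value; for lower-is-better, five minus the number of edges strictly
    below it.  Either way a value exactly on an edge takes the higher score.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"{bins.index_id}: measurement is NaN")
    if bins.direction == "higher":
        return int(sum(value >= e for e in bins.edges))
    return int(5 - sum(value > e for e in bins.edges))


def batch_relative_deviations(values: Mapping[str, float]) -> dict[str, float]:
    """Absolute deviation from the batch median, in batch-MAD units.

    With a zero MAD (all batch values identical) organoids at the median get
    deviation 0 and any other value maps to infinity.
    """
    arr = np.asarray(list(values.values()), dtype=float)
    if arr.size == 0:
        raise ValueError("empty batch")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    out = {}
    for k, v in values.items():
        dev = abs(v - med)
        if mad == 0:
            out[k] = 0.0 if dev == 0 else math.inf
        else:
            out[k] = dev / mad
    return out


def default_bins() -> dict[str, ScoreBins]:
    """The packaged default bins, keyed by index id."""
    return bins_from_config(default_config()["bins"])


def bins_from_config(config: Mapping[str, Mapping]) -> dict[str, ScoreBins]:
    return {
        index_id: ScoreBins(
            index_id=index_id,
            direction=cfg["direction"],
            edges=tuple(float(e) for e in cfg["edges"]),
            units=cfg.get("units", ""),
            relative=cfg.get("relative"),
        )
        for index_id, cfg in config.items()
    }


def _aggregate(index_id: str, value: float | Sequence[float]) -> float:
    """Mean over replicate slices; scalars pass through."""
    if np.iterable(value) and not isinstance(value, str):
        arr = np.asarray(list(value), dtype=float)
        if arr.size == 0:
            raise ValueError(f"{index_id}: empty measurement list")
        if not np.isfinite(arr).all():
            raise ValueError(f"{index_id}: non-finite replicate measurement")
        return float(arr.mean())
    return float(value)


def score_indices(
    measurements: Mapping[str, float | Sequence[float]],
    bins: Mapping[str, ScoreBins] | None = None,
) -> dict[str, object]:
    """Turn per-index measurements into raw scores for rubric evaluation.

    ``measurements`` maps index id -> scalar or per-slice list (averaged by
    arithmetic mean before mapping).  Batch-relative indices (B1/B2) must be
    supplied already converted to MAD deviations via
    :func:`batch_relative_deviations`.  Indices known to the bin set but
    absent from the measurements are emitted as not-assessed.
    """
    bins = default_bins() if bins is None else bins
    unknown = set(measurements) - set(bins)
    if unknown:
        raise ValueError(f"no bins defined for indices {sorted(unknown)}")
    out: dict[str, object] = {}
    for index_id, b in bins.items():
        if index_id in measurements:
            out[index_id] = map_measurement(_aggregate(index_id, measurements[index_id]), b)
        else:
            out[index_id] = NOT_ASSESSED
    return out
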