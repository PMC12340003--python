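"""Hierarchical QC rubric: data model, score-card evaluation, batch summaries.

The rubric scores an organoid on ordered criteria (A Morphology, B Size and
growth, C Cellular populations, D Cytoarchitecture, E Cytotoxicity), each
split into indices rated 0 (poor) to 5 (high quality).  Evaluation is
hierarchical: the first index scoring below its minimum fails the organoid and
everything downstream is left unevaluated.  Criteria that pass all per-index
minima are additionally checked against a composite minimum over their index
sum (for morphology, 9/15 rather than the naive 8/15), and finally the grand
total is compared against the mode threshold (16/25 for the Initial QC on
criteria A-B, 35/50 for the Final QC).
"""

from __future__ import annotations

import math
import statistics
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "IndexDef",
    "CriterionDef",
    "QCScheme",
    "IndexScore",
    "ScoreCard",
    "CompositeVerdict",
    "BatchSummary",
    "SKIPPED",
    "NOT_ASSESSED",
    "evaluate",
    "check_composites",
    "batch_summary",
    "load_scheme",
    "default_scheme",
]

#: Sentinel raw-score value: the index was deliberately left out of the
#: assessment (e.g. growth not re-measured post treatment).  Contributes 0 to
#: the total and removes 5 points from the achievable maximum.
NOT_ASSESSED = "NA"

#: Sentinel raw-score value: no score exists because evaluation stopped before
#: this index (printed as "x" in score tables).  Does not reduce the
#: achievable maximum -- the index could have been assessed.
SKIPPED = "x"

_NA_TOKENS = {"na", "n/a", ""}
_SKIP_TOKENS = {"x", "-"}

SCORE_MIN, SCORE_MAX = 0, 5


class SchemeError(ValueError):
    """Invalid rubric definition."""


class ScoreInputError(ValueError):
    """Invalid raw-score input for evaluation."""


@dataclass(frozen=True)
class IndexDef:
    """One scored sub-item of a criterion (e.g. A2, border integrity)."""

    id: str
    name: str
    criterion_id: str
    min_score: int
    order: int
    quantitative: bool = False

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.min_score <= SCORE_MAX:
            raise SchemeError(
                f"index {self.id}: min_score {self.min_score} outside 0-5"
            )


@dataclass(frozen=True)
class CriterionDef:
    """A readout family (A..E) with its ordered indices and composite minimum."""

    id: str
    name: str
    indices: tuple[IndexDef, ...]
    composite_min: int | None
    order: int

    def __post_init__(self) -> None:
        if not self.indices:
            raise SchemeError(f"criterion {self.id} has no indices")
        if self.composite_min is not None:
            lo = sum(ix.min_score for ix in self.indices)
            hi = SCORE_MAX * len(self.indices)
            if not lo <= self.composite_min <= hi:
                raise SchemeError(
                    f"criterion {self.id}: composite_min {self.composite_min} "
                    f"outside [{lo}, {hi}]"
                )

    @property
    def effective_composite_min(self) -> int:
        """Composite minimum, defaulting to the sum of index minima."""
        if self.composite_min is not None:
            return self.composite_min
        return sum(ix.min_score for ix in self.indices)


@dataclass(frozen=True)
class QCScheme:
    """A full rubric in one mode (initial or final)."""

    name: str
    mode: str
    criteria: tuple[CriterionDef, ...]
    total_min: int
    reference_max: int
    early_exit_level: str = "index"  # "index" | "criterion"

    def __post_init__(self) -> None:
        if self.early_exit_level not in ("index", "criterion"):
            raise SchemeError(
                f"early_exit_level must be 'index' or 'criterion', "
                f"got {self.early_exit_level!r}"
            )
        ids = [ix.id for ix in self.indices()]
        if len(ids) != len(set(ids)):
            raise SchemeError("duplicate index ids in scheme")
        if self.total_min > self.nominal_max:
            raise SchemeError(
                f"total_min {self.total_min} exceeds achievable maximum "
                f"{self.nominal_max}"
            )

    def indices(self) -> Iterator[IndexDef]:
        for crit in self.criteria:
            yield from crit.indices

    @property
    def index_map(self) -> dict[str, IndexDef]:
        return {ix.id: ix for ix in self.indices()}

    @property
    def nominal_max(self) -> int:
        return SCORE_MAX * sum(len(c.indices) for c in self.criteria)

    def effective_total_min(self, max_achievable: int) -> int:
        """Pass threshold rescaled to the achievable maximum.

        The default thresholds are fractions of a reference maximum (16/25
        initial, 35/50 final); when not-assessed indices change the achievable
        maximum the threshold scales proportionally, rounded up.
        """
        if max_achievable == self.reference_max:
            return self.total_min
        return math.ceil(self.total_min * max_achievable / self.reference_max)


@dataclass(frozen=True)
class IndexScore:
    """Evaluated state of one index on one organoid."""

    index_id: str
    state: str  # "scored" | "not_assessed" | "not_evaluated"
    value: int | None = None

    def __post_init__(self) -> None:
        if (self.state == "scored") != (self.value is not None):
            raise ScoreInputError(
                f"{self.index_id}: value must be present iff state is 'scored'"
            )


@dataclass(frozen=True)
class ScoreCard:
    """One organoid's evaluated card."""

    organoid_id: str
    condition: str
    mode: str
    scores: tuple[IndexScore, ...]
    total: int
    max_achievable: int
    total_min: int
    status: str  # "passed" | "failed"
    failure_point: str | None
    reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.status == "passed"

    def score_of(self, index_id: str) -> IndexScore:
        for s in self.scores:
            if s.index_id == index_id:
                return s
        raise KeyError(index_id)


@dataclass(frozen=True)
class CompositeVerdict:
    criterion_id: str
    total: int
    required: int
    passed: bool


def _parse_raw(value: object, index_id: str) -> object:
    """Normalize one raw input cell to an int, NOT_ASSESSED, or SKIPPED."""
    if value is None:
        return NOT_ASSESSED
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _NA_TOKENS:
            return NOT_ASSESSED
        if token in _SKIP_TOKENS:
            return SKIPPED
        try:
            value = int(token)
        except ValueError:
            raise ScoreInputError(
                f"index {index_id}: score {value!r} is not an integer, 'NA' or 'x'"
            ) from None
    if isinstance(value, float):
        if math.isnan(value):
            return NOT_ASSESSED
        if not value.is_integer():
            raise ScoreInputError(f"index {index_id}: score {value} is not an integer")
        value = int(value)
    if isinstance(value, int) and not isinstance(value, bool):
        if not SCORE_MIN <= value <= SCORE_MAX:
            raise ScoreInputError(f"index {index_id}: score {value} outside 0-5")
        return value
    raise ScoreInputError(f"index {index_id}: unsupported score {value!r}")


def evaluate(
    scores_in: Mapping[str, object],
    scheme: QCScheme,
    organoid_id: str = "",
    condition: str = "",
    unmeasurable: Mapping[str, str] | None = None,
) -> ScoreCard:
    """Evaluate raw per-index scores hierarchically against a rubric.

    Parameters
    ----------
    scores_in
        Mapping index id -> raw score.  Accepted values: integers 0-5; ``"NA"``
        / ``None`` / NaN for deliberately not-assessed indices; ``"x"`` for
        indices never reached (only legal at or after the failure point).
    scheme
        The rubric (criteria visited in scheme order, indices in index order).
    unmeasurable
        Optional mapping criterion id -> reason for criteria that could not be
        measured at all (e.g. an organoid too fragile to section): the card
        fails at that criterion's first index, which is left ``not_evaluated``.

    Returns
    -------
    ScoreCard
        With the first below-minimum index (or first violated composite, or a
        missed total threshold) as the failure point; indices downstream of a
        failure are ``not_evaluated``.
    """
    unmeasurable = dict(unmeasurable or {})
    index_map = scheme.index_map
    for key in scores_in:
        if key not in index_map:
            raise ScoreInputError(f"index {key!r} not defined in scheme {scheme.name}")
    for crit_id in unmeasurable:
        if crit_id not in {c.id for c in scheme.criteria}:
            raise ScoreInputError(f"criterion {crit_id!r} not defined in scheme")
    parsed = {k: _parse_raw(v, k) for k, v in scores_in.items()}

    results: list[IndexScore] = []
    total = 0
    n_not_assessed = 0
    failure_point: str | None = None
    reason: str | None = None

    def mark_unreached(ix: IndexDef) -> IndexScore:
        # An explicit NA was decided independently of the hierarchy and still
        # reduces the achievable maximum; anything else is simply unreached.
        nonlocal n_not_assessed
        if parsed.get(ix.id, SKIPPED) is NOT_ASSESSED:
            n_not_assessed += 1
            return IndexScore(ix.id, "not_assessed")
        return IndexScore(ix.id, "not_evaluated")

    for crit in scheme.criteria:
        if failure_point is not None:
            results.extend(mark_unreached(ix) for ix in crit.indices)
            continue

        if crit.id in unmeasurable:
            results.append(IndexScore(crit.indices[0].id, "not_evaluated"))
            results.extend(mark_unreached(ix) for ix in crit.indices[1:])
            failure_point = crit.indices[0].id
            reason = unmeasurable[crit.id]
            continue

        crit_sum = 0
        n_scored = 0
        failed_in_criterion = False
        for ix in crit.indices:
            raw = parsed.get(ix.id, SKIPPED)
            if failed_in_criterion and scheme.early_exit_level == "index":
                results.append(mark_unreached(ix))
                continue
            if raw is NOT_ASSESSED:
                results.append(IndexScore(ix.id, "not_assessed"))
                n_not_assessed += 1
                continue
            if raw is SKIPPED:
                raise ScoreInputError(
                    f"index {ix.id}: no score provided but evaluation reaches it "
                    f"('x' is only valid after a failure point)"
                )
            value = int(raw)  # already validated
            results.append(IndexScore(ix.id, "scored", value))
            total += value
            crit_sum += value
            n_scored += 1
            if value < ix.min_score:
                failed_in_criterion = True
                if failure_point is None:
                    failure_point = (
                        ix.id if scheme.early_exit_level == "index" else crit.id
                    )

        if failed_in_criterion:
            continue
        # Composite check over the fully scored part of the criterion; the
        # requirement scales down when some of its indices are not assessed.
        if n_scored > 0:
            required = _scaled_composite_min(crit, n_scored)
            if crit_sum < required:
                failure_point = crit.id

    n_total = sum(len(c.indices) for c in scheme.criteria)
    max_achievable = SCORE_MAX * (n_total - n_not_assessed)
    total_min = scheme.effective_total_min(max_achievable)
    if failure_point is None and total < total_min:
        failure_point = "total"
    status = "failed" if failure_point is not None else "passed"

    return ScoreCard(
        organoid_id=str(organoid_id),
        condition=str(condition),
        mode=scheme.mode,
        scores=tuple(results),
        total=total,
        max_achievable=max_achievable,
        total_min=total_min,
        status=status,
        failure_point=failure_point,
        reason=reason,
    )


def _scaled_composite_min(crit: CriterionDef, n_scored: int) -> int:
    """Composite requirement scaled to the number of actually scored indices."""
    nominal = crit.effective_composite_min
    n = len(crit.indices)
    if n_scored == n:
        return nominal
    return math.ceil(nominal * n_scored / n)


def check_composites(card: ScoreCard, scheme: QCScheme) -> list[CompositeVerdict]:
    """Per-criterion composite verdicts for an evaluated card.

    Criteria with no scored index are omitted; criteria containing
    not-assessed indices are compared against a proportionally scaled
    composite minimum (rounded up).
    """
    by_id = {s.index_id: s for s in card.scores}
    verdicts = []
    for crit in scheme.criteria:
        scored = [
            by_id[ix.id].value
            for ix in crit.indices
            if ix.id in by_id and by_id[ix.id].state == "scored"
        ]
        if not scored:
            continue
        required = _scaled_composite_min(crit, len(scored))
        total = sum(scored)
        verdicts.append(CompositeVerdict(crit.id, total, required, total >= required))
    return verdicts


@dataclass(frozen=True)
class BatchSummary:
    n: int
    n_passed: int
    n_failed: int
    exclusion_pct: int
    median_total: float
    median_total_by_condition: dict[str, float]
    score_distributions: dict[str, dict[int, int]]
    failure_points: dict[str, int]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def batch_summary(cards: Sequence[ScoreCard]) -> BatchSummary:
    """Summarize a homogeneous batch of evaluated cards.

    Returns pass/fail counts, the exclusion percentage (rounded half-up to an
    integer percent), total medians overall and per condition, per-index score
    distributions over scored values, and a failure-point histogram.
    """
    if not cards:
        raise ValueError("batch_summary requires a non-empty list of cards")
    modes = {c.mode for c in cards}
    if len(modes) > 1:
        raise ValueError(f"mixed modes in batch: {sorted(modes)}")
    n = len(cards)
    n_failed = sum(not c.passed for c in cards)
    by_condition: dict[str, list[int]] = {}
    for c in cards:
        by_condition.setdefault(c.condition, []).append(c.total)
    dists: dict[str, Counter] = {}
    for c in cards:
        for s in c.scores:
            if s.state == "scored":
                dists.setdefault(s.index_id, Counter())[s.value] += 1
    failure_points = Counter(
        c.failure_point for c in cards if c.failure_point is not None
    )
    return BatchSummary(
        n=n,
        n_passed=n - n_failed,
        n_failed=n_failed,
        exclusion_pct=_round_half_up(100.0 * n_failed / n),
        median_total=statistics.median(c.total for c in cards),
        median_total_by_condition={
            k: statistics.median(v) for k, v in sorted(by_condition.items())
        },
        score_distributions={k: dict(sorted(v.items())) for k, v in sorted(dists.items())},
        failure_points=dict(sorted(failure_points.items())),
    )


# ---------------------------------------------------------------------------
# Scheme loading


def _build_scheme(config: Mapping, mode: str, **overrides) -> QCScheme:
    modes = config.get("modes", {})
    if mode not in modes:
        raise SchemeError(f"mode {mode!r} not defined; available: {sorted(modes)}")
    mode_cfg = modes[mode]
    wanted = list(mode_cfg["criteria"])
    crit_cfg = {c["id"]: c for c in config["criteria"]}
    missing = [cid for cid in wanted if cid not in crit_cfg]
    if missing:
        raise SchemeError(f"mode {mode!r} references unknown criteria {missing}")
    criteria = []
    for c_order, cid in enumerate(wanted):
        c = crit_cfg[cid]
        indices = tuple(
            IndexDef(
                id=ix["id"],
                name=ix.get("name", ix["id"]),
                criterion_id=cid,
                min_score=int(ix["min_score"]),
                order=i_order,
                quantitative=bool(ix.get("quantitative", False)),
            )
            for i_order, ix in enumerate(c["indices"])
        )
        criteria.append(
            CriterionDef(
                id=cid,
                name=c.get("name", cid),
                indices=indices,
                composite_min=c.get("composite_min"),
                order=c_order,
            )
        )
    params = dict(
        name=config.get("name", "scheme"),
        mode=mode,
        criteria=tuple(criteria),
        total_min=int(mode_cfg["total_min"]),
        reference_max=int(mode_cfg["reference_max"]),
        early_exit_level=config.get("early_exit_level", "index"),
    )
    params.update(overrides)
    return QCScheme(**params)


def load_scheme(source: str | Path | Mapping, mode: str = "final", **overrides) -> QCScheme:
    """Build a :class:`QCScheme` from a YAML/JSON file path or a parsed mapping.

    ``overrides`` may replace ``total_min``, ``reference_max`` or
    ``early_exit_level`` (e.g. criterion-level early exit).
    """
    if isinstance(source, Mapping):
        config = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    return _build_scheme(config, mode, **overrides)


def _default_config() -> dict:
    text = resources.files("organoidqc.data").joinpath("default_scheme.yaml").read_text()
    return yaml.safe_load(text)


def default_scheme(mode: str = "final", **overrides) -> QCScheme:
    """The packaged 60-day cortical organoid rubric in the requested mode."""
    return _build_scheme(_default_config(), mode, **overrides)


def default_config() -> dict:
    """Raw packaged rubric configuration (criteria, modes, bins)."""
    return _default_config()
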