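"""Readers, writers and report generation.

CSV dialect: comma-separated, UTF-8, "." decimal; the literal ``NA`` marks a
deliberately not-assessed index and ``x`` an index skipped because evaluation
stopped earlier.  Images are single- or multi-page TIFF or PNG; pixel size
always comes from the caller (sidecar config or CLI flag), never from
embedded metadata.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scheme_engine import (
    BatchSummary,
    QCScheme,
    ScoreCard,
    ScoreInputError,
    batch_summary,
    evaluate,
)

__all__ = [
    "read_scores",
    "example_scores",
    "evaluate_table",
    "cards_frame",
    "write_report",
    "read_image",
    "write_image",
]

_META_COLUMNS = {"organoid_id", "condition"}


def read_scores(path: str | Path, scheme: QCScheme | None = None) -> pd.DataFrame:
    """Read a raw score table.

    Expects an ``organoid_id`` column plus one column per index id; an
    optional ``condition`` column labels the experimental group.  Cells hold
    integers 0-5, ``NA``/empty (not assessed) or ``x`` (skipped after a
    failure).  If a scheme is given, column names and score ranges are
    validated against it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "organoid_id" not in df.columns:
        raise ScoreInputError(f"{path}: missing required column 'organoid_id'")
    index_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not index_cols:
        raise ScoreInputError(f"{path}: no index columns found")
    if scheme is not None:
        known = set(scheme.index_map)
        unknown = [c for c in index_cols if c not in known]
        if unknown:
            raise ScoreInputError(f"{path}: unknown index columns {unknown}")
    for col in index_cols:
        for row_i, cell in enumerate(df[col]):
            token = str(cell).strip().lower()
            if token in ("", "na", "n/a", "x", "-"):
                continue
            try:
                value = int(token)
            except ValueError:
                raise ScoreInputError(
                    f"{path}: row {row_i + 2}, column {col}: "
                    f"score {cell!r} is not an integer, 'NA' or 'x'"
                ) from None
            if not 0 <= value <= 5:
                raise ScoreInputError(
                    f"{path}: row {row_i + 2}, column {col}: score {value} outside 0-5"
                )
    return df


def example_scores() -> pd.DataFrame:
    """The packaged worked example: final-mode scores for six organoids from
    a graded hydrogen-peroxide exposure experiment."""
    with resources.as_file(
        resources.files("organoidqc.data").joinpath("example_final_scores.csv")
    ) as p:
        return read_scores(p)


def evaluate_table(df: pd.DataFrame, scheme: QCScheme) -> list[ScoreCard]:
    """Evaluate every row of a raw score table against a rubric."""
    index_cols = [c for c in df.columns if c not in _META_COLUMNS]
    cards = []
    for _, row in df.iterrows():
        scores = {c: row[c] for c in index_cols}
        cards.append(
            evaluate(
                scores,
                scheme,
                organoid_id=str(row["organoid_id"]),
                condition=str(row.get("condition", "")),
            )
        )
    return cards


def cards_frame(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Evaluated cards as a table: raw scores plus total/max/status columns."""
    index_ids = [s.index_id for s in cards[0].scores]
    rows = []
    for card in cards:
        row: dict[str, object] = {
            "organoid_id": card.organoid_id,
            "condition": card.condition,
        }
        for s in card.scores:
            row[s.index_id] = (
                s.value if s.state == "scored" else ("NA" if s.state == "not_assessed" else "x")
            )
        row.update(
            total=card.total,
            max=card.max_achievable,
            status=card.status,
            failure_point=card.failure_point or "",
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=["organoid_id", "condition", *index_ids,
                                       "total", "max", "status", "failure_point"])


def _summary_dict(summary: BatchSummary) -> dict:
    return {
        "n": summary.n,
        "n_passed": summary.n_passed,
        "n_failed": summary.n_failed,
        "exclusion_pct": summary.exclusion_pct,
        "median_total": summary.median_total,
        "median_total_by_condition": summary.median_total_by_condition,
        "score_distributions": summary.score_distributions,
        "failure_points": summary.failure_points,
    }


def _markdown_report(cards: Sequence[ScoreCard], summary: BatchSummary) -> str:
    """Human-readable report: per-organoid score lines, condition medians,
    pass/fail and the failed step, then batch-level statistics."""
    mode = cards[0].mode
    lines = [
        f"# QC report ({mode} scoring)",
        "",
        f"Organoids evaluated: {summary.n} "
        f"(passed {summary.n_passed}, failed {summary.n_failed}, "
        f"exclusion {summary.exclusion_pct}%)",
        "",
        "| organoid | condition | scores | total | result | failed step |",
        "|---|---|---|---|---|---|",
    ]
    for card in cards:
        shown = " ".join(
            f"{s.index_id}={s.value}" if s.state == "scored"
            else f"{s.index_id}={'NA' if s.state == 'not_assessed' else 'x'}"
            for s in card.scores
        )
        lines.append(
            f"| #{card.organoid_id} | {card.condition} | {shown} "
            f"| {card.total}/{card.max_achievable} | {card.status} "
            f"| {card.failure_point or ''} |"
        )
    lines += ["", "Median total by condition:", ""]
    for cond, med in summary.median_total_by_condition.items():
        lines.append(f"- {cond or '(none)'}: {med:g}")
    if summary.failure_points:
        lines += ["", "Failure points:", ""]
        for point, count in summary.failure_points.items():
            lines.append(f"- {point}: {count}")
    lines.append("")
    return "\n".join(lines)


def write_report(
    cards: Sequence[ScoreCard],
    out_dir: str | Path,
    prefix: str = "qc",
) -> dict[str, Path]:
    """Write per-organoid CSV, JSON batch summary, and a Markdown report.

    Returns the paths written, keyed by artifact kind.  Output is
    deterministic for identical input.
    """
    if not cards:
        raise ValueError("no cards to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = batch_summary(cards)
    paths = {
        "cards": out_dir / f"{prefix}_cards.csv",
        "summary": out_dir / f"{prefix}_summary.json",
        "report": out_dir / f"{prefix}_report.md",
    }
    cards_frame(cards).to_csv(paths["cards"], index=False)
    paths["summary"].write_text(json.dumps(_summary_dict(summary), indent=2) + "\n")
    paths["report"].write_text(_markdown_report(cards, summary))
    return paths


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG raster (2-D, or pages x rows x cols for multi-page)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write a raster as TIFF or PNG depending on the extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
        return
    import imageio.v3 as iio

    iio.imwrite(path, data)
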