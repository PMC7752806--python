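"""Blockwise CR scoring: trial results -> per-subject learning series.

The repeated-measures unit of analysis is the percentage of conditioned
responses per block of 10 acquisition trials: 6 blocks in Week 1 (60
trials) and 3 in Week 2 (30 trials), CS+ and CS- trials pooled (both are
scored over identical windows by the detector).  A subject's learning
series is the 9-vector [w1b1..w1b6, w2b1..w2b3].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import TrialResult
from .protocol import TrialKind, Week

__all__ = [
    "LearningSeries",
    "block_cr_percent",
    "assemble_learning_matrix",
    "LEARNING_COLUMNS",
]

LEARNING_COLUMNS = [f"w1b{i}" for i in range(1, 7)] + [f"w2b{i}" for i in range(1, 4)]

DEFAULT_BLOCK_SIZE = 10  # 60 Week-1 / 30 Week-2 trials over 6 / 3 blocks


@dataclass(frozen=True)
class LearningSeries:
    subject_id: str
    week1_blocks: tuple[float, ...]
    week2_blocks: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = self.week1_blocks + self.week2_blocks
        if len(self.week1_blocks) != 6 or len(self.week2_blocks) != 3:
            raise ValueError("expect 6 Week-1 and 3 Week-2 blocks")
        if not all(0.0 <= v <= 100.0 for v in vals):
            raise ValueError("block CR% must lie in [0, 100]")

    @property
    def values(self) -> np.ndarray:
        return np.array(self.week1_blocks + self.week2_blocks, dtype=float)


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        {
            "kind": r.trial.kind.value if isinstance(r, TrialResult) else r[0],
            "cr_present": r.cr_present if isinstance(r, TrialResult) else bool(r[1]),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def block_cr_percent(
    results,
    block_size: int = DEFAULT_BLOCK_SIZE,
    cs_plus_only: bool = False,
) -> list[float]:
    """Per-block CR percentages over acquisition trials, presentation order.

    ``results`` is an ordered sequence of :class:`TrialResult` (or a tidy
    frame with ``kind``/``cr_present`` columns).  US-alone trials must have
    been excluded upstream; the trial count must divide into whole blocks.
    ``cs_plus_only`` restricts the numerator and denominator to CS+ trials
    within each block (sensitivity analysis; blocks still span
    ``block_size`` presented trials).
    """
    df = _as_frame(results)
    if (df["kind"] == TrialKind.US_ALONE.value).any():
        raise ValueError("US-alone trials are excluded from CR scoring")
    n = len(df)
    if n == 0 or n % block_size:
        raise ValueError(f"trial count {n} not divisible by block size {block_size}")
    out = []
    for b in range(n // block_size):
        chunk = df.iloc[b * block_size : (b + 1) * block_size]
        if cs_plus_only:
            chunk = chunk[chunk["kind"] == TrialKind.CS_PLUS.value]
            if len(chunk) == 0:
                raise ValueError("block contains no CS+ trials")
        out.append(100.0 * float(chunk["cr_present"].mean()))
    return out


def assemble_learning_matrix(
    results_by_subject: dict[str, dict[Week, object]],
    block_size: int = DEFAULT_BLOCK_SIZE,
    cs_plus_only: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Subjects x 9-block learning matrix plus an exclusion report.

    ``results_by_subject`` maps subject id -> {Week.WEEK1: results,
    Week.WEEK2: results}; subjects missing either session are excluded and
    listed in the report.  Columns are ``w1b1..w1b6, w2b1..w2b3``.
    """
    rows, report = {}, []
    for sid, by_week in results_by_subject.items():
        missing = [w for w in (Week.WEEK1, Week.WEEK2) if w not in by_week]
        if missing:
            report.append(
                {"subject_id": sid,
                 "reason": "missing " + ", ".join(w.name for w in missing)}
            )
            continue
        w1 = block_cr_percent(by_week[Week.WEEK1], block_size, cs_plus_only)
        w2 = block_cr_percent(by_week[Week.WEEK2], block_size, cs_plus_only)
        if len(w1) != 6 or len(w2) != 3:
            report.append({"subject_id": sid, "reason": "unexpected block count"})
            continue
        rows[sid] = w1 + w2
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=LEARNING_COLUMNS)
    matrix.index.name = "subject_id"
    return matrix, report


def learning_matrix_from_truth(truth: pd.DataFrame, block_size: int = 10) -> pd.DataFrame:
    """Learning matrix computed from planted CR draws (no detection)."""
    acq = truth[truth["kind"] != TrialKind.US_ALONE.value]
    results = {}
    for sid, sub in acq.groupby("subject_id", sort=False):
        by_week = {}
        for week in (Week.WEEK1, Week.WEEK2):
            d = sub[sub["week"] == int(week)].sort_values("trial_index")
            by_week[week] = pd.DataFrame(
                {"kind": d["kind"].to_numpy(), "cr_present": d["cr_draw"].to_numpy()}
            )
        results[sid] = by_week
    matrix, _ = assemble_learning_matrix(results, block_size)
    return matrix
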