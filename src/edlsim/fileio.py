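"""Plain-text interchange formats.

Event tables are tab-separated text with header columns ``cues``,
``outcomes`` and ``frequency``; multiple labels inside one cell are
joined by ``"_"`` (the convention of the naive-discriminative-learning
ecosystem), which is why ``"_"`` is reserved and may not occur inside a
label.  An empty outcomes cell denotes an empty outcome set.  Weight
matrices are written wide (cues as rows) and weight histories long
(trial, cue, outcome, weight), both deterministically ordered so that
identical runs produce byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .events import LABEL_SEPARATOR, FrequencyTable, LearningEvent, check_label
from .learner import WeightHistory, WeightMatrix

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_weight_history",
    "write_weight_history",
]

_COLUMNS = ("cues", "outcomes", "frequency")


def _split_cell(cell: str, line_no: int, label_sep: str) -> frozenset[str]:
    if cell == "":
        return frozenset()
    labels = cell.split(label_sep)
    out = set()
    for lab in labels:
        if lab == "":
            raise ValueError(f"line {line_no}: empty label in cell {cell!r}")
        try:
            check_label(lab)
        except ValueError as err:
            raise ValueError(f"line {line_no}: {err}") from None
        out.add(lab)
    if len(out) < len(labels):
        warnings.warn(
            f"line {line_no}: duplicated label(s) in cell {cell!r}; set semantics applied",
            UserWarning,
            stacklevel=3,
        )
    return frozenset(out)


def read_event_table(path, label_sep: str = LABEL_SEPARATOR) -> FrequencyTable:
    """Read a TSV event table (columns cues, outcomes, frequency).

    Round-trips bit-exactly with :func:`write_event_table`.  A custom
    ``label_sep`` may be supplied for files using a different
    within-cell joiner.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event table {path} is missing required column {col!r}")
    rows = []
    for k, rec in enumerate(df.itertuples(index=False)):
        line_no = k + 2  # 1-based, after the header line
        cues = _split_cell(rec.cues, line_no, label_sep)
        outcomes = _split_cell(rec.outcomes, line_no, label_sep)
        try:
            freq = float(rec.frequency)
        except ValueError:
            raise ValueError(f"line {line_no}: frequency {rec.frequency!r} is not a number") from None
        if not freq > 0:
            raise ValueError(f"line {line_no}: frequency must be positive, got {freq}")
        rows.append((LearningEvent(cues, outcomes), freq))
    return FrequencyTable(rows)


def _format_frequency(f: float) -> str:
    return str(int(f)) if float(f).is_integer() else repr(f)


def write_event_table(table: FrequencyTable, path, label_sep: str = LABEL_SEPARATOR) -> None:
    """Write a frequency table as TSV; labels within a cell sorted and joined."""
    lines = ["\t".join(_COLUMNS)]
    for ev, f in table.rows:
        lines.append(
            "\t".join(
                (
                    label_sep.join(sorted(ev.cues)),
                    label_sep.join(sorted(ev.outcomes)),
                    _format_frequency(f),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_weight_matrix(weights: WeightMatrix, path) -> None:
    """Write a weight matrix wide (rows = cues, columns = outcomes), sorted."""
    df = weights.to_frame().sort_index(axis=0).sort_index(axis=1)
    df.to_csv(path, sep="\t", index_label="cue", float_format="%.17g")


def read_weight_matrix(path) -> WeightMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cue", float_precision="round_trip")
    return WeightMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


def write_weight_history(history: WeightHistory, path) -> None:
    """Write a history long (trial, cue, outcome, weight), lexicographically ordered.

    Trial indices are 0-based.  Identical runs produce byte-identical
    files.
    """
    recs = sorted(history.records, key=lambda r: (r[0], r[1], r[2]))
    lines = ["trial\tcue\toutcome\tweight"]
    for t, c, o, w in recs:
        lines.append(f"{t}\t{c}\t{o}\t{w:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_weight_history(path) -> WeightHistory:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"trial": int, "cue": str, "outcome": str, "weight": float},
        float_precision="round_trip",
    )
    for col in ("trial", "cue", "outcome", "weight"):
        if col not in df.columns:
            raise ValueError(f"weight history {path} is missing required column {col!r}")
    pairs = sorted({(c, o) for c, o in zip(df["cue"], df["outcome"])})
    trials = sorted(df["trial"].unique())
    idx = {p: k for k, p in enumerate(pairs)}
    tix = {t: r for r, t in enumerate(trials)}
    import numpy as np

    values = np.zeros((len(trials), len(pairs)))
    for t, c, o, w in df.itertuples(index=False):
        values[tix[t], idx[(c, o)]] = w
    return WeightHistory(pairs, values)
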