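"""Canonical long-format trial table and report serialisation.

The trial table is a TSV with one row per trial and columns
``subject  paradigm  session  trial  cue_1  cue_2  cue_3  chosen
outcome  scr_left  scr_right  rating  rating_type``; optional fields
are empty when missing.  Floats are written with ``repr`` so a write /
read round trip is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .task import TrialRecord

__all__ = ["TRIAL_COLUMNS", "write_trial_table", "read_trial_table",
           "SchemaError", "group_by_subject"]

TRIAL_COLUMNS = ["subject", "paradigm", "session", "trial",
                 "cue_1", "cue_2", "cue_3", "chosen", "outcome",
                 "scr_left", "scr_right", "rating", "rating_type"]


class SchemaError(ValueError):
    """A trial-table row violated the schema; carries the row number."""


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_trial_table(records: Sequence[TrialRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRIAL_COLUMNS)
        for r in records:
            cues = list(r.cues_shown) + [""] * (3 - len(r.cues_shown))
            w.writerow([
                r.subject, r.paradigm, r.session, r.trial,
                cues[0], cues[1], cues[2], r.chosen, r.outcome,
                _fmt(r.scr_left), _fmt(r.scr_right), _fmt(r.rating),
                _fmt(r.rating_type)])


def read_trial_table(path) -> list[TrialRecord]:
    records = []
    with open(path, newline="") as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd, None)
        if header != TRIAL_COLUMNS:
            raise SchemaError(f"bad header: expected {TRIAL_COLUMNS}, "
                              f"got {header}")
        for lineno, row in enumerate(rd, start=2):
            if not row:
                continue
            if len(row) != len(TRIAL_COLUMNS):
                raise SchemaError(f"row {lineno}: expected "
                                  f"{len(TRIAL_COLUMNS)} fields, got {len(row)}")
            d = dict(zip(TRIAL_COLUMNS, row))
            try:
                cues = tuple(c for c in (d["cue_1"], d["cue_2"], d["cue_3"]) if c)
                records.append(TrialRecord(
                    subject=d["subject"], paradigm=d["paradigm"],
                    session=int(d["session"]), trial=int(d["trial"]),
                    cues_shown=cues, chosen=d["chosen"],
                    outcome=int(d["outcome"]),
                    scr_left=float(d["scr_left"]) if d["scr_left"] else None,
                    scr_right=float(d["scr_right"]) if d["scr_right"] else None,
                    rating=float(d["rating"]) if d["rating"] else None,
                    rating_type=d["rating_type"] or None))
            except (ValueError, KeyError) as e:
                raise SchemaError(f"row {lineno}: {e}") from e
    return records


def group_by_subject(records: Sequence[TrialRecord]) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.subject, []).append(r)
    return out
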