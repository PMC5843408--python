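"""Ingestion of study source-data archives into the canonical trial table.

The original behavioural data of the two experiments are distributed
as zip archives ("source data" accompanying the behavioural figures).
Their internal layout is not documented, so ingestion is
adapter-based: an adapter inspects the archive's file list, decides
whether it recognises the layout, and maps the source files onto
canonical :class:`~relieflearn.task.TrialRecord` rows.  An archive no
adapter claims raises :class:`UnrecognisedLayoutError` listing what was
found, so a new adapter can be written on first contact with the real
files.  Ingestion is atomic: either a full table and provenance report
are returned, or an error is raised and nothing is written.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .io import TRIAL_COLUMNS, read_trial_table
from .task import TrialRecord

__all__ = ["ingest_study_data", "register_adapter", "UnrecognisedLayoutError",
           "IngestReport"]


class UnrecognisedLayoutError(RuntimeError):
    pass


@dataclass
class IngestReport:
    experiment: int
    adapter: str
    n_subjects: int
    n_sessions: int
    n_trials: int
    n_ratings: int
    unmapped_files: list


_ADAPTERS: dict = {}


def register_adapter(name: str):
    """Register ``fn(namelist) -> bool`` claim and ``fn.load(zf)`` loader."""
    def deco(fn: Callable):
        _ADAPTERS[name] = fn
        return fn
    return deco


@register_adapter("canonical_tsv")
class _CanonicalTsvAdapter:
    """Archive containing one or more canonical trial-table TSVs."""

    @staticmethod
    def claims(names) -> bool:
        return any(n.endswith(".tsv") for n in names)

    @staticmethod
    def load(zf: zipfile.ZipFile):
        records, used = [], []
        for n in zf.namelist():
            if not n.endswith(".tsv"):
                continue
            with zf.open(n) as fh:
                text = fh.read().decode()
            first = text.split("\n", 1)[0].split("\t")
            if first != TRIAL_COLUMNS:
                continue
            import tempfile, os
            with tempfile.NamedTemporaryFile(
                    "w", suffix=".tsv", delete=False) as tmp:
                tmp.write(text)
                tmp_path = tmp.name
            try:
                records.extend(read_trial_table(tmp_path))
            finally:
                os.unlink(tmp_path)
            used.append(n)
        if not records:
            raise UnrecognisedLayoutError("no canonical TSV found")
        return records, used


def ingest_study_data(archive_path, experiment: int) -> tuple[list, IngestReport]:
    """Map a source-data archive onto the canonical trial table.

    Tries each registered adapter in turn; if none claims the layout,
    raises :class:`UnrecognisedLayoutError` with the archive's file list
    and instructions for writing an adapter.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    archive_path = Path(archive_path)
    if not archive_path.exists():
        raise FileNotFoundError(
            f"source-data archive not found: {archive_path}")
    try:
        zf = zipfile.ZipFile(archive_path)
        names = zf.namelist()
    except zipfile.BadZipFile as e:
        raise UnrecognisedLayoutError(f"corrupted archive: {e}") from e
    with zf:
        for name, adapter in _ADAPTERS.items():
            if adapter.claims(names):
                records, used = adapter.load(zf)
                subjects = {r.subject for r in records}
                sessions = {(r.subject, r.paradigm, r.session) for r in records}
                return records, IngestReport(
                    experiment=experiment, adapter=name,
                    n_subjects=len(subjects), n_sessions=len(sessions),
                    n_trials=len(records),
                    n_ratings=sum(r.rating is not None for r in records),
                    unmapped_files=[n for n in names if n not in used])
    raise UnrecognisedLayoutError(
        "no registered adapter recognises this archive layout.\n"
        f"Files found: {names}\n"
        "Write an adapter with @register_adapter(name): a class with "
        "claims(namelist) -> bool and load(zipfile) -> (records, used_files) "
        "mapping the source files to canonical TrialRecord rows.")
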