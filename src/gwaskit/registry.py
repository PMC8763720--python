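"""Flat-file study registry: per-study canonical TSV + metadata JSON, plus a
single JSON index of all registered studies."""

from __future__ import annotations

import json
from pathlib import Path

from .io import read_sumstats, write_sumstats
from .types import StudyMetadata, SumstatsTable

INDEX_NAME = "index.json"


class RegistryConflictError(RuntimeError):
    """Raised when registering a study_id that already exists."""


def _index_path(registry_dir: Path) -> Path:
    return registry_dir / INDEX_NAME


def _load_index(registry_dir: Path) -> list[dict]:
    p = _index_path(registry_dir)
    if not p.exists():
        return []
    return json.loads(p.read_text())


def register_study(
    table: SumstatsTable,
    registry_dir: str | Path,
    qc_verdict: str | None = None,
    force: bool = False,
    overwrite: bool = False,
) -> str:
    """Register one study in the directory registry.

    A QC verdict must accompany the table (``qc_verdict`` or a ``qc_report``
    attribute previously attached); a ``recommended`` verdict — or the
    explicit ``force`` override — gates registration, mirroring an
    upload-review step where the final decision rests with the user.
    """
    registry_dir = Path(registry_dir)
    registry_dir.mkdir(parents=True, exist_ok=True)
    verdict = qc_verdict
    if verdict is None:
        report = getattr(table, "qc_report", None)
        verdict = getattr(report, "verdict", None)
    if verdict is None and not force:
        raise ValueError(
            "no QC verdict attached; run qc first or pass force=True to override"
        )
    if verdict == "not_recommended" and not force:
        raise ValueError(
            "study not recommended for upload by QC; pass force=True to override"
        )

    sid = table.metadata.study_id
    index = _load_index(registry_dir)
    existing = {e["study_id"] for e in index}
    if sid in existing and not overwrite:
        raise RegistryConflictError(f"study_id {sid!r} already registered")

    write_sumstats(table, registry_dir / f"{sid}.tsv")
    meta = table.metadata.to_dict()
    meta["n_records"] = table.n_records
    meta["qc_verdict"] = verdict
    (registry_dir / f"{sid}.json").write_text(json.dumps(meta, indent=2) + "\n")
    index = [e for e in index if e["study_id"] != sid] + [meta]
    _index_path(registry_dir).write_text(json.dumps(index, indent=2) + "\n")
    return sid


def list_studies(registry_dir: str | Path, domain: str | None = None) -> list[dict]:
    """Metadata entries in the registry, optionally filtered by domain."""
    index = _load_index(Path(registry_dir))
    if domain is not None:
        index = [e for e in index if e.get("domain") == domain]
    return index


def load_study(registry_dir: str | Path, study_id: str) -> SumstatsTable:
    """Load one registered study back into memory."""
    registry_dir = Path(registry_dir)
    meta_path = registry_dir / f"{study_id}.json"
    if not meta_path.exists():
        raise KeyError(f"study_id {study_id!r} not in registry")
    meta = json.loads(meta_path.read_text())
    metadata = StudyMetadata.from_dict(meta)
    return read_sumstats(registry_dir / f"{study_id}.tsv", metadata=metadata)
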