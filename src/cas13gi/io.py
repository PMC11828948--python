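"""On-disk formats: library CSV, oligo FASTA, sample sheets, manifests.

All formats are plain text: CSV for library definitions, TSV for matrices
and results, FASTA/FASTQ for sequences, JSON for reports and manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .library import GuideArray, GuideElement, LibraryDesign, build_library, render_oligo

__all__ = [
    "write_elements_csv",
    "read_elements_csv",
    "write_constructs_csv",
    "write_oligos_fasta",
    "read_sample_sheet",
    "write_manifest",
    "file_sha256",
]


def write_elements_csv(elements: Sequence, path: str | Path) -> None:
    rows = []
    for e in elements:
        rows.append(
            dict(
                element_id=e.element_id,
                target=e.target,
                spacer=e.spacer if e.element_kind == "guide" else "",
                group=getattr(e, "group", ""),
                rank=getattr(e, "rank", ""),
                element_kind=e.element_kind,
                members=";".join(e.members) if e.element_kind == "array" else "",
                member_spacers=";".join(e.spacers) if e.element_kind == "array" else "",
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_elements_csv(path: str | Path) -> list:
    df = pd.read_csv(path, dtype=str).fillna("")
    elements: list = []
    for r in df.itertuples():
        if r.element_kind == "array":
            elements.append(
                GuideArray(
                    element_id=r.element_id,
                    target=r.target,
                    members=tuple(r.members.split(";")),
                    spacers=tuple(r.member_spacers.split(";")),
                )
            )
        else:
            elements.append(
                GuideElement(
                    element_id=r.element_id,
                    target=r.target,
                    spacer=r.spacer,
                    group=int(r.group or 0),
                    rank=int(r.rank or 0),
                )
            )
    return elements


def read_library_csv(path: str | Path, strategy: str) -> LibraryDesign:
    return build_library(read_elements_csv(path), strategy)


def write_constructs_csv(library: LibraryDesign, path: str | Path) -> None:
    library.constructs_frame().to_csv(path, index=False)


def write_oligos_fasta(library: LibraryDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in library.constructs:
            fh.write(f">{c.construct_id}\n{render_oligo(c, library)}\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, condition, replicate [, fastq_r1, fastq_r2]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if (df["condition"] == "baseline").sum() < 1:
        raise ValueError("sample sheet needs a baseline sample")
    dup = df.duplicated(subset=["condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (condition, replicate) rows in sample sheet")
    return df.set_index("sample_id")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, stage_outputs: dict, params: dict, seed: int) -> None:
    manifest = dict(
        seed=seed,
        params=params,
        outputs={
            stage: {str(p): file_sha256(p) for p in paths if Path(p).exists()}
            for stage, paths in stage_outputs.items()
        },
    )
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
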