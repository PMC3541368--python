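"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are deliberately plain:

- chromatograms: CSV with ``rt_seconds,intensity`` columns preceded by
  ``# key=value`` metadata lines (mz_low, mz_high, sample_id, optionally
  peptide and condition);
- PSM tables: CSV with the canonical column set, modifications encoded as
  ``pos:delta;pos:delta``;
- image stacks: one multi-page TIFF per channel, z as pages, paired by a
  YAML manifest (never by filename guessing);
- proteins: FASTA; transcript sets: one ID per line;
- ground truth for synthetic fixtures: a YAML sidecar next to the fixture.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .imgquant import ImageStack, NuclearMask
from .motifscan import ProteinRecord
from .msquant import PSM_COLUMNS, ChromatogramTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_psm_csv",
    "read_psm_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_tiff",
    "write_fasta",
    "read_fasta",
    "write_id_list",
    "read_id_list",
    "write_yaml",
    "read_yaml",
]


# -- chromatogram CSV -------------------------------------------------------

def write_trace_csv(trace: ChromatogramTrace, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "mz_low": trace.mz_window[0],
        "mz_high": trace.mz_window[1],
        "sample_id": trace.sample_id,
    }
    if trace.peptide:
        meta["peptide"] = trace.peptide
    if trace.condition:
        meta["condition"] = trace.condition
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        pd.DataFrame(
            {"rt_seconds": trace.retention_times, "intensity": trace.intensities}
        ).to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> ChromatogramTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(_stdio.StringIO("\n".join(body_lines)))
    for required in ("mz_low", "mz_high"):
        if required not in meta:
            raise ValueError(f"trace file {path} lacks metadata line '# {required}=...'")
    return ChromatogramTrace(
        retention_times=df["rt_seconds"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        mz_window=(float(meta["mz_low"]), float(meta["mz_high"])),
        sample_id=meta.get("sample_id", ""),
        peptide=meta.get("peptide", ""),
        condition=meta.get("condition", ""),
    )


# -- PSM CSV ----------------------------------------------------------------

def _encode_mods(mods: Sequence[tuple[int, float]]) -> str:
    return ";".join(f"{pos}:{delta!r}" for pos, delta in mods)


def _decode_mods(text: str) -> tuple[tuple[int, float], ...]:
    if not isinstance(text, str) or not text.strip():
        return ()
    out = []
    for item in text.split(";"):
        pos, _, delta = item.partition(":")
        out.append((int(pos), float(delta)))
    return tuple(out)


def write_psm_csv(psms: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical PSM columns; extra columns (e.g. synthetic ground
    truth) are preserved after the canonical ones."""
    df = psms.copy()
    df["modifications"] = df["modifications"].map(
        lambda m: _encode_mods(m) if not isinstance(m, str) else m
    )
    extra = [c for c in df.columns if c not in PSM_COLUMNS]
    df[list(PSM_COLUMNS) + extra].to_csv(path, index=False)


def read_psm_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table {path} lacks column(s): {sorted(missing)}")
    df["modifications"] = df["modifications"].map(_decode_mods)
    if df["validated"].dtype == object:
        df["validated"] = df["validated"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    else:
        df["validated"] = df["validated"].astype(bool)
    if "true_pass" in df.columns and df["true_pass"].dtype == object:
        df["true_pass"] = df["true_pass"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    return df


# -- TIFF stacks ------------------------------------------------------------

def write_stack_tiff(stack: ImageStack, path: str | Path) -> None:
    """One channel per file, z-planes as pages, float32 intensities."""
    tifffile.imwrite(Path(path), stack.voxels.astype(np.float32))


def read_stack_tiff(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (0.041, 0.232, 0.232),
    channel_label: str = "signal",
) -> ImageStack:
    voxels = tifffile.imread(Path(path))
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis]
    return ImageStack(
        voxels=np.asarray(voxels, dtype=float),
        voxel_size=voxel_size,
        channel_label=channel_label,
    )


def write_mask_tiff(mask: NuclearMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.voxels.astype(np.uint8))


# -- FASTA ------------------------------------------------------------------

def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# -- ID lists ---------------------------------------------------------------

def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def read_id_list(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


# -- YAML sidecars / manifests ----------------------------------------------

def write_yaml(data: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
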