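"""Readers, writers, config handling and run manifests.

FASTA goes through Biopython, TIFF through tifffile, tables through
pandas. All writes are atomic (temp file + rename) so interrupted runs
never leave partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .design import DesignConfig, ProbeSet
from .errors import InvalidInputError
from .imaging import ImageStack, MycelialMask, QuantResult
from .sequences import SequenceRecord

PACKAGE_VERSION = "0.1.0"


# --------------------------------------------------------------------------
# atomic writes

def atomic_write_text(path: os.PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path: os.PathLike, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: os.PathLike, role: str) -> List[SequenceRecord]:
    """Read a (multi-record) FASTA file, assigning every record the role."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    try:
        records = [
            SequenceRecord(rec.id, str(rec.seq), role)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # Biopython parse failure
        raise InvalidInputError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return records


def write_fasta(path: os.PathLike, records: Iterable[SequenceRecord]) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.role)
        for r in records
    ]
    lines = []
    for rec in bio:
        lines.append(f">{rec.id} {rec.description}")
        lines.append(str(rec.seq))
    atomic_write_text(path, "\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# probe tables

def probe_table(probe_set: ProbeSet) -> pd.DataFrame:
    """Tidy per-candidate table with metrics, flags and acceptance."""
    flag_names = ("unique", "tm", "levenshtein", "structure")
    rows = []
    for i, c in enumerate(probe_set.candidates):
        row = {
            "id": f"probe_{c.source_id}_{c.position}",
            "source_id": c.source_id,
            "position": c.position,
            "strand": "-",  # probe is the reverse complement of the target site
            "target_kmer": c.target_kmer,
            "probe_sequence": c.probe_sequence,
            "tm_c": c.tm_c,
            "min_suffix_lev": c.min_suffix_lev,
        }
        for name in flag_names:
            row[f"flag_{name}"] = c.flags.get(name)
        row["accepted"] = c.accepted
        rows.append(row)
    return pd.DataFrame(rows)


def write_probe_tsv(path: os.PathLike, probe_set: ProbeSet) -> None:
    df = probe_table(probe_set)
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_accepted_fasta(path: os.PathLike, probe_set: ProbeSet) -> None:
    """Accepted probes as FASTA; header carries the 1-based inclusive
    coordinates of the target site for human readability."""
    lines = []
    for c in probe_set.accepted:
        start1 = c.position + 1
        end1 = c.position + len(c.target_kmer)
        lines.append(f">probe_{c.source_id}_{c.position} {c.source_id}:{start1}-{end1}")
        lines.append(c.probe_sequence)
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------------
# TIFF stacks

def read_stack(
    path: os.PathLike,
    channel_roles: Dict[str, int],
    pixel_size_um: float,
    image_id: Optional[str] = None,
) -> ImageStack:
    """Read a TIFF into an ImageStack.

    Accepts (c, z, y, x), (c, y, x) (single slice) or (y, x) (single
    channel, single slice) arrays.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise InvalidInputError(
            f"cannot interpret TIFF of shape {data.shape} as (c, z, y, x)"
        )
    return ImageStack(
        data=np.asarray(data, dtype=float),
        channel_roles=channel_roles,
        pixel_size_um=pixel_size_um,
        image_id=image_id or path.stem,
    )


def _tiff_bytes(array: np.ndarray) -> bytes:
    buf = io.BytesIO()
    tifffile.imwrite(buf, array)
    return buf.getvalue()


def write_stack(path: os.PathLike, stack: ImageStack) -> None:
    """Write a float stack as 16-bit TIFF, linearly quantized from the
    [0, max] intensity range (documented rounding: round-half-even)."""
    data = np.asarray(stack.data, dtype=float)
    peak = data.max() if data.max() > 0 else 1.0
    scaled = np.rint(data / peak * 65535.0).astype(np.uint16)
    atomic_write_bytes(path, _tiff_bytes(scaled))


def write_mask_tiff(path: os.PathLike, mask: MycelialMask) -> None:
    atomic_write_bytes(path, _tiff_bytes(mask.mask.astype(np.uint8) * 255))


# --------------------------------------------------------------------------
# quantification tables

def density_table(results: Sequence[QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "image_id": r.image_id,
                "count": len(r.blobs_in_mask),
                "area_um2": r.mask.area_um2,
                "density_per_100um2": (
                    r.density.density_per_100um2 if r.density else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def blob_table(results: Sequence[QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        in_mask_keys = {
            (round(float(b[0]), 6), round(float(b[1]), 6))
            for b in r.blobs_in_mask.blobs
        }
        for b in r.blobs_all.blobs:
            rows.append(
                {
                    "image_id": r.image_id,
                    "y": float(b[0]),
                    "x": float(b[1]),
                    "sigma": float(b[2]),
                    "response": float(b[3]),
                    "in_mask": (
                        round(float(b[0]), 6),
                        round(float(b[1]), 6),
                    )
                    in in_mask_keys,
                }
            )
    return pd.DataFrame(
        rows, columns=["image_id", "y", "x", "sigma", "response", "in_mask"]
    )


# --------------------------------------------------------------------------
# config and manifest

def load_yaml_config(path: Optional[os.PathLike]) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidInputError(f"config {path} must be a mapping")
    return data


def merge_config(base: dict, overrides: dict) -> dict:
    """Flat merge; explicit (non-None) overrides win over file values."""
    out = dict(base)
    for key, value in overrides.items():
        if value is not None:
            out[key] = value
    return out


def file_digest(path: os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: os.PathLike,
    subcommand: str,
    inputs: Sequence[os.PathLike],
    resolved_config: dict,
    counts: Optional[dict] = None,
) -> Path:
    """Write run metadata (tool version, timestamp, input digests, resolved
    config, stage survivor counts) beside the outputs."""
    manifest = {
        "tool": "endofish",
        "version": PACKAGE_VERSION,
        "subcommand": subcommand,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "config": _jsonable(resolved_config),
        "counts": counts or {},
    }
    path = Path(out_dir) / f"manifest_{subcommand}.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
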