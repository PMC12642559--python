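"""On-disk formats: MGF spectra, candidate JSON, results CSV, checkpoints.

The MGF dialect is deliberately strict: blocks are delimited by BEGIN IONS /
END IONS, header keys are case-insensitive, PEPMASS may carry an optional
second (intensity) token, CHARGE is optional, and the adduct is read from an
ADDUCT= or PRECURSOR_TYPE= header. Malformed blocks raise MgfParseError
naming the 1-based block index rather than being skipped, because silently
dropping queries corrupts downstream metrics.

The checkpoint is a single self-contained file: a JSON header (config,
element-scaler state, array manifest, format version) followed by raw
little-endian float64 array bytes in sorted-name order. The layout is fully
deterministic, so save -> load -> save round-trips bit-identically.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import SUPPORTED_ADDUCTS, parse_molecule
from .spectra import ElementScaler, RawSpectrum

logger = logging.getLogger(__name__)

CHECKPOINT_MAGIC = b"SPECMOLCKPT"
CHECKPOINT_VERSION = "1"


class MgfParseError(ValueError):
    pass


class CandidateFileError(ValueError):
    pass


class CheckpointError(ValueError):
    pass


@dataclass
class CandidateFile:
    """Mapping query_id -> candidate SMILES lists (validated, capped)."""

    candidates: dict[str, list[str]]
    mode: str = "custom"  # by_mass | by_formula | custom
    n_dropped: int = 0


# --- MGF -----------------------------------------------------------------

_ADDUCT_KEYS = ("ADDUCT", "PRECURSOR_TYPE")
_KNOWN_KEYS = {"TITLE", "PEPMASS", "CHARGE", "MOLECULE_ID", "SMILES", *_ADDUCT_KEYS}


def read_mgf(path) -> list[RawSpectrum]:
    """Parse an MGF file into a list of :class:`RawSpectrum`.

    One spectrum per BEGIN IONS/END IONS block; unknown header keys are
    preserved in the spectrum's metadata map.
    """
    path = Path(path)
    text = path.read_text()
    spectra: list[RawSpectrum] = []
    block: list[str] | None = None
    n_block = 0
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.upper() == "BEGIN IONS":
            if block is not None:
                raise MgfParseError(f"block {n_block + 1}: nested BEGIN IONS")
            block = []
            n_block += 1
            continue
        if line.upper() == "END IONS":
            if block is None:
                raise MgfParseError(f"block {n_block}: END IONS without BEGIN IONS")
            spectra.append(_parse_block(block, n_block))
            block = None
            continue
        if block is not None:
            block.append(line)
    if block is not None:
        raise MgfParseError(f"block {n_block}: missing END IONS")
    return spectra


def _parse_block(lines: list[str], index: int) -> RawSpectrum:
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for line in lines:
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            headers[key.strip().upper()] = value.strip()
        else:
            toks = line.split()
            if len(toks) < 2:
                raise MgfParseError(f"block {index}: malformed peak line {line!r}")
            try:
                mz, inten = float(toks[0]), float(toks[1])
            except ValueError as exc:
                raise MgfParseError(
                    f"block {index}: non-numeric peak line {line!r}"
                ) from exc
            if mz <= 0 or inten < 0:
                raise MgfParseError(
                    f"block {index}: invalid peak (mz={mz}, intensity={inten})"
                )
            peaks.append((mz, inten))
    if "PEPMASS" not in headers:
        raise MgfParseError(f"block {index}: missing PEPMASS")
    try:
        precursor_mz = float(headers["PEPMASS"].split()[0])
    except ValueError as exc:
        raise MgfParseError(f"block {index}: non-numeric PEPMASS") from exc
    if precursor_mz <= 0:
        raise MgfParseError(f"block {index}: non-positive PEPMASS")
    if not peaks:
        raise MgfParseError(f"block {index}: no peaks")
    adduct = None
    for key in _ADDUCT_KEYS:
        if key in headers:
            adduct = headers[key]
            break
    if adduct is None:
        adduct = "[M+H]+"  # common default for positive-mode exports
    if adduct not in SUPPORTED_ADDUCTS:
        raise MgfParseError(
            f"block {index}: unsupported adduct {adduct!r}; "
            f"supported adducts: {list(SUPPORTED_ADDUCTS)}"
        )
    spectrum_id = headers.get("TITLE", f"spectrum_{index}")
    metadata = {k: v for k, v in headers.items() if k not in _KNOWN_KEYS}
    return RawSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        adduct=adduct,
        peaks=tuple(peaks),
        molecule_id=headers.get("MOLECULE_ID"),
        smiles=headers.get("SMILES"),
        metadata=metadata,
    )


def write_mgf(spectra: list[RawSpectrum], path) -> None:
    """Write spectra in the same MGF dialect read_mgf accepts."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.spectrum_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        lines.append(f"ADDUCT={s.adduct}")
        if s.molecule_id is not None:
            lines.append(f"MOLECULE_ID={s.molecule_id}")
        if s.smiles is not None:
            lines.append(f"SMILES={s.smiles}")
        for k, v in sorted(s.metadata.items()):
            lines.append(f"{k}={v}")
        for mz, inten in s.peaks:
            lines.append(f"{mz:.6f} {inten:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# --- candidate JSON ------------------------------------------------------

def read_candidates(path, mode: str = "custom", cap: int = 256) -> CandidateFile:
    """Read a flat {query_id: [smiles, ...]} candidate JSON.

    Invalid SMILES are dropped with a logged warning and counted; candidate
    lists are truncated to ``cap`` entries.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise CandidateFileError("top-level JSON value must be an object")
    out: dict[str, list[str]] = {}
    dropped = 0
    for qid, lst in obj.items():
        if not isinstance(lst, list):
            raise CandidateFileError(f"candidates for {qid!r} must be an array")
        kept: list[str] = []
        for smi in lst:
            try:
                parse_molecule(smi)
            except Exception:
                dropped += 1
                logger.warning("query %s: dropping invalid SMILES %r", qid, smi)
                continue
            kept.append(smi)
        if not kept:
            logger.warning("query %s has no valid candidates; will be skipped", qid)
        out[qid] = kept[:cap]
    return CandidateFile(out, mode=mode, n_dropped=dropped)


def write_candidates(cands: CandidateFile, path) -> None:
    Path(path).write_text(json.dumps(cands.candidates, indent=1, sort_keys=True))


# --- results CSV ---------------------------------------------------------

def write_results(tables, path) -> None:
    """Write ranking tables as CSV (query_id, candidate_smiles, score, rank).

    Rows sorted by (query_id, rank, candidate_smiles); floats rendered with 6
    decimal places so byte output is deterministic for fixed input.
    """
    import pandas as pd

    rows = [
        {
            "query_id": t.query_id,
            "candidate_smiles": smiles,
            "score": f"{score:.6f}",
            "rank": rank,
        }
        for t in tables
        for smiles, score, rank in t.entries
    ]
    df = pd.DataFrame(rows, columns=["query_id", "candidate_smiles", "score", "rank"])
    if len(df):
        df = df.sort_values(["query_id", "rank", "candidate_smiles"], kind="mergesort")
    df.to_csv(path, index=False)


# --- checkpoint ----------------------------------------------------------

@dataclass
class Checkpoint:
    """Self-contained model state: parameters, scaler, config, version."""

    params: dict[str, np.ndarray]
    scaler: ElementScaler
    config: dict
    version: str = CHECKPOINT_VERSION
    extra: dict = field(default_factory=dict)


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    names = sorted(ckpt.params)
    manifest = {n: list(ckpt.params[n].shape) for n in names}
    header = json.dumps(
        {
            "version": ckpt.version,
            "config": ckpt.config,
            "scaler": ckpt.scaler.max_count,
            "arrays": manifest,
            "extra": ckpt.extra,
        },
        sort_keys=True,
    ).encode()
    with open(path, "wb") as fh:
        fh.write(CHECKPOINT_MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        for n in names:
            fh.write(np.ascontiguousarray(ckpt.params[n], dtype="<f8").tobytes())


def load_checkpoint(path) -> Checkpoint:
    with open(path, "rb") as fh:
        magic = fh.read(len(CHECKPOINT_MAGIC))
        if magic != CHECKPOINT_MAGIC:
            raise CheckpointError(f"{path}: not a specmol checkpoint")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"{path}: checkpoint version {header.get('version')!r} "
                f"incompatible with supported version {CHECKPOINT_VERSION!r}"
            )
        params: dict[str, np.ndarray] = {}
        for name in sorted(header["arrays"]):
            shape = tuple(header["arrays"][name])
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(count * 8)
            params[name] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    return Checkpoint(
        params=params,
        scaler=ElementScaler(header["scaler"]),
        config=header["config"],
        version=header["version"],
        extra=header.get("extra", {}),
    )
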