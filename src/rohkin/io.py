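"""Interchange tables and reports shared by all pipeline stages.

Every writer embeds a metadata header (``# key = value`` lines: package
version, master seed, parameter hash) so any artifact records how it was
produced; readers skip those lines.  Coordinates are written with 4 decimal
places in cM.  Writers stage to a temporary file and rename, so a failed
run leaves no partial output, and refuse to overwrite existing files unless
forced.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from . import __version__
from .pedigree import ROHSegment
from .profiles import DEFAULT_BINNING, ROHBinning, ROHProfile, bin_profile

__all__ = [
    "params_hash",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "write_report",
    "read_report",
]


def params_hash(params: dict[str, Any]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed: int | None, params: dict[str, Any] | None) -> str:
    lines = [f"# rohkin_version = {__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if params:
        lines.append(f"# params_hash = {params_hash(params)}")
    return "\n".join(lines) + "\n"


def _safe_write(path: str | Path, text: str, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_segments_tsv(
    path: str | Path,
    segments: Iterable[tuple[str, int, ROHSegment]],
    seed: int | None = None,
    params: dict[str, Any] | None = None,
    force: bool = False,
) -> None:
    """Segment table: individual_id, replicate, chromosome, start/end/length cM."""
    rows = ["individual_id\treplicate\tchromosome\tstart_cM\tend_cM\tlength_cM"]
    for ind, rep, seg in segments:
        rows.append(
            f"{ind}\t{rep}\t{seg.chromosome}\t{seg.start_cM:.4f}"
            f"\t{seg.end_cM:.4f}\t{seg.length_cM:.4f}"
        )
    _safe_write(path, _header(seed, params) + "\n".join(rows) + "\n", force)


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    required = {"individual_id", "chromosome", "start_cM", "end_cM", "length_cM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def segments_from_frame(df: pd.DataFrame) -> dict[str, list[ROHSegment]]:
    """Group a segment table into per-individual ROHSegment lists."""
    out: dict[str, list[ROHSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.individual_id), []).append(
            ROHSegment(str(row.chromosome), float(row.start_cM), float(row.end_cM))
        )
    return out


def _profile_columns(binning: ROHBinning) -> list[str]:
    cols = ["individual_id"]
    for lab in binning.labels[:-1]:
        cols += [f"sum_{lab}", f"n_{lab}"]
    cols += [f"sum_{binning.labels[-1]}", f"n_{binning.labels[-1]}"]
    cols += ["longest_cM", "n_snps_covered"]
    return cols


def write_profiles_tsv(
    path: str | Path,
    profiles: Iterable[ROHProfile],
    seed: int | None = None,
    params: dict[str, Any] | None = None,
    force: bool = False,
) -> None:
    profiles = list(profiles)
    binning = profiles[0].binning if profiles else DEFAULT_BINNING
    rows = ["\t".join(_profile_columns(binning))]
    for p in profiles:
        vals: list[str] = [p.individual_id]
        for s, n in zip(p.bin_sums, p.bin_counts):
            vals += [f"{s:.4f}", str(n)]
        vals += [
            f"{p.longest_cM:.4f}",
            "" if p.n_snps_covered is None else str(p.n_snps_covered),
        ]
        rows.append("\t".join(vals))
    _safe_write(path, _header(seed, params) + "\n".join(rows) + "\n", force)


def read_profiles_tsv(
    path: str | Path, binning: ROHBinning = DEFAULT_BINNING
) -> list[ROHProfile]:
    """Read a profile table (schema written by :func:`write_profiles_tsv`).

    Segment lists are not recoverable from the binned table; profiles are
    reconstructed with empty segment tuples and the binned statistics, which
    is all the downstream estimators use.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    labels = binning.labels
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sums = tuple(float(d[f"sum_{lab}"]) for lab in labels)
        counts = tuple(int(d[f"n_{lab}"]) for lab in labels)
        cov = d.get("n_snps_covered")
        cov = None if cov is None or pd.isna(cov) else int(cov)
        out.append(
            ROHProfile(
                individual_id=str(d["individual_id"]),
                segments=(),
                bin_sums=sums,
                bin_counts=counts,
                sum_gt20_cM=sums[-1],
                longest_cM=float(d["longest_cM"]),
                n_snps_covered=cov,
                binning=binning,
            )
        )
    return out


def profile_from_segments(
    individual_id: str,
    df: pd.DataFrame,
    binning: ROHBinning = DEFAULT_BINNING,
    n_snps_covered: int | None = None,
) -> ROHProfile:
    """Build a profile from the rows of a segment table for one individual
    (accepts tables written by this package or reformatted external calls)."""
    sub = df[df["individual_id"] == individual_id]
    segs = [
        ROHSegment(str(r.chromosome), float(r.start_cM), float(r.end_cM))
        for r in sub.itertuples(index=False)
    ]
    return bin_profile(individual_id, segs, binning, n_snps_covered=n_snps_covered)


def write_report(
    path: str | Path,
    payload: dict[str, Any],
    seed: int | None = None,
    params: dict[str, Any] | None = None,
    force: bool = False,
) -> None:
    """JSON report with a metadata block."""
    doc = {
        "metadata": {
            "rohkin_version": __version__,
            "seed": seed,
            "params_hash": params_hash(params) if params else None,
        },
        **payload,
    }
    _safe_write(path, json.dumps(doc, indent=2, default=float) + "\n", force)


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
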