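"""Genetic-map coordinate system.

All simulation and segment arithmetic in this package happens in genetic-map
units (centimorgans).  A :class:`GenomeMap` is an ordered collection of
autosomes with their genetic lengths; marker-level positions are optional and
carried only for bp<->cM interpolation and for the EIGENSTRAT/PLINK writers.
The X chromosome is deliberately excluded: every analysis downstream is
autosomal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ChromosomeMap", "GenomeMap", "load_genetic_map", "write_map"]

#: chromosome names never treated as autosomes
_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26"}


@dataclass(frozen=True)
class ChromosomeMap:
    """One autosome in genetic-map coordinates.

    Parameters
    ----------
    name
        Chromosome identifier (``"1"`` ... ``"22"``).
    length_cM
        Genetic length in centimorgans; must be positive.
    positions
        Optional marker rows ``(marker_id, physical_bp, genetic_cM)`` with
        non-decreasing genetic positions whose last entry equals
        ``length_cM``.
    """

    name: str
    length_cM: float
    positions: tuple[tuple[str, int, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.length_cM > 0:
            raise ValueError(f"chromosome {self.name}: length_cM must be > 0")
        if self.positions is not None:
            cms = np.asarray([p[2] for p in self.positions], dtype=float)
            if np.any(np.diff(cms) < 0):
                raise ValueError(
                    f"chromosome {self.name}: genetic positions must be non-decreasing"
                )
            if abs(cms[-1] - self.length_cM) > 1e-6:
                raise ValueError(
                    f"chromosome {self.name}: length_cM ({self.length_cM}) must equal "
                    f"last genetic position ({cms[-1]})"
                )

    def bp_to_cM(self, bp: float) -> float:
        """Piecewise-linear interpolation of genetic position from physical."""
        if self.positions is None:
            raise ValueError(f"chromosome {self.name} carries no marker positions")
        bps = np.asarray([p[1] for p in self.positions], dtype=float)
        cms = np.asarray([p[2] for p in self.positions], dtype=float)
        return float(np.interp(bp, bps, cms))

    def cM_to_bp(self, cm: float) -> float:
        if self.positions is None:
            raise ValueError(f"chromosome {self.name} carries no marker positions")
        bps = np.asarray([p[1] for p in self.positions], dtype=float)
        cms = np.asarray([p[2] for p in self.positions], dtype=float)
        return float(np.interp(cm, cms, bps))


@dataclass(frozen=True)
class GenomeMap:
    """Ordered autosomes; houses the total map length G used by F*G arithmetic."""

    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("a GenomeMap needs at least one autosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in GenomeMap")
        for n in names:
            if n.upper() in _NON_AUTOSOMES:
                raise ValueError(f"non-autosome {n!r} not allowed in GenomeMap")

    @property
    def total_length_cM(self) -> float:
        return float(sum(c.length_cM for c in self.chromosomes))

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == str(name):
                return c
        raise KeyError(name)


def _load_default() -> GenomeMap:
    ref = importlib.resources.files("rohkin.data") / "default_map.tsv"
    chroms = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, length = line.split("\t")
        chroms.append(ChromosomeMap(name=name, length_cM=float(length)))
    return GenomeMap(chromosomes=tuple(chroms))


def _load_length_table(path: Path) -> GenomeMap:
    chroms = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        name = parts[0]
        if name.upper() in _NON_AUTOSOMES:
            continue
        chroms.append(ChromosomeMap(name=name, length_cM=float(parts[1])))
    if not chroms:
        raise ValueError(f"{path}: no autosomes found")
    return GenomeMap(chromosomes=tuple(chroms))


def _load_plink_map(path: Path) -> GenomeMap:
    """PLINK .map dialect: chrom, marker id, genetic position (cM), bp."""
    per_chrom: dict[str, list[tuple[str, int, float]]] = {}
    order: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, marker, cm, bp = line.split()[:4]
        if chrom.upper() in _NON_AUTOSOMES:
            continue
        if chrom not in per_chrom:
            per_chrom[chrom] = []
            order.append(chrom)
        per_chrom[chrom].append((marker, int(bp), float(cm)))
    if not per_chrom:
        raise ValueError(f"{path}: no autosomes found")
    chroms = []
    for name in order:
        rows = per_chrom[name]
        cms = [r[2] for r in rows]
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise ValueError(f"{path}: decreasing genetic positions on chromosome {name}")
        # shift so the map spans [0, L)
        offset = cms[0]
        rows = [(m, bp, cm - offset) for m, bp, cm in rows]
        length = rows[-1][2]
        if length <= 0:
            raise ValueError(f"{path}: chromosome {name} has zero genetic length")
        chroms.append(
            ChromosomeMap(name=name, length_cM=length, positions=tuple(rows))
        )
    return GenomeMap(chromosomes=tuple(chroms))


def load_genetic_map(source: str | Path = "default") -> GenomeMap:
    """Load a genetic map.

    ``source="default"`` returns the bundled 22-autosome sex-averaged map
    (total length 3545.75 cM).  Otherwise ``source`` is a path to either a
    PLINK ``.map`` file (4 columns) or a two-column chrom/length_cM table.
    """
    if source == "default":
        return _load_default()
    path = Path(source)
    if not path.is_file():
        raise FileNotFoundError(f"genetic map not readable: {path}")
    first = ""
    for line in path.read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            first = line
            break
    ncols = len(first.split())
    if ncols >= 4:
        return _load_plink_map(path)
    if ncols == 2:
        return _load_length_table(path)
    raise ValueError(f"{path}: unrecognized map format ({ncols} columns)")


def write_map(genome: GenomeMap, path: str | Path) -> None:
    """Write a PLINK .map dialect file (synthetic end markers when the map
    carries no marker positions)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in genome.chromosomes:
            rows = c.positions
            if rows is None:
                rows = (
                    (f"chr{c.name}_start", 1, 0.0),
                    (f"chr{c.name}_end", 2, c.length_cM),
                )
            for marker, bp, cm in rows:
                fh.write(f"{c.name}\t{marker}\t{cm:.4f}\t{bp}\n")
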