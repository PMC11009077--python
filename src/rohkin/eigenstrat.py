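"""EIGENSTRAT text-dialect reader/writer.

Three files sharing a prefix: ``.geno`` (one character per individual per
site line: reference-allele count 0/1/2, 9 missing), ``.snp`` (six columns:
marker id, chromosome, genetic position in Morgans, physical bp, ref, alt)
and ``.ind`` (individual id, sex code, population label).

Genetic positions are stored in Morgans in ``.snp`` per the format
convention and converted to/from the cM used everywhere else in this
package.  Allele frequencies are not part of the format; the reader
estimates them from the non-missing calls unless given explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .caller import MISSING, GenotypeMatrix

__all__ = ["read_eigenstrat", "write_eigenstrat"]


def write_eigenstrat(
    genotypes: GenotypeMatrix,
    prefix: str | Path,
    sex_codes: dict[str, str] | None = None,
    population: str = "synthetic",
) -> None:
    prefix = Path(prefix)
    sites = genotypes.sites
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for i, row in enumerate(sites.itertuples(index=False)):
            marker = f"snp_{row.chromosome}_{i}"
            fh.write(
                f"{marker}\t{row.chromosome}\t{row.cM / 100.0:.6f}\t{row.bp}"
                f"\t{row.ref}\t{row.alt}\n"
            )
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for ind in genotypes.individuals:
            sex = (sex_codes or {}).get(ind, "U")
            fh.write(f"{ind}\t{sex}\t{population}\n")
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for i in range(len(sites)):
            fh.write("".join(str(v) for v in genotypes.calls[i]) + "\n")


def read_eigenstrat(
    prefix: str | Path,
    ploidy_mode: str = "diploid",
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    prefix = Path(prefix)
    for ext in (".geno", ".snp", ".ind"):
        if not prefix.with_suffix(ext).is_file():
            raise FileNotFoundError(f"missing {prefix.with_suffix(ext)}")
    snp = pd.read_csv(
        prefix.with_suffix(".snp"),
        sep=r"\s+",
        header=None,
        names=["marker", "chromosome", "morgans", "bp", "ref", "alt"],
        dtype={"chromosome": str},
    )
    ind = pd.read_csv(
        prefix.with_suffix(".ind"),
        sep=r"\s+",
        header=None,
        names=["individual", "sex", "population"],
    )
    lines = prefix.with_suffix(".geno").read_text().splitlines()
    if len(lines) != len(snp):
        raise ValueError(".geno line count does not match .snp")
    calls = np.empty((len(snp), len(ind)), dtype=np.int8)
    for i, line in enumerate(lines):
        if len(line) != len(ind):
            raise ValueError(f".geno line {i + 1}: expected {len(ind)} characters")
        calls[i] = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
    sites = pd.DataFrame(
        {
            "chromosome": snp["chromosome"],
            "bp": snp["bp"],
            "cM": snp["morgans"] * 100.0,
            "ref": snp["ref"],
            "alt": snp["alt"],
        }
    )
    if freqs is not None:
        sites["freq"] = np.asarray(freqs, dtype=float)
    else:
        with np.errstate(invalid="ignore"):
            obs = np.ma.masked_equal(calls, MISSING)
            # alt frequency from mean ref-allele count
            f = 1.0 - obs.mean(axis=1).filled(1.0) / 2.0
        sites["freq"] = np.clip(f, 1e-3, 1.0 - 1e-3)
    return GenotypeMatrix(sites, list(ind["individual"]), calls, ploidy_mode)
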