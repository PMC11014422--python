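"""Plain-text interchange formats.

SNP matrices use a one-line-header TSV dialect::

    #population=X Ne=20 L=10 generation=19
    0	1	0	...

followed by Ne rows of L tab-separated 0/1 values (1-based loci, left to
right).  Parameter sidecars and run configs are YAML.  A minimal haploid
VCF export (one sample per carrier, single-allele GT) is provided for
interoperability with standard variant tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from divsel.simulator import DrawnParams, FixedParams
from divsel.sumstats import SummaryVector

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_params_yaml",
    "read_params_yaml",
    "load_config",
    "write_vcf",
    "sumstats_frame",
    "write_sumstats_tsv",
    "read_sumstats_tsv",
]


def write_matrix_tsv(
    path: str | Path, matrix: np.ndarray, population: str, generation: int
) -> None:
    """Write one population matrix in the header-TSV dialect."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    Ne, L = matrix.shape
    with open(path, "w") as fh:
        fh.write(f"#population={population} Ne={Ne} L={L} generation={generation}\n")
        for row in matrix:
            fh.write("\t".join(map(str, row)) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a population matrix; returns (matrix, header metadata)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing #-header line")
        meta: dict[str, Any] = {}
        for item in header[1:].split():
            key, _, value = item.partition("=")
            meta[key] = int(value) if value.lstrip("-").isdigit() else value
        matrix = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
    if matrix.shape != (meta["Ne"], meta["L"]):
        raise ValueError(
            f"{path}: matrix shape {matrix.shape} does not match header "
            f"({meta['Ne']}, {meta['L']})"
        )
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError(f"{path}: matrix entries must be 0/1")
    return matrix, meta


def write_params_yaml(
    path: str | Path, drawn: DrawnParams, fixed: FixedParams | None = None
) -> None:
    """Write the drawn (and optionally fixed) parameters as YAML."""
    doc: dict[str, Any] = {
        "drawn": {
            "sel_loci": list(drawn.sel_loci),
            "sel_coeffs": [float(s) for s in drawn.sel_coeffs],
            "sel_alleles": list(drawn.sel_alleles),
            "m": float(drawn.m),
            "sex": int(drawn.sex),
        }
    }
    if fixed is not None:
        doc["fixed"] = {
            "r": fixed.r,
            "t_star": fixed.t_star,
            "n_cycles": fixed.n_cycles,
            "Ne": fixed.Ne,
            "L": fixed.L,
            "snp_spacing": fixed.snp_spacing,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_params_yaml(
    path: str | Path,
) -> tuple[DrawnParams, FixedParams | None]:
    doc = yaml.safe_load(Path(path).read_text())
    d = doc["drawn"]
    drawn = DrawnParams(
        sel_loci=tuple(d["sel_loci"]),
        sel_coeffs=tuple(d["sel_coeffs"]),
        sel_alleles=tuple(d.get("sel_alleles", ())),
        m=d["m"],
        sex=d["sex"],
    )
    fixed = None
    if "fixed" in doc:
        fixed = FixedParams(**doc["fixed"])
    return drawn, fixed


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a run configuration.

    Required keys mirror the fixed parameters (``r``, ``t_star``,
    ``n_cycles``, ``Ne``, ``L``, ``snp_spacing``); optional keys are
    ``seed`` and a ``prior`` block (``s_bound``, ``candidate_loci``,
    ``m_set``, ``sex_set``).  Returns ``{"fixed": FixedParams, ...}`` with
    the remaining keys passed through.
    """
    doc = yaml.safe_load(Path(path).read_text())
    fixed = FixedParams(
        r=float(doc["r"]),
        t_star=int(doc["t_star"]),
        n_cycles=int(doc["n_cycles"]),
        Ne=int(doc["Ne"]),
        L=int(doc["L"]),
        snp_spacing=int(doc["snp_spacing"]),
    )
    out: dict[str, Any] = {"fixed": fixed}
    for key in ("seed", "prior"):
        if key in doc:
            out[key] = doc[key]
    return out


def write_vcf(
    path: str | Path,
    matrix: np.ndarray,
    fixed: FixedParams,
    sample_prefix: str = "carrier",
) -> None:
    """Export one population as a haploid VCF (single-allele GT calls).

    CHROM is fixed to ``sim1`` and POS is ``locus_index * snp_spacing``
    (1-based loci).  REF/ALT are placeholder bases A/T standing for the
    0/1 alleles.
    """
    matrix = np.asarray(matrix, dtype=np.uint8)
    Ne, L = matrix.shape
    samples = [f"{sample_prefix}{i}" for i in range(Ne)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=sim1,length={fixed.genome_length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for locus in range(1, L + 1):
            pos = locus * fixed.snp_spacing
            gts = "\t".join(str(int(g)) for g in matrix[:, locus - 1])
            fh.write(f"sim1\t{pos}\tsnp{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def sumstats_frame(sv: SummaryVector) -> pd.DataFrame:
    """Long-format frame with columns locus, stat_name, value."""
    rows = []
    for name in sv.stat_names:
        vec = sv.get(name)
        for locus, value in enumerate(vec, start=1):
            rows.append(dict(locus=locus, stat_name=name, value=float(value)))
    return pd.DataFrame(rows)


def write_sumstats_tsv(path: str | Path, sv: SummaryVector) -> None:
    sumstats_frame(sv).to_csv(path, sep="\t", index=False)


def read_sumstats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
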