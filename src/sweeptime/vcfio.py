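"""VCF and manifest serialization for simulated sweep samples.

Genotypes are written as unphased diploid VCF v4.2 records ("0/1" separator),
one sample column per sampled individual, with synthetic REF/ALT alleles
(the simulator is allele-label-free).  The recorded fixation time, sweep age
and all simulation parameters travel in ``##sweeptime_*`` header lines so a
VCF is self-describing.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import SweepResult

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}

MANIFEST_COLUMNS = [
    "sim_id", "scenario", "NA", "s", "h", "mu", "R", "ta", "r", "K",
    "L", "n", "tf", "attempts", "status",
]


def _int_positions(positions: np.ndarray, L: int) -> np.ndarray:
    """Map continuous coordinates to unique, strictly increasing 1-based
    integer positions."""
    pos = np.floor(positions).astype(np.int64) + 1
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def write_vcf(result: SweepResult, path: str) -> None:
    """Write a completed SweepResult as an uncompressed VCF v4.2 file."""
    if result.status != "complete":
        raise ValueError("cannot write an abandoned simulation to VCF")
    params = result.params
    n, S = result.dosages.shape
    pos = _int_positions(result.positions, params.L)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sweeptime",
        f"##sweeptime_tf={result.tf}",
        f"##sweeptime_ta={result.ta}",
        f"##sweeptime_attempts={result.attempts}",
    ]
    for key, val in params.as_dict().items():
        lines.append(f"##sweeptime_param_{key}={val}")
    lines.append(f"##contig=<ID=1,length={max(params.L, int(pos[-1]) if S else params.L)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = "\t".join(f"i{j}" for j in range(n))
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}")
    dos = result.dosages
    for j in range(S):
        gts = "\t".join(_GT[int(d)] for d in dos[:, j])
        lines.append(f"1\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read an unphased VCF back into (dosages, positions, metadata).

    Uses cyvcf2 when available, falling back to a plain-text parse (the
    files this package writes are simple biallelic GT-only records).
    Metadata holds any ``##sweeptime_*`` header entries.
    """
    meta = {}
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("##"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        if line.startswith("##sweeptime_"):
            key, _, val = line[2:].strip().partition("=")
            meta[key.replace("sweeptime_", "")] = val
    try:
        from cyvcf2 import VCF

        positions, rows = [], []
        vcf = VCF(path, gts012=True)
        for variant in vcf:
            positions.append(variant.POS)
            rows.append(variant.gt_types.copy())
        vcf.close()
        if rows:
            dosages = np.vstack(rows).T.astype(np.uint8)
            positions = np.asarray(positions, dtype=float)
        else:
            dosages = np.zeros((0, 0), dtype=np.uint8)
            positions = np.zeros(0)
    except ImportError:  # pragma: no cover - cyvcf2 is a declared dependency
        positions, rows = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                positions.append(float(fields[1]))
                rows.append(
                    [sum(int(x) for x in gt.replace("|", "/").split("/"))
                     for gt in fields[9:]]
                )
        dosages = (
            np.asarray(rows, dtype=np.uint8).T
            if rows else np.zeros((0, 0), dtype=np.uint8)
        )
        positions = np.asarray(positions, dtype=float)
    return dosages, positions, meta


def manifest_row(sim_id: str, result: SweepResult) -> dict:
    p = result.params
    return {
        "sim_id": sim_id, "scenario": p.scenario, "NA": p.NA, "s": p.s,
        "h": p.h, "mu": p.mu, "R": p.R, "ta": result.ta, "r": p.r, "K": p.K,
        "L": p.L, "n": p.n,
        "tf": result.tf if result.tf is not None else np.nan,
        "attempts": result.attempts, "status": result.status,
    }


def build_manifest(results: Iterable[tuple[str, SweepResult]]) -> pd.DataFrame:
    return pd.DataFrame(
        [manifest_row(sid, res) for sid, res in results], columns=MANIFEST_COLUMNS
    )


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
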