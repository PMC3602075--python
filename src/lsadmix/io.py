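"""Genotype file readers and ADMIXTURE-style .P/.Q writers.

Two plain-text genotype dialects are supported:

* ``matrix`` — whitespace-delimited integers, by default one locus per
  row and one individual per column;
* ``z012`` — the ``vcftools --012`` layout: one individual per row, the
  first column an individual index, ``-1`` marking missing genotypes.
  Transposed to loci-by-individuals on load.

Missing genotypes either raise (default) or are mean-imputed per locus
(observed locus mean rounded to the nearest integer, halves up).

Fitted matrices are written in the de-facto ``.P`` / ``.Q`` convention:
``<prefix>.P`` has one locus per row and K frequency columns;
``<prefix>.Q`` has one individual per row and K proportion columns (the
in-memory K x N matrix is transposed on write).  Six fixed decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import validate_genotypes

__all__ = ["GenotypeFileSpec", "read_genotypes", "write_pq", "read_p_file", "read_q_file"]

FORMATS = ("matrix", "z012")
ORIENTATIONS = ("loci-by-individuals", "individuals-by-loci")
MISSING_POLICIES = ("error", "mean_impute")


@dataclass(frozen=True)
class GenotypeFileSpec:
    """Where and how to read a genotype matrix."""

    path: str | Path
    format: str = "matrix"
    orientation: str = "loci-by-individuals"
    missing_policy: str = "error"

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(
                f"missing_policy must be one of {MISSING_POLICIES}, got {self.missing_policy!r}"
            )


def _parse_int_table(path: Path) -> np.ndarray:
    rows: list[list[int]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for colno, tok in enumerate(tokens, start=1):
                try:
                    row.append(int(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer token {tok!r} at line {lineno}, column {colno}"
                    ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} ({len(row)} fields, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty genotype file")
    return np.array(rows, dtype=np.int64)


def _impute_missing(G: np.ndarray, policy: str, path: Path) -> np.ndarray:
    """Resolve -1 entries in a loci-by-individuals table."""
    missing = G == -1
    if not missing.any():
        return G
    if policy == "error":
        l, i = np.argwhere(missing)[0]
        raise ValueError(
            f"{path}: missing genotype (-1) at locus {l + 1}, individual {i + 1} "
            "(missing_policy='error'; use 'mean_impute' to fill)"
        )
    G = G.astype(np.float64)
    G[missing] = np.nan
    means = np.nanmean(G, axis=1)
    if np.isnan(means).any():
        l = int(np.flatnonzero(np.isnan(means))[0])
        raise ValueError(f"{path}: locus {l + 1} has no observed genotypes to impute from")
    fill = np.floor(means + 0.5)  # nearest integer, halves up
    G[missing] = np.broadcast_to(fill[:, None], G.shape)[missing]
    return G.astype(np.int64)


def read_genotypes(spec: GenotypeFileSpec | str | Path) -> np.ndarray:
    """Read a genotype file into an M x N loci-by-individuals matrix."""
    if not isinstance(spec, GenotypeFileSpec):
        spec = GenotypeFileSpec(path=spec)
    path = Path(spec.path)
    table = _parse_int_table(path)

    if spec.format == "z012":
        table = table[:, 1:]  # drop the individual-index column
        if table.shape[1] == 0:
            raise ValueError(f"{path}: z012 file has no genotype columns")
        table = table.T  # individuals-by-loci on disk
    elif spec.orientation == "individuals-by-loci":
        table = table.T

    bad = (table < -1) | (table > 2)
    if bad.any():
        l, i = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: genotype {table[l, i]} outside {{-1, 0, 1, 2}} at "
            f"locus {l + 1}, individual {i + 1}"
        )
    table = _impute_missing(table, spec.missing_policy, path)
    return validate_genotypes(table)


def write_pq(prefix: str | Path, P: np.ndarray, Q: np.ndarray) -> tuple[Path, Path]:
    """Write ``<prefix>.P`` and ``<prefix>.Q`` (individuals as rows)."""
    prefix = Path(prefix)
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    p_path = prefix.with_name(prefix.name + ".P")
    q_path = prefix.with_name(prefix.name + ".Q")
    np.savetxt(p_path, P, fmt="%.6f", delimiter=" ")
    np.savetxt(q_path, Q.T, fmt="%.6f", delimiter=" ")
    return p_path, q_path


def read_p_file(path: str | Path) -> np.ndarray:
    """Read an M x K ``.P`` frequency file."""
    return np.loadtxt(path, dtype=np.float64, ndmin=2)


def read_q_file(path: str | Path) -> np.ndarray:
    """Read a ``.Q`` file (individuals as rows) into a K x N matrix."""
    return np.loadtxt(path, dtype=np.float64, ndmin=2).T
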