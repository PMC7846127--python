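"""Readers and writers: plink BED/BIM/FAM, TSV matrices, labels and weights.

Genotypes are exchanged either as plink 1.9 binary triples (SNP-major BED
with its BIM/FAM sidecars; dosages count occurrences of the BIM allele-1)
or as plain TSV with a header row of individual IDs and one row per locus.
Missing genotypes (plink code 0b01) are surfaced as -1; estimators reject
them, so callers either drop incomplete loci at read time
(``drop_missing_loci=True``) or handle missingness upstream.

Relatedness matrices are TSV with an ID header and a leading metadata
comment line recording the form (``# form=coancestry``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model_core import RelatednessMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_bed",
    "write_bed",
    "read_labels",
    "read_weights",
    "read_matrix",
    "write_matrix",
]

logger = logging.getLogger("structkin")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # plink 1.9, SNP-major
#: 2-bit plink code -> dosage of allele 1 (-1 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 3, 1: 2, 2: 0, -1: 1}


def write_bed(prefix: str | Path, X: NDArray, ids: list[str] | None = None,
              variant_ids: list[str] | None = None) -> None:
    """Write dosages (n individuals x m loci) as plink BED/BIM/FAM.

    Synthetic variant records are emitted: chromosome 1, positions 1..m,
    alleles A (allele 1, the counted one) and B.
    """
    prefix = Path(prefix)
    X = np.asarray(X)
    n, m = X.shape
    if ids is None:
        ids = [f"ind{j}" for j in range(n)]
    if variant_ids is None:
        variant_ids = [f"snp{i}" for i in range(m)]

    lut = np.zeros(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[np.int8(dos).view(np.uint8)] = code  # -1 lands at byte 255
    codes = lut[X.T.astype(np.int8).view(np.uint8)]

    n_pad = (-n) % 4
    if n_pad:
        codes = np.concatenate([codes, np.zeros((m, n_pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | codes[:, :, 1] << 2 | codes[:, :, 2] << 4
              | codes[:, :, 3] << 6).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for i, vid in enumerate(variant_ids):
            fh.write(f"1\t{vid}\t0\t{i + 1}\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_bed(prefix: str | Path) -> tuple[NDArray[np.int8], list[str], list[str]]:
    """Read a plink BED/BIM/FAM triple; returns (X, individual_ids, variant_ids).

    Dosages count the BIM allele-1; missing entries are -1.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major plink 1.9)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * bytes_per_snp:
        raise ValueError(f"{prefix}.bed: size inconsistent with BIM/FAM dimensions")
    body = body.reshape(m, bytes_per_snp)
    X = np.empty((n, m), dtype=np.int8)
    for shift in range(4):
        take = (body >> (2 * shift)) & 0b11
        cols = np.arange(shift, n, 4)
        X[cols, :] = _CODE_TO_DOSAGE[take[:, : len(cols)]].T
    return X, list(fam[1].astype(str)), list(bim[1].astype(str))


def write_genotypes(path: str | Path, X: NDArray, ids: list[str] | None = None,
                    fmt: str | None = None) -> None:
    """Write genotypes as TSV (header of individual IDs, one row per locus)
    or as a BED prefix (``fmt='bed'``)."""
    if fmt == "bed" or (fmt is None and not str(path).endswith(".tsv")):
        write_bed(path, X, ids)
        return
    X = np.asarray(X)
    if ids is None:
        ids = [f"ind{j}" for j in range(X.shape[0])]
    pd.DataFrame(X.T, columns=ids).to_csv(path, sep="\t", index=False)


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    *,
    drop_missing_loci: bool = False,
) -> tuple[NDArray[np.int8], list[str]]:
    """Read genotypes from a BED prefix or TSV; returns (X, individual_ids).

    With ``drop_missing_loci`` any locus containing a missing call is
    removed (logged); otherwise missing entries stay as -1 and downstream
    estimators will refuse the matrix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix == ".tsv" else "bed"
    if fmt == "bed":
        X, ids, _ = read_bed(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        ids = list(df.columns.astype(str))
        X = df.to_numpy(dtype=np.int8).T
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if drop_missing_loci:
        keep = ~(X < 0).any(axis=0)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropped %d loci with missing genotypes", dropped)
            X = X[:, keep]
    return X, ids


def read_labels(path: str | Path, ids: list[str] | None = None) -> NDArray:
    """Subpopulation labels from a two-column TSV (id, label).

    If ``ids`` is given, rows are mapped onto that order; unknown or
    duplicate IDs are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    if df["id"].duplicated().any():
        raise ValueError("duplicate IDs in label file")
    if ids is None:
        return df["label"].to_numpy()
    lookup = dict(zip(df["id"], df["label"]))
    missing = [i for i in ids if i not in lookup]
    if missing:
        raise ValueError(f"label file missing IDs: {missing[:5]}")
    return np.array([lookup[i] for i in ids])


def read_weights(path: str | Path | None, ids: list[str]) -> NDArray[np.float64]:
    """Weight vector from a two-column TSV (id, weight); uniform if absent.

    Negative weights are errors; weights off from sum 1 by more than 1e-6
    are renormalized with a logged warning.
    """
    n = len(ids)
    if path is None:
        return np.full(n, 1.0 / n)
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "w"],
                     dtype={"id": str, "w": float})
    if df["id"].duplicated().any():
        raise ValueError("duplicate IDs in weight file")
    lookup = dict(zip(df["id"], df["w"]))
    missing = [i for i in ids if i not in lookup]
    if missing:
        raise ValueError(f"weight file missing IDs: {missing[:5]}")
    w = np.array([lookup[i] for i in ids], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if abs(s - 1.0) > 1e-6:
        logger.warning("weights sum to %.8f; renormalizing to 1", s)
    return w / s


def write_matrix(path: str | Path, M: RelatednessMatrix) -> None:
    """Relatedness matrix as TSV with ID header and a form metadata line."""
    ids = M.ids or [f"ind{j}" for j in range(M.n)]
    with open(path, "w") as fh:
        fh.write(f"# form={M.form}\n")
        fh.write("\t".join(ids) + "\n")
        for row in M.values:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> RelatednessMatrix:
    """Read a relatedness matrix written by :func:`write_matrix`."""
    with open(path) as fh:
        first = fh.readline().strip()
        form = "coancestry"
        if first.startswith("#"):
            meta = dict(kv.split("=", 1) for kv in first[1:].split() if "=" in kv)
            form = meta.get("form", form)
            header = fh.readline()
        else:
            header = first
        ids = header.strip().split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return RelatednessMatrix(values=values, form=form, ids=ids)  # type: ignore[arg-type]
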