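"""Genotype matrix I/O: delimited text tables and VCF.

Genotypes at a biallelic SNP are coded by alternate-allele count:
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate.
Missing observations use the out-of-band sentinel :data:`MISSING`.
"""

from __future__ import annotations

import csv
import io
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

#: Out-of-band integer code for a missing genotype.
MISSING: int = -1

#: Text tokens recognised as missing when reading tables.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"NA", "N", "?", "-1", "."})

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeFormatError(ValueError):
    """Structural problem in an input file (ragged row, missing GT field...)."""


class GenotypeValueError(ValueError):
    """A cell holds something other than 0/1/2 or a missing token."""


@dataclass
class GenotypeMatrix:
    """Samples x loci integer genotype matrix, the universal container.

    Parameters
    ----------
    sample_ids, locus_ids
        Opaque identifiers; lengths must match the matrix shape.
    genotypes
        Integer array of shape ``(n_samples, n_loci)`` with entries in
        {0, 1, 2, MISSING}.
    positions
        Optional per-locus base-pair coordinates, strictly increasing.
    meta
        Free-form provenance (e.g. the VCF reader's skip counter).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x loci array")
        ns, nl = self.genotypes.shape
        if ns != len(self.sample_ids) or nl != len(self.locus_ids):
            raise ValueError(
                f"shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.genotypes, list(_VALID_CODES))
        if bad.any():
            s, l = np.argwhere(bad)[0]
            raise GenotypeValueError(
                f"invalid genotype code {self.genotypes[s, l]} at "
                f"sample {self.sample_ids[s]!r}, locus {self.locus_ids[l]!r}"
            )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.positions) != nl:
                raise ValueError("positions length does not match locus count")
            if nl > 1 and not np.all(np.diff(self.positions) > 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the genotype is missing."""
        return self.genotypes == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=list(self.locus_ids),
            genotypes=self.genotypes.copy(),
            positions=None if self.positions is None else self.positions.copy(),
            meta=dict(self.meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Value equality on identifiers, genotypes and positions."""
        if self.sample_ids != other.sample_ids or self.locus_ids != other.locus_ids:
            return False
        if not np.array_equal(self.genotypes, other.genotypes):
            return False
        if (self.positions is None) != (other.positions is None):
            return False
        if self.positions is not None and not np.array_equal(
            self.positions, other.positions
        ):
            return False
        return True

    __eq__ = equals  # type: ignore[assignment]
    __hash__ = None  # type: ignore[assignment]


def _as_text_stream(source) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _detect_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise GenotypeFormatError("could not detect delimiter (expected tab or comma)")


def _parse_cell(token: str, missing_tokens: frozenset[str], where: str) -> int:
    token = token.strip()
    if token in missing_tokens:
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise GenotypeValueError(f"invalid genotype value {token!r} at {where}")


def read_genotype_table(
    source,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    orientation: str = "loci_as_rows",
) -> GenotypeMatrix:
    """Read a delimited genotype table.

    Default layout (``loci_as_rows``): header row of sample IDs, first
    column locus IDs, optional second column named ``pos``/``position``
    holding integer base-pair coordinates. ``samples_as_rows`` transposes
    the roles (header = locus IDs, first column = sample IDs, no
    positions column). Delimiter is auto-detected among tab and comma.
    """
    if orientation not in ("loci_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    missing_tokens = frozenset(missing_tokens)
    stream, owned = _as_text_stream(source)
    try:
        text = stream.read()
    finally:
        if owned:
            stream.close()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise GenotypeFormatError("empty input")
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header = [c.strip() for c in rows[0]]

    has_pos = (
        orientation == "loci_as_rows"
        and len(header) >= 2
        and header[1].lower() in ("pos", "position")
    )
    id_cols = 2 if has_pos else 1
    col_ids = header[id_cols:]
    width = len(header)

    row_ids: list[str] = []
    positions: list[int] = []
    cells: list[list[int]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise GenotypeFormatError(
                f"row {i} has {len(row)} fields, expected {width}"
            )
        row_ids.append(row[0].strip())
        if has_pos:
            try:
                positions.append(int(row[1]))
            except ValueError:
                raise GenotypeFormatError(
                    f"row {i}: position {row[1]!r} is not an integer"
                ) from None
        cells.append(
            [
                _parse_cell(tok, missing_tokens, f"row {i}, column {j + 1}")
                for j, tok in enumerate(row[id_cols:], start=id_cols)
            ]
        )

    data = np.array(cells, dtype=np.int16).reshape(len(row_ids), len(col_ids))
    if orientation == "loci_as_rows":
        return GenotypeMatrix(
            sample_ids=col_ids,
            locus_ids=row_ids,
            genotypes=data.T,
            positions=np.array(positions, dtype=np.int64) if has_pos else None,
        )
    return GenotypeMatrix(sample_ids=row_ids, locus_ids=col_ids, genotypes=data)


def write_genotype_table(
    matrix: GenotypeMatrix,
    dest,
    missing_token: str = "NA",
    delimiter: str = "\t",
) -> None:
    """Write ``matrix`` in the loci-as-rows layout read back by
    :func:`read_genotype_table` (round-trip identity)."""
    stream, owned = (
        (dest, False) if hasattr(dest, "write") else (open(dest, "w", encoding="utf-8"), True)
    )
    try:
        header = ["locus"]
        if matrix.positions is not None:
            header.append("pos")
        header.extend(matrix.sample_ids)
        stream.write(delimiter.join(header) + "\n")
        for j, locus in enumerate(matrix.locus_ids):
            row = [locus]
            if matrix.positions is not None:
                row.append(str(int(matrix.positions[j])))
            for g in matrix.genotypes[:, j]:
                row.append(missing_token if g == MISSING else str(int(g)))
            stream.write(delimiter.join(row) + "\n")
    finally:
        if owned:
            stream.close()


def read_vcf(source) -> GenotypeMatrix:
    """Read diploid GT fields from a VCF into a genotype matrix.

    Only biallelic records are retained; records with more than one ALT
    allele are skipped and counted in ``meta["skipped_non_biallelic"]``.
    GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any GT containing ``.`` maps
    to MISSING; phase separators ``|`` and ``/`` are equivalent. FILTER
    is ignored. Haploid GT entries are rejected (the method is defined
    on diploid genotypes).
    """
    from cyvcf2 import VCF

    tmp_path = None
    if hasattr(source, "read"):
        text = source.read()
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        path = tmp_path
    else:
        path = str(source)

    try:
        vcf = VCF(path)
        sample_ids = list(vcf.samples)
        if not sample_ids:
            raise GenotypeFormatError("VCF has no sample columns")
        locus_ids: list[str] = []
        positions: list[int] = []
        chroms: set[str] = set()
        columns: list[np.ndarray] = []
        skipped = 0
        for v in vcf:
            if len(v.ALT) != 1:
                skipped += 1
                continue
            if "GT" not in (v.FORMAT or []):
                raise GenotypeFormatError(
                    f"record {v.CHROM}:{v.POS} has no GT format field"
                )
            col = np.empty(len(sample_ids), dtype=np.int16)
            for s, gt in enumerate(v.genotypes):
                alleles = gt[:-1]  # last element is the phased flag
                if len(alleles) != 2:
                    raise GenotypeFormatError(
                        f"non-diploid GT for sample {sample_ids[s]} at "
                        f"{v.CHROM}:{v.POS}"
                    )
                a, b = alleles
                if a < 0 or b < 0:
                    col[s] = MISSING
                else:
                    if a > 1 or b > 1:
                        raise GenotypeFormatError(
                            f"allele index >1 in biallelic record at {v.CHROM}:{v.POS}"
                        )
                    col[s] = a + b
            columns.append(col)
            locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
            positions.append(v.POS)
            chroms.add(v.CHROM)
        vcf.close()
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)

    geno = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int16)
    )
    pos_arr: np.ndarray | None = None
    if len(chroms) == 1 and len(positions) > 0:
        diffs = np.diff(positions)
        if len(diffs) == 0 or np.all(diffs > 0):
            pos_arr = np.asarray(positions, dtype=np.int64)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        genotypes=geno,
        positions=pos_arr,
        meta={"skipped_non_biallelic": skipped},
    )
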