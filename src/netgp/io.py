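"""Delimited file formats.

Native genotype format (``tsv_counts``): a TSV whose header row is
``sample_id`` followed by marker ids; each subsequent row is a sample id and
its allele counts, one of ``0``, ``1``, ``2`` or ``NA`` for a missing call.

PLINK-.raw-style dialect (``plink_raw``): whitespace-delimited with the six
leading columns FID IID PAT MAT SEX PHENOTYPE, then one column per marker
(ids may carry a trailing ``_<allele>`` suffix, which is stripped); counts
are again 0/1/2/NA and the IID column provides the sample id.

Phenotypes: two columns (sample id, value), tab- or whitespace-delimited,
with an optional ``sample_id`` header line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ParseError, ValidationError
from .genotypes import RawGenotypeTable
from .phenotypes import PhenotypeRecord

__all__ = [
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "GENOTYPE_DIALECTS",
]

GENOTYPE_DIALECTS = ("tsv_counts", "plink_raw")
_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def _parse_count(token: str, path: Path, lineno: int) -> float:
    try:
        return _TOKENS[token]
    except KeyError:
        raise ParseError(
            f"{path}:{lineno}: genotype token must be 0/1/2/NA, found {token!r}"
        ) from None


def load_genotypes(path: str | Path, dialect: str = "tsv_counts") -> RawGenotypeTable:
    """Parse a genotype file; malformed rows raise ParseError with the line number."""
    path = Path(path)
    if dialect not in GENOTYPE_DIALECTS:
        raise ValidationError(f"dialect must be one of {GENOTYPE_DIALECTS}, got {dialect!r}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty genotype file")
    if dialect == "tsv_counts":
        header = lines[0].split("\t")
        if header[:1] != ["sample_id"]:
            raise ParseError(f"{path}:1: header must start with 'sample_id'")
        marker_ids = header[1:]
        id_col, skip = 0, 1
        splitter = lambda s: s.split("\t")  # noqa: E731
    else:
        header = lines[0].split()
        if header[:2] != ["FID", "IID"]:
            raise ParseError(f"{path}:1: PLINK .raw header must start with 'FID IID'")
        marker_ids = [h.rsplit("_", 1)[0] if "_" in h else h for h in header[6:]]
        id_col, skip = 1, 6
        splitter = str.split
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = splitter(line)
        if len(fields) != skip + len(marker_ids):
            raise ParseError(
                f"{path}:{lineno}: expected {skip + len(marker_ids)} fields, found {len(fields)}"
            )
        sid = fields[id_col]
        if sid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        seen.add(sid)
        sample_ids.append(sid)
        rows.append([_parse_count(tok, path, lineno) for tok in fields[skip:]])
    if not rows:
        raise ParseError(f"{path}:2: genotype file has no sample rows")
    return RawGenotypeTable(
        sample_ids=sample_ids, marker_ids=marker_ids, counts=np.array(rows, dtype=float)
    )


def write_genotypes(table: RawGenotypeTable, path: str | Path) -> None:
    """Write the native tsv_counts format; the exact inverse of load_genotypes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(table.marker_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            tokens = ["NA" if np.isnan(c) else str(int(c)) for c in row]
            fh.write(sid + "\t" + "\t".join(tokens) + "\n")


def load_phenotypes(
    path: str | Path, genotype_sample_ids: list[str] | None = None
) -> tuple[PhenotypeRecord, list[str]]:
    """Read (sample id, value) pairs; align to the genotype sample order.

    Returns the record and the list of ids dropped by the inner join (either
    side). Without ``genotype_sample_ids`` the file order is kept and the
    dropped list is empty.
    """
    path = Path(path)
    pairs: dict[str, float] = {}
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, found {len(fields)}")
        sid, value = fields
        if lineno == 1 and sid.lower() in ("sample_id", "id", "iid"):
            continue
        try:
            y = float(value)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric phenotype {value!r}") from None
        if sid in pairs:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        pairs[sid] = y
    if not pairs:
        raise ParseError(f"{path}:1: phenotype file has no records")
    if genotype_sample_ids is None:
        ids = list(pairs)
        return PhenotypeRecord(sample_ids=ids, y=np.array([pairs[s] for s in ids])), []
    kept = [s for s in genotype_sample_ids if s in pairs]
    if not kept:
        raise ValidationError("no overlapping sample ids between phenotypes and genotypes")
    dropped = sorted((set(pairs) | set(genotype_sample_ids)) - set(kept))
    return PhenotypeRecord(sample_ids=kept, y=np.array([pairs[s] for s in kept])), dropped


def write_phenotypes(rec: PhenotypeRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tvalue\n")
        for sid, y in zip(rec.sample_ids, rec.y):
            fh.write(f"{sid}\t{float(y)!r}\n")
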