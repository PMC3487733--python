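"""Reading and writing the pipeline's external representations.

Sequences arrive as FASTA (COI barcode region, IUPAC nucleotide codes),
specimen metadata as a delimited table, and hierarchical-clustering
dendrograms leave as Newick.  Parsing of FASTA itself is delegated to
Biopython; this module adds the domain typing, validation and normalization
(uppercasing, gap stripping, U→T) the downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")
SITE_TYPES = ("forested", "non-forested")

METADATA_COLUMNS = (
    "specimen_id",
    "order",
    "family",
    "genus",
    "site_id",
    "site_type",
    "substrate",
    "method",
    "year",
)


class FastaParseError(ValueError):
    """Malformed FASTA input (empty record, duplicate id, bad residue)."""


class MetadataSchemaError(ValueError):
    """Metadata table missing required columns."""


class MetadataValueError(ValueError):
    """Metadata row with a value outside its vocabulary."""


@dataclass(frozen=True)
class BarcodeSequence:
    """One specimen's COI barcode: id plus normalized IUPAC residues.

    ``n_ambiguous`` counts every residue outside {A,C,G,T}: 'N' and the
    partial ambiguity codes (R, Y, ...) alike, since the <1% quality bound
    on ambiguous sites does not distinguish between them.
    """

    specimen_id: str
    residues: str

    def __post_init__(self):
        if not self.specimen_id:
            raise FastaParseError("specimen id must be non-empty")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise FastaParseError(
                f"record {self.specimen_id!r}: non-IUPAC residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for r in self.residues if r not in UNAMBIGUOUS)

    @property
    def ambiguous_fraction(self) -> float:
        return self.n_ambiguous / self.length if self.length else 0.0


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata row linking a specimen to taxonomy, site and substrate."""

    specimen_id: str
    order: str
    family: str
    genus: str
    site_id: str
    site_type: str
    substrate: str
    method: str
    year: int
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise MetadataValueError(
                f"specimen {self.specimen_id!r}: site_type {self.site_type!r} "
                f"not in {SITE_TYPES}"
            )


def _normalize(raw: str) -> str:
    return raw.upper().replace("-", "").replace("U", "T")


def read_fasta(path) -> list[BarcodeSequence]:
    """Read barcode sequences from FASTA.

    The first whitespace-delimited token of each header is the specimen id.
    Residues are uppercased, gap characters stripped and 'U' mapped to 'T'
    so mixed-provenance inputs normalize to one alphabet.

    Raises
    ------
    FastaParseError
        On an empty-sequence record or a duplicate specimen id.
    """
    out: list[BarcodeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        residues = _normalize(str(rec.seq))
        if not residues:
            raise FastaParseError(f"record {sid!r} has an empty sequence")
        if sid in seen:
            raise FastaParseError(f"duplicate specimen id {sid!r}")
        seen.add(sid)
        out.append(BarcodeSequence(sid, residues))
    return out


def write_fasta(seqs: Iterable[BarcodeSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.specimen_id}\n{s.residues}\n")


def _detect_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_metadata(path) -> list[SpecimenRecord]:
    """Read the specimen metadata table (tab- or comma-delimited, sniffed).

    Required columns: specimen_id, order, family, genus, site_id, site_type,
    substrate, method, year.  Unknown extra columns are preserved verbatim in
    ``SpecimenRecord.extras``.
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataSchemaError(f"metadata missing required columns: {missing}")
    extra_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = dict(zip(df.columns, row))
        sid = d["specimen_id"]
        if sid in seen:
            raise MetadataValueError(f"line {i}: duplicate specimen_id {sid!r}")
        seen.add(sid)
        if d["site_type"] not in SITE_TYPES:
            raise MetadataValueError(
                f"line {i}: site_type {d['site_type']!r} not in {SITE_TYPES}"
            )
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                order=d["order"],
                family=d["family"],
                genus=d["genus"],
                site_id=d["site_id"],
                site_type=d["site_type"],
                substrate=d["substrate"],
                method=d["method"],
                year=int(d["year"]),
                extras={c: d[c] for c in extra_cols},
            )
        )
    return records


def metadata_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Tabular view of metadata records (extras re-expanded as columns)."""
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in METADATA_COLUMNS}
        d.update(r.extras)
        rows.append(d)
    return pd.DataFrame(rows)


def write_metadata(records: Sequence[SpecimenRecord], path, sep: str = "\t") -> None:
    metadata_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Newick serialization of ultrametric merge trees
# ---------------------------------------------------------------------------

_NEWICK_SPECIAL = set("(),:;'\" \t\n[]")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_SPECIAL:
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(dendrogram) -> str:
    """Serialize a merge tree (labels + SciPy-format linkage) to Newick.

    Merge heights are dissimilarities at which clusters join; the tree is
    rendered ultrametric by placing every internal node at half its merge
    height, so two leaves joined at height h each get a branch of h/2 and
    cophenetic distances are preserved.  A single leaf serializes as
    ``label:0.0;``.
    """
    labels = list(dendrogram.labels)
    if len(labels) != len(set(labels)):
        raise ValueError("dendrogram leaf labels must be unique")
    n = len(labels)
    if n == 0:
        raise ValueError("empty dendrogram")
    if n == 1:
        return f"{_quote(labels[0])}:0.0;"
    Z = dendrogram.linkage
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return _quote(labels[node])
        left, right, h, _ = Z[node - n]
        parts = []
        for child in (int(left), int(right)):
            bl = h / 2.0 - heights[child] / 2.0
            parts.append(f"{render(child)}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"

    for k, (_, _, h, _) in enumerate(Z):
        heights[n + k] = float(h)
    return render(n + len(Z) - 1) + ";"


def write_newick(dendrogram, path) -> None:
    Path(path).write_text(newick_string(dendrogram) + "\n")
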