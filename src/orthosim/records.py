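"""Sequence records, standard-format I/O, and pluggable acquisition backends.

A dataset is a FASTA file of CDS sequences (headers
``GENE|Species binomial|ACCESSION|ISOFORM``) plus a TSV manifest.  The
acquisition layer mirrors the gene -> RefSeq -> mRNA/CDS retrieval
workflow behind a small backend interface: the fixture backend serves a
local directory (the test substrate), while an optional live backend
queries NCBI E-utilities over the network and is never exercised in the
test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
FASTA_WRAP = 60
MANIFEST_COLUMNS = ["gene_symbol", "species", "accession", "isoform_label", "cds_length", "source"]


class FastaFormatError(ValueError):
    """Malformed FASTA input (duplicate header, empty body, bad characters)."""


class ManifestError(ValueError):
    """Malformed or inconsistent manifest TSV."""


class AcquisitionError(RuntimeError):
    """Backend failure while fetching records for a query."""


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase, map U->T, reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FastaFormatError(f"{context}: invalid characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One gene x species coding sequence with provenance."""

    gene_symbol: str
    species: str
    accession: str
    isoform_label: str = ""
    cds_seq: str = ""
    mrna_seq: str = ""  # stored for provenance; the analysis aligns CDSs

    def __post_init__(self) -> None:
        if not self.cds_seq:
            raise ValueError(f"{self.accession}: empty CDS")
        object.__setattr__(self, "cds_seq", normalize_sequence(self.cds_seq, self.accession))

    @property
    def header(self) -> str:
        return f"{self.gene_symbol}|{self.species}|{self.accession}|{self.isoform_label}"


@dataclass(frozen=True)
class GeneSpeciesQuery:
    gene_symbol: str
    species: str

    def __post_init__(self) -> None:
        if not self.gene_symbol or not self.species:
            raise ValueError("gene_symbol and species must be non-empty")


@dataclass
class Manifest:
    """Tabular index of a dataset: one row per stored sequence record."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        self.rows = self.rows[MANIFEST_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[SequenceRecord], source: str = "fixture") -> "Manifest":
        return cls(
            pd.DataFrame(
                [
                    {
                        "gene_symbol": r.gene_symbol,
                        "species": r.species,
                        "accession": r.accession,
                        "isoform_label": r.isoform_label,
                        "cds_length": len(r.cds_seq),
                        "source": source,
                    }
                    for r in records
                ],
                columns=MANIFEST_COLUMNS,
            )
        )

    def validate_against(self, records: list[SequenceRecord]) -> None:
        by_key = {(r.gene_symbol, r.species, r.accession): r for r in records}
        if len(by_key) != len(records):
            raise ManifestError("duplicate (gene, species, accession) among records")
        for row in self.rows.itertuples(index=False):
            rec = by_key.get((row.gene_symbol, row.species, row.accession))
            if rec is None:
                raise ManifestError(f"manifest row {row.accession} has no sequence record")
            if int(row.cds_length) != len(rec.cds_seq):
                raise ManifestError(
                    f"{row.accession}: manifest cds_length {row.cds_length} "
                    f"!= sequence length {len(rec.cds_seq)}"
                )


# ---------------------------------------------------------------------------
# FASTA I/O

def _parse_header(header: str) -> tuple[str, str, str, str]:
    parts = header.split("|")
    if len(parts) != 4:
        raise FastaFormatError(
            f"header {header!r}: expected 'GENE|Species|ACCESSION|ISOFORM'"
        )
    return parts[0], parts[1], parts[2], parts[3]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (header, normalized sequence) pairs.

    Rejects duplicate headers and empty sequence bodies, reporting the
    offending header's line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    seen: dict[str, int] = {}
    current: str | None = None
    body_len = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(">"):
            if current is not None and body_len == 0:
                raise FastaFormatError(
                    f"{path}:{seen[current]}: empty sequence for header {current!r}"
                )
            header = line[1:].strip()
            if header in seen:
                raise FastaFormatError(f"{path}:{lineno}: duplicate header {header!r}")
            seen[header] = lineno
            current = header
            body_len = 0
        elif line.strip():
            if current is None:
                raise FastaFormatError(f"{path}:{lineno}: sequence data before any header")
            body_len += len(line.strip())
    if current is not None and body_len == 0:
        raise FastaFormatError(f"{path}:{seen[current]}: empty sequence for header {current!r}")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, normalize_sequence(str(rec.seq), rec.description)))
    return out


def write_fasta(records: list[tuple[str, str]] | list[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA, sorted stably as given."""
    seq_records = []
    for item in records:
        if isinstance(item, SequenceRecord):
            header, seq = item.header, item.cds_seq
        else:
            header, seq = item
        seq_records.append(SeqRecord(Seq(seq), id=header.split()[0], description=""))
        seq_records[-1].description = ""
        seq_records[-1].id = header
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seq_records)


def records_from_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a dataset FASTA whose headers follow the pipe-delimited grammar."""
    out = []
    for header, seq in read_fasta(path):
        gene, species, accession, isoform = _parse_header(header)
        out.append(
            SequenceRecord(
                gene_symbol=gene,
                species=species,
                accession=accession,
                isoform_label=isoform,
                cds_seq=seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Manifest I/O

def save_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> Manifest:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cds_length": "int64"}, keep_default_na=False)
    except (ValueError, OSError) as exc:
        raise ManifestError(f"{path}: {exc}") from exc
    return Manifest(df)


# ---------------------------------------------------------------------------
# Acquisition backends

class AcquisitionBackend(Protocol):
    """Contract: return every stored mRNA/CDS product for a gene x species."""

    def fetch(self, query: GeneSpeciesQuery) -> list[SequenceRecord]: ...


class FixtureBackend:
    """Serve records from a dataset directory (``sequences.fasta`` + ``manifest.tsv``).

    A pure function of the directory contents: repeated fetches return
    byte-identical records.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        fasta = self.directory / "sequences.fasta"
        if not fasta.exists():
            raise AcquisitionError(f"fixture directory {self.directory} has no sequences.fasta")
        try:
            self._records = records_from_fasta(fasta)
        except FastaFormatError:
            raise
        except OSError as exc:
            raise AcquisitionError(f"cannot read fixture {fasta}: {exc}") from exc
        manifest_path = self.directory / "manifest.tsv"
        if manifest_path.exists():
            load_manifest(manifest_path).validate_against(self._records)

    def fetch(self, query: GeneSpeciesQuery) -> list[SequenceRecord]:
        return [
            r
            for r in self._records
            if r.gene_symbol == query.gene_symbol and r.species == query.species
        ]


class LiveNCBIBackend:
    """Optional E-utilities adapter: gene search -> gene ID -> RefSeq mRNAs -> CDS.

    Requires network access; experimental and deliberately untested.  The
    fixture backend implements the same contract offline.
    """

    EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(self, email: str = "", tool: str = "orthosim"):
        self.email = email
        self.tool = tool

    def _get(self, endpoint: str, params: dict) -> bytes:
        import urllib.parse
        import urllib.request

        params = {**params, "tool": self.tool, **({"email": self.email} if self.email else {})}
        url = f"{self.EUTILS}/{endpoint}?{urllib.parse.urlencode(params)}"
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                return resp.read()
        except OSError as exc:
            raise AcquisitionError(f"E-utilities request failed: {url}: {exc}") from exc

    def fetch(self, query: GeneSpeciesQuery) -> list[SequenceRecord]:
        import json

        term = f"{query.gene_symbol}[Gene Name] AND {query.species}[Organism]"
        search = json.loads(
            self._get("esearch.fcgi", {"db": "gene", "term": term, "retmode": "json"})
        )
        gene_ids = search.get("esearchresult", {}).get("idlist", [])
        records: list[SequenceRecord] = []
        for gid in gene_ids:
            link = json.loads(
                self._get(
                    "elink.fcgi",
                    {"dbfrom": "gene", "db": "nuccore", "id": gid,
                     "linkname": "gene_nuccore_refseqrna", "retmode": "json"},
                )
            )
            rna_ids: list[str] = []
            for ls in link.get("linksets", []):
                for db in ls.get("linksetdbs", []):
                    rna_ids.extend(db.get("links", []))
            for rid in rna_ids:
                gb = self._get(
                    "efetch.fcgi", {"db": "nuccore", "id": rid, "rettype": "gb", "retmode": "text"}
                )
                rec = SeqIO.read(io.StringIO(gb.decode()), "genbank")
                for feat in rec.features:
                    if feat.type != "CDS":
                        continue
                    cds = str(feat.extract(rec.seq))
                    isoform = ""
                    for name in feat.qualifiers.get("product", []):
                        if "isoform" in name:
                            isoform = name.rsplit(" ", 1)[-1]
                    records.append(
                        SequenceRecord(
                            gene_symbol=query.gene_symbol,
                            species=query.species,
                            accession=rec.id,
                            isoform_label=isoform,
                            cds_seq=cds,
                            mrna_seq=str(rec.seq),
                        )
                    )
        return records


def fetch_gene_records(
    query: GeneSpeciesQuery, backend: AcquisitionBackend
) -> list[SequenceRecord]:
    """Fetch every stored mRNA/CDS product for ``query`` (empty if absent)."""
    return backend.fetch(query)


def select_product(records: list[SequenceRecord]) -> SequenceRecord:
    """Pick the analysis product among a gene x species' isoforms.

    The "X1" predicted isoform is preferred when present; otherwise the
    longest CDS wins, ties broken by lexicographically smallest accession.
    Permutation-invariant over the input list.
    """
    if not records:
        raise ValueError("select_product requires at least one record")
    keys = {(r.gene_symbol, r.species) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple gene x species combinations: {sorted(keys)}")
    x1 = sorted((r for r in records if r.isoform_label == "X1"), key=lambda r: r.accession)
    if x1:
        return x1[0]
    return min(records, key=lambda r: (-len(r.cds_seq), r.accession))


__all__ = [
    "SequenceRecord", "GeneSpeciesQuery", "Manifest", "AcquisitionBackend",
    "FixtureBackend", "LiveNCBIBackend", "fetch_gene_records", "select_product",
    "read_fasta", "write_fasta", "records_from_fasta", "load_manifest",
    "save_manifest", "normalize_sequence", "FastaFormatError", "ManifestError",
    "AcquisitionError",
]
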