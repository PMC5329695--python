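"""Readers/writers for FASTA templates, taxonomy TSVs and primer tables.

FASTA handling goes through Biopython's SeqIO; taxonomy and primer
tables are plain TSVs read with pandas. The six published amplification
primers ship as a packaged default set (`load_packaged_primers`), and a
constructed E. coli-like 16S reference as `load_packaged_reference`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Primer, TemplateRecord, ValidationError
from . import iupac

__all__ = [
    "read_templates",
    "write_templates",
    "read_fasta",
    "write_fasta",
    "read_primers",
    "load_packaged_primers",
    "load_packaged_reference",
]

TAXONOMY_COLUMNS = ("id", "phylum", "class")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        try:
            seqs[rec.id] = iupac.normalize(str(rec.seq))
        except iupac.InvalidNucleotideError as e:
            raise ValidationError(f"record {rec.id!r}: {e}") from e
    return seqs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(tax.columns[:3]) != list(TAXONOMY_COLUMNS):
        raise ValidationError(
            f"taxonomy TSV must have header {TAXONOMY_COLUMNS}, "
            f"got {tuple(tax.columns)}"
        )
    if tax["id"].duplicated().any():
        dup = tax.loc[tax["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate id {dup!r} in taxonomy table")
    return tax.set_index("id")


def read_templates(fasta_path: str | Path,
                   taxonomy_path: str | Path | None = None,
                   strict: bool = True,
                   has_flanks: bool = False) -> list[TemplateRecord]:
    """Load template records from FASTA plus an optional taxonomy TSV.

    The taxonomy TSV has header ``id<TAB>phylum<TAB>class``. In strict
    mode every FASTA id must be present; otherwise missing ids are
    labelled "unclassified".
    """
    seqs = read_fasta(fasta_path)
    tax = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    records = []
    for name, seq in seqs.items():
        if tax is not None and name in tax.index:
            phylum, klass = tax.loc[name, "phylum"], tax.loc[name, "class"]
        elif tax is not None and strict:
            raise ValidationError(f"FASTA id {name!r} absent from taxonomy table")
        else:
            phylum, klass = "unclassified", ""
        records.append(TemplateRecord(id=name, sequence=seq,
                                      taxon_phylum=phylum, taxon_class=klass,
                                      has_flanks=has_flanks))
    return records


def write_templates(records: Iterable[TemplateRecord],
                    fasta_path: str | Path,
                    taxonomy_path: str | Path) -> None:
    records = list(records)
    write_fasta([(r.id, r.sequence) for r in records], fasta_path)
    pd.DataFrame(
        {"id": [r.id for r in records],
         "phylum": [r.taxon_phylum for r in records],
         "class": [r.taxon_class for r in records]}
    ).to_csv(taxonomy_path, sep="\t", index=False)


def _primer_from_row(name, seq, orientation, start, end) -> Primer:
    fp = None
    if start not in (None, "") and not pd.isna(start):
        fp = (int(start), int(end))
    return Primer(name=str(name), sequence=str(seq),
                  orientation=str(orientation), intended_footprint=fp)


def read_primers(path: str | Path) -> list[Primer]:
    """Load primers from a TSV (columns name, sequence, orientation and
    optional footprint_start/footprint_end) or a YAML list of mappings."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        return [
            _primer_from_row(e["name"], e["sequence"], e["orientation"],
                             e.get("footprint_start"), e.get("footprint_end"))
            for e in entries
        ]
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "sequence", "orientation"):
        if col not in df.columns:
            raise ValidationError(f"primer table missing column {col!r}")
    return [
        _primer_from_row(row["name"], row["sequence"], row["orientation"],
                         row.get("footprint_start"), row.get("footprint_end"))
        for _, row in df.iterrows()
    ]


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("primer16s") / "data" / name))


def load_packaged_primers() -> dict[str, Primer]:
    """The six published amplification primers, keyed by name."""
    return {p.name: p for p in read_primers(_data_path("primers.tsv"))}


def load_packaged_reference() -> str:
    """The packaged 1,542-nt constructed E. coli-like 16S reference."""
    seqs = read_fasta(_data_path("ecoli16s_synthetic.fasta"))
    return next(iter(seqs.values()))
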