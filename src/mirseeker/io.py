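"""File formats: FASTA/FASTQ input, collapsed-read TSV/FASTA, labelled
reference collections and the bundled candidate-table fixture."""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .annotation_filters import ReferenceCollection, ReferenceRecord
from .preprocess import CollapsedRead, RawRead
from .seq import canonical

_COUNT_HEADER = re.compile(r"_x(\d+)$")


def read_sequences(path: str | Path, library: str | None = None) -> Iterator[RawRead]:
    """Stream reads from FASTA or FASTQ (qualities ignored by design).

    A ``_xCOUNT`` suffix on a FASTA id marks a pre-collapsed sequence and is
    honoured by :func:`read_collapsed_fasta`; here each record is one read.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    lib = library or path.stem
    for rec in SeqIO.parse(str(path), fmt):
        yield RawRead(rec.id, str(rec.seq), lib)


def read_collapsed_fasta(path: str | Path, library: str | None = None) -> list[CollapsedRead]:
    """Load a collapsed set from FASTA with ``>id_xCOUNT`` headers."""
    lib = library or Path(path).stem
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_HEADER.search(rec.id)
        count = int(m.group(1)) if m else 1
        out.append(CollapsedRead(str(rec.seq), count, {lib: count}))
    return out


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f">s{i}_x{read.abundance_total}\n{read.sequence}\n")


def write_collapsed_tsv(reads: list[CollapsedRead], path: str | Path) -> None:
    libs = sorted({lib for r in reads for lib in r.abundance_by_library})
    rows = [
        {
            "sequence": r.sequence,
            "length": r.length,
            "total": r.abundance_total,
            **{lib: r.abundance_by_library.get(lib, 0) for lib in libs},
        }
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_collapsed_tsv(path: str | Path) -> list[CollapsedRead]:
    df = pd.read_csv(path, sep="\t")
    libs = [c for c in df.columns if c not in ("sequence", "length", "total")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        by_lib = {lib: int(d[lib]) for lib in libs if int(d[lib]) > 0}
        out.append(CollapsedRead(d["sequence"], int(d["total"]), by_lib))
    return out


_KV_TOKEN = re.compile(r"(\w+)=([^;\s]+)")


def read_reference_collection(
    path: str | Path,
    default_species: str = "other",
    default_class: str = "genomic",
    manifest: str | Path | None = None,
) -> ReferenceCollection:
    """Load references from FASTA; species/class come from ``key=value``
    tokens in the description (``species=rice; class=rRNA``) or a sidecar
    TSV manifest with columns id, species, class."""
    meta: dict[str, tuple[str, str]] = {}
    if manifest is not None:
        mdf = pd.read_csv(manifest, sep="\t")  # columns: id, species, class
        for rid, species, cls in mdf.itertuples(index=False, name=None):
            meta[str(rid)] = (str(species), str(cls))
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(_KV_TOKEN.findall(rec.description))
        species, cls = meta.get(rec.id, (None, None))
        species = species or tokens.get("species", default_species)
        cls = cls or tokens.get("class", default_class)
        records.append(ReferenceRecord(rec.id, canonical(str(rec.seq)), species, cls))
    return ReferenceCollection(records)


def write_reference_collection(collection: ReferenceCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in collection:
            fh.write(f">{rec.id} species={rec.species}; class={rec.cls}\n{rec.sequence}\n")


def load_table6() -> pd.DataFrame:
    """The bundled table of 44 novel miRNA candidates (name, sequence,
    abundance, star fields, confidence) used as a reference fixture."""
    with resources.files("mirseeker.data").joinpath("table6.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"abundance": "Int64"})
    return df
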