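"""Shared format readers/writers: FASTA, GenBank, CSV tables, provenance.

Sequence I/O goes through Biopython's SeqIO (FASTA records at a fixed
60-column wrap; GenBank with features preserved); tables through pandas.
Every CLI run records a JSON provenance sidecar (inputs, parameters, seed,
package version).
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .clonesim import SeqMol

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "read_table",
    "write_table",
    "seqmol_to_record",
    "record_to_seqmol",
    "write_provenance",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} mapping.

    Mixed-case input is normalised to uppercase with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: mixed-case sequence normalised to uppercase")
        out[rec.id] = seq.upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    """Write sequences as FASTA, 60 characters per line."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def seqmol_to_record(mol: SeqMol) -> SeqRecord:
    """Convert a SeqMol to a GenBank-ready SeqRecord with features."""
    rec = SeqRecord(Seq(mol.seq), id=mol.name or "molecule", description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    for start, end, label in mol.features:
        rec.features.append(
            SeqFeature(FeatureLocation(start, end), type="misc_feature",
                       qualifiers={"label": [label]})
        )
    for j in mol.junctions:
        rec.features.append(
            SeqFeature(
                FeatureLocation(max(0, j.site_start),
                                max(0, j.site_start) + len(j.site)),
                type="misc_feature",
                qualifiers={
                    "label": [f"junction_{j.kind}"],
                    "note": [f"site={j.site};regenerates={','.join(j.regenerated_sites) or 'none'}"],
                },
            )
        )
    return rec


def record_to_seqmol(rec: SeqRecord) -> SeqMol:
    features = tuple(
        (int(f.location.start), int(f.location.end),
         (f.qualifiers.get("label") or [f.type])[0])
        for f in rec.features
    )
    topology = rec.annotations.get("topology", "linear")
    return SeqMol(str(rec.seq).upper(), topology=topology, name=rec.id,
                  features=features)


def read_genbank(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return records


def write_genbank(path: str | Path, records: Iterable[SeqRecord | SeqMol]) -> None:
    recs = [seqmol_to_record(r) if isinstance(r, SeqMol) else r for r in records]
    for r in recs:
        r.annotations.setdefault("molecule_type", "DNA")
    SeqIO.write(recs, str(path), "genbank")


def read_table(path: str | Path, required_columns: Iterable[str] = ()) -> pd.DataFrame:
    """Read a CSV table, enforcing a header schema."""
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_provenance(
    out_dir: str | Path, subcommand: str, parameters: Mapping, seed: int | None
) -> Path:
    """Emit the JSON provenance record accompanying every CLI run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "gdtandem",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": {k: str(v) for k, v in parameters.items()},
        "seed": seed,
        "argv": sys.argv,
    }
    path = out_dir / f"{subcommand}.provenance.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
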