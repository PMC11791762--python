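"""Serialisation: extended FASTA, strict-IUPAC FASTA + BED, reads, manifests.

Oligo stores are written as *extended FASTA*: standard FASTA syntax whose
sequences use the non-IUPAC letter M for 5-methylcytosine (declared in
each record's description).  For interoperability with tools that reject
M, a strict-IUPAC export writes C at methylated positions alongside a
BED file (0-based, half-open) of methylated-cytosine coordinates.

Read sets are written as FASTA of basecalled sequences plus a TSV
sidecar of per-C methylation scores (read id, 0-based position, 0-255
score).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .packets import Oligo, StoreManifest
from .readsim import ReadRecord

__all__ = [
    "write_oligos_fasta",
    "read_oligos_fasta",
    "write_iupac_fasta_bed",
    "write_manifest",
    "read_manifest",
    "write_reads",
    "read_reads",
]

ALPHABET_NOTE = "alphabet=ATCGM M=5-methylcytosine"


def write_oligos_fasta(oligos: list[Oligo], path: str | Path) -> None:
    """One record per oligo; id is the address, description carries the role."""
    records = [
        SeqRecord(
            Seq(o.letters),
            id=str(o.address),
            description=f"role={o.role} {ALPHABET_NOTE}",
        )
        for o in oligos
    ]
    SeqIO.write(records, str(path), "fasta")


def read_oligos_fasta(path: str | Path) -> list[Oligo]:
    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = "data"
        for tok in rec.description.split():
            if tok.startswith("role="):
                role = tok[5:]
        oligos.append(Oligo(int(rec.id), str(rec.seq), role))
    return oligos


def write_iupac_fasta_bed(
    oligos: list[Oligo], fasta_path: str | Path, bed_path: str | Path
) -> None:
    """Strict-IUPAC export: M rendered as C plus a BED of methylated positions."""
    records = []
    bed_lines = []
    for o in oligos:
        records.append(
            SeqRecord(
                Seq(o.letters.replace("M", "C")),
                id=str(o.address),
                description=f"role={o.role}",
            )
        )
        for i, c in enumerate(o.letters):
            if c == "M":
                bed_lines.append(f"{o.address}\t{i}\t{i + 1}\t5mC")
    SeqIO.write(records, str(fasta_path), "fasta")
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))


def write_manifest(manifest: StoreManifest, path: str | Path) -> None:
    Path(path).write_text(manifest.to_json() + "\n")


def read_manifest(path: str | Path) -> StoreManifest:
    return StoreManifest.from_json(Path(path).read_text())


def write_reads(reads: list[ReadRecord], fasta_path: str | Path, meth_path: str | Path) -> None:
    """Basecalled reads as FASTA plus a TSV sidecar of methylation scores."""
    records = [
        SeqRecord(
            Seq(r.bases),
            id=f"read{i}",
            description=f"source={r.source_address if r.source_address is not None else '.'}",
        )
        for i, r in enumerate(reads)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["read_id\tposition\tmeth_prob"]
    for i, r in enumerate(reads):
        for pos in sorted(r.meth_probs):
            lines.append(f"read{i}\t{pos}\t{r.meth_probs[pos]}")
    Path(meth_path).write_text("\n".join(lines) + "\n")


def read_reads(fasta_path: str | Path, meth_path: str | Path) -> list[ReadRecord]:
    probs_by_read: dict[str, dict[int, int]] = {}
    lines = Path(meth_path).read_text().splitlines()
    for line in lines[1:]:
        rid, pos, p = line.split("\t")
        probs_by_read.setdefault(rid, {})[int(pos)] = int(p)
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        source = None
        for tok in rec.description.split():
            if tok.startswith("source=") and tok[7:] != ".":
                source = int(tok[7:])
        reads.append(
            ReadRecord(str(rec.seq), probs_by_read.get(rec.id, {}), source_address=source)
        )
    return reads
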