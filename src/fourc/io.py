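"""File formats: FASTA/FASTQ (Biopython), BED, bedGraph, TSV, YAML.

All genomic records use 0-based half-open coordinates, which is also BED's
native convention.  The frag-end library round-trips through BED6 plus
three extra columns (sequence, unique, blind); profiles are written as TSV
with one column per processing state and as per-state bedGraph tracks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import Anchor
from .expression import ExpressionTable
from .fragends import LEFT, RIGHT, FragEnd, GenomeSequence
from .profiles import CoverageProfile, Viewpoint, genomic_order

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_fragend_bed",
    "read_fragend_bed",
    "write_fragend_fasta",
    "write_profile_tsv",
    "write_profile_bedgraph",
    "read_anchor_centers",
    "read_viewpoint_yaml",
    "write_viewpoint_yaml",
    "read_expression_tsv",
    "write_expression_tsv",
]


# -- FASTA / FASTQ ----------------------------------------------------------


def read_fasta(path) -> list[GenomeSequence]:
    records = [
        GenomeSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(genome: Iterable[GenomeSequence], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.chrom_name, description="")
        for g in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """FASTQ records as (id, sequence, quality-string); Phred is ignored
    downstream."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# -- frag-end library -------------------------------------------------------

_SIDE_CODE = {LEFT: "L", RIGHT: "R"}
_SIDE_DECODE = {"L": LEFT, "R": RIGHT}


def write_fragend_bed(library: Sequence[FragEnd], path) -> None:
    """BED6 + sequence/unique/blind columns.

    The BED interval is the genomic footprint of the frag-end sequence;
    strand encodes the reading direction (+ for a left flank read
    rightward, − for a right flank read leftward).
    """
    with open(path, "w") as fh:
        for fe in library:
            if fe.side == LEFT:
                start, end, strand = fe.pos, fe.pos + len(fe.sequence), "+"
            else:
                start, end, strand = fe.pos - len(fe.sequence), fe.pos, "-"
            fh.write(
                "\t".join(
                    [
                        fe.chrom,
                        str(start),
                        str(end),
                        fe.id,
                        str(fe.fragment_index),
                        strand,
                        fe.sequence,
                        "1" if fe.is_unique else "0",
                        "1" if fe.is_blind else "0",
                    ]
                )
                + "\n"
            )


def read_fragend_bed(path) -> list[FragEnd]:
    library = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand, seq, uniq, blind = (
                line.rstrip("\n").split("\t")
            )
            side = _SIDE_DECODE[name.rsplit(":", 1)[1]]
            pos = int(start) if side == LEFT else int(end)
            library.append(
                FragEnd(
                    chrom=chrom,
                    pos=pos,
                    side=side,
                    sequence=seq,
                    fragment_index=int(score),
                    is_unique=uniq == "1",
                    is_blind=blind == "1",
                )
            )
    if not library:
        raise ValueError(f"no frag-ends in {path}")
    return library


def write_fragend_fasta(library: Sequence[FragEnd], path) -> None:
    records = [
        SeqRecord(Seq(fe.sequence), id=fe.id, description="")
        for fe in library
    ]
    SeqIO.write(records, str(path), "fasta")


# -- profiles ---------------------------------------------------------------


def write_profile_tsv(
    profiles_by_state: dict[str, CoverageProfile], path
) -> None:
    """One row per frag-end in genomic order, one value column per state
    (e.g. raw / normalized / smoothed)."""
    first = next(iter(profiles_by_state.values()))
    order = genomic_order(first.library)
    data = {
        "chrom": [first.library[i].chrom for i in order],
        "pos": [first.library[i].pos for i in order],
        "fragend_id": [first.library[i].id for i in order],
    }
    for state, profile in profiles_by_state.items():
        data[state] = [f"{profile.counts[i]:.6f}" for i in order]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile_bedgraph(
    profile: CoverageProfile, path, track_name: str | None = None
) -> None:
    """Point intervals (pos, pos+1) valued by the profile's current state."""
    name = track_name or f"{profile.viewpoint.name}_{profile.state}"
    order = genomic_order(profile.library)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for i in order:
            fe = profile.library[i]
            fh.write(f"{fe.chrom}\t{fe.pos}\t{fe.pos + 1}\t{profile.counts[i]:.6f}\n")


# -- anchors, viewpoints, expression ---------------------------------------


def read_anchor_centers(path) -> list[tuple[str, int]]:
    """Anchor positions from BED (chrom, start, end → midpoint) or from a
    two-column chrom/center text file."""
    centers = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) >= 3 and fields[2].isdigit():
                start, end = int(fields[1]), int(fields[2])
                centers.append((fields[0], (start + end) // 2))
            else:
                centers.append((fields[0], int(fields[1])))
    if not centers:
        raise ValueError(f"no anchor centers in {path}")
    return centers


def write_anchor_bed(anchors: Sequence[Anchor], path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")


def read_viewpoint_yaml(path) -> Viewpoint:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return Viewpoint(
        name=data["name"],
        chrom=data["chrom"],
        position=int(data["position"]),
        reading_primer=data["reading_primer"],
        nonreading_primer=data.get("nonreading_primer", ""),
    )


def write_viewpoint_yaml(viewpoint: Viewpoint, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "name": viewpoint.name,
                "chrom": viewpoint.chrom,
                "position": viewpoint.position,
                "reading_primer": viewpoint.reading_primer,
                "nonreading_primer": viewpoint.nonreading_primer,
            },
            fh,
            sort_keys=False,
        )


def write_expression_tsv(table: ExpressionTable, path) -> None:
    rows = []
    for sample in table.quantities.columns:
        info = table.sample_info.loc[sample]
        for gene in table.quantities.index:
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "genotype": info["genotype"],
                    "tissue": info["tissue"],
                    "quantity": table.quantities.loc[gene, sample],
                    "is_reference": int(gene in table.reference_genes),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    quantities = df.pivot(index="gene", columns="sample", values="quantity")
    info = df.drop_duplicates("sample").set_index("sample")[["genotype", "tissue"]]
    quantities = quantities[list(info.index)]
    refs = sorted(df.loc[df["is_reference"] == 1, "gene"].unique())
    return ExpressionTable(
        quantities=quantities, sample_info=info, reference_genes=refs
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
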