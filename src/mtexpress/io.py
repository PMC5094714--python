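"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is TSV (or FASTA / newick / JSON) so intermediate results remain
inspectable: pileups as (position, A, C, G, T), counts as genes × samples,
genotypes as sites × samples, variants as a minimal VCF-like table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mtexpress.eqtl import GenotypeMatrix
from mtexpress.mtconsensus import ConsensusSequence, PileupMatrix, VariantCall
from mtexpress.phylo import HaplogroupDefinition

__all__ = [
    "read_pileup", "write_pileup",
    "read_counts", "write_counts",
    "read_sample_table", "write_sample_table",
    "read_genotypes", "write_genotypes",
    "read_haplogroup_definitions", "write_haplogroup_definitions",
    "write_consensus_fasta", "read_consensus_fasta",
    "write_variants", "write_json",
]


def read_pileup(path: str | Path, sample_id: str | None = None) -> PileupMatrix:
    frame = pd.read_csv(path, sep="\t")
    return PileupMatrix.from_frame(frame, sample_id or Path(path).stem)


def write_pileup(pileup: PileupMatrix, path: str | Path) -> None:
    pileup.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return frame.set_index("sample_id", drop=False)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, ploidy: str) -> GenotypeMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0)
    if ploidy == "haploid":
        data = data.astype(str)
    return GenotypeMatrix(data=data, ploidy=ploidy)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.data.to_csv(path, sep="\t")


def read_haplogroup_definitions(
    path: str | Path, reference_length: int = 16569
) -> HaplogroupDefinition:
    frame = pd.read_csv(path, sep="\t")
    return HaplogroupDefinition.from_frame(frame, reference_length)


def write_haplogroup_definitions(
    defs: HaplogroupDefinition, path: str | Path
) -> None:
    defs.to_frame().to_csv(path, sep="\t", index=False)


def write_consensus_fasta(
    consensuses: Sequence[ConsensusSequence], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.sample_id, description="")
        for c in consensuses
    ]
    SeqIO.write(records, str(path), "fasta")


def read_consensus_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_variants(
    variants_by_sample: Mapping[str, Sequence[VariantCall]], path: str | Path
) -> None:
    rows = [
        (sample, v.position, v.reference, v.observed, v.major_fraction)
        for sample, calls in variants_by_sample.items()
        for v in calls
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "POS", "REF", "ALT", "AF"]
    ).to_csv(path, sep="\t", index=False)


def write_json(payload, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
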