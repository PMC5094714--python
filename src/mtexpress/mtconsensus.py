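"""Consensus calling from mtDNA base-count pileups and variant extraction.

Human mtDNA is transcribed as strand-wide polycistrons, so bulk RNA-seq
covers essentially the whole mitochondrial genome; a per-position base-count
pileup therefore suffices to reconstruct each sample's mtDNA sequence by a
majority rule.  Positions failing depth or majority thresholds (or tied) are
emitted as N.  Variants are substitutions of the consensus against the
reference, with universal RNA-DNA difference (RDD) positions masked so that
transcriptome-only artifacts never enter the genotype matrix.

Coordinates are 1-based inclusive on the linear rCRS frame of 16,569 bases;
circularity is ignored because pileups are positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MT_LENGTH = 16569  # rCRS coordinate frame

_BASE_ORDER = "ACGT"
_BASE_ARR = np.array(list(_BASE_ORDER + "N"))

__all__ = [
    "MT_LENGTH",
    "PileupMatrix",
    "ConsensusSequence",
    "VariantCall",
    "call_consensus",
    "call_variants",
    "build_site_matrix",
]


@dataclass(frozen=True)
class PileupMatrix:
    """Per-sample base counts: one (nA, nC, nG, nT) row per mtDNA position."""

    sample_id: str
    counts: np.ndarray  # shape (length, 4), columns A, C, G, T

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("pileup counts must be a (length, 4) array")
        if (counts < 0).any():
            raise ValueError("pileup counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, columns=list(_BASE_ORDER))
        frame.insert(0, "position", np.arange(1, self.length + 1))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str) -> "PileupMatrix":
        frame = frame.sort_values("position")
        positions = frame["position"].to_numpy()
        if positions[0] != 1 or not np.array_equal(
            positions, np.arange(1, len(positions) + 1)
        ):
            raise ValueError("pileup table must cover positions 1..L contiguously")
        return cls(
            sample_id=sample_id,
            counts=frame[list(_BASE_ORDER)].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority-rule consensus over {A,C,G,T,N} with per-site major fractions."""

    sample_id: str
    sequence: str
    major_fraction: np.ndarray | None = None  # NaN where the call is N

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("consensus may contain only A, C, G, T, N")
        if self.major_fraction is not None and len(self.major_fraction) != len(
            self.sequence
        ):
            raise ValueError("major_fraction length must match sequence")


@dataclass(frozen=True)
class VariantCall:
    """One substitution of the consensus against the reference."""

    position: int  # 1-based
    reference: str
    observed: str
    major_fraction: float

    def __post_init__(self) -> None:
        if self.observed == self.reference:
            raise ValueError("variant observed allele equals reference")


def call_consensus(
    pileup: PileupMatrix,
    min_depth: int = 5,
    min_major_fraction: float = 0.7,
    reference_length: int | None = None,
) -> ConsensusSequence:
    """Majority-rule consensus of a pileup.

    At each position the base with the highest count is emitted iff the
    total depth is at least ``min_depth`` and that base's fraction of the
    depth is at least ``min_major_fraction``; otherwise (including exact
    ties for the top count) the position is N.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 < min_major_fraction <= 1.0:
        raise ValueError("min_major_fraction must lie in (0.5, 1]")
    if reference_length is not None and pileup.length != reference_length:
        raise ValueError(
            f"pileup length {pileup.length} != reference length {reference_length}"
        )
    counts = pileup.counts
    depth = counts.sum(axis=1)
    order = np.argsort(counts, axis=1, kind="stable")
    top = order[:, -1]
    top_count = np.take_along_axis(counts, top[:, None], axis=1)[:, 0]
    second_count = np.take_along_axis(counts, order[:, -2][:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        fraction = np.where(depth > 0, top_count / np.maximum(depth, 1), 0.0)
    ok = (
        (depth >= min_depth)
        & (fraction >= min_major_fraction)
        & (top_count > second_count)
    )
    codes = np.where(ok, top, 4)
    sequence = "".join(_BASE_ARR[codes])
    major_fraction = np.where(ok, fraction, np.nan)
    return ConsensusSequence(
        sample_id=pileup.sample_id, sequence=sequence, major_fraction=major_fraction
    )


def call_variants(
    consensus: ConsensusSequence,
    reference: str,
    rdd_sites: Sequence[int] = (),
) -> list[VariantCall]:
    """Substitutions of the consensus against the reference, RDD masked.

    One call per position where a called base (not N) differs from the
    reference; positions listed in ``rdd_sites`` are excluded regardless of
    allele, since a universal RNA-DNA difference carries no information
    about the underlying DNA haplotype.
    """
    if len(consensus.sequence) != len(reference):
        raise ValueError("consensus and reference lengths differ")
    masked = {int(p) for p in rdd_sites}
    calls: list[VariantCall] = []
    frac = consensus.major_fraction
    for idx, (obs, ref) in enumerate(zip(consensus.sequence, reference)):
        pos = idx + 1
        if obs == "N" or obs == ref or pos in masked:
            continue
        calls.append(
            VariantCall(
                position=pos,
                reference=ref,
                observed=obs,
                major_fraction=float(frac[idx]) if frac is not None else 1.0,
            )
        )
    return calls


def build_site_matrix(
    variants_by_sample: Mapping[str, Sequence[VariantCall]],
    consensuses: Mapping[str, ConsensusSequence],
    min_carriers: int = 10,
):
    """Haploid allele matrix over the cohort's polymorphic positions.

    Rows are positions where any sample carries a variant; each sample's
    entry is its consensus base there (N allowed).  A site is retained only
    if at least one non-major allele is carried by ``min_carriers`` or more
    samples.  At most the three most frequent alleles are kept per site;
    rarer alleles are recoded N, mirroring the at-most-three-allele
    structure observed in real mtDNA cohorts.
    """
    from mtexpress.eqtl import GenotypeMatrix

    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    samples = list(consensuses)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a site matrix")
    if set(variants_by_sample) - set(samples):
        raise ValueError("variant lists include samples without consensus")

    positions = sorted(
        {v.position for calls in variants_by_sample.values() for v in calls}
    )
    if not positions:
        return GenotypeMatrix(
            data=pd.DataFrame(index=pd.Index([], name="site"), columns=samples),
            ploidy="haploid",
        )

    rows = []
    kept_positions = []
    for pos in positions:
        alleles = np.array(
            [consensuses[s].sequence[pos - 1] for s in samples], dtype="<U1"
        )
        called = alleles[alleles != "N"]
        if called.size == 0:
            continue
        uniq, counts = np.unique(called, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        uniq, counts = uniq[order], counts[order]
        if len(uniq) > 3:
            drop = set(uniq[3:])
            alleles = np.where(np.isin(alleles, list(drop)), "N", alleles)
            uniq, counts = uniq[:3], counts[:3]
        if len(uniq) < 2 or counts[1:].max() < min_carriers:
            continue
        rows.append(alleles)
        kept_positions.append(pos)

    data = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, len(samples)), dtype="<U1"),
        index=pd.Index(kept_positions, name="site"),
        columns=samples,
    )
    return GenotypeMatrix(data=data, ploidy="haploid")
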