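"""Exon inclusion-rate profiles from transcript-level abundance tables.

A cassette exon's inclusion rate in a sample is the FPKM mass of the
transcripts that cover the exon divided by the total FPKM of the host
gene's transcripts, so it always lies in [0, 1].  Because lowly expressed
genes give unreliable rate estimates, profiles are only kept for genes
whose expression is above a per-sample percentile (default 80th, taken
across all genes in that sample) in at least ``min_samples`` samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptQuant",
    "ExonRecord",
    "InclusionMatrix",
    "DatasetIneligibleError",
    "gene_expression",
    "exon_inclusion_rate",
    "build_inclusion_matrix",
    "exons_from_transcripts",
    "read_transcript_table",
    "write_transcript_table",
]


class DatasetIneligibleError(ValueError):
    """Raised when a dataset has too few samples to yield usable profiles."""


@dataclass
class TranscriptQuant:
    """Per-transcript abundance plus which exons the transcript covers.

    ``includes_exon`` maps exon ids of the host gene to whether this
    transcript's structure contains the exon; ``abundance`` maps sample id
    to a nonnegative FPKM.
    """

    transcript_id: str
    gene_id: str
    includes_exon: Mapping[str, bool]
    abundance: Mapping[str, float]

    def __post_init__(self) -> None:
        for sample, fpkm in self.abundance.items():
            if fpkm < 0:
                raise ValueError(
                    f"negative FPKM {fpkm} for {self.transcript_id}/{sample}"
                )

    def covers(self, exon_id: str) -> bool:
        return bool(self.includes_exon.get(exon_id, False))


@dataclass(frozen=True)
class ExonRecord:
    """A cassette exon and its host gene."""

    exon_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError(f"exon {self.exon_id!r} has empty gene_id")


@dataclass
class InclusionMatrix:
    """Exon-by-sample inclusion rates with NaN for undefined cells.

    ``values`` is a float DataFrame indexed by exon id with one column per
    sample; ``gene_ids`` maps each exon (same index) to its host gene.
    """

    values: pd.DataFrame
    gene_ids: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.equals(self.gene_ids.index):
            raise ValueError("gene_ids index must match the value matrix rows")
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("inclusion rates must lie in [0, 1]")

    @property
    def exon_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_exons(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", self.gene_ids)
        out.index.name = "exon_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InclusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index = df.index.astype(str)
        gene_ids = df.pop("gene_id").astype(str)
        return cls(values=df, gene_ids=gene_ids)


def gene_expression(
    transcripts: Sequence[TranscriptQuant], gene: str, sample: str
) -> float:
    """Total expression of a gene in a sample: the sum of FPKM over all of
    the gene's transcripts."""
    matched = [t for t in transcripts if t.gene_id == gene]
    if not matched:
        raise KeyError(f"no transcripts for gene {gene!r}")
    return float(sum(t.abundance.get(sample, 0.0) for t in matched))


def exon_inclusion_rate(
    transcripts: Sequence[TranscriptQuant], exon: ExonRecord, sample: str
) -> float:
    """Inclusion rate of one exon in one sample.

    Ratio of the summed FPKM of transcripts covering the exon to the
    summed FPKM of all transcripts of the host gene.  Returns NaN when the
    gene is unexpressed in the sample (0/0 carries no splicing signal).
    """
    gene_txs = [t for t in transcripts if t.gene_id == exon.gene_id]
    if not gene_txs:
        raise KeyError(f"host gene {exon.gene_id!r} of {exon.exon_id!r} has no transcripts")
    total = sum(t.abundance.get(sample, 0.0) for t in gene_txs)
    if total == 0:
        return math.nan
    included = sum(
        t.abundance.get(sample, 0.0) for t in gene_txs if t.covers(exon.exon_id)
    )
    return included / total


def build_inclusion_matrix(
    transcripts: Sequence[TranscriptQuant],
    exons: Sequence[ExonRecord],
    samples: Sequence[str],
    percentile: float = 80.0,
    min_samples: int = 6,
) -> InclusionMatrix:
    """Inclusion-rate matrix restricted to well-expressed host genes.

    The expression threshold is the given percentile (linear-interpolation
    convention) of the gene-expression distribution computed separately in
    each sample; a gene qualifies when it is strictly above the threshold
    in at least ``min_samples`` samples.  Only exons of qualifying genes
    appear in the output; retained cells are NaN only where the gene is
    entirely unexpressed in that sample.
    """
    samples = list(samples)
    if len(samples) < min_samples:
        raise DatasetIneligibleError(
            f"dataset ineligible: {len(samples)} samples < required {min_samples}"
        )
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")

    genes = sorted({t.gene_id for t in transcripts})
    expr = pd.DataFrame(0.0, index=genes, columns=samples)
    for t in transcripts:
        for s in samples:
            expr.loc[t.gene_id, s] += t.abundance.get(s, 0.0)

    thresholds = expr.quantile(percentile / 100.0, axis=0, interpolation="linear")
    qualifying = (expr.gt(thresholds, axis=1).sum(axis=1) >= min_samples)
    kept_genes = set(expr.index[qualifying])

    by_gene: dict[str, list[TranscriptQuant]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    kept = [e for e in exons if e.gene_id in kept_genes and e.gene_id in by_gene]
    rows = np.full((len(kept), len(samples)), np.nan)
    for r, exon in enumerate(kept):
        gene_txs = by_gene[exon.gene_id]
        for c, s in enumerate(samples):
            total = sum(t.abundance.get(s, 0.0) for t in gene_txs)
            if total > 0:
                inc = sum(
                    t.abundance.get(s, 0.0)
                    for t in gene_txs
                    if t.covers(exon.exon_id)
                )
                rows[r, c] = inc / total
    values = pd.DataFrame(rows, index=[e.exon_id for e in kept], columns=samples)
    gene_ids = pd.Series(
        [e.gene_id for e in kept], index=values.index, dtype=object
    )
    return InclusionMatrix(values=values, gene_ids=gene_ids)


def exons_from_transcripts(
    transcripts: Sequence[TranscriptQuant],
) -> list[ExonRecord]:
    """Derive the exon universe (exon -> host gene) from transcript models."""
    seen: dict[str, str] = {}
    for t in transcripts:
        for exon_id, covered in t.includes_exon.items():
            if not covered:
                continue
            prev = seen.get(exon_id)
            if prev is not None and prev != t.gene_id:
                raise ValueError(
                    f"exon {exon_id!r} claimed by genes {prev!r} and {t.gene_id!r}"
                )
            seen[exon_id] = t.gene_id
    return [ExonRecord(e, g) for e, g in sorted(seen.items())]


# ---------------------------------------------------------------------------
# Transcript table TSV:
#   transcript_id  gene_id  exon_ids(semicolon-separated covered exons)  <samples...>


def read_transcript_table(path: str | Path) -> tuple[list[TranscriptQuant], list[str]]:
    """Read a transcript abundance table; returns (transcripts, sample ids)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = ["transcript_id", "gene_id", "exon_ids"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"transcript table missing column {col!r}")
    samples = [c for c in df.columns if c not in required]
    transcripts = []
    for row in df.itertuples(index=False):
        covered = [e for e in str(getattr(row, "exon_ids") or "").split(";") if e and e != "nan"]
        transcripts.append(
            TranscriptQuant(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                includes_exon={e: True for e in covered},
                abundance={s: float(getattr(row, s)) for s in samples},
            )
        )
    return transcripts, samples


def write_transcript_table(
    transcripts: Sequence[TranscriptQuant], samples: Sequence[str], path: str | Path
) -> None:
    rows = []
    for t in transcripts:
        covered = ";".join(sorted(e for e, c in t.includes_exon.items() if c))
        rows.append(
            [t.transcript_id, t.gene_id, covered]
            + [t.abundance.get(s, 0.0) for s in samples]
        )
    pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "exon_ids", *samples]
    ).to_csv(path, sep="\t", index=False)
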