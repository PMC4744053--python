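"""Reading, validation and QC screening of aligned barcode data.

A dataset is an aligned nucleotide FASTA (all sequences the same length,
default 658 bp for the Folmer COI fragment) joined one-to-one on sample id
to a tab-separated specimen table carrying the morphospecies, genus, tribe
and locality columns. Quality screening flags putative nuclear
mitochondrial pseudogenes (Numts): sequences whose in-frame translation
under the invertebrate mitochondrial code contains an internal stop codon,
or whose gap count is incompatible with an intact reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SpecimenRecord",
    "AlignedBarcode",
    "BarcodeDataset",
    "read_dataset",
    "write_dataset",
    "screen_pseudogenes",
    "count_by_sampling",
    "ValidationError",
]

METADATA_COLUMNS = ["sample_id", "morphospecies", "genus", "tribe", "country", "province", "source"]

#: Unambiguous bases, IUPAC ambiguity codes and the alignment gap character.
_BASES = set("ACGT")
_IUPAC_AMBIG = set("RYSWKMBDHVN")
_ALLOWED = _BASES | _IUPAC_AMBIG | {"-"}

#: Invertebrate mitochondrial genetic code (NCBI translation table 5); the
#: only stop codons are TAA and TAG (AGA/AGG encode serine).
INVERTEBRATE_MITO_TABLE = 5


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen row of the metadata table."""

    sample_id: str
    morphospecies: str
    genus: str
    tribe: str
    country: str = ""
    province: str = ""
    source: str = "field"

    def __post_init__(self) -> None:
        for attr in ("sample_id", "morphospecies", "genus", "tribe"):
            if not getattr(self, attr):
                raise ValidationError(f"SpecimenRecord.{attr} must be non-empty")
        if self.source not in ("field", "genbank"):
            raise ValidationError(f"source must be 'field' or 'genbank', got {self.source!r}")


@dataclass(frozen=True)
class AlignedBarcode:
    """One aligned barcode sequence; stored uppercase."""

    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValidationError(
                f"sequence {self.sample_id}: illegal characters {sorted(bad)}"
            )


@dataclass
class BarcodeDataset:
    """Aligned sequences joined 1:1 to specimen metadata.

    ``frame_offset`` is the number of leading alignment columns before the
    first complete codon; the 658-bp Folmer fragment begins mid-codon, so
    the conventional offset is 1.
    """

    records: list[SpecimenRecord]
    alignment: list[AlignedBarcode]
    frame_offset: int = 1

    def __post_init__(self) -> None:
        if not self.alignment:
            raise ValidationError("dataset has no sequences")
        ids_fasta = [a.sample_id for a in self.alignment]
        ids_meta = [r.sample_id for r in self.records]
        if len(set(ids_fasta)) != len(ids_fasta):
            dups = sorted({i for i in ids_fasta if ids_fasta.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dups}")
        if len(set(ids_meta)) != len(ids_meta):
            dups = sorted({i for i in ids_meta if ids_meta.count(i) > 1})
            raise ValidationError(f"duplicate metadata ids: {dups}")
        missing = sorted(set(ids_fasta) - set(ids_meta))
        extra = sorted(set(ids_meta) - set(ids_fasta))
        if missing or extra:
            raise ValidationError(
                f"join error: fasta ids missing from metadata {missing}; "
                f"metadata ids missing from fasta {extra}"
            )
        lengths = {len(a.sequence) for a in self.alignment}
        if len(lengths) != 1:
            raise ValidationError(f"alignment error: mixed sequence lengths {sorted(lengths)}")
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        # keep metadata in FASTA order for reproducible downstream output
        by_id = {r.sample_id: r for r in self.records}
        self.records = [by_id[i] for i in ids_fasta]

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.alignment]

    @property
    def length(self) -> int:
        return len(self.alignment[0].sequence)

    def __len__(self) -> int:
        return len(self.alignment)

    def record_of(self, sample_id: str) -> SpecimenRecord:
        if not hasattr(self, "_rec_index"):
            self._rec_index = {r.sample_id: r for r in self.records}
        return self._rec_index[sample_id]

    def species_of(self, sample_id: str) -> str:
        return self.record_of(sample_id).morphospecies

    def to_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame in alignment order."""
        return pd.DataFrame([vars(r) for r in self.records], columns=METADATA_COLUMNS)


def read_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    frame_offset: int = 1,
    max_missing_fraction: float = 0.5,
) -> BarcodeDataset:
    """Read and validate an aligned FASTA plus a tab-separated metadata table.

    Sequences with at least ``max_missing_fraction`` gap/N characters are
    rejected as truncated records.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise ValidationError(f"no sequences found in {fasta_path}")
    alignment = []
    for rec in seqs:
        s = str(rec.seq).upper()
        n_missing = sum(1 for c in s if c in "-N")
        if s and n_missing / len(s) >= max_missing_fraction:
            raise ValidationError(
                f"sequence {rec.id}: {n_missing}/{len(s)} gap/N characters "
                f"(>= {max_missing_fraction:.0%}); truncated record?"
            )
        alignment.append(AlignedBarcode(rec.id, s))

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in ("sample_id", "morphospecies", "genus", "tribe") if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata table missing required columns: {missing_cols}")
    records = [
        SpecimenRecord(
            sample_id=row["sample_id"],
            morphospecies=row["morphospecies"],
            genus=row["genus"],
            tribe=row["tribe"],
            country=row.get("country", ""),
            province=row.get("province", ""),
            source=row.get("source", "field") or "field",
        )
        for _, row in meta.iterrows()
    ]
    return BarcodeDataset(records=records, alignment=alignment, frame_offset=frame_offset)


def write_dataset(ds: BarcodeDataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write the dataset back to FASTA + tab-separated metadata (round-trip safe)."""
    recs = [SeqRecord(Seq(a.sequence), id=a.sample_id, description="") for a in ds.alignment]
    SeqIO.write(recs, str(fasta_path), "fasta")
    ds.to_frame().to_csv(metadata_path, sep="\t", index=False)


def screen_pseudogenes(ds: BarcodeDataset, frame_offset: int | None = None) -> list[tuple[str, str]]:
    """Flag putative Numts: internal in-frame stop codons or frame-shifting gaps.

    Returns ``(sample_id, reason)`` pairs; an empty list means the dataset is
    clean. Codons containing gaps or ambiguity codes are skipped (treated as
    missing data), so partial records do not trigger spurious stops.
    """
    if frame_offset is None:
        frame_offset = ds.frame_offset
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    flags: list[tuple[str, str]] = []
    for ab in ds.alignment:
        seq = ab.sequence
        if len(seq) - frame_offset < 3:
            raise ValueError(f"sequence {ab.sample_id} too short for frame offset {frame_offset}")
        n_gaps = seq.count("-")
        if n_gaps % 3 != 0:
            flags.append((ab.sample_id, f"frameshift indel ({n_gaps} gap columns, not a multiple of 3)"))
            continue
        coding = seq[frame_offset:].replace("-", "")
        coding = coding[: len(coding) - len(coding) % 3]
        stop_at = None
        for i in range(0, len(coding) - 3, 3):  # exclude the terminal codon
            codon = coding[i : i + 3]
            if set(codon) <= _BASES:
                aa = str(Seq(codon).translate(table=INVERTEBRATE_MITO_TABLE))
                if aa == "*":
                    stop_at = i // 3 + 1
                    break
        if stop_at is not None:
            flags.append((ab.sample_id, f"internal stop at codon {stop_at}"))
    return flags


def count_by_sampling(ds: BarcodeDataset) -> tuple[int, int]:
    """Partition morphospecies into singletons vs multi-specimen species.

    Returns ``(n_singleton_species, n_multi_species)``; the two counts sum to
    the number of distinct morphospecies labels.
    """
    counts = ds.to_frame()["morphospecies"].value_counts()
    n_single = int((counts == 1).sum())
    return n_single, int(len(counts) - n_single)
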