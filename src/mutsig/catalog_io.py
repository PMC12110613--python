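"""Somatic-mutation records, channel classification and mutation catalogs.

Reads Simple Somatic Mutation (SSM) tab-separated files in the ICGC dialect
(1-based inclusive coordinates, ``-`` for the null allele), retrieves flanking
sequence context either from embedded ``context5``/``context3`` columns or
from an indexed FASTA, classifies every event into its SBS96 / DBS78 / ID83
channel and assembles per-sample count matrices.

Coordinate conventions
----------------------
Positions are 1-based and refer to the first affected reference base.
Insertions are anchored at the base *after which* the inserted sequence
occurs, so ``context5`` ends at the anchor base and ``context3`` starts at
the next reference base.

Indel binning
-------------
1-bp events are binned by the length of the homopolymer run of the affected
base (the run containing the deleted base, or the run adjacent to the
insertion point). Longer events are binned by the number of maximal tandem
copies of the event unit on the forward strand extending 3' of the locus
(deletions count the deleted copy itself). Deletions of length >= 2 with a
single copy and flanking homology of >= 1 bp are microhomology channels;
homology is the longer of the prefix of the deleted sequence matched by the
3' flank and its suffix matched by the 5' flank, capped at event length - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    ChannelScheme,
    canonical_dbs,
    channel_index,
    channel_labels,
    complement,
    revcomp,
)

logger = logging.getLogger(__name__)

MIN_FLANK = 10


class SsmFormatError(ValueError):
    """The SSM file is missing a required column or is otherwise unreadable."""


class ContextError(ValueError):
    """A record's sequence context is too short for the required scan."""


class MutationKind(str, Enum):
    SNV = "SNV"
    DNV = "DNV"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic event with flanking sequence context.

    ``ref``/``alt`` use ``"-"`` for the null allele (pure insertion /
    deletion). Context strings are uppercase ACGT, immediately adjacent to
    the event on each side.
    """

    sample_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    kind: MutationKind
    context5: str
    context3: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chromosome}:{self.position}")
        k, ref, alt = self.kind, self.ref, self.alt
        ok = (
            (k is MutationKind.SNV and len(ref) == 1 and len(alt) == 1 and "-" not in (ref, alt))
            or (k is MutationKind.DNV and len(ref) == 2 and len(alt) == 2 and "-" not in (ref, alt))
            or (k is MutationKind.INS and ref == "-" and len(alt) >= 1 and alt != "-")
            or (k is MutationKind.DEL and alt == "-" and len(ref) >= 1 and ref != "-")
        )
        if not ok:
            raise ValueError(f"alleles {ref!r}>{alt!r} inconsistent with kind {k.value}")

    @property
    def event_length(self) -> int:
        if self.kind is MutationKind.INS:
            return len(self.alt)
        if self.kind is MutationKind.DEL:
            return len(self.ref)
        return len(self.ref)

    def reverse_complemented(self) -> "MutationRecord":
        """The same event read from the opposite strand."""
        rc = lambda a: a if a == "-" else revcomp(a)
        return MutationRecord(
            sample_id=self.sample_id,
            chromosome=self.chromosome,
            position=self.position,
            ref=rc(self.ref),
            alt=rc(self.alt),
            kind=self.kind,
            context5=revcomp(self.context3),
            context3=revcomp(self.context5),
        )


@dataclass
class SkipReport:
    """Tally of rows dropped while reading an SSM file."""

    malformed: int = 0
    ambiguous_base: int = 0
    out_of_bounds: int = 0
    unsupported: int = 0

    @property
    def total(self) -> int:
        return self.malformed + self.ambiguous_base + self.out_of_bounds + self.unsupported


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_sbs(record: MutationRecord) -> str:
    """SBS96 channel of a single-base substitution.

    Purine references are reverse-complemented (together with both flanks
    and the alternate base) so every channel is reported on the pyrimidine
    strand.
    """
    if record.kind is not MutationKind.SNV:
        raise TypeError(f"classify_sbs requires an SNV, got {record.kind.value}")
    if not record.context5 or not record.context3:
        raise ContextError("SNV needs at least one base of 5' and 3' context")
    ref, alt = record.ref, record.alt
    five, three = record.context5[-1], record.context3[0]
    if ref in "AG":
        ref, alt = complement(ref), complement(alt)
        five, three = complement(record.context3[0]), complement(record.context5[-1])
    return f"{five}[{ref}>{alt}]{three}"


def classify_dbs(record: MutationRecord) -> str:
    """DBS78 channel of a doublet substitution."""
    if record.kind is not MutationKind.DNV:
        raise TypeError(f"classify_dbs requires a DNV, got {record.kind.value}")
    if record.ref[0] == record.alt[0] or record.ref[1] == record.alt[1]:
        raise ValueError(f"invalid DNV {record.ref}>{record.alt}: shared base at same offset")
    ref, alt = canonical_dbs(record.ref, record.alt)
    return f"{ref}>{alt}"


def _leading_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def _leading_copies(seq: str, unit: str) -> int:
    L, n = len(unit), 0
    while seq[n * L : (n + 1) * L] == unit:
        n += 1
    return n


def _prefix_match(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel(record: MutationRecord) -> str:
    """ID83 channel of an insertion or deletion."""
    if record.kind not in (MutationKind.INS, MutationKind.DEL):
        raise TypeError(f"classify_indel requires INS/DEL, got {record.kind.value}")
    seq = record.alt if record.kind is MutationKind.INS else record.ref
    L = len(seq)
    need3 = max(MIN_FLANK, 5 * L)
    if len(record.context5) < MIN_FLANK or len(record.context3) < need3:
        raise ContextError(
            f"indel of length {L} needs >= {MIN_FLANK} bp 5' and >= {need3} bp 3' context"
        )
    op = "Ins" if record.kind is MutationKind.INS else "Del"

    if L == 1:
        base = seq
        run = _leading_run(record.context5[::-1], base) + _leading_run(record.context3, base)
        if op == "Del":
            run += 1  # the deleted base itself
            digit = min(run, 6) - 1
        else:
            digit = min(run, 5)
        norm = base if base in "CT" else complement(base)
        return f"1:{op}:{norm}:{digit}"

    copies = _leading_copies(record.context3, seq)
    if op == "Del":
        copies += 1  # the deleted copy itself
        if copies == 1:
            mh = max(
                _prefix_match(seq, record.context3),
                _prefix_match(seq[::-1], record.context5[::-1]),
            )
            mh = min(mh, L - 1)
            if mh >= 1:
                return f"{min(L, 5)}:Del:M:{min(mh, 5)}"
        digit = min(copies, 6) - 1
    else:
        digit = min(copies, 5)
    return f"{min(L, 5)}:{op}:R:{digit}"


_CLASSIFIERS = {
    ChannelScheme.SBS96: (classify_sbs, (MutationKind.SNV,)),
    ChannelScheme.DBS78: (classify_dbs, (MutationKind.DNV,)),
    ChannelScheme.ID83: (classify_indel, (MutationKind.INS, MutationKind.DEL)),
}


def classify(record: MutationRecord, scheme: ChannelScheme | str) -> str:
    """Dispatch to the classifier of ``scheme``."""
    fn, _ = _CLASSIFIERS[ChannelScheme(scheme)]
    return fn(record)


def kinds_for_scheme(scheme: ChannelScheme | str) -> tuple[MutationKind, ...]:
    return _CLASSIFIERS[ChannelScheme(scheme)][1]


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------


@dataclass
class MutationCatalog:
    """Samples x channels non-negative count matrix for one channel scheme."""

    sample_ids: list[str]
    channel_scheme: ChannelScheme
    counts: np.ndarray
    channel_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        canonical = channel_labels(self.channel_scheme)
        if self.channel_labels is None:
            self.channel_labels = canonical
        if tuple(self.channel_labels) != canonical:
            raise ValueError("channel labels must follow the scheme's canonical ordering")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(canonical)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sample_ids)}, {len(canonical)})"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("catalog entries must be non-negative integers")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def burdens(self) -> pd.Series:
        """Per-sample mutation totals (TMB for this scheme)."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="tmb")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=list(self.channel_labels))

    def to_tsv(self, path: str | Path) -> None:
        """Write in COSMIC layout: channel rows, one column per sample."""
        df = self.to_frame().T
        df.index.name = "MutationType"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scheme: ChannelScheme | str) -> "MutationCatalog":
        scheme = ChannelScheme(scheme)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(channel_labels(scheme)))
        if df.isna().any().any():
            raise SsmFormatError(f"catalog at {path} lacks canonical {scheme.value} channels")
        return cls(
            sample_ids=list(df.columns),
            channel_scheme=scheme,
            counts=df.to_numpy().T.astype(np.int64),
        )


def build_catalog(
    records: Iterable[MutationRecord],
    scheme: ChannelScheme | str,
    sample_ids: Sequence[str] | None = None,
) -> MutationCatalog:
    """Count records of the scheme's mutation kinds into a catalog.

    Records of other kinds are ignored. Samples are the sorted distinct
    sample ids of *all* records (or the explicit ``sample_ids``); samples
    with no classifiable record get an all-zero row.
    """
    records = list(records)
    if not records and sample_ids is None:
        raise ValueError("no records and no explicit sample ids")
    scheme = ChannelScheme(scheme)
    kinds = kinds_for_scheme(scheme)
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    row = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), scheme.n_channels), dtype=np.int64)
    for rec in records:
        if rec.kind not in kinds or rec.sample_id not in row:
            continue
        counts[row[rec.sample_id], channel_index(scheme, classify(rec, scheme))] += 1
    return MutationCatalog(list(sample_ids), scheme, counts)


# ---------------------------------------------------------------------------
# SSM TSV IO
# ---------------------------------------------------------------------------

_COLUMN_SYNONYMS = {
    "sample": ("icgc_sample_id", "sample_id", "sample"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("chromosome_start", "start", "position", "pos"),
    "end": ("chromosome_end", "end"),
    "ref": ("reference_genome_allele", "reference_allele", "ref"),
    "alt": ("mutated_to_allele", "mutated_allele", "tumor_allele", "alt"),
}

SSM_COLUMNS = [
    "icgc_sample_id",
    "chromosome",
    "chromosome_start",
    "chromosome_end",
    "reference_genome_allele",
    "mutated_to_allele",
    "mutation_type",
    "context5",
    "context3",
]

_KIND_NAMES = {
    MutationKind.SNV: "single base substitution",
    MutationKind.DNV: "double base substitution",
    MutationKind.INS: "insertion of <=200bp",
    MutationKind.DEL: "deletion of <=200bp",
}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for key, names in _COLUMN_SYNONYMS.items():
        for name in names:
            if name in lower:
                resolved[key] = lower[name]
                break
        else:
            raise SsmFormatError(
                f"SSM file is missing a '{names[0]}' column (any of {list(names)})"
            )
    return resolved


def _infer_kind(ref: str, alt: str) -> MutationKind | None:
    if ref == "-":
        return MutationKind.INS
    if alt == "-":
        return MutationKind.DEL
    if len(ref) == 1 and len(alt) == 1:
        return MutationKind.SNV
    if len(ref) == 2 and len(alt) == 2:
        return MutationKind.DNV
    return None


def _fasta_context(fasta, chrom: str, position: int, event_len: int, kind: MutationKind):
    """Fetch flanks from a pyfaidx.Fasta; returns None if out of bounds."""
    want3 = max(MIN_FLANK, 5 * event_len)
    if kind is MutationKind.INS:
        lo5, hi5 = position - MIN_FLANK, position  # context5 ends at anchor base
        lo3, hi3 = position, position + want3
    else:
        lo5, hi5 = position - 1 - MIN_FLANK, position - 1
        lo3, hi3 = position - 1 + event_len, position - 1 + event_len + want3
    if lo5 < 0:
        return None
    chrom_len = len(fasta[chrom])
    if hi3 > chrom_len:
        return None
    c5 = str(fasta[chrom][lo5:hi5]).upper()
    c3 = str(fasta[chrom][lo3:hi3]).upper()
    return c5, c3


def read_ssm_with_report(
    path: str | Path, fasta=None
) -> tuple[list[MutationRecord], SkipReport]:
    """Parse an SSM TSV; returns the records plus a tally of skipped rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)
    lower = {c.lower(): c for c in df.columns}
    c5_col, c3_col = lower.get("context5"), lower.get("context3")
    if (c5_col is None or c3_col is None) and fasta is None:
        raise SsmFormatError(
            "SSM file has no context5/context3 columns; a reference FASTA is required"
        )
    records: list[MutationRecord] = []
    report = SkipReport()
    acgt = set(BASES)
    for row in df.itertuples(index=False):
        row = row._asdict()
        ref = row[cols["ref"]].upper()
        alt = row[cols["alt"]].upper()
        kind = _infer_kind(ref, alt)
        if kind is None:
            report.unsupported += 1
            continue
        try:
            position = int(row[cols["start"]])
        except ValueError:
            report.malformed += 1
            continue
        for allele in (ref, alt):
            if allele != "-" and not set(allele) <= acgt:
                kind = None
                break
        if kind is None:
            report.ambiguous_base += 1
            continue
        event_len = len(alt) if kind is MutationKind.INS else len(ref)
        if c5_col is not None and c3_col is not None and row[c5_col] and row[c3_col]:
            c5, c3 = row[c5_col].upper(), row[c3_col].upper()
        else:
            chrom = row[cols["chromosome"]]
            if fasta is None or chrom not in fasta:
                report.malformed += 1
                continue
            ctx = _fasta_context(fasta, chrom, position, event_len, kind)
            if ctx is None:
                report.out_of_bounds += 1
                logger.warning("context window out of bounds at %s:%s", chrom, position)
                continue
            c5, c3 = ctx
        if not (set(c5) <= acgt and set(c3) <= acgt):
            report.ambiguous_base += 1
            continue
        try:
            records.append(
                MutationRecord(
                    sample_id=row[cols["sample"]],
                    chromosome=row[cols["chromosome"]],
                    position=position,
                    ref=ref,
                    alt=alt,
                    kind=kind,
                    context5=c5,
                    context3=c3,
                )
            )
        except ValueError:
            report.malformed += 1
    if report.total:
        logger.info("read_ssm: skipped %d rows (%s)", report.total, report)
    return records, report


def read_ssm(path: str | Path, fasta=None) -> list[MutationRecord]:
    """Parse an SSM TSV into mutation records (skipped rows are logged)."""
    return read_ssm_with_report(path, fasta)[0]


def write_ssm(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as an SSM TSV with embedded context columns."""
    rows = [
        {
            "icgc_sample_id": r.sample_id,
            "chromosome": r.chromosome,
            "chromosome_start": r.position,
            "chromosome_end": r.position + (0 if r.kind is MutationKind.INS else r.event_length - 1),
            "reference_genome_allele": r.ref,
            "mutated_to_allele": r.alt,
            "mutation_type": _KIND_NAMES[r.kind],
            "context5": r.context5,
            "context3": r.context3,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SSM_COLUMNS).to_csv(path, sep="\t", index=False)
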