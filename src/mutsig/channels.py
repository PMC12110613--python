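"""Canonical mutation-channel schemes.

Three channel schemes are supported, following the COSMIC conventions:

* ``SBS96``  — single-base substitutions in trinucleotide context,
  pyrimidine-strand normalized: labels like ``"A[C>A]A"``.
* ``DBS78``  — doublet-base substitutions collapsed onto the ten canonical
  reference doublets: labels like ``"CC>AA"``.
* ``ID83``   — small insertions/deletions binned by length, affected base
  (1-bp events), repeat-unit copy number, and microhomology: labels like
  ``"1:Del:C:0"`` or ``"5:Del:M:5"``.

Homopolymer/repeat channels carry a 0-based bin digit; microhomology
channels carry the (capped) homology length, so the digit ranges differ by
channel family exactly as in the COSMIC ID83 label set.
"""

from __future__ import annotations

from enum import Enum

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


class ChannelScheme(str, Enum):
    SBS96 = "SBS96"
    DBS78 = "DBS78"
    ID83 = "ID83"

    @property
    def n_channels(self) -> int:
        return len(channel_labels(self))


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def _sbs96_labels() -> list[str]:
    labels = []
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"):
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


# Ten reference doublets closed under reverse complement.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def _dbs78_labels() -> list[str]:
    labels = []
    for ref in DBS_CANONICAL_REFS:
        alts = set()
        for a0 in BASES:
            for a1 in BASES:
                if a0 == ref[0] or a1 == ref[1]:
                    continue
                alt = a0 + a1
                if revcomp(ref) == ref:
                    # palindromic reference: alt and its revcomp are the
                    # same event read from the two strands
                    alt = min(alt, revcomp(alt))
                alts.add(alt)
        labels.extend(f"{ref}>{alt}" for alt in sorted(alts))
    return labels


def canonical_dbs(ref: str, alt: str) -> tuple[str, str]:
    """Map a doublet substitution onto its canonical strand."""
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if revcomp(ref) == ref:
        alt = min(alt, revcomp(alt))
    return ref, alt


def _id83_labels() -> list[str]:
    labels = []
    for base in ("C", "T"):
        labels.extend(f"1:Del:{base}:{i}" for i in range(6))
    for base in ("C", "T"):
        labels.extend(f"1:Ins:{base}:{i}" for i in range(6))
    for length in (2, 3, 4, 5):
        labels.extend(f"{length}:Del:R:{i}" for i in range(6))
    for length in (2, 3, 4, 5):
        labels.extend(f"{length}:Ins:R:{i}" for i in range(6))
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels.extend(f"{length}:Del:M:{m}" for m in range(1, max_mh + 1))
    return labels


SBS96_LABELS: tuple[str, ...] = tuple(_sbs96_labels())
DBS78_LABELS: tuple[str, ...] = tuple(_dbs78_labels())
ID83_LABELS: tuple[str, ...] = tuple(_id83_labels())

_LABELS = {
    ChannelScheme.SBS96: SBS96_LABELS,
    ChannelScheme.DBS78: DBS78_LABELS,
    ChannelScheme.ID83: ID83_LABELS,
}

_INDEX = {scheme: {lab: i for i, lab in enumerate(labs)} for scheme, labs in _LABELS.items()}


def channel_labels(scheme: ChannelScheme | str) -> tuple[str, ...]:
    """Canonically ordered channel labels for a scheme."""
    return _LABELS[ChannelScheme(scheme)]


def channel_index(scheme: ChannelScheme | str, label: str) -> int:
    return _INDEX[ChannelScheme(scheme)][label]
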