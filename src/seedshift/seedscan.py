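"""Canonical miRNA seed-site discovery in 3'UTR sequences.

A miRNA represses a transcript mainly through Watson-Crick pairing between
its *seed* (miRNA nucleotides 2-7, read 5'->3') and a complementary stretch
in the target 3'UTR.  Four canonical site classes are recognised, in
increasing order of efficacy:

``6mer``
    perfect match to the seed (miRNA positions 2-7);
``7mer-1a``
    6mer plus a literal adenosine in the target opposite miRNA position 1
    (the "A" is recognised directly by Argonaute, not by base pairing);
``7mer-m8``
    6mer plus an additional match to miRNA position 8;
``8mer``
    both extensions at once.

This module derives the four target-strand patterns from a mature miRNA
sequence and enumerates every occurrence in a set of 3'UTRs, reporting each
seed locus once with its strongest class (8mer > 7mer-m8 > 7mer-1a > 6mer).
Coordinates are 1-based inclusive on the given (sense) strand; no
reverse-strand scanning is performed, as 3'UTRs are supplied already
stranded.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AlphabetError",
    "SiteClass",
    "MatureMiRNA",
    "SitePatternSet",
    "UTRRecord",
    "SeedSite",
    "ScanResult",
    "reverse_complement",
    "derive_site_patterns",
    "scan_utr",
    "scan_collection",
    "read_utr_fasta",
    "site_gene_set",
    "MIR_324_5P",
]

#: Mature hsa/mmu-miR-324-5p (miRBase MIMAT0000761); identical in human and
#: mouse.  Provided as a convenience default for this pipeline's motivating
#: use case; any mature miRNA sequence may be supplied instead.
MIR_324_5P = "CGCAUCCCCUAGGGCAUUGGUGU"


class AlphabetError(ValueError):
    """A sequence contains a character outside the nucleotide alphabet."""


class SiteClass(Enum):
    """Canonical seed-match classes, declared weakest to strongest."""

    SIX_MER = "6mer"
    SEVEN_MER_1A = "7mer-1a"
    SEVEN_MER_M8 = "7mer-m8"
    EIGHT_MER = "8mer"

    @property
    def rank(self) -> int:
        """Efficacy rank: 1 (6mer) .. 4 (8mer)."""
        return _RANKS[self]

    @classmethod
    def from_label(cls, label: "SiteClass | str") -> "SiteClass":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown site class {label!r}; expected one of: {valid}") from None

    def __lt__(self, other: "SiteClass") -> bool:
        if not isinstance(other, SiteClass):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "SiteClass") -> bool:
        if not isinstance(other, SiteClass):
            return NotImplemented
        return self.rank <= other.rank

    def __gt__(self, other: "SiteClass") -> bool:
        if not isinstance(other, SiteClass):
            return NotImplemented
        return self.rank > other.rank

    def __ge__(self, other: "SiteClass") -> bool:
        if not isinstance(other, SiteClass):
            return NotImplemented
        return self.rank >= other.rank


_RANKS = {
    SiteClass.SIX_MER: 1,
    SiteClass.SEVEN_MER_1A: 2,
    SiteClass.SEVEN_MER_M8: 3,
    SiteClass.EIGHT_MER: 4,
}

ALL_CLASSES: tuple[SiteClass, ...] = (
    SiteClass.EIGHT_MER,
    SiteClass.SEVEN_MER_M8,
    SiteClass.SEVEN_MER_1A,
    SiteClass.SIX_MER,
)

#: The three "highly seed-complementary" classes usually meant by a
#: canonical site; 6mers are reported only on request (permissive mode).
CANONICAL_CLASSES: tuple[SiteClass, ...] = (
    SiteClass.EIGHT_MER,
    SiteClass.SEVEN_MER_M8,
    SiteClass.SEVEN_MER_1A,
)

_COMPLEMENT_RNA = {"A": "U", "U": "A", "T": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str, output_alphabet: str = "RNA") -> str:
    """Reverse complement of a nucleotide string.

    ``T`` and ``U`` are treated as equivalent on input; the output uses the
    requested alphabet (``"RNA"`` -> U, ``"DNA"`` -> T).  Applying the
    function twice returns the input up to case and U/T normalisation.
    """
    comp = []
    for i, ch in enumerate(seq.upper()):
        c = _COMPLEMENT_RNA.get(ch)
        if c is None:
            raise AlphabetError(
                f"invalid nucleotide {seq[i]!r} at position {i + 1} (1-based)"
            )
        comp.append(c)
    rc = "".join(reversed(comp))
    if output_alphabet.upper() == "DNA":
        return rc.replace("U", "T")
    if output_alphabet.upper() == "RNA":
        return rc
    raise ValueError(f"output_alphabet must be 'RNA' or 'DNA', got {output_alphabet!r}")


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name plus 5'->3' sequence (RNA or DNA letters)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGUT")
        if bad:
            raise AlphabetError(
                f"miRNA {self.name!r}: invalid characters {sorted(bad)} in sequence"
            )
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.name!r}: length {len(seq)} < 8; positions 1-8 must exist"
            )

    @property
    def rna(self) -> str:
        """Uppercased RNA-alphabet sequence."""
        return _normalize_rna(self.sequence)

    @property
    def seed(self) -> str:
        """Positions 2-7 (the seed proper), 5'->3'."""
        return self.rna[1:7]


@dataclass(frozen=True)
class SitePatternSet:
    """Target-strand (5'->3') match patterns for one miRNA's site classes.

    Patterns are stored in the RNA alphabet.  By construction the 8mer is the
    7mer-m8 plus a terminal ``A``, and the 7mer-1a is the 6mer plus a terminal
    ``A``; the 6mer is the 3'-terminal hexamer of the 7mer-m8.
    """

    mirna_name: str
    patterns: Mapping[SiteClass, str]

    def __getitem__(self, site_class: SiteClass | str) -> str:
        return self.patterns[SiteClass.from_label(site_class)]

    def core_offset(self, site_class: SiteClass | str) -> int:
        """Offset of the shared 6mer core within the class pattern."""
        cls = SiteClass.from_label(site_class)
        return 1 if cls in (SiteClass.EIGHT_MER, SiteClass.SEVEN_MER_M8) else 0


def derive_site_patterns(mirna: MatureMiRNA) -> SitePatternSet:
    """Derive the canonical 8mer/7mer-m8/7mer-1a/6mer target patterns.

    6mer = reverse complement of miRNA positions 2-7; 7mer-m8 additionally
    covers position 8; the ``A`` completing the 7mer-1a and 8mer is a literal
    target adenosine (not a complement of miRNA position 1).
    """
    seq = mirna.rna
    six = reverse_complement(seq[1:7], "RNA")
    m8 = reverse_complement(seq[1:8], "RNA")
    return SitePatternSet(
        mirna_name=mirna.name,
        patterns={
            SiteClass.SIX_MER: six,
            SiteClass.SEVEN_MER_1A: six + "A",
            SiteClass.SEVEN_MER_M8: m8,
            SiteClass.EIGHT_MER: m8 + "A",
        },
    )


@dataclass(frozen=True)
class UTRRecord:
    """One 3'UTR sequence, 5'->3', RNA or DNA alphabet (N allowed)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"UTR {self.gene_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGUTN")
        if bad:
            raise AlphabetError(
                f"UTR {self.gene_id!r}: invalid characters {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class SeedSite:
    """One located site: 1-based inclusive coordinates on the sense strand."""

    gene_id: str
    start: int
    end: int
    site_class: SiteClass
    matched_sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """All (possibly overlapping) 0-based match starts of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_utr(
    utr: UTRRecord,
    patterns: SitePatternSet,
    classes: Sequence[SiteClass | str] | None = None,
) -> list[SeedSite]:
    """Locate every requested seed site in one 3'UTR.

    Overlapping matches that share the same 6mer core locus are reported once
    with the strongest requested class (8mer > 7mer-m8 > 7mer-1a > 6mer);
    distinct loci are all reported, sorted by start coordinate.  ``N`` never
    matches.  A site-free UTR yields an empty list.
    """
    requested = ALL_CLASSES if classes is None else tuple(
        SiteClass.from_label(c) for c in classes
    )
    seq_rna = _normalize_rna(utr.sequence)
    seq_orig = utr.sequence.upper()
    # core locus (0-based start of the shared 6mer) -> best (class, match start)
    best: dict[int, tuple[SiteClass, int]] = {}
    for cls in sorted(set(requested), key=lambda c: c.rank, reverse=True):
        pat = patterns[cls]
        off = patterns.core_offset(cls)
        for i in _find_all(seq_rna, pat):
            core = i + off
            if core not in best:
                best[core] = (cls, i)
    sites = []
    for core in sorted(best):
        cls, i = best[core]
        n = len(patterns[cls])
        sites.append(
            SeedSite(
                gene_id=utr.gene_id,
                start=i + 1,
                end=i + n,
                site_class=cls,
                matched_sequence=seq_orig[i : i + n],
            )
        )
    sites.sort(key=lambda s: s.start)
    return sites


def read_utr_fasta(path: Union[str, Path]) -> list[UTRRecord]:
    """Read 3'UTRs from a (possibly gzipped) FASTA; record id = gene symbol."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            records = [
                UTRRecord(gene_id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")
            ]
    except OSError as exc:
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc
    except ValueError as exc:
        raise IOError(f"malformed FASTA {path}: {exc}") from exc
    return records


@dataclass
class ScanResult:
    """Flattened site list plus per-gene site counts by class.

    ``counts`` has one entry per scanned gene (site-free genes map to an
    empty Counter keyed by class label strings).
    """

    mirna_name: str
    sites: list[SeedSite]
    counts: dict[str, Counter] = field(default_factory=dict)

    @property
    def total_sites(self) -> int:
        return len(self.sites)

    def gene_set(self, min_class: SiteClass | str = SiteClass.SEVEN_MER_1A) -> set[str]:
        """Genes with at least one site of class >= ``min_class``."""
        floor = SiteClass.from_label(min_class)
        return {s.gene_id for s in self.sites if s.site_class >= floor}

    def counts_frame(self) -> pd.DataFrame:
        """Per-gene counts as a DataFrame (one column per site class)."""
        cols = [c.value for c in ALL_CLASSES]
        data = {
            g: [cnt.get(c, 0) for c in cols] for g, cnt in sorted(self.counts.items())
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=cols).rename_axis("gene_id")

    def to_bed(self, path: Union[str, Path]) -> None:
        """Write sites as BED-like 6-column TSV.

        Coordinates are 0-based half-open *in this export only* (BED
        convention); everywhere else in the package they are 1-based
        inclusive.  Score column = class rank (6mer=1 .. 8mer=4).
        """
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(
                    f"{s.gene_id}\t{s.start - 1}\t{s.end}\t{s.site_class.value}"
                    f"\t{s.site_class.rank}\t+\n"
                )

    def counts_json(self, path: Union[str, Path]) -> None:
        payload = {
            g: {c: int(n) for c, n in sorted(cnt.items())} for g, cnt in sorted(self.counts.items())
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def scan_collection(
    utrs: Union[str, Path, Iterable[UTRRecord]],
    patterns: SitePatternSet,
    classes: Sequence[SiteClass | str] | None = None,
) -> ScanResult:
    """Scan a FASTA file or an iterable of UTR records.

    Duplicate gene ids have their counts merged (with a warning); gene-level
    sets are the unit of all downstream analysis, so per-record coordinates
    of duplicated ids remain valid but indistinguishable in ``sites``.
    """
    if isinstance(utrs, (str, Path)):
        utrs = read_utr_fasta(utrs)
    sites: list[SeedSite] = []
    counts: dict[str, Counter] = {}
    for rec in utrs:
        if rec.gene_id in counts:
            logger.warning("duplicate FASTA id %r: merging site counts", rec.gene_id)
        rec_sites = scan_utr(rec, patterns, classes)
        sites.extend(rec_sites)
        cnt = counts.setdefault(rec.gene_id, Counter())
        cnt.update(s.site_class.value for s in rec_sites)
    return ScanResult(mirna_name=patterns.mirna_name, sites=sites, counts=counts)


def site_gene_set(
    scan: ScanResult, min_class: SiteClass | str = SiteClass.SEVEN_MER_1A
) -> set[str]:
    """Genes carrying >= 1 site of class >= ``min_class``.

    In-house alternative to an externally downloaded site-containing gene
    list (e.g. from TargetScan).
    """
    return scan.gene_set(min_class)
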