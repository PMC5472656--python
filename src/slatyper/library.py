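"""Allele reference library, nomenclature parsing, and in-silico PCR.

The SLA (swine leukocyte antigen) class I region carries three classical,
peptide-presenting loci: SLA-1, SLA-2 and SLA-3.  Genotyping by amplicon
sequencing rests on a reference library of known coding sequences and a pair
of "universal" primers sitting in conserved stretches of exons 2-4.  This
module loads such a library, extracts the amplicon each primer pair would
produce from each allele (degeneracy-aware, zero-mismatch in-silico PCR) and
summarises how many alleles the amplicon can resolve specifically versus only
to a group of indistinguishable alleles.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCI = ("SLA-1", "SLA-2", "SLA-3")
UNASSIGNED = "unassigned"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_iupac(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


class AlleleNameError(ValueError):
    """Raised for allele labels that cannot be parsed."""


class LibraryError(ValueError):
    """Raised for malformed reference libraries."""


def parse_allele_name(label: str) -> tuple[str, str]:
    """Split an allele label into (locus, designation).

    Both legacy (``SLA-1*0401``) and colon-delimited (``SLA-2*06:14``) forms
    are accepted.  Labels without a ``*`` (e.g. provisional novel-sequence ids
    such as ``NS#7``) and labels with an unknown prefix map to the
    ``unassigned`` locus.
    """
    if not label or not label.strip():
        raise AlleleNameError("empty allele label")
    label = label.strip()
    if "*" not in label:
        return UNASSIGNED, label
    prefix, _, designation = label.partition("*")
    if not prefix or not designation:
        raise AlleleNameError(f"malformed allele label: {label!r}")
    if prefix in LOCI:
        return prefix, designation
    return UNASSIGNED, designation


@dataclass(frozen=True)
class AlleleRecord:
    """One named reference coding sequence."""

    name: str
    sequence: str
    locus: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.sequence:
            raise LibraryError(f"allele {self.name!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise LibraryError(
                f"allele {self.name!r} contains non-ACGT characters: "
                f"{''.join(sorted(bad))}"
            )
        if not self.locus:
            object.__setattr__(self, "locus", parse_allele_name(self.name)[0])

    @property
    def length(self) -> int:
        return len(self.sequence)


class AlleleLibrary:
    """A collection of allele records with an exact-sequence index.

    Two records may share a sequence (alleles only resolvable as a group over
    the amplified region) but never a name.
    """

    def __init__(self, records: Iterable[AlleleRecord]):
        self.records: list[AlleleRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.name in seen:
                raise LibraryError(f"duplicate allele name: {rec.name!r}")
            seen.add(rec.name)
        self.index: dict[str, list[str]] = defaultdict(list)
        for rec in self.records:
            self.index[rec.sequence].append(rec.name)
        self.index = dict(self.index)
        self._by_name = {rec.name: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> AlleleRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.records]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlleleLibrary":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(AlleleRecord(name=rec.description.strip(),
                                        sequence=str(rec.seq).upper()))
        if not records:
            raise LibraryError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(r.sequence), id=r.name, description="")
                for r in self.records]
        SeqIO.write(recs, str(path), "fasta")


def load_library(path: str | Path) -> AlleleLibrary:
    """Load an allele reference library from FASTA (headers are labels)."""
    return AlleleLibrary.from_fasta(path)


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; the reverse primer is given 5'->3' on the
    antisense strand, so its binding site on the sense strand is its reverse
    complement."""

    name: str
    forward: str
    reverse: str
    expected_product_nt: int | None = None

    def __post_init__(self):
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt: {p!r}")
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"{label} primer has non-IUPAC characters: {sorted(bad)}")

    @property
    def reverse_site(self) -> str:
        """Sense-strand binding site of the reverse primer."""
        return revcomp_iupac(self.reverse)


# Published universal SLA class I primer pairs (exon 2 forward; exon 3 or
# exon 4 reverse).  The short pair yields a 320-nt product covering 191 nt of
# exon 2 and 129 nt of exon 3; the long pair extends through exon 3 (510 nt).
SHORT_PRIMERS = PrimerPair("SLA-classI-320", "CGTGGACGACACGCAGTTC",
                           "TCCAGYAGCGCAGGTCCTC", 320)
LONG_PRIMERS = PrimerPair("SLA-classI-510", "CGTGGACGACACGCAGTTC",
                          "AGGTCAGAGCTGGGGRGG", 510)

BUILTIN_PRIMERS = {"short": SHORT_PRIMERS, "long": LONG_PRIMERS}


def iupac_match_at(template: str, pos: int, pattern: str) -> bool:
    """True when the IUPAC ``pattern`` matches ``template`` exactly at ``pos``
    (degenerate positions expand; zero mismatches elsewhere)."""
    if pos < 0 or pos + len(pattern) > len(template):
        return False
    for i, p in enumerate(pattern):
        if template[pos + i] not in IUPAC[p]:
            return False
    return True


def find_site(template: str, pattern: str, start: int = 0) -> int:
    """5'-most exact degeneracy-aware match position of ``pattern`` in
    ``template`` at or after ``start``; -1 when absent."""
    last = len(template) - len(pattern)
    for pos in range(start, last + 1):
        if iupac_match_at(template, pos, pattern):
            return pos
    return -1


@dataclass(frozen=True)
class Amplicon:
    """In-silico PCR product, including the primer-binding regions.

    Coordinates are 1-based inclusive on the source allele.  The ``insert``
    view strips the primer-binding regions: those bases are dictated by the
    primers rather than the template, so clustering and resolvability operate
    on the insert.
    """

    allele_name: str
    sequence: str
    start: int
    end: int
    fwd_len: int
    rev_len: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def insert(self) -> str:
        return self.sequence[self.fwd_len:len(self.sequence) - self.rev_len]


def extract_amplicon(allele: AlleleRecord, primers: PrimerPair) -> Amplicon | None:
    """Simulate PCR of ``allele`` with ``primers``.

    The 5'-most exact match of the forward primer on the sense strand is
    paired with the 5'-most downstream match of the reverse primer's
    sense-strand site.  Returns None when either site is absent (the allele is
    not amplified).
    """
    seq = allele.sequence
    fpos = find_site(seq, primers.forward)
    if fpos < 0:
        return None
    rsite = primers.reverse_site
    rpos = find_site(seq, rsite, fpos + len(primers.forward))
    if rpos < 0:
        return None
    end = rpos + len(rsite)  # exclusive, 0-based
    return Amplicon(
        allele_name=allele.name,
        sequence=seq[fpos:end],
        start=fpos + 1,
        end=end,
        fwd_len=len(primers.forward),
        rev_len=len(rsite),
    )


UNIQUE, GROUP, NOT_AMPLIFIED = "unique", "group", "not_amplified"


@dataclass(frozen=True)
class AlleleResolution:
    allele: str
    status: str
    group_members: tuple[str, ...] = ()
    amplicon_length: int | None = None

    @property
    def group_label(self) -> str:
        return "/".join(self.group_members)


@dataclass
class ResolvabilityReport:
    """How well one primer pair separates the library's alleles.

    Alleles whose amplified inserts are identical form an equivalence class
    ("group-specific allele level"); fractions are percentages over the
    amplified alleles only.
    """

    primer_name: str
    per_allele: dict[str, AlleleResolution]
    fraction_unique: float
    fraction_group: float
    groups: list[tuple[str, ...]]

    @property
    def n_amplified(self) -> int:
        return sum(1 for r in self.per_allele.values()
                   if r.status != NOT_AMPLIFIED)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("allele\tstatus\tgroup_members\tamplicon_length\n")
            for r in self.per_allele.values():
                length = "" if r.amplicon_length is None else r.amplicon_length
                fh.write(f"{r.allele}\t{r.status}\t{r.group_label}\t{length}\n")

    def summary(self) -> dict:
        return {
            "primer_pair": self.primer_name,
            "n_alleles": len(self.per_allele),
            "n_amplified": self.n_amplified,
            "fraction_unique_pct": round(self.fraction_unique, 1),
            "fraction_group_pct": round(self.fraction_group, 1),
            "groups": ["/".join(g) for g in self.groups],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def resolvability(library: AlleleLibrary, primers: PrimerPair) -> ResolvabilityReport:
    """Classify each allele as uniquely resolvable, group-resolvable or not
    amplified, based on insert identity of the in-silico PCR products."""
    if len(library) == 0:
        raise LibraryError("empty allele library")
    inserts: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for rec in library:
        amp = extract_amplicon(rec, primers)
        if amp is not None:
            inserts[rec.name] = amp.insert
            lengths[rec.name] = amp.length
    by_insert: dict[str, list[str]] = defaultdict(list)
    for name, ins in inserts.items():
        by_insert[ins].append(name)

    per_allele: dict[str, AlleleResolution] = {}
    groups: list[tuple[str, ...]] = []
    for ins, members in by_insert.items():
        members = tuple(sorted(members))
        if len(members) > 1:
            groups.append(members)
    groups.sort()
    member_group = {m: g for g in groups for m in g}

    n_unique = 0
    for rec in library:
        name = rec.name
        if name not in inserts:
            per_allele[name] = AlleleResolution(name, NOT_AMPLIFIED)
        elif name in member_group:
            per_allele[name] = AlleleResolution(
                name, GROUP, member_group[name], lengths[name])
        else:
            n_unique += 1
            per_allele[name] = AlleleResolution(
                name, UNIQUE, (name,), lengths[name])

    n_amp = len(inserts)
    fu = 100.0 * n_unique / n_amp if n_amp else 0.0
    fg = 100.0 * (n_amp - n_unique) / n_amp if n_amp else 0.0
    return ResolvabilityReport(primers.name, per_allele, fu, fg, groups)
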