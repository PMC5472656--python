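"""Cluster identification against the allele library and per-sample genotypes.

Each retained cluster is looked up against the library's amplified inserts:
an exact hit to one allele is a *specific* call, an exact hit shared by
several alleles is a *group* call (slash-joined label, counted as one carried
allele), and a near-miss at >= 95% alignment identity is a *novel candidate*
whose closest match and similarity (e.g. "604/605") are recorded.  Anything
below 95% is unclassified.

Cluster read fractions within a sample proxy relative transcription; across
the three classical loci the expected ordering is SLA-2 > SLA-1 >> SLA-3.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import Align

from .library import (AlleleLibrary, LibraryError, PrimerPair, SHORT_PRIMERS,
                      UNASSIGNED, extract_amplicon, parse_allele_name)
from .reads import Cluster, SampleClusterResult

SPECIFIC, GROUP_CALL, NOVEL, UNCLASSIFIED = ("specific", "group",
                                             "novel_candidate", "unclassified")


def _aligner() -> Align.PairwiseAligner:
    # global alignment, unit costs, free end gaps: amplicons share
    # primer-anchored ends, so terminal gaps carry no signal
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = -1
    try:
        a.end_insertion_score = 0
        a.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.86
        a.target_end_gap_score = 0
        a.query_end_gap_score = 0
    return a


def alignment_identity(query: str, target: str,
                       aligner: Align.PairwiseAligner | None = None
                       ) -> tuple[int, int]:
    """(matches, alignment length) of the best global alignment with free end
    gaps; length counts internal gap columns but not terminal gap columns."""
    aligner = aligner or _aligner()
    aln = aligner.align(query, target)[0]
    q, t = aln[0], aln[1]
    n = len(q)
    start = 0
    while start < n and (q[start] == "-" or t[start] == "-"):
        start += 1
    end = n
    while end > start and (q[end - 1] == "-" or t[end - 1] == "-"):
        end -= 1
    matches = sum(1 for i in range(start, end) if q[i] == t[i] and q[i] != "-")
    return matches, end - start


class TypingIndex:
    """Exact-insert lookup plus alignment targets for one library + primer
    pair.  Alleles the primers do not amplify are absent."""

    def __init__(self, library: AlleleLibrary, primers: PrimerPair = SHORT_PRIMERS):
        if len(library) == 0:
            raise LibraryError("empty allele library")
        self.primers = primers
        self.exact: dict[str, tuple[str, ...]] = defaultdict(tuple)
        self.inserts: list[tuple[str, str]] = []
        exact: dict[str, list[str]] = defaultdict(list)
        for rec in library:
            amp = extract_amplicon(rec, primers)
            if amp is None:
                continue
            exact[amp.insert].append(rec.name)
            self.inserts.append((rec.name, amp.insert))
        if not self.inserts:
            raise LibraryError(
                f"no library allele is amplified by {primers.name}")
        self.exact = {seq: tuple(sorted(names)) for seq, names in exact.items()}
        self._aligner = _aligner()


@dataclass
class AlleleCall:
    sample: str
    rank: int
    status: str
    names: tuple[str, ...]                  # 1 for specific, >=2 for group
    similarity: tuple[int, int]             # (matches, alignment length)
    read_count: int
    read_fraction: float = 0.0
    closest_match: str = ""                 # novel candidates only
    sequence: str = ""

    @property
    def label(self) -> str:
        return "/".join(self.names) if self.names else "-"

    @property
    def similarity_str(self) -> str:
        return f"{self.similarity[0]}/{self.similarity[1]}"

    @property
    def locus(self) -> str:
        if self.status in (SPECIFIC, GROUP_CALL):
            loci = {parse_allele_name(n)[0] for n in self.names}
            return loci.pop() if len(loci) == 1 else UNASSIGNED
        return UNASSIGNED


def match_cluster(cluster: Cluster, index: TypingIndex,
                  min_identity: float = 0.95) -> AlleleCall:
    """Identify one cluster: exact insert hit, else best alignment hit."""
    seq = cluster.sequence
    hit = index.exact.get(seq)
    if hit:
        n = len(seq)
        status = SPECIFIC if len(hit) == 1 else GROUP_CALL
        return AlleleCall(cluster.sample, cluster.rank, status, hit, (n, n),
                          cluster.size, sequence=seq)
    best_name, best = "", (-1, 1)
    for name, insert in index.inserts:
        matches, length = alignment_identity(seq, insert, index._aligner)
        if matches * best[1] > best[0] * length:  # higher identity
            best_name, best = name, (matches, length)
    identity = best[0] / best[1]
    if identity >= min_identity:
        return AlleleCall(cluster.sample, cluster.rank, NOVEL, (), best,
                          cluster.size, closest_match=best_name, sequence=seq)
    return AlleleCall(cluster.sample, cluster.rank, UNCLASSIFIED, (), best,
                      cluster.size, closest_match=best_name, sequence=seq)


@dataclass
class NovelSequence:
    ns_id: str
    sequence: str
    total_reads: int
    carriers: tuple[str, ...]
    closest_match: str
    similarity: tuple[int, int]
    low_confidence: bool
    locus: str = UNASSIGNED

    @property
    def similarity_str(self) -> str:
        return f"{self.similarity[0]}/{self.similarity[1]}"


def call_novels(calls: Iterable[AlleleCall]) -> list[NovelSequence]:
    """Group identical novel-candidate sequences across samples into a
    registry with stable ids (NS#1, NS#2, ... by total read support, ties by
    sequence).  A novel carried by a single animal is low-confidence: only
    recurrence across individuals (independent PCRs) argues against a PCR
    artifact."""
    by_seq: dict[str, list[AlleleCall]] = defaultdict(list)
    for call in calls:
        if call.status == NOVEL:
            by_seq[call.sequence].append(call)
    entries = []
    for seq, group in by_seq.items():
        total = sum(c.read_count for c in group)
        carriers = tuple(sorted({c.sample for c in group}))
        entries.append((total, seq, group, carriers))
    entries.sort(key=lambda e: (-e[0], e[1]))
    registry = []
    for i, (total, seq, group, carriers) in enumerate(entries):
        registry.append(NovelSequence(
            ns_id=f"NS#{i + 1}",
            sequence=seq,
            total_reads=total,
            carriers=carriers,
            closest_match=group[0].closest_match,
            similarity=group[0].similarity,
            low_confidence=len(carriers) == 1,
        ))
    return registry


@dataclass
class SampleGenotype:
    sample: str
    calls: list[AlleleCall]
    alleles_per_locus: dict[str, int]
    homozygous_loci: tuple[str, ...]
    duplication_flags: tuple[str, ...]
    locus_fractions: dict[str, float]
    typing_failed: bool = False

    def alleles_by_locus(self) -> dict[str, list[str]]:
        """Locus -> called allele tokens (group calls as single tokens),
        suitable for haplotype inference."""
        out: dict[str, list[str]] = defaultdict(list)
        for call in self.calls:
            token = call.label if call.status != NOVEL else call.sequence
            out[call.locus].append(token)
        return dict(out)


def genotype_sample(sample: str, calls: list[AlleleCall],
                    typing_failed: bool = False) -> SampleGenotype:
    """Summarise one sample: read fractions, homozygosity per locus, locus
    duplications (> 2 called alleles at one locus)."""
    total = sum(c.read_count for c in calls)
    for c in calls:
        c.read_fraction = c.read_count / total if total else 0.0
    per_locus: Counter = Counter(c.locus for c in calls)
    locus_fracs: dict[str, float] = defaultdict(float)
    for c in calls:
        locus_fracs[c.locus] += c.read_fraction
    return SampleGenotype(
        sample=sample,
        calls=calls,
        alleles_per_locus=dict(per_locus),
        homozygous_loci=tuple(sorted(l for l, n in per_locus.items()
                                     if n == 1 and l != UNASSIGNED)),
        duplication_flags=tuple(sorted(l for l, n in per_locus.items()
                                       if n > 2 and l != UNASSIGNED)),
        locus_fractions=dict(locus_fracs),
        typing_failed=typing_failed or not calls,
    )


def genotype_run(sample_results: Mapping[str, SampleClusterResult],
                 library: AlleleLibrary, primers: PrimerPair = SHORT_PRIMERS,
                 min_identity: float = 0.95
                 ) -> tuple[dict[str, SampleGenotype], list[NovelSequence]]:
    """Type every sample's retained clusters and build the novel registry.
    Novel registry loci (once assigned) are not back-propagated here; novel
    calls stay under ``unassigned`` until placed phylogenetically."""
    index = TypingIndex(library, primers)
    genotypes: dict[str, SampleGenotype] = {}
    all_calls: list[AlleleCall] = []
    for sample in sorted(sample_results):
        res = sample_results[sample]
        calls = [match_cluster(c, index, min_identity) for c in res.clusters]
        genotypes[sample] = genotype_sample(sample, calls, res.typing_failed)
        all_calls.extend(calls)
    registry = call_novels(all_calls)
    return genotypes, registry
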