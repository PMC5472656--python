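"""Raw paired FASTQ -> per-sample, filtered clusters of identical inserts.

Stage order follows the typing protocol: demultiplex on exact 6-nt barcodes
plus degeneracy-aware primer prefixes (on both mates), quality-trim read ends
below Q17 (98% base-call accuracy), join mates on the best ungapped overlap
(>= 35 nt, >= 80% identity), dereplicate each sample at 100% sequence
identity, discard clusters under 10 reads, flag PCR chimeras with a
two-parent crossover test, keep the 20 largest non-chimeric clusters, and
finally flag overlong splice-variant artifacts (stop codons in all three
reading frames) and other off-size clusters.

Rejected reads are data, not errors: every stage reports counts so that the
run's loss accounting is conserved exactly.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .library import PrimerPair, iupac_match_at, revcomp

BARCODE_LEN = 6

NO_BARCODE, BARCODE_CONFLICT, NO_PRIMER = ("no_barcode", "barcode_conflict",
                                           "no_primer")

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


@dataclass
class MergedRead:
    sample: str
    sequence: str
    overlap_len: int
    mismatches_in_overlap: int


@dataclass
class Cluster:
    sample: str
    sequence: str
    size: int
    rank: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream paired Phred+33 FASTQ files (gzip allowed)."""

    def opener(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with opener(path1) as f1, opener(path2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            h2 = f2.readline()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            rid = h1[1:].strip().split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            yield ReadPair(
                rid, s1,
                np.frombuffer(q1.encode(), dtype=np.uint8).astype(np.int16) - 33,
                s2,
                np.frombuffer(q2.encode(), dtype=np.uint8).astype(np.int16) - 33,
            )


def phred_from_accuracy(acc: float) -> int:
    """Phred score equivalent to a base-call accuracy, e.g. 0.98 -> Q17."""
    if not 0.0 < acc < 1.0:
        raise ValueError(f"accuracy must be in (0, 1), got {acc}")
    return round(-10.0 * math.log10(1.0 - acc))


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadPair]]
    rejected: Counter
    n_input: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


def demultiplex(pairs: Iterable[ReadPair], barcodes: Mapping[str, str],
                primers: PrimerPair) -> DemuxResult:
    """Assign read pairs to samples by exact barcode + primer prefixes.

    A pair belongs to a sample iff mate 1 starts with the sample barcode
    immediately followed by the forward primer and mate 2 starts with the
    same barcode followed by the reverse primer (degeneracy-aware, zero
    mismatches).  Barcode and primer prefixes are stripped from assigned
    reads.  Rejects are tallied by reason.
    """
    for bc in barcodes.values():
        if len(bc) != BARCODE_LEN:
            raise ValueError(f"barcodes must be {BARCODE_LEN} nt, got {bc!r}")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be distinct")
    sample_of = {bc: s for s, bc in barcodes.items()}
    flen = len(primers.forward)
    rlen = len(primers.reverse)

    result = DemuxResult(by_sample={s: [] for s in barcodes}, rejected=Counter())
    for pair in pairs:
        result.n_input += 1
        b1 = pair.seq1[:BARCODE_LEN]
        b2 = pair.seq2[:BARCODE_LEN]
        s1 = sample_of.get(b1)
        s2 = sample_of.get(b2)
        if s1 is None or s2 is None:
            result.rejected[NO_BARCODE] += 1
            continue
        if s1 != s2:
            result.rejected[BARCODE_CONFLICT] += 1
            continue
        if not (iupac_match_at(pair.seq1, BARCODE_LEN, primers.forward)
                and iupac_match_at(pair.seq2, BARCODE_LEN, primers.reverse)):
            result.rejected[NO_PRIMER] += 1
            continue
        cut1 = BARCODE_LEN + flen
        cut2 = BARCODE_LEN + rlen
        result.by_sample[s1].append(ReadPair(
            pair.id,
            pair.seq1[cut1:], pair.qual1[cut1:],
            pair.seq2[cut2:], pair.qual2[cut2:]))
    return result


def quality_trim(seq: str, quals: np.ndarray, q_min: int = 17
                 ) -> tuple[str, np.ndarray] | None:
    """Remove the maximal low-quality (< q_min) prefix and suffix.

    Interior low-quality bases are retained.  Returns None when nothing
    survives (the read is discarded)."""
    ok = np.asarray(quals) >= q_min
    if not ok.any():
        return None
    first = int(np.argmax(ok))
    last = len(ok) - int(np.argmax(ok[::-1]))
    return seq[first:last], np.asarray(quals)[first:last]


def merge_pairs(seq1: str, qual1: np.ndarray, seq2: str, qual2: np.ndarray,
                min_overlap: int = 35, min_match: float = 0.80
                ) -> MergedRead | None:
    """Join mates on the best ungapped overlap of revcomp(mate 2) vs mate 1.

    Every overlap >= ``min_overlap`` is scored; an overlap is admissible when
    matches/overlap >= ``min_match``.  Among admissible overlaps the highest
    identity wins, ties broken by longer overlap, then smaller shift.  The
    consensus takes the higher-quality base at mismatching positions.
    Returns None (unjoined) when no admissible overlap exists.
    """
    if not seq1 or not seq2:
        return None
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(seq2).encode(), dtype=np.uint8)
    qa = np.asarray(qual1)
    qb = np.asarray(qual2)[::-1]
    L1, L2 = len(a), len(b)
    if min(L1, L2) < min_overlap:
        return None

    # matches(o) for every offset o of b's start relative to a's start,
    # via per-base cross-correlation (exact integer counts)
    m = np.zeros(L1 + L2 - 1)
    for base in (65, 67, 71, 84):
        m += np.correlate((a == base).astype(np.float64),
                          (b == base).astype(np.float64), mode="full")
    offsets = np.arange(-(L2 - 1), L1)
    matches = np.rint(m).astype(np.int64)
    overlap = np.minimum(L1, offsets + L2) - np.maximum(0, offsets)

    valid = overlap >= min_overlap
    if not valid.any():
        return None
    identity = np.where(valid, matches / np.maximum(overlap, 1), -1.0)
    admissible = valid & (identity >= min_match)
    if not admissible.any():
        return None
    idx = np.nonzero(admissible)[0]
    # best identity; ties -> longer overlap -> smaller |offset| -> smaller offset
    order = sorted(idx, key=lambda i: (-identity[i], -overlap[i],
                                       abs(int(offsets[i])), int(offsets[i])))
    best = order[0]
    o = int(offsets[best])
    ov = int(overlap[best])
    n_mismatch = ov - int(matches[best])

    start = min(0, o)
    end = max(L1, o + L2)
    out = np.empty(end - start, dtype=np.uint8)
    pos = np.arange(start, end)
    in_a = (pos >= 0) & (pos < L1)
    in_b = (pos >= o) & (pos < o + L2)
    out[in_a] = a[pos[in_a]]
    only_b = in_b & ~in_a
    out[only_b] = b[pos[only_b] - o]
    both = in_a & in_b
    if n_mismatch:
        pa = pos[both]
        amask = a[pa] != b[pa - o]
        mm = pa[amask]
        use_b = qb[mm - o] > qa[mm]
        out[np.searchsorted(pos, mm[use_b])] = b[mm[use_b] - o]
    return MergedRead("", out.tobytes().decode(), ov, n_mismatch)


def dereplicate(merged: Iterable[MergedRead | str], sample: str = ""
                ) -> list[Cluster]:
    """Group reads into clusters of 100% identical sequences, sorted by size
    descending (ties by sequence) with 1-based ranks."""
    counts: Counter = Counter()
    for item in merged:
        seq = item if isinstance(item, str) else item.sequence
        counts[seq] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [Cluster(sample, seq, size, rank=i + 1)
            for i, (seq, size) in enumerate(ordered)]


def size_filter(clusters: list[Cluster], min_reads: int = 10,
                max_clusters: int | None = 20) -> list[Cluster]:
    """Drop clusters with fewer than ``min_reads`` reads (strictly less) and
    cap the retained list at ``max_clusters`` by rank."""
    kept = [c for c in clusters if c.size >= min_reads]
    kept.sort(key=lambda c: c.rank)
    if max_clusters is not None:
        kept = kept[:max_clusters]
    return kept


CHIMERA, SPLICE_VARIANT, OFF_SIZE = "chimera", "splice_variant", "off_size"


def detect_chimeras(clusters: list[Cluster], min_fold: float = 2.0,
                    min_diagnostic: int = 3) -> list[Cluster]:
    """Flag clusters fully explained as a two-parent, single-crossover model.

    For each candidate, every ordered pair of same-length clusters at least
    ``min_fold`` times its size is considered as (left parent, right parent).
    The candidate is a chimera iff some crossover reproduces it exactly
    (100% model identity, possible because dereplication is at 100%
    identity), neither parent alone is identical to it, and each side carries
    at least ``min_diagnostic`` positions diagnostic of its parent.
    """
    for cand in clusters:
        parents = [p for p in clusters
                   if p is not cand and p.size >= min_fold * cand.size
                   and p.length == cand.length]
        if _is_chimera(cand.sequence, parents, min_diagnostic):
            cand.flags.add(CHIMERA)
    return clusters


def _is_chimera(seq: str, parents: list[Cluster], min_diagnostic: int) -> bool:
    L = len(seq)
    c = np.frombuffer(seq.encode(), dtype=np.uint8)
    arrs = [(p, np.frombuffer(p.sequence.encode(), dtype=np.uint8))
            for p in parents]
    for pa, a in arrs:
        if pa.sequence == seq:
            continue
        # longest prefix of seq matching parent A
        diff_a = np.nonzero(a != c)[0]
        pref_a = int(diff_a[0]) if diff_a.size else L
        for pb, b in arrs:
            if pb is pa or pb.sequence == seq:
                continue
            diff_b = np.nonzero(b != c)[0]
            suf_b = L - (int(diff_b[-1]) + 1) if diff_b.size else L
            # a crossover k must satisfy L - suf_b <= k <= pref_a
            lo, hi = L - suf_b, pref_a
            if lo > hi:
                continue
            dab = np.nonzero(a != b)[0]
            # diagnostic sites: positions where the parents differ; the left
            # side matches A, the right side matches B (model is exact)
            n_left = np.searchsorted(dab, np.arange(lo, hi + 1), side="left")
            n_right = dab.size - n_left
            if np.any((n_left >= min_diagnostic) & (n_right >= min_diagnostic)):
                return True
    return False


def has_stops_in_all_frames(seq: str) -> bool:
    for frame in range(3):
        codons = (seq[i:i + 3] for i in range(frame, len(seq) - 2, 3))
        if not any(c in STOP_CODONS for c in codons):
            return False
    return True


def artifact_filter(clusters: list[Cluster], expected_len: int,
                    tol: int = 15) -> list[Cluster]:
    """Flag off-length clusters.

    Clusters within ``tol`` nt of the expected insert length pass.  Longer
    clusters with a stop codon in all three sense reading frames are
    alternative-splicing artifacts (``splice_variant``, removed from typing);
    other off-length clusters are ``off_size`` — excluded from typing but
    reported, so a sample dominated by them can be called typing-failed.
    """
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    for c in clusters:
        if abs(c.length - expected_len) <= tol:
            continue
        if c.length > expected_len + tol and has_stops_in_all_frames(c.sequence):
            c.flags.add(SPLICE_VARIANT)
        else:
            c.flags.add(OFF_SIZE)
    return clusters


@dataclass
class SampleClusterResult:
    sample: str
    clusters: list[Cluster]              # retained, typed clusters
    removed: dict[str, list[Cluster]]    # reason -> clusters
    n_merged: int = 0
    n_unjoined: int = 0
    n_trim_discarded: int = 0
    typing_failed: bool = False

    @property
    def retained_reads(self) -> int:
        return sum(c.size for c in self.clusters)

    def dominant(self, min_fraction: float = 0.05) -> list[Cluster]:
        total = self.retained_reads
        if total == 0:
            return []
        return [c for c in self.clusters if c.size / total >= min_fraction]


@dataclass
class PipelineStats:
    n_input: int = 0
    n_assigned: int = 0
    rejected: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input_pairs": self.n_input,
            "demultiplex": {"assigned": self.n_assigned,
                            "rejected": dict(self.rejected)},
            "per_sample": self.per_sample,
        }


def process_sample(sample: str, pairs: list[ReadPair], *,
                   expected_len: int, q_min: int = 17, min_overlap: int = 35,
                   min_match: float = 0.80, min_reads: int = 10,
                   max_clusters: int = 20, length_tol: int = 15,
                   dominant_fraction: float = 0.05) -> SampleClusterResult:
    """Trim, merge, dereplicate and filter one demultiplexed sample."""
    merged: list[MergedRead] = []
    n_unjoined = n_trim_discarded = 0
    for pair in pairs:
        t1 = quality_trim(pair.seq1, pair.qual1, q_min)
        t2 = quality_trim(pair.seq2, pair.qual2, q_min)
        if t1 is None or t2 is None:
            n_trim_discarded += 1
            continue
        m = merge_pairs(t1[0], t1[1], t2[0], t2[1], min_overlap, min_match)
        if m is None:
            n_unjoined += 1
            continue
        m.sample = sample
        merged.append(m)

    clusters = dereplicate(merged, sample)
    removed: dict[str, list[Cluster]] = defaultdict(list)
    removed["below_min_reads"] = [c for c in clusters if c.size < min_reads]
    clusters = size_filter(clusters, min_reads, max_clusters=None)
    clusters = detect_chimeras(clusters)
    removed[CHIMERA] = [c for c in clusters if CHIMERA in c.flags]
    clusters = [c for c in clusters if CHIMERA not in c.flags]
    clusters = size_filter(clusters, min_reads=0, max_clusters=max_clusters)
    clusters = artifact_filter(clusters, expected_len, length_tol)
    removed[SPLICE_VARIANT] = [c for c in clusters if SPLICE_VARIANT in c.flags]
    removed[OFF_SIZE] = [c for c in clusters if OFF_SIZE in c.flags]
    retained = [c for c in clusters if not c.flags]

    result = SampleClusterResult(
        sample=sample, clusters=retained, removed=dict(removed),
        n_merged=len(merged), n_unjoined=n_unjoined,
        n_trim_discarded=n_trim_discarded)
    # a sample whose dominant signal is entirely off-size failed typing
    # (e.g. a mis-sized product from poor primer specificity)
    off = removed[OFF_SIZE]
    if not retained:
        result.typing_failed = True
    elif off:
        total = sum(c.size for c in retained) + sum(c.size for c in off)
        off_sizes = sum(c.size for c in off)
        if off_sizes / total >= 0.5:
            result.typing_failed = True
    return result


def run_read_pipeline(pairs: Iterable[ReadPair], barcodes: Mapping[str, str],
                      primers: PrimerPair, *, expected_len: int,
                      q_min: int = 17, min_overlap: int = 35,
                      min_match: float = 0.80, min_reads: int = 10,
                      max_clusters: int = 20, length_tol: int = 15,
                      dominant_fraction: float = 0.05
                      ) -> tuple[dict[str, SampleClusterResult], PipelineStats]:
    """Full pipeline: demultiplex then per-sample processing, with loss
    accounting at every stage."""
    demux = demultiplex(pairs, barcodes, primers)
    stats = PipelineStats(n_input=demux.n_input, n_assigned=demux.n_assigned,
                          rejected=dict(demux.rejected))
    results: dict[str, SampleClusterResult] = {}
    for sample in sorted(demux.by_sample):
        res = process_sample(
            sample, demux.by_sample[sample], expected_len=expected_len,
            q_min=q_min, min_overlap=min_overlap, min_match=min_match,
            min_reads=min_reads, max_clusters=max_clusters,
            length_tol=length_tol, dominant_fraction=dominant_fraction)
        results[sample] = res
        stats.per_sample[sample] = {
            "input_pairs": len(demux.by_sample[sample]),
            "trim_discarded": res.n_trim_discarded,
            "unjoined": res.n_unjoined,
            "merged": res.n_merged,
            "clusters_retained": len(res.clusters),
            "retained_reads": res.retained_reads,
            "removed": {k: len(v) for k, v in res.removed.items()},
            "typing_failed": res.typing_failed,
        }
    return results, stats
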