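"""Synthetic amplicon sequencing data with ground truth.

Generates fixture allele libraries whose sequences carry the published
universal primer sites verbatim, builds haplotypes over them, and emits
barcoded paired-end reads with the statistical structure the downstream
pipeline assumes:

* read 1 = sample barcode + forward primer + insert prefix,
  read 2 = sample barcode + reverse primer + reverse-complemented insert
  prefix (both mates of a pair carry the same 6-nt barcode);
* per-allele depth scaled by locus-specific transcription weights
  (default SLA-2 > SLA-1 >> SLA-3);
* per-cycle Phred quality declining linearly toward the read ends, with
  substitution errors modulated by the realized quality;
* PCR chimeras (single crossover between two templates of the same sample),
  barcode-free spike-in pairs (emulating the PhiX fraction added for
  sequence diversity), and overlong splice-variant templates carrying stop
  codons in all three reading frames.

Everything is driven by a single seeded generator; the ground-truth table
reconciles exactly with the emitted read counts.
"""

from __future__ import annotations

import dataclasses
import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .haplotypes import Haplotype
from .library import (AlleleLibrary, AlleleRecord, PrimerPair, SHORT_PRIMERS,
                      extract_amplicon, revcomp)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 4-nt period puts a TAA stop in every reading frame
_SPLICE_JUNK_UNIT = "TAAA"


@dataclass
class FixturePool:
    """A self-consistent synthetic reference: library, haplotypes, primers
    and sample barcodes (pairwise Hamming distance >= 2)."""

    library: AlleleLibrary
    haplotypes: dict[str, Haplotype]
    primers: PrimerPair
    barcodes: dict[str, str]

    def genotype_alleles(self, hap_ids: tuple[str, str]) -> list[str]:
        """Distinct allele names carried by a (possibly homozygous) genotype."""
        names: list[str] = []
        for hid in hap_ids:
            for _, locus_names in self.haplotypes[hid].alleles:
                names.extend(locus_names)
        return sorted(set(names))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def _barcodes(rng: np.random.Generator, n: int, length: int = 6) -> list[str]:
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= 2 for bc in out):
            out.append(cand)
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place pairwise-distant barcodes")
    return out


def make_fixture_library(
    n_alleles_per_locus: int = 4,
    divergence: int = 6,
    seed: int = 42,
    insert_len: int = 282,
    n_samples: int = 6,
    locus_divergence: int = 40,
    primers: PrimerPair = SHORT_PRIMERS,
) -> FixturePool:
    """Build a synthetic allele library amplifiable by the real primers.

    Alleles at each locus are derived from a per-locus ancestral insert by
    ``divergence`` random substitutions, with between-locus divergence
    (``locus_divergence`` substitutions from a common base) far exceeding the
    within-locus spread, as for the real loci.  All inserts are pairwise
    distinct.  Haplotypes carry one allele per locus, sampled without
    replacement.
    """
    if n_alleles_per_locus < 1:
        raise ValueError("need at least one allele per locus")
    if divergence < 1:
        raise ValueError("divergence must be >= 1")
    if not 0 < divergence <= insert_len:
        raise ValueError("divergence exceeds insert length")
    rng = np.random.default_rng(seed)
    # a fixed realization of the (degenerate) primer sites embedded in templates
    fwd_site = primers.forward.replace("Y", "C").replace("R", "A")
    rev_site = revcomp(primers.reverse.replace("Y", "T").replace("R", "G"))

    base = _random_seq(rng, insert_len)
    records: list[AlleleRecord] = []
    inserts_seen: set[str] = set()
    per_locus_names: dict[str, list[str]] = {}
    for li, locus in enumerate(("SLA-1", "SLA-2", "SLA-3")):
        ancestor = _mutate(rng, base, locus_divergence)
        names: list[str] = []
        for ai in range(n_alleles_per_locus):
            for _ in range(200):
                ins = _mutate(rng, ancestor, divergence)
                if ins not in inserts_seen and fwd_site not in ins \
                        and rev_site not in ins:
                    break
            else:
                raise ValueError(
                    "requested alleles exceed distinct-sequence capacity")
            inserts_seen.add(ins)
            name = f"{locus}*{ai + 1:02d}:01"
            flank5 = _random_seq(rng, 20)
            flank3 = _random_seq(rng, 20)
            records.append(AlleleRecord(
                name=name,
                sequence=flank5 + fwd_site + ins + rev_site + flank3))
            names.append(name)
        per_locus_names[locus] = names

    library = AlleleLibrary(records)
    haplotypes: dict[str, Haplotype] = {}
    order = {locus: rng.permutation(n_alleles_per_locus)
             for locus in per_locus_names}
    for h in range(n_alleles_per_locus):
        hid = f"HpSim-{h + 1}"
        alleles = {locus: [per_locus_names[locus][order[locus][h]]]
                   for locus in per_locus_names}
        haplotypes[hid] = Haplotype.from_dict(hid, alleles)

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    barcodes = dict(zip(samples, _barcodes(rng, n_samples)))
    return FixturePool(library, haplotypes, primers, barcodes)


@dataclass
class SimConfig:
    """Study conditions for a simulated sequencing run."""

    genotypes: dict[str, tuple[str, str]]
    depth_per_allele: int = 2000
    locus_weights: dict[str, float] = field(
        default_factory=lambda: {"SLA-1": 1.0, "SLA-2": 1.5, "SLA-3": 0.3})
    error_rate: float = 0.001
    q_start: float = 37.0
    q_end: float = 22.0
    q_jitter: float = 3.0
    chimera_rate: float = 0.02
    spikein_fraction: float = 0.30
    splice_variant_rate: float = 0.01
    read_length: int = 250
    seed: int = 42

    def __post_init__(self):
        for name in ("error_rate", "chimera_rate", "spikein_fraction",
                     "splice_variant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_allele < 1:
            raise ValueError("depth_per_allele must be >= 1")
        if any(w <= 0 for w in self.locus_weights.values()):
            raise ValueError("locus weights must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["genotypes"] = {s: list(g) for s, g in d["genotypes"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genotypes"] = {s: tuple(g) for s, g in d["genotypes"].items()}
        return cls(**d)


@dataclass
class SimRead:
    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


@dataclass
class SimTruth:
    """Ground truth for recovery tests; counts reconcile with emitted reads."""

    allele_counts: dict[str, Counter]      # sample -> allele -> clean pairs
    chimera_counts: dict[str, int]
    splice_counts: dict[str, int]
    chimera_parents: dict[str, Counter]    # sample -> (parentA, parentB) -> n
    spikein_count: int = 0
    total_pairs: int = 0

    def sample_total(self, sample: str) -> int:
        return (sum(self.allele_counts[sample].values())
                + self.chimera_counts[sample] + self.splice_counts[sample])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tallele\tclean_pairs\tchimera_pairs\tsplice_pairs\n")
            for sample in sorted(self.allele_counts):
                for allele, n in sorted(self.allele_counts[sample].items()):
                    fh.write(f"{sample}\t{allele}\t{n}\t\t\n")
                fh.write(f"{sample}\t*\t\t{self.chimera_counts[sample]}\t"
                         f"{self.splice_counts[sample]}\n")
            fh.write(f"*\tspikein\t{self.spikein_count}\t\t\n")


def _quality_profile(cfg: SimConfig, length: int) -> np.ndarray:
    return np.linspace(cfg.q_start, cfg.q_end, length)


def _error_scale(cfg: SimConfig) -> float:
    """Scale factor so the profile's mean per-base error equals error_rate."""
    prof = _quality_profile(cfg, cfg.read_length)
    mean_err = float(np.mean(10.0 ** (-prof / 10.0)))
    return cfg.error_rate / mean_err if mean_err > 0 else 0.0


def _emit_batch(rng: np.random.Generator, cfg: SimConfig, scale: float,
                template: str, n: int) -> list[tuple[str, np.ndarray, str, np.ndarray]]:
    """n read pairs from one template string, with quality-modulated errors."""
    out = []
    s1 = np.frombuffer(template.encode(), dtype=np.uint8)[:cfg.read_length]
    s2 = np.frombuffer(revcomp(template).encode(), dtype=np.uint8)[:cfg.read_length]
    for mate in (s1, s2):
        L = len(mate)
        prof = _quality_profile(cfg, cfg.read_length)[:L]
        quals = np.clip(np.rint(prof + rng.normal(0.0, cfg.q_jitter, (n, L))),
                        2, 40).astype(np.int8)
        perr = np.clip(scale * 10.0 ** (-quals / 10.0), 0.0, 0.75)
        errs = rng.random((n, L)) < perr
        seqs = np.tile(mate, (n, 1))
        if errs.any():
            idx = np.nonzero(errs)
            shift = rng.integers(1, 4, size=len(idx[0]))
            # rotate within ACGT so the substituted base always differs
            cur = np.searchsorted(_BASES, seqs[idx])
            seqs[idx] = _BASES[(cur + shift) % 4]
        out.append((seqs, quals))
    (seq1s, qual1s), (seq2s, qual2s) = out
    return [(seq1s[i].tobytes().decode(), qual1s[i],
             seq2s[i].tobytes().decode(), qual2s[i]) for i in range(n)]


def simulate_reads(pool: FixturePool, cfg: SimConfig
                   ) -> tuple[list[SimRead], SimTruth]:
    """Emit barcoded paired-end reads for every sample in ``cfg.genotypes``."""
    primer_len = len(pool.primers.forward)
    if cfg.read_length < 6 + primer_len + 35:
        raise ValueError(
            "read_length shorter than barcode + primer + 35 nt; "
            "pairs would be unmergeable by construction")
    rng = np.random.default_rng(cfg.seed)
    scale = _error_scale(cfg)

    amplicons: dict[str, str] = {}
    for rec in pool.library:
        amp = extract_amplicon(rec, pool.primers)
        if amp is not None:
            amplicons[rec.name] = amp.sequence

    locus_of = {rec.name: rec.locus for rec in pool.library}
    reads: list[SimRead] = []
    truth = SimTruth(allele_counts={}, chimera_counts={}, splice_counts={},
                     chimera_parents={})
    rid = 0

    def splice_template(allele: str) -> str:
        amp = amplicons[allele]
        ins = amp[primer_len:len(amp) - primer_len]
        junk = _SPLICE_JUNK_UNIT * 30  # 120 nt, frame-breaking
        mid = len(ins) // 2
        ins2 = ins[:mid] + junk + ins[mid:]
        return amp[:primer_len] + ins2 + amp[len(amp) - primer_len:]

    for sample in sorted(cfg.genotypes):
        hap_pair = cfg.genotypes[sample]
        for hid in hap_pair:
            if hid not in pool.haplotypes:
                raise ValueError(f"unknown haplotype {hid!r} for sample {sample}")
        bc = pool.barcodes[sample]
        alleles = pool.genotype_alleles(hap_pair)
        truth.allele_counts[sample] = Counter()
        truth.chimera_counts[sample] = 0
        truth.splice_counts[sample] = 0
        truth.chimera_parents[sample] = Counter()
        for allele in alleles:
            if allele not in amplicons:
                raise ValueError(f"allele {allele} is not amplified by "
                                 f"{pool.primers.name}")
            weight = cfg.locus_weights.get(locus_of[allele], 1.0)
            n = int(round(cfg.depth_per_allele * weight))
            u = rng.random(n)
            n_splice = int(np.sum(u < cfg.splice_variant_rate))
            can_chimerize = len(alleles) >= 2
            n_chim = int(np.sum(
                (u >= cfg.splice_variant_rate)
                & (u < cfg.splice_variant_rate + cfg.chimera_rate))) \
                if can_chimerize else 0
            n_clean = n - n_splice - n_chim

            batches: list[tuple[str, int, str | None]] = []
            if n_clean:
                batches.append((amplicons[allele], n_clean, None))
            if n_splice:
                batches.append((splice_template(allele), n_splice, "splice"))
            for template, count, label in batches:
                # the same sample barcode tags both primers, so it appears at
                # the 5' end of the sense strand and (reverse-complemented)
                # at its 3' end; both mates then start with barcode + primer
                for (s1, q1, s2, q2) in _emit_batch(
                        rng, cfg, scale, bc + template + revcomp(bc), count):
                    rid += 1
                    reads.append(SimRead(f"read{rid:07d}", s1, q1, s2, q2))
                if label == "splice":
                    truth.splice_counts[sample] += count
                else:
                    truth.allele_counts[sample][allele] += count
            # chimeras: single crossover, this allele as the left parent
            for _ in range(n_chim):
                others = [a for a in alleles if a != allele]
                other = others[rng.integers(len(others))]
                ins_a = amplicons[allele][primer_len:-primer_len]
                ins_b = amplicons[other][primer_len:-primer_len]
                L = min(len(ins_a), len(ins_b))
                k = int(rng.integers(40, L - 40 + 1))
                chim_ins = ins_a[:k] + ins_b[k:len(ins_b)]
                template = (amplicons[allele][:primer_len] + chim_ins
                            + amplicons[other][-primer_len:])
                (s1, q1, s2, q2), = _emit_batch(
                    rng, cfg, scale, bc + template + revcomp(bc), 1)
                rid += 1
                reads.append(SimRead(f"read{rid:07d}", s1, q1, s2, q2))
                truth.chimera_counts[sample] += 1
                truth.chimera_parents[sample][(allele, other)] += 1

    # barcode-free spike-in contaminants (random sequence)
    n_real = len(reads)
    if cfg.spikein_fraction > 0 and n_real:
        planned = int(round(n_real / (1.0 - cfg.spikein_fraction)))
        n_spike = int(rng.binomial(planned, cfg.spikein_fraction))
        prof = _quality_profile(cfg, cfg.read_length)
        for _ in range(n_spike):
            rid += 1
            s1 = _random_seq(rng, cfg.read_length)
            s2 = _random_seq(rng, cfg.read_length)
            q1 = np.clip(np.rint(prof + rng.normal(0, cfg.q_jitter,
                                                   cfg.read_length)),
                         2, 40).astype(np.int8)
            q2 = np.clip(np.rint(prof + rng.normal(0, cfg.q_jitter,
                                                   cfg.read_length)),
                         2, 40).astype(np.int8)
            reads.append(SimRead(f"read{rid:07d}", s1, q1, s2, q2))
        truth.spikein_count = n_spike

    truth.total_pairs = len(reads)
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return reads, truth


def _open_maybe_gz(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: list[SimRead], path1: str | Path, path2: str | Path) -> None:
    """Write read pairs as Phred+33 FASTQ (gzip when the suffix is .gz)."""
    with _open_maybe_gz(Path(path1), "wt") as f1, \
            _open_maybe_gz(Path(path2), "wt") as f2:
        for r in reads:
            f1.write(f"@{r.id}/1\n{r.seq1}\n+\n"
                     f"{''.join(chr(q + 33) for q in r.qual1)}\n")
            f2.write(f"@{r.id}/2\n{r.seq2}\n+\n"
                     f"{''.join(chr(q + 33) for q in r.qual2)}\n")


def write_fixture(pool: FixturePool, cfg: SimConfig, out_dir: str | Path,
                  gz: bool = False) -> dict[str, Path]:
    """Write library FASTA, barcode TSV, paired FASTQ, truth TSV and the
    config YAML; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": out / "library.fasta",
        "barcodes": out / "barcodes.tsv",
        "fastq1": out / ("reads_R1.fastq.gz" if gz else "reads_R1.fastq"),
        "fastq2": out / ("reads_R2.fastq.gz" if gz else "reads_R2.fastq"),
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
        "haplotypes": out / "true_haplotypes.tsv",
    }
    pool.library.to_fasta(paths["library"])
    with open(paths["barcodes"], "w") as fh:
        fh.write("sample\tbarcode\n")
        for sample, bc in sorted(pool.barcodes.items()):
            fh.write(f"{sample}\t{bc}\n")
    reads, truth = simulate_reads(pool, cfg)
    write_fastq(reads, paths["fastq1"], paths["fastq2"])
    truth.to_tsv(paths["truth"])
    cfg.to_yaml(paths["config"])
    with open(paths["haplotypes"], "w") as fh:
        fh.write("haplotype\tlocus\talleles\n")
        for hid, hap in sorted(pool.haplotypes.items()):
            for locus, names in hap.alleles:
                fh.write(f"{hid}\t{locus}\t{','.join(names)}\n")
    return paths
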