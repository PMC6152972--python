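"""Synthetic small-RNA datasets with known ground truth.

Generates genomes carrying planted pre-miRNA hairpins and simulates
male/female small-RNA libraries with the statistical structure the analysis
pipeline assumes: a read-length distribution peaked at 22 nt, a 5'-U bias of
mature strands, controlled arm-usage ratios, star-strand read fractions,
5'-end jitter, sex-biased abundances, clustered loci at exact genomic
distances, and mutated homologous loci in sister genomes. Every planted
feature is recorded in a truth table so downstream stages can be scored as
parameter-recovery problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .seqcore import (dna_to_rna, duplex_geometry, fold, reverse_complement,
                      reverse_complement_rna, rna_to_dna)

BASES = np.array(list("ACGT"))

DEFAULT_LENGTH_DIST = {20: 0.05, 21: 0.20, 22: 0.50, 23: 0.20, 24: 0.05}
DEFAULT_JITTER = {-2: 0.02, -1: 0.05, 0: 0.86, 1: 0.05, 2: 0.02}
DEFAULT_STAR_JITTER = {-2: 0.05, -1: 0.12, 0: 0.66, 1: 0.12, 2: 0.05}
DEFAULT_LIBRARIES = [
    ("male_1", "male", 20_000), ("male_2", "male", 20_000),
    ("male_3", "male", 20_000),
    ("female_1", "female", 20_000), ("female_2", "female", 20_000),
    ("female_3", "female", 20_000),
]


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    ``arm_bias`` is the fraction of a locus's reads coming from its mature
    (dominant) arm; ``star_fraction`` is the equivalent star/mature read
    ratio. The two parameterize the same split — when ``arm_bias`` is None
    it is derived as 1/(1+star_fraction). ``n_biased_loci`` loci receive a
    sex-biased log2 fold change of ±``lfc_magnitude`` (alternating female/
    male direction); ``lfc_sd`` adds Gaussian spread on top of every locus's
    planted log2 fold change.
    """

    genome_length: int = 100_000
    n_loci: int = 30
    n_clustered_pairs: int = 2
    cluster_gap_bp: tuple[int, ...] = (73, 920)
    mature_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    u5_bias: float = 0.7
    arm_bias: float | None = None
    star_fraction: float = 0.1
    five_prime_jitter: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_JITTER))
    star_five_prime_jitter: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STAR_JITTER))
    libraries: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(DEFAULT_LIBRARIES))
    lfc_magnitude: float = 2.0
    lfc_sd: float = 0.0
    n_biased_loci: int = 10
    homolog_mutation_rate: float = 0.02
    loop_len: int = 8
    star_overhang: int = 2
    n_mismatches: int = 2  # duplex mismatches per planted hairpin
    decoy_fraction: float = 0.10
    reference_decoy_fraction: float = 0.5
    substitution_error_rate: float = 0.0
    rng_seed: int = 0

    def effective_arm_bias(self) -> float:
        if self.arm_bias is not None:
            return self.arm_bias
        return 1.0 / (1.0 + self.star_fraction)

    def validate(self) -> list[str]:
        errors = []
        for name, dist in (("mature_length_dist", self.mature_length_dist),
                           ("five_prime_jitter", self.five_prime_jitter),
                           ("star_five_prime_jitter", self.star_five_prime_jitter)):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                errors.append(f"{name} probabilities must sum to 1")
        if any(not 18 <= l <= 30 for l in self.mature_length_dist):
            errors.append("mature lengths must lie in [18, 30]")
        if any(depth <= 0 for _, _, depth in self.libraries):
            errors.append("library depths must be positive")
        b = self.effective_arm_bias()
        if not 0.5 < b <= 1.0:
            errors.append("arm_bias must lie in (0.5, 1.0]")
        # each locus needs precursor (<70 nt) plus spacing; clusters need gaps
        needed = self.n_loci * 300 + sum(self.cluster_gap_bp[:self.n_clustered_pairs])
        if self.genome_length < needed:
            errors.append(
                f"genome_length {self.genome_length} too small for "
                f"{self.n_loci} loci (need >= {needed})")
        if not 0 <= self.star_overhang <= 3:
            errors.append("star_overhang must lie in [0, 3]")
        return errors


# ---------------------------------------------------------------------------
# Hairpin construction
# ---------------------------------------------------------------------------

@dataclass
class Hairpin:
    """A constructed precursor with known duplex coordinates (local, 0-based
    half-open on the precursor)."""

    precursor: str  # RNA
    mature: tuple[int, int]
    star: tuple[int, int]
    loop: tuple[int, int]
    mature_arm: str  # "5p" or "3p"


def _nonpairing_fill(context: str, size: int) -> str:
    """A homo-run that cannot base-pair (not even G:U) with ``context``."""
    if "U" not in context and "T" not in context:
        return "A" * size
    if "G" not in context:
        return "C" * size
    return "A" * size


def build_hairpin(mature_seq: str, loop_len: int = 8,
                  bulges: list[tuple[str, int, int]] | None = None,
                  star_overhang: int = 2,
                  mature_arm: str = "5p",
                  mismatches: list[int] | None = None) -> Hairpin:
    """Construct a pre-miRNA whose mature/star duplex has exactly the
    requested bulges and mismatches.

    ``bulges`` entries are (arm, offset, size): arm "star" inserts ``size``
    unpairable nucleotides into the star strand facing mature position
    ``offset``; arm "mature" deletes the star bases facing
    mature[offset:offset+size], leaving those mature positions bulged.
    ``mismatches`` lists mature offsets whose facing star base is replaced
    with a non-pairing base (real precursors are never perfectly
    complementary, and the mismatches keep mature reads from mapping onto
    the star arm). The star strand carries a ``star_overhang``-nt 3'
    extension beyond the duplex (the canonical Drosha/Dicer signature).
    """
    mature = dna_to_rna(mature_seq.upper())
    if not 18 <= len(mature) <= 30:
        raise ValueError(f"mature length {len(mature)} outside [18, 30]")
    if loop_len < 3:
        raise ValueError("loop_len < 3 is sterically impossible for a hairpin")
    if mature_arm not in ("5p", "3p"):
        raise ValueError("mature_arm must be '5p' or '3p'")
    L = len(mature)
    # star core pairs the mature: star[i] faces mature[L-1-i]
    star = list(reverse_complement(mature))
    for offset in (mismatches or []):
        if not 0 <= offset < L:
            raise ValueError(f"mismatch offset {offset} outside the mature arm")
        star[L - 1 - offset] = mature[offset]  # same base never pairs itself
    for arm, offset, size in (bulges or []):
        if size < 0:
            raise ValueError("bulge size must be >= 0")
        if not 0 <= offset < L:
            raise ValueError(f"bulge offset {offset} outside the mature arm")
        if arm == "star":
            at = L - offset  # insertion point facing mature[offset]
            ctx = mature[max(0, offset - 2):offset + 3]
            star[at:at] = list(_nonpairing_fill(ctx, size))
        elif arm == "mature":
            del star[max(0, L - offset - size):L - offset]
        else:
            raise ValueError(f"unknown bulge arm {arm!r}")
    star_core = "".join(star)
    loop_seq = _nonpairing_fill(mature[-4:] + star_core[:4], loop_len)
    ovh = _nonpairing_fill(mature[:4], star_overhang)

    if mature_arm == "5p":
        precursor = mature + loop_seq + star_core + ovh
        m_iv = (0, L)
        s_iv = (L + loop_len, len(precursor))
        loop_iv = (L, L + loop_len)
    else:
        star_full = star_core + ovh  # 3' overhang sits at the duplex end
        precursor = star_full + loop_seq + mature
        s_iv = (0, len(star_full))
        loop_iv = (len(star_full), len(star_full) + loop_len)
        m_iv = (loop_iv[1], len(precursor))
    return Hairpin(precursor, m_iv, s_iv, loop_iv, mature_arm)


# ---------------------------------------------------------------------------
# Truth table and locus planting
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_arm: str
    mature_seq: str  # RNA, 5'->3'
    star_seq: str
    mature_start: int  # genomic, forward coordinates
    mature_end: int
    star_start: int
    star_end: int
    arm_bias: float
    lfc: float
    cluster_id: str | None
    precursor: str  # RNA, 5'->3'


@dataclass
class TruthTable:
    records: list[LocusTruth]
    decoy_sequences: set[str] = field(default_factory=set)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def by_id(self, locus_id: str) -> LocusTruth:
        for rec in self.records:
            if rec.locus_id == locus_id:
                return rec
        raise KeyError(locus_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def _genomic_arm(start: int, end: int, strand: str, local: tuple[int, int],
                 plen: int) -> tuple[int, int]:
    """Map a precursor-local interval to forward-genome coordinates."""
    if strand == "+":
        return start + local[0], start + local[1]
    return end - local[1], end - local[0]


def plant_loci(genome: str, placements: list[tuple[str, int, str, Hairpin]],
               chrom: str = "chr1",
               cluster_ids: dict[str, str] | None = None,
               arm_biases: dict[str, float] | None = None,
               lfcs: dict[str, float] | None = None) -> tuple[str, TruthTable]:
    """Embed precursors into a genome by substitution at fixed positions.

    ``placements`` holds (locus_id, position, strand, hairpin). Minus-strand
    loci are inserted as the reverse complement of the precursor, so the
    transcribed strand reads the precursor 5'->3'. Overlapping placements
    raise, naming the offending locus.
    """
    cluster_ids = cluster_ids or {}
    arm_biases = arm_biases or {}
    lfcs = lfcs or {}
    seq = list(genome)
    occupied: list[tuple[int, int, str]] = []
    records = []
    for locus_id, pos, strand, hp in placements:
        plen = len(hp.precursor)
        end = pos + plen
        if pos < 0 or end > len(genome):
            raise ValueError(f"locus {locus_id} falls outside the genome")
        for s, e, other in occupied:
            if pos < e and s < end:
                raise ValueError(f"locus {locus_id} overlaps locus {other}")
        occupied.append((pos, end, locus_id))
        insert = rna_to_dna(hp.precursor)
        if strand == "-":
            insert = reverse_complement(insert)
        seq[pos:end] = insert
        m = _genomic_arm(pos, end, strand, hp.mature, plen)
        s_ = _genomic_arm(pos, end, strand, hp.star, plen)
        records.append(LocusTruth(
            locus_id=locus_id, chrom=chrom, start=pos, end=end, strand=strand,
            mature_arm=hp.mature_arm,
            mature_seq=hp.precursor[hp.mature[0]:hp.mature[1]],
            star_seq=hp.precursor[hp.star[0]:hp.star[1]],
            mature_start=m[0], mature_end=m[1],
            star_start=s_[0], star_end=s_[1],
            arm_bias=arm_biases.get(locus_id, float("nan")),
            lfc=lfcs.get(locus_id, 0.0),
            cluster_id=cluster_ids.get(locus_id),
            precursor=hp.precursor,
        ))
    return "".join(seq), TruthTable(records)


def _draw_categorical(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def random_mature(rng: np.random.Generator, length: int, u5_bias: float) -> str:
    """A random mature sequence (RNA) with a 5'-U preference."""
    seq = "".join(BASES[rng.integers(0, 4, size=length)])
    seq = dna_to_rna(seq)
    if rng.random() < u5_bias:
        seq = "U" + seq[1:]
    return seq


def _sample_clean_hairpin(cfg: SimConfig, rng: np.random.Generator,
                          max_tries: int = 100) -> Hairpin:
    """Draw a mature sequence whose constructed precursor folds into a
    clean canonical hairpin (real pre-miRNAs are selected for exactly this;
    arbitrary random sequences occasionally prefer alternative structures).
    """
    for _ in range(max_tries):
        length = int(_draw_categorical(rng, cfg.mature_length_dist))
        mature = random_mature(rng, length, cfg.u5_bias)
        arm = "5p" if rng.random() < 0.5 else "3p"
        mm = sorted(int(m) for m in rng.choice(
            np.arange(4, length - 4), size=cfg.n_mismatches, replace=False)
        ) if cfg.n_mismatches else []
        hp = build_hairpin(mature, loop_len=cfg.loop_len,
                           star_overhang=cfg.star_overhang, mature_arm=arm,
                           mismatches=mm)
        geo = duplex_geometry(fold(hp.precursor), hp.mature, hp.star)
        if geo.space == cfg.loop_len and geo.max_bulge <= 3 \
                and geo.paired_fraction >= 0.85:
            return hp
    raise RuntimeError("could not sample a cleanly folding hairpin")


def generate_genome(cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[str, TruthTable]:
    """Random genome with ``cfg.n_loci`` planted hairpins.

    The first 2*n_clustered_pairs loci form clustered pairs at the exact
    gaps in ``cfg.cluster_gap_bp``; remaining loci are placed at random
    non-overlapping positions (>=200 nt apart). Strands alternate so both
    orientations are exercised.
    """
    errors = cfg.validate()
    if errors:
        raise ValueError("; ".join(errors))
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    genome = "".join(BASES[rng.integers(0, 4, size=cfg.genome_length)])

    hairpins = [_sample_clean_hairpin(cfg, rng) for _ in range(cfg.n_loci)]

    # lay loci left to right with randomized spacing; clusters first
    placements = []
    cluster_ids = {}
    cursor = int(rng.integers(100, 300))
    idx = 0
    for c in range(cfg.n_clustered_pairs):
        gap = cfg.cluster_gap_bp[c % len(cfg.cluster_gap_bp)]
        strand = "+" if c % 2 == 0 else "-"
        a, b = f"locus{idx:03d}", f"locus{idx + 1:03d}"
        placements.append((a, cursor, strand, hairpins[idx]))
        cursor += len(hairpins[idx].precursor) + gap
        placements.append((b, cursor, strand, hairpins[idx + 1]))
        cursor += len(hairpins[idx + 1].precursor) + int(rng.integers(200, 400))
        cluster_ids[a] = cluster_ids[b] = f"cluster{c}"
        idx += 2
    while idx < cfg.n_loci:
        strand = "+" if rng.random() < 0.5 else "-"
        locus_id = f"locus{idx:03d}"
        placements.append((locus_id, cursor, strand, hairpins[idx]))
        cursor += len(hairpins[idx].precursor) + int(rng.integers(200, 400))
        idx += 1
    if cursor > cfg.genome_length:
        raise ValueError(f"locus {placements[-1][0]} overflows the genome")

    bias = cfg.effective_arm_bias()
    arm_biases = {f"locus{i:03d}": bias for i in range(cfg.n_loci)}
    lfcs = {}
    for i in range(cfg.n_loci):
        lfc = 0.0
        if i < cfg.n_biased_loci:
            lfc = cfg.lfc_magnitude if i % 2 == 0 else -cfg.lfc_magnitude
        if cfg.lfc_sd > 0:
            lfc += rng.normal(0.0, cfg.lfc_sd)
        lfcs[f"locus{i:03d}"] = lfc
    return plant_loci(genome, placements, cluster_ids=cluster_ids,
                      arm_biases=arm_biases, lfcs=lfcs)


# ---------------------------------------------------------------------------
# Reference ncRNA sets and sister genomes
# ---------------------------------------------------------------------------

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA")


def make_reference_sets(rng: np.random.Generator, n_per_class: int = 3,
                        length: int = 150) -> dict[str, dict[str, str]]:
    """Random reference sequences per known-ncRNA class (DNA)."""
    refs = {}
    for cls in NCRNA_CLASSES:
        refs[cls] = {
            f"{cls}_{i}": "".join(BASES[rng.integers(0, 4, size=length)])
            for i in range(n_per_class)
        }
    return refs


def make_sister_genome(genome: str, truth: TruthTable, mutation_rate: float,
                       rng: np.random.Generator,
                       present_loci: set[str] | None = None) -> str:
    """A homologous genome: genome-wide substitutions at ``mutation_rate``;
    loci absent from ``present_loci`` (when given) are overwritten with
    random sequence, deleting the homolog."""
    seq = np.array(list(genome))
    mask = rng.random(len(seq)) < mutation_rate
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        idx = np.where(mask)[0]
        orig = np.array([code.get(seq[i], 0) for i in idx])
        seq[idx] = BASES[(orig + shifts) % 4]
    out = "".join(seq)
    if present_loci is not None:
        out_l = list(out)
        for rec in truth:
            if rec.locus_id not in present_loci:
                repl = BASES[rng.integers(0, 4, size=rec.end - rec.start)]
                out_l[rec.start:rec.end] = repl
        out = "".join(out_l)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimReads:
    libraries: dict[str, list[str]]  # library name -> DNA read sequences
    conditions: dict[str, str]
    expected: pd.DataFrame  # locus x library expected mature-read counts


def _arm_read(genome: str, start: int, end: int, strand: str,
              offset: int) -> str:
    """Read from an arm with the 5' start shifted by ``offset`` (3' fixed)."""
    if strand == "+":
        return genome[start + offset:end]
    return reverse_complement(genome[start:end - offset])


def simulate_reads(genome: str, truth: TruthTable, cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   references: dict[str, dict[str, str]] | None = None
                   ) -> SimReads:
    """Draw per-library reads from planted arms plus background decoys.

    Locus abundances are log-normal (a single draw shared across libraries);
    sex bias multiplies the female mean by 2^(lfc/2) and divides the male
    mean by the same factor. Decoy reads (``decoy_fraction`` of depth) come
    half from the supplied reference ncRNA sets and half from random
    non-locus genome background, with lengths spread beyond the 18-30 nt
    window so the length filter has work to do.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 1)
    n = len(truth.records)
    if n == 0 or not cfg.libraries:
        warnings.warn("degenerate configuration: no loci or no libraries")
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    weights /= weights.sum() if n else 1.0

    jit_keys = sorted(cfg.five_prime_jitter)
    jit_p = np.array([cfg.five_prime_jitter[k] for k in jit_keys], dtype=float)
    jit_p /= jit_p.sum()
    sjit_keys = sorted(cfg.star_five_prime_jitter)
    sjit_p = np.array([cfg.star_five_prime_jitter[k] for k in sjit_keys],
                      dtype=float)
    sjit_p /= sjit_p.sum()

    locus_spans = [(r.start - 40, r.end + 40) for r in truth]

    libraries: dict[str, list[str]] = {}
    conditions: dict[str, str] = {}
    expected = pd.DataFrame(0.0, index=[r.locus_id for r in truth],
                            columns=[name for name, _, _ in cfg.libraries])
    decoy_seqs: set[str] = set()
    ref_pool = []
    if references:
        for cls in sorted(references):
            ref_pool.extend(references[cls][k] for k in sorted(references[cls]))

    for lib_name, condition, depth in cfg.libraries:
        conditions[lib_name] = condition
        reads: list[str] = []
        locus_budget = depth * (1.0 - cfg.decoy_fraction)
        for i, rec in enumerate(truth):
            factor = 2.0 ** (rec.lfc / 2.0) if condition == "female" \
                else 2.0 ** (-rec.lfc / 2.0)
            mean = locus_budget * weights[i] * factor
            n_reads = rng.poisson(mean)
            bias = rec.arm_bias if np.isfinite(rec.arm_bias) \
                else cfg.effective_arm_bias()
            n_mat = rng.binomial(n_reads, bias)
            expected.iloc[i, expected.columns.get_loc(lib_name)] = mean * bias
            for kind, count in (("mature", n_mat), ("star", n_reads - n_mat)):
                if count == 0:
                    continue
                if kind == "mature":
                    a0, a1 = rec.mature_start, rec.mature_end
                    offs = rng.choice(jit_keys, size=count, p=jit_p)
                else:
                    a0, a1 = rec.star_start, rec.star_end
                    offs = rng.choice(sjit_keys, size=count, p=sjit_p)
                for off in offs:
                    reads.append(_arm_read(genome, a0, a1, rec.strand, int(off)))
        # decoys
        n_decoy = rng.poisson(depth * cfg.decoy_fraction)
        for _ in range(n_decoy):
            length = int(rng.integers(16, 33))
            if ref_pool and rng.random() < cfg.reference_decoy_fraction:
                src = ref_pool[rng.integers(0, len(ref_pool))]
                pos = int(rng.integers(0, max(1, len(src) - length)))
                seq = src[pos:pos + length]
            else:
                for _try in range(50):
                    pos = int(rng.integers(0, len(genome) - length))
                    if not any(s < pos + length and pos < e
                               for s, e in locus_spans):
                        break
                seq = genome[pos:pos + length]
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            decoy_seqs.add(seq)
            reads.append(seq)
        if cfg.substitution_error_rate > 0:
            reads = [_mutate_read(r, cfg.substitution_error_rate, rng)
                     for r in reads]
        libraries[lib_name] = reads
    truth.decoy_sequences |= decoy_seqs
    return SimReads(libraries=libraries, conditions=conditions,
                    expected=expected)


def _mutate_read(read: str, rate: float, rng: np.random.Generator) -> str:
    out = list(read)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def write_fastq(reads: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Direct count-matrix and transcriptome simulation (for the statistical
# stages, where read-level simulation adds nothing)
# ---------------------------------------------------------------------------

def simulate_count_matrix(n_mirnas: int, depth: int = 100_000,
                          n_per_condition: int = 3, lfc: float = 0.0,
                          n_biased: int = 0, seed: int = 0
                          ) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """miRNA x library Poisson count matrix with planted log2 fold changes.

    Returns (counts, condition labels, planted per-miRNA lfc). The first
    ``n_biased`` miRNAs carry ±``lfc`` (alternating direction, positive =
    female-biased); the rest are null.
    """
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(0.0, 1.0, size=n_mirnas)
    weights /= weights.sum()
    lfcs = np.zeros(n_mirnas)
    for i in range(n_biased):
        lfcs[i] = lfc if i % 2 == 0 else -lfc
    libs = [(f"male_{i}", "male") for i in range(n_per_condition)] + \
           [(f"female_{i}", "female") for i in range(n_per_condition)]
    counts = {}
    conditions = {}
    for name, cond in libs:
        factor = np.where(lfcs == 0, 1.0,
                          2.0 ** (lfcs / 2.0) if cond == "female"
                          else 2.0 ** (-lfcs / 2.0))
        counts[name] = rng.poisson(depth * weights * factor)
        conditions[name] = cond
    index = [f"mir{i:04d}" for i in range(n_mirnas)]
    return (pd.DataFrame(counts, index=index), conditions,
            pd.Series(lfcs, index=index, name="lfc"))


def simulate_transcriptome(mirnas: dict[str, str], n_genes: int = 50,
                           utr_len: int = 500, site_prob: float = 0.5,
                           seed: int = 0
                           ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random 3'UTRs (RNA) with planted perfect-complement target sites.

    Each gene receives, per miRNA, a full reverse-complement site with
    probability ``site_prob``. Returns ({gene: utr}, truth table of planted
    sites with gene, mirna, position)."""
    rng = np.random.default_rng(seed)
    utrs = {}
    rows = []
    ids = sorted(mirnas)
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        utr = list(dna_to_rna("".join(BASES[rng.integers(0, 4, size=utr_len)])))
        used: list[tuple[int, int]] = []
        for mid in ids:
            if rng.random() >= site_prob:
                continue
            site = reverse_complement_rna(dna_to_rna(mirnas[mid].upper()))
            for _try in range(30):
                pos = int(rng.integers(0, utr_len - len(site)))
                if not any(s < pos + len(site) and pos < e for s, e in used):
                    used.append((pos, pos + len(site)))
                    utr[pos:pos + len(site)] = site
                    rows.append({"gene": gene, "mirna": mid, "position": pos})
                    break
        utrs[gene] = "".join(utr)
    return utrs, pd.DataFrame(rows, columns=["gene", "mirna", "position"])
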