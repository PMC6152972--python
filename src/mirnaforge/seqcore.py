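"""Shared sequence machinery.

Exact-match read mapping over a genome k-mer index, nested RNA secondary
structure folding by weighted base-pair maximization, and extraction of the
mature/star duplex geometry (loop "space", largest internal bulge) that the
discovery and homology stages validate candidate hairpins against.

All intervals are 0-based, half-open on the forward strand. GFF3 export adds
1 to starts (1-based, inclusive); BED export is unchanged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

#: pair weights for the folding objective (strong/medium/weak pairs)
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
#: bonus per helix-continuing pair ((i,j) on top of (i+1,j-1)); breaks the
#: many score ties of pure pair maximization in favor of contiguous stems,
#: which is what distinguishes a real duplex from scattered isolated pairs
STACK_BONUS = 0.5
MIN_LOOP = 3  # minimal hairpin loop length (nt)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA (T) or RNA (U) string.

    The alphabet is inferred from the presence of U; for U-less sequences
    that are known to be RNA use :func:`reverse_complement_rna`.
    """
    if "U" in seq or "u" in seq:
        return seq.translate(RNA_COMPLEMENT)[::-1]
    return seq.translate(DNA_COMPLEMENT)[::-1]


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, G<->C)."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA into {name: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def interval_to_gff3(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GFF3 columns 4/5)."""
    return start + 1, end


def gff3_to_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GFF3) -> 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# Genome index and exact mapping
# ---------------------------------------------------------------------------

@dataclass
class GenomeIndex:
    """Fixed-word-length k-mer index over named DNA sequences.

    Words are stored on the forward strand only; minus-strand queries are
    resolved by looking up the reverse complement of the query, so every
    reported interval lives on the forward coordinate system.
    """

    sequences: dict[str, str]
    k: int = 18
    kmer_table: dict[str, list[tuple[str, int]]] = field(repr=False, default=None)

    def __post_init__(self):
        if self.kmer_table is None:
            table: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for name in sorted(self.sequences):
                seq = self.sequences[name].upper()
                for pos in range(len(seq) - self.k + 1):
                    word = seq[pos:pos + self.k]
                    if "N" not in word:
                        table[word].append((name, pos))
            self.kmer_table = dict(table)

    def positions(self, word: str) -> list[tuple[str, int]]:
        return self.kmer_table.get(word, [])


def map_exact(read: str, index: GenomeIndex) -> list[tuple[str, tuple[int, int], str]]:
    """All zero-mismatch occurrences of ``read`` on both strands.

    Returns (sequence name, (start, end), strand) triples in deterministic
    order (name, start, strand). Reads containing N never map. The read must
    be at least as long as the index word size.
    """
    read = rna_to_dna(read.upper())
    if "N" in read:
        return []
    if len(read) < index.k:
        raise ValueError(
            f"read length {len(read)} shorter than index word size {index.k}"
        )
    hits = []
    for strand, query in (("+", read), ("-", reverse_complement(read))):
        seed = query[:index.k]
        for name, pos in index.positions(seed):
            if index.sequences[name][pos:pos + len(query)] == query:
                hits.append((name, (pos, pos + len(query)), strand))
    hits.sort(key=lambda h: (h[0], h[1][0], h[2]))
    return hits


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """A nested (pseudoknot-free) secondary structure.

    ``pairing[i]`` is the partner index of position i, or -1 when unpaired.
    ``hairpin_arms`` are the 5'/3' arm intervals flanking the main hairpin
    loop (the loop whose closing stem carries the most pairs), or None when
    the structure has no pairs.
    """

    sequence: str
    pairing: list[int]
    score: float
    n_pairs: int
    hairpin_arms: tuple[tuple[int, int], tuple[int, int]] | None
    loop: tuple[int, int] | None

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairing):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def _pair_score_matrix(seq: str) -> np.ndarray:
    code = {"A": 0, "C": 1, "G": 2, "U": 3}
    tab = np.zeros((4, 4))
    for (a, b), w in PAIR_WEIGHTS.items():
        tab[code[a], code[b]] = w
    enc = np.array([code[c] for c in seq], dtype=np.intp)
    return tab[enc[:, None], enc[None, :]]


def fold(seq: str) -> FoldResult:
    """Maximum-weight nested folding (GC=3, AU=2, GU=1, min loop 3, plus a
    0.5 stacking bonus per helix-continuing pair).

    Accepts RNA (or DNA, transcribed internally) up to precursor scale.
    Two-matrix DP: V(i,j) is the best score with (i,j) paired, W(i,j) the
    best score for the interval; the traceback prefers split decompositions
    on residual ties so terminal bases stay unpaired.
    """
    rna = dna_to_rna(seq.upper())
    for pos, c in enumerate(rna):
        if c not in "ACGU":
            raise ValueError(f"invalid base {c!r} at position {pos}")
    n = len(rna)
    if n == 0:
        return FoldResult("", [], 0.0, 0, None, None)

    S = _pair_score_matrix(rna)
    W = np.zeros((n, n))
    V = np.full((n, n), -np.inf)
    for d in range(MIN_LOOP + 1, n):
        i = np.arange(n - d)
        j = i + d
        inner = np.maximum(W[i + 1, j - 1], V[i + 1, j - 1] + STACK_BONUS)
        V[i, j] = np.where(S[i, j] > 0, S[i, j] + inner, -np.inf)
        best = V[i, j]
        for m in range(d):  # split after position i+m (m=0 covers i unpaired)
            best = np.maximum(best, W[i, i + m] + W[i + m + 1, j])
        W[i, j] = best

    pairing = [-1] * n
    stack = [("W", 0, n - 1)]
    while stack:
        which, i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if which == "W":
            w = W[i, j]
            if w == 0:
                continue
            split = None
            for m in range(j - i):
                if w == W[i, i + m] + W[i + m + 1, j]:
                    split = m
                    break
            if split is not None:
                stack.append(("W", i, i + split))
                stack.append(("W", i + split + 1, j))
            else:
                stack.append(("V", i, j))
        else:
            pairing[i], pairing[j] = j, i
            v = V[i, j]
            if v == S[i, j] + V[i + 1, j - 1] + STACK_BONUS:
                stack.append(("V", i + 1, j - 1))  # continue the helix
            else:
                stack.append(("W", i + 1, j - 1))

    n_pairs = sum(1 for p in pairing if p >= 0) // 2
    arms, loop = _main_hairpin(pairing)
    return FoldResult(rna, pairing, float(W[0, n - 1]), n_pairs, arms, loop)


def _main_hairpin(pairing: list[int]):
    """Locate the hairpin loop with the deepest enclosing stem."""
    pairs = [(i, j) for i, j in enumerate(pairing) if j > i]
    if not pairs:
        return None, None
    best = None
    for i, j in pairs:
        if any(pairing[p] >= 0 for p in range(i + 1, j)):
            continue  # not a loop-closing pair
        enclosing = [(a, b) for a, b in pairs if a <= i and b >= j]
        if best is None or len(enclosing) > best[0]:
            arm5 = (min(a for a, _ in enclosing), i + 1)
            arm3 = (j, max(b for _, b in enclosing) + 1)
            best = (len(enclosing), (arm5, arm3), (i + 1, j))
    if best is None:  # pairs exist but none closes a clean loop (cannot happen
        return None, None  # for nested structures; defensive)
    return best[1], best[2]


def duplex_partner_run(pairing: list[int], mature: tuple[int, int],
                       max_jump: int = 8,
                       min_space: int = MIN_LOOP
                       ) -> list[tuple[int, int]] | None:
    """Locate the mature/star duplex as the longest consistent partner run.

    For positions of ``mature`` paired outside the interval, nestedness makes
    partner positions strictly decreasing; within a genuine mature/star
    duplex consecutive partners differ by at most a bulge, while pairs into
    flanking sequence appear as large jumps. The longest run with steps
    <= ``max_jump`` on both strands is taken as the duplex; loop-proximal
    stray pairs that would leave no room for a hairpin loop (<``min_space``
    nt between the arms) are trimmed off. Returns the run as (mature
    position, partner) pairs, or None when nothing pairs outside the
    interval.
    """
    m0, m1 = mature
    pairs = [(p, pairing[p]) for p in range(m0, m1)
             if pairing[p] >= 0 and not m0 <= pairing[p] < m1]
    if not pairs:
        return None
    best: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    for p, q in pairs:
        if run and run[-1][1] - q <= max_jump and p - run[-1][0] <= max_jump \
                and q < run[-1][1]:
            run.append((p, q))
        else:
            if len(run) > len(best):
                best = run
            run = [(p, q)]
    if len(run) > len(best):
        best = run

    for _ in range(4):  # trim loop-proximal noise pairs
        star = run_interval(best)
        if len(best) <= 1:
            break
        if star[0] >= m1:       # star downstream of the mature
            if star[0] - m1 >= min_space:
                break
            best = [pq for pq in best if pq[1] != star[0]]
        elif star[1] <= m0:     # star upstream
            if m0 - star[1] >= min_space:
                break
            best = [pq for pq in best if pq[1] != star[1] - 1]
        else:                   # overlapping: let the caller reject
            break
    return best


def run_interval(run: list[tuple[int, int]]) -> tuple[int, int]:
    """Partner-side interval covered by a duplex run."""
    qs = [q for _, q in run]
    return min(qs), max(qs) + 1


# ---------------------------------------------------------------------------
# Duplex geometry
# ---------------------------------------------------------------------------

@dataclass
class DuplexGeometry:
    space: int
    max_bulge: int
    paired_fraction: float


def duplex_geometry(fold_result: FoldResult, mature: tuple[int, int],
                    star: tuple[int, int]) -> DuplexGeometry:
    """Geometry of the mature/star duplex within a folded precursor.

    ``space`` counts nucleotides strictly between the loop-proximal ends of
    the two intervals; ``max_bulge`` is the longest run of positions inside
    either interval (between its first and last duplex-paired position) that
    are not paired into the partner interval. Terminal overhangs therefore do
    not count as bulges.
    """
    (a0, a1), (b0, b1) = sorted([tuple(mature), tuple(star)])
    if b0 < a1:
        raise ValueError(f"mature and star intervals overlap: {mature} vs {star}")
    space = b0 - a1

    pairing = fold_result.pairing
    max_bulge = 0
    for (lo, hi), (plo, phi) in (((a0, a1), (b0, b1)), ((b0, b1), (a0, a1))):
        in_duplex = [plo <= pairing[p] < phi for p in range(lo, hi)]
        if not any(in_duplex):
            continue
        first = in_duplex.index(True)
        last = len(in_duplex) - 1 - in_duplex[::-1].index(True)
        run = 0
        for flag in in_duplex[first:last + 1]:
            run = 0 if flag else run + 1
            max_bulge = max(max_bulge, run)

    m0, m1 = mature
    paired = sum(
        1 for p in range(m0, m1)
        if star[0] <= pairing[p] < star[1]
    )
    paired_fraction = paired / max(m1 - m0, 1)
    return DuplexGeometry(space=space, max_bulge=max_bulge,
                          paired_fraction=paired_fraction)
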