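"""Novel miRNA locus calling from mapped clean tags.

Mapped tags are grouped into read stacks (shared 5' position). Each stack
abundant enough to seed a candidate (``min_seed_stack`` reads, well below
the acceptance threshold) nucleates a precursor window around itself — the
long flank tried on either side, the better-folding orientation kept. The
window is folded, the star arm is located as the most abundant stack
consistent with the duplex predicted by the fold, and the locus is accepted
when the read-evidence and duplex-geometry criteria hold: >= 10
mature-strand reads summed over libraries, >= 1 star read, loop space
<= 35 nt and largest duplex bulge <= 5 nt. Tags mapping to more than
``max_hits`` genomic positions are treated as repetitive and excluded, so
only non-repetitive loci are called. Stacks falling inside an already
evaluated window (e.g. the star stack of a called locus) do not re-seed.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .preprocess import ReadTag
from .seqcore import (DuplexGeometry, FoldResult, GenomeIndex, dna_to_rna,
                      duplex_geometry, duplex_partner_run, fold, map_exact,
                      reverse_complement, run_interval)


@dataclass
class DiscoveryParams:
    min_mature_reads: int = 10
    min_star_reads: int = 1
    max_space: int = 35
    min_space: int = 3         # a real hairpin needs a loop between the arms
    max_bulge: int = 5
    max_hits: int = 5          # multi-mapping cutoff; above = repetitive
    min_seed_stack: int = 4    # reads a stack needs to nucleate a candidate
    flank_long: int = 70       # precursor window, star side
    flank_short: int = 15      # precursor window, other side
    stack_window: int = 2      # 5'-jitter window when summing arm evidence
    min_fold_score: float | None = None  # optional fold-score cutoff


@dataclass
class HairpinLocus:
    id: str
    chrom: str
    start: int                 # precursor window, forward genome coords
    end: int
    strand: str
    precursor: str             # RNA, transcript orientation
    fold_result: FoldResult | None
    mature: tuple[int, int]    # local (precursor) coords
    star: tuple[int, int] | None
    mature_arm: str | None     # 5p / 3p
    mature_reads: dict[str, int] = field(default_factory=dict)
    star_reads: dict[str, int] = field(default_factory=dict)
    geometry: DuplexGeometry | None = None
    status: str = "candidate"

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def total_mature(self) -> int:
        return sum(self.mature_reads.values())

    @property
    def total_star(self) -> int:
        return sum(self.star_reads.values())

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature[0]:self.mature[1]]

    def mature_genomic(self) -> tuple[int, int]:
        """Mature interval in forward genome coordinates."""
        if self.strand == "+":
            return self.start + self.mature[0], self.start + self.mature[1]
        return self.end - self.mature[1], self.end - self.mature[0]


def _five_prime(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end


def call_loci(tags: list[ReadTag], index: GenomeIndex,
              params: DiscoveryParams | None = None) -> list[HairpinLocus]:
    """Call candidate miRNA loci from clean tags; returns every evaluated
    candidate with ``status`` accepted or rejected:<reason>."""
    params = params or DiscoveryParams()
    by_strand: dict[tuple[str, str], list] = defaultdict(list)
    for tag in tags:
        locs = map_exact(tag.sequence, index)
        if not locs or len(locs) > params.max_hits:
            continue  # unmapped or repetitive
        for chrom, (s, e), strand in locs:
            by_strand[(chrom, strand)].append((s, e, tag))

    stacks: dict[tuple[str, str], Counter] = {}
    starts_sorted: dict[tuple[str, str], list] = {}
    for key, items in by_strand.items():
        items.sort(key=lambda x: (x[0], x[1], x[2].sequence))
        c: Counter = Counter()
        for s, e, tag in items:
            c[_five_prime(s, e, key[1])] += tag.total
        stacks[key] = c
        starts_sorted[key] = [it[0] for it in items]

    seeds = []
    for (chrom, strand), c in stacks.items():
        for p5, count in c.items():
            if count >= params.min_seed_stack:
                seeds.append((-count, chrom, p5, strand))
    seeds.sort()

    consumed: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    loci = []
    for negc, chrom, p5, strand in seeds:
        if any(w0 <= p5 < w1 for w0, w1 in consumed[(chrom, strand)]):
            continue
        locus = _evaluate_seed(chrom, strand, p5, by_strand[(chrom, strand)],
                               starts_sorted[(chrom, strand)],
                               stacks[(chrom, strand)], index, params)
        if locus is None:
            continue
        consumed[(chrom, strand)].append((locus.start, locus.end))
        loci.append(locus)

    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    accepted_i = 0
    for i, locus in enumerate(loci):
        if locus.accepted:
            accepted_i += 1
            locus.id = f"mir-n{accepted_i:03d}"
        else:
            locus.id = f"candidate{i:03d}"
    return loci


def _window_items(items, starts, w0, w1):
    """Mapped tags whose interval lies within [w0, w1) (starts are sorted)."""
    lo = bisect_left(starts, w0)
    hi = bisect_right(starts, w1)
    return [it for it in items[lo:hi] if it[1] <= w1]


def _evaluate_seed(chrom, strand, p5, items, starts, stacks, index, params):
    genome = index.sequences[chrom]
    # representative interval: the highest-count tag starting at this stack
    best_tag = None
    for s, e, tag in items:
        if _five_prime(s, e, strand) == p5:
            if best_tag is None or tag.total > best_tag[2].total:
                best_tag = (s, e, tag)
    if best_tag is None:
        return None
    ds, de, _ = best_tag

    windows = []
    for star_side in ("down", "up"):
        if (strand == "+") == (star_side == "down"):
            w0, w1 = ds - params.flank_short, de + params.flank_long
        else:
            w0, w1 = ds - params.flank_long, de + params.flank_short
        w0, w1 = max(0, w0), min(len(genome), w1)
        window = genome[w0:w1]
        if strand == "-":
            window = reverse_complement(window)
        windows.append((w0, w1, fold(dna_to_rna(window)), window))

    def mature_local(w0, w1):
        if strand == "+":
            return ds - w0, de - w0
        return w1 - de, w1 - ds

    # keep the window where the mature sits in the longest clean duplex
    def window_score(entry):
        w0, w1, fr, _ = entry
        m0, m1 = mature_local(w0, w1)
        run = duplex_partner_run(fr.pairing, (m0, m1))
        return (len(run) if run else 0, fr.score)

    w0, w1, fold_res, window_seq = max(windows, key=window_score)
    m0, m1 = mature_local(w0, w1)
    locus = HairpinLocus(id="", chrom=chrom, start=w0, end=w1, strand=strand,
                         precursor=dna_to_rna(window_seq),
                         fold_result=fold_res, mature=(m0, m1), star=None,
                         mature_arm=None)
    local_items = _window_items(items, starts, w0, w1)

    run = duplex_partner_run(fold_res.pairing, (m0, m1))
    if run is None or len(run) < max(4, (m1 - m0) // 3):
        locus.status = "rejected:no_hairpin"
        return locus
    star_pred = run_interval(run)
    star5 = star_pred[0]
    locus.mature_arm = "5p" if m0 < star_pred[0] else "3p"

    # arm evidence: sum stacks within the jitter window of each arm 5' end
    def arm_counts(local5):
        counts: Counter = Counter()
        for s, e, tag in local_items:
            q5 = _five_prime(s, e, strand)
            local = (q5 - w0) if strand == "+" else (w1 - q5)
            if abs(local - local5) <= params.stack_window:
                for lib, c in tag.counts.items():
                    counts[lib] += c
        return dict(counts)

    locus.mature_reads = arm_counts(m0)

    # observed star: most abundant stack near the predicted star 5' end
    star_obs = None
    best = 0
    for s, e, tag in local_items:
        q5 = _five_prime(s, e, strand)
        local5 = (q5 - w0) if strand == "+" else (w1 - q5)
        if abs(local5 - star5) <= params.stack_window + 3:
            c = stacks[q5]
            if c > best:
                best = c
                if strand == "+":
                    star_obs = (s - w0, e - w0)
                else:
                    star_obs = (w1 - e, w1 - s)
    locus.star = star_obs if star_obs is not None else star_pred
    if star_obs is not None:
        locus.star_reads = arm_counts(locus.star[0])

    try:
        locus.geometry = duplex_geometry(fold_res, locus.mature, locus.star)
    except ValueError:
        locus.status = "rejected:no_hairpin"
        return locus

    if params.min_fold_score is not None and fold_res.score < params.min_fold_score:
        locus.status = "rejected:weak_fold"
    elif locus.geometry.space > params.max_space or \
            locus.geometry.space < params.min_space:
        locus.status = "rejected:space"
    elif locus.geometry.max_bulge > params.max_bulge:
        locus.status = "rejected:bulge"
    elif star_obs is None or locus.total_star < params.min_star_reads:
        locus.status = "rejected:no_star"
    elif locus.total_mature < params.min_mature_reads:
        locus.status = "rejected:low_mature"
    else:
        locus.status = "accepted"
    return locus


def length_spectrum(loci: list[HairpinLocus]) -> tuple[dict[int, float], int | None]:
    """Distribution of accepted mature lengths and its mode."""
    lengths = [l.mature[1] - l.mature[0] for l in loci if l.accepted]
    if not lengths:
        return {}, None
    counts = Counter(lengths)
    total = sum(counts.values())
    dist = {k: counts[k] / total for k in sorted(counts)}
    mode = max(sorted(counts), key=lambda k: counts[k])
    return dist, mode


def first_nt_bias(loci: list[HairpinLocus]) -> dict[str, float]:
    """Frequency of A/C/G/U at the mature 5' position of accepted loci."""
    out = {b: 0.0 for b in "ACGU"}
    accepted = [l for l in loci if l.accepted]
    if not accepted:
        return out
    counts = Counter(l.mature_seq[0] for l in accepted)
    total = sum(counts.values())
    for b in out:
        out[b] = counts.get(b, 0) / total
    return out
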