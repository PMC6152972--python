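"""Cross-genome miRNA homology and genomic clustering.

Homologs are found by 7-mer word seeding followed by ungapped extension
along the diagonal (a stand-in for low-stringency blastn with word size 7);
each candidate location is extended by 90 nt of flanking sequence on both
sides and the window is folded to check that the match still sits on one arm
of a hairpin whose mature/star duplex satisfies the loop-space (<= 35 nt)
and bulge (<= 5 nt) limits. Genomic clusters are chains of loci whose
consecutive gaps are below a distance threshold; shared 7-mer seeds
(positions 2-8) flag likely duplication-born cluster members.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .seqcore import (DuplexGeometry, FoldResult, GenomeIndex, dna_to_rna,
                      duplex_geometry, duplex_partner_run, fold,
                      reverse_complement, rna_to_dna, run_interval)


@dataclass
class HomologParams:
    word: int = 7
    flank: int = 90
    min_coverage: float = 0.80   # matched fraction of query positions
    min_identity: float = 0.85   # identity within the extended run
    max_space: int = 35
    min_space: int = 3           # below the minimal hairpin loop: no duplex
    max_bulge: int = 5
    min_fold_pairs: int = 12     # below this the window has no hairpin
    min_paired_fraction: float = 0.5  # of the matched arm, into its partner


@dataclass
class HomologHit:
    query_id: str
    genome: str
    chrom: str
    interval: tuple[int, int]
    strand: str
    identity: float
    coverage: float
    window: tuple[int, int]
    fold_result: FoldResult | None
    geometry: DuplexGeometry | None
    verdict: str  # homolog / no_hairpin / geometry_fail


def _diagonal_candidates(query: str, index: GenomeIndex):
    """Seed 7-mer hits grouped by (chrom, strand, diagonal)."""
    k = index.k
    diags = defaultdict(list)
    for strand in ("+", "-"):
        q = query if strand == "+" else reverse_complement(query)
        for qpos in range(len(q) - k + 1):
            for chrom, gpos in index.positions(q[qpos:qpos + k]):
                diags[(chrom, strand, gpos - qpos)].append(qpos)
    return diags


def _extend(query: str, genome: str, offset: int) -> tuple[int, int]:
    """Ungapped alignment of the full query at diagonal ``offset``; returns
    (matches, aligned length) over the in-genome part of the query."""
    matches = aligned = 0
    for qpos in range(len(query)):
        g = offset + qpos
        if 0 <= g < len(genome):
            aligned += 1
            if genome[g] == query[qpos]:
                matches += 1
    return matches, aligned


def homolog_search(query_id: str, query: str, genome_name: str,
                   index: GenomeIndex,
                   params: HomologParams | None = None) -> list[HomologHit]:
    """Word-seeded homolog search with flank-extended hairpin validation.

    Returns the best-verdict hit per candidate location; locations whose
    seeded extension covers < min_coverage of the query or falls below
    min_identity are discarded before folding.
    """
    params = params or HomologParams()
    query = rna_to_dna(query.upper())
    if "N" in query:
        raise ValueError("query contains N")
    if not 18 <= len(query) <= 30:
        raise ValueError(f"query length {len(query)} outside [18, 30]")

    hits = []
    seen: set[tuple[str, str, int]] = set()
    for (chrom, strand, offset), qposs in sorted(_diagonal_candidates(query, index).items()):
        key = (chrom, strand, offset)
        if key in seen:
            continue
        seen.add(key)
        genome = index.sequences[chrom]
        oriented = query if strand == "+" else reverse_complement(query)
        matches, aligned = _extend(oriented, genome, offset)
        coverage = aligned / len(query)
        identity = matches / aligned if aligned else 0.0
        if coverage < params.min_coverage or \
                matches / len(query) < params.min_coverage * params.min_identity or \
                identity < params.min_identity:
            continue
        g0 = max(0, offset)
        g1 = min(len(genome), offset + len(query))
        w0 = max(0, g0 - params.flank)
        w1 = min(len(genome), g1 + params.flank)
        window = genome[w0:w1]
        if strand == "-":
            window = reverse_complement(window)
            m_local = (w1 - g1, w1 - g0)
        else:
            m_local = (g0 - w0, g1 - w0)
        fr = fold(dna_to_rna(window))
        verdict, geometry = _validate_hairpin(fr, m_local, params)
        hits.append(HomologHit(
            query_id=query_id, genome=genome_name, chrom=chrom,
            interval=(g0, g1), strand=strand, identity=identity,
            coverage=coverage, window=(w0, w1), fold_result=fr,
            geometry=geometry, verdict=verdict))
    hits.sort(key=lambda h: (h.verdict != "homolog", -h.identity,
                             h.chrom, h.interval[0], h.strand))
    return hits


def _validate_hairpin(fr: FoldResult, mature: tuple[int, int],
                      params: HomologParams):
    if fr.n_pairs < params.min_fold_pairs:
        return "no_hairpin", None
    m0, m1 = mature
    run = duplex_partner_run(fr.pairing, (m0, m1))
    if run is None:
        return "geometry_fail", None
    star = run_interval(run)
    if star[0] < m1 and m0 < star[1]:  # partner region overlaps the match
        return "geometry_fail", None
    geometry = duplex_geometry(fr, mature, star)
    if geometry.paired_fraction < params.min_paired_fraction or \
            geometry.space > params.max_space or \
            geometry.space < params.min_space or \
            geometry.max_bulge > params.max_bulge:
        return "geometry_fail", geometry
    return "homolog", geometry


def classify_conservation(query_ids: list[str],
                          hits_per_genome: dict[str, dict[str, list[HomologHit]]]
                          ) -> tuple[dict[str, str], dict[str, float]]:
    """Per-miRNA conservation class across sister genomes.

    ``hits_per_genome`` maps genome name -> query id -> hits. A query is
    present in a genome when any hit has verdict 'homolog'. Classes: 'both'
    (every genome), 'one' (some but not all), 'neither'."""
    genomes = sorted(hits_per_genome)
    classes = {}
    for qid in query_ids:
        n_present = sum(
            any(h.verdict == "homolog"
                for h in hits_per_genome[g].get(qid, []))
            for g in genomes)
        if n_present == len(genomes) and genomes:
            classes[qid] = "both"
        elif n_present > 0:
            classes[qid] = "one"
        else:
            classes[qid] = "neither"
    n = max(len(query_ids), 1)
    fractions = {cls: sum(1 for c in classes.values() if c == cls) / n
                 for cls in ("both", "one", "neither")}
    return classes, fractions


@dataclass
class MirnaCluster:
    cluster_id: str
    genome: str
    chrom: str
    members: list[str]             # locus ids ordered by position
    gaps: list[int]                # nt between consecutive precursors
    shared_seed: dict[tuple[str, str], bool]


def seed_of(mature: str, seed_len: int = 7) -> str:
    """The seed region: nucleotides 2..(1+seed_len) of the mature sequence."""
    seq = dna_to_rna(mature.upper())
    if len(seq) < 1 + seed_len:
        raise ValueError("sequence shorter than the seed region")
    return seq[1:1 + seed_len]


def find_clusters(loci: list[tuple[str, str, str, int, int, str]],
                  max_gap: int = 10_000) -> list[MirnaCluster]:
    """Single-linkage genomic clustering of miRNA loci.

    ``loci`` rows are (locus_id, genome, chrom, start, end, mature_seq).
    Consecutive loci on the same chromosome whose gap (start of next minus
    end of previous) is <= ``max_gap`` chain into one cluster; singletons are
    not clusters. Input order does not matter."""
    grouped = defaultdict(list)
    for locus_id, genome, chrom, start, end, mature in loci:
        grouped[(genome, chrom)].append((start, end, locus_id, mature))
    clusters = []
    n = 0
    for (genome, chrom) in sorted(grouped):
        items = sorted(grouped[(genome, chrom)])
        chain = [items[0]]
        for item in items[1:]:
            if item[0] - chain[-1][1] <= max_gap:
                chain.append(item)
            else:
                if len(chain) > 1:
                    clusters.append(_make_cluster(n, genome, chrom, chain))
                    n += 1
                chain = [item]
        if len(chain) > 1:
            clusters.append(_make_cluster(n, genome, chrom, chain))
            n += 1
    return clusters


def _make_cluster(n, genome, chrom, chain):
    members = [c[2] for c in chain]
    gaps = [chain[i + 1][0] - chain[i][1] for i in range(len(chain) - 1)]
    shared = {}
    for i in range(len(chain)):
        for j in range(i + 1, len(chain)):
            try:
                same = seed_of(chain[i][3]) == seed_of(chain[j][3])
            except ValueError:
                same = False
            shared[(chain[i][2], chain[j][2])] = same
    return MirnaCluster(cluster_id=f"cluster{n:03d}", genome=genome,
                        chrom=chrom, members=members, gaps=gaps,
                        shared_seed=shared)


def cluster_distance_ratio(gaps: dict[str, float], focal: str
                           ) -> tuple[float, int]:
    """Fold-ratio of the focal genome's intra-cluster gap to the mean gap of
    the other genomes, raw and rounded to the nearest integer fold."""
    others = [g for name, g in gaps.items() if name != focal]
    if not others:
        raise ValueError("need at least one non-focal genome")
    mean_others = sum(others) / len(others)
    if mean_others == 0:
        raise ValueError("non-focal gaps average to zero")
    ratio = gaps[focal] / mean_others
    return ratio, round(ratio)
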