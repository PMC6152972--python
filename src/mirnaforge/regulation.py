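"""Target prediction, differential expression and enrichment statistics.

Target sites are called by two independent criteria — an exact Watson-Crick
seed match (positions 2-8, optionally 2-9; G:U wobbles disqualify) and a
hybridization-energy threshold (ΔG <= -20 kcal/mol by default) computed
from nearest-neighbor stack energies over the best ungapped duplex core —
and retained when both agree (the multi-predictor consensus rule).

Sex-biased expression is tested per miRNA by a depth-normalized exact
binomial test on condition-pooled counts, with Benjamini-Hochberg FDR
reported alongside raw p-values; raw p < 0.05 defines a biased call.
Annotation-term enrichment uses the one-sided Fisher exact test. The
2^-ΔΔCt relative-quantification fold change is included for qPCR
validation arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import dna_to_rna, reverse_complement_rna

# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------


def seed_match(mirna: str, utr: str, seed_len: int = 7) -> list[int]:
    """Positions in ``utr`` whose bases exactly Watson-Crick pair the miRNA
    seed (positions 2..1+seed_len). The returned position is the start of
    the seed-complementary site on the UTR. G:U pairs never match because
    the site must equal the strict WC complement."""
    if seed_len not in (7, 8):
        raise ValueError("seed_len must be 7 or 8")
    mirna = dna_to_rna(mirna.upper())
    utr = dna_to_rna(utr.upper())
    seed = mirna[1:1 + seed_len]
    if len(seed) < seed_len or len(utr) < seed_len:
        return []
    site = reverse_complement_rna(seed)
    positions = []
    start = utr.find(site)
    while start >= 0:
        positions.append(start)
        start = utr.find(site, start + 1)
    return positions


# ---------------------------------------------------------------------------
# Duplex hybridization energy
# ---------------------------------------------------------------------------

#: Watson-Crick nearest-neighbor stack free energies, ΔG°37 kcal/mol
#: (Turner 2004 set), keyed by the 5'->3' dinucleotide of one strand; the
#: partner strand is its WC complement. Rotational symmetry fills all 16.
_CANONICAL_STACKS = {
    "AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
    "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
}
HELIX_INIT = 4.09  # duplex initiation penalty, kcal/mol

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _full_stack_table() -> dict[str, float]:
    table = dict(_CANONICAL_STACKS)
    for dinuc, dg in list(_CANONICAL_STACKS.items()):
        rotated = _WC[dinuc[1]] + _WC[dinuc[0]]
        table.setdefault(rotated, dg)
    return table


STACK_DG = _full_stack_table()


def duplex_energy(mirna: str, context: str) -> float:
    """ΔG (kcal/mol) of the best ungapped Watson-Crick duplex core between
    the miRNA and a target-site context.

    Every antiparallel ungapped alignment is scanned; within an alignment,
    each maximal run of WC pairs scores the sum of its nearest-neighbor
    stack energies plus the helix initiation penalty. The most negative run
    over all alignments is returned; 0.0 means no stabilizing duplex."""
    mirna = dna_to_rna(mirna.upper())
    context = dna_to_rna(context.upper())
    if not mirna or not context:
        return 0.0
    rc = reverse_complement_rna(mirna)
    n, m = len(rc), len(context)
    best = 0.0
    for offset in range(-(n - 1), m):
        run_dg = None  # None = no open run
        prev_matched = False
        for t in range(n):
            j = offset + t
            matched = 0 <= j < m and context[j] == rc[t] and rc[t] in "ACGU"
            if matched and prev_matched:
                run_dg += STACK_DG[context[j - 1:j + 1]]
                best = min(best, run_dg)
            elif matched:
                run_dg = HELIX_INIT
            prev_matched = matched
    return best if best < 0 else 0.0


# ---------------------------------------------------------------------------
# Consensus target prediction
# ---------------------------------------------------------------------------

@dataclass
class TargetPair:
    mirna_id: str
    gene_id: str
    position: int
    criteria_passed: tuple[str, ...]
    duplex_dg: float
    consensus: bool


def consensus_targets(mirnas: dict[str, str], utrs: dict[str, str],
                      seed_len: int = 7, dg_cutoff: float = -20.0
                      ) -> tuple[list[TargetPair], pd.DataFrame]:
    """Predict target sites and apply the >=2-criterion consensus rule.

    Returns (all seed-anchored sites with their criteria, per-miRNA summary
    with the number of consensus target genes and the mean across miRNAs).
    """
    pairs = []
    for mid in sorted(mirnas):
        mseq = dna_to_rna(mirnas[mid].upper())
        tail = len(mseq) - 1 - seed_len  # bases pairing upstream of the seed
        for gene in sorted(utrs):
            utr = dna_to_rna(utrs[gene].upper())
            for pos in seed_match(mseq, utr, seed_len):
                ctx0 = max(0, pos - tail - 4)
                ctx1 = min(len(utr), pos + seed_len + 5)
                dg = duplex_energy(mseq, utr[ctx0:ctx1])
                criteria = ["seed"]
                if dg <= dg_cutoff:
                    criteria.append("energy")
                pairs.append(TargetPair(
                    mirna_id=mid, gene_id=gene, position=pos,
                    criteria_passed=tuple(criteria), duplex_dg=dg,
                    consensus=len(criteria) >= 2))
    rows = []
    for mid in sorted(mirnas):
        genes = {p.gene_id for p in pairs if p.mirna_id == mid and p.consensus}
        rows.append({"mirna": mid, "n_target_genes": len(genes)})
    summary = pd.DataFrame(rows, columns=["mirna", "n_target_genes"])
    return pairs, summary


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (robust to a minority of
    truly differential rows, unlike raw totals)."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geomean = log_counts.mean(axis=1)
    ratios = log_counts.sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    if factors.isna().any():  # degenerate: fall back to totals
        totals = counts.sum(axis=0).astype(float)
        return totals / totals.mean()
    return factors / factors.mean()


def de_test(counts: pd.DataFrame, conditions: dict[str, str],
            p_cutoff: float = 0.05, dispersion: float | None = None,
            normalization: str = "median-ratio") -> pd.DataFrame:
    """Two-condition (male/female) differential expression.

    Counts are pooled per condition; each miRNA's female count is tested
    against the depth-expected proportion with a two-sided exact binomial
    test (or a dispersion-inflated normal approximation when ``dispersion``
    > 1 is given for overdispersed data). Library depths come from
    median-of-ratios size factors (``normalization="total"`` uses column
    sums instead). log2 fold change is female over male on depth-normalized
    counts with a 0.5 pseudocount. Raw p < p_cutoff defines the bias call;
    BH FDR over all tested miRNAs is reported alongside. miRNAs with zero
    total count are excluded with a warning."""
    libs = list(counts.columns)
    cond = pd.Series({l: conditions[l] for l in libs})
    if set(cond) != {"male", "female"}:
        missing = {"male", "female"} - set(cond)
        raise ValueError(f"need libraries for both conditions; missing {missing}")
    if normalization == "median-ratio":
        depth = size_factors(counts)
    elif normalization == "total":
        depth = counts.sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    d_m = float(depth[cond[cond == "male"].index].sum())
    d_f = float(depth[cond[cond == "female"].index].sum())
    p0 = d_f / (d_m + d_f)

    x_m = counts[cond[cond == "male"].index].sum(axis=1)
    x_f = counts[cond[cond == "female"].index].sum(axis=1)
    total = x_m + x_f
    zero = total == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} miRNAs with zero counts")
    keep = counts.index[~zero]

    rows = []
    for mid in keep:
        n = int(total[mid])
        k = int(x_f[mid])
        if dispersion is not None and dispersion > 1:
            se = np.sqrt(dispersion * n * p0 * (1 - p0))
            z = (k - n * p0) / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
        else:
            p = float(stats.binomtest(k, n, p0).pvalue)
        lfc = float(np.log2(((k + 0.5) / d_f) / ((x_m[mid] + 0.5) / d_m)))
        rows.append({"mirna": mid, "log2fc": lfc, "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["mirna", "log2fc", "p_value"])
    result["fdr"] = bh_fdr(result["p_value"].to_numpy()) if len(result) else []
    result["biased"] = "none"
    sig = result["p_value"] < p_cutoff
    result.loc[sig & (result["log2fc"] > 0), "biased"] = "female"
    result.loc[sig & (result["log2fc"] < 0), "biased"] = "male"
    return result.set_index("mirna")


# ---------------------------------------------------------------------------
# Enrichment and qPCR arithmetic
# ---------------------------------------------------------------------------

def fisher_enrichment(gene_set: set[str], universe: set[str],
                      term_map: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per annotation term.

    ``term_map`` maps gene -> set of terms and must cover the universe;
    ``gene_set`` must be a subset of the universe. Returns per-term counts,
    odds ratio, exact p and BH FDR, ordered by p."""
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    by_term: dict[str, set[str]] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):
            by_term.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(by_term):
        with_term = by_term[term]
        a = len(gene_set & with_term)
        b = len(gene_set) - a
        c = len(with_term) - a
        d = len(universe) - len(gene_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "in_set_with_term": a,
                     "in_set_without": b, "out_set_with_term": c,
                     "out_set_without": d, "odds_ratio": float(odds),
                     "p_value": float(p)})
    table = pd.DataFrame(rows, columns=["term", "in_set_with_term",
                                        "in_set_without", "out_set_with_term",
                                        "out_set_without", "odds_ratio",
                                        "p_value"])
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    else:
        table["fdr"] = []
    return table


def ddct_fold_change(ct_target_a: float, ct_ref_a: float,
                     ct_target_b: float, ct_ref_b: float) -> float:
    """Relative expression fold change by the 2^-ΔΔCt method: condition A
    vs condition B, each normalized to its reference-gene Ct."""
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(2.0 ** -ddct)
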