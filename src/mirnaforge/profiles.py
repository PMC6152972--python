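"""Arm-usage and 5'-isomiR profiling.

Quantifies 5p/3p arm read fractions per locus, calls dominance with a
configurable ratio threshold, detects arm switches between two datasets
(e.g. two species), catalogs 5'-end start-position spectra (isomiRs) and
their fidelity (modal-offset fraction), and contrasts mature vs star 5'
fidelity across loci with a sign test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .discovery import HairpinLocus


@dataclass
class ArmUsageProfile:
    locus_id: str
    reads_5p: int
    reads_3p: int
    dominant: str  # "5p", "3p" or "codominant"
    fraction_5p: float


@dataclass
class IsomirProfile:
    locus_id: str
    species: str  # "mature" or "star"
    start_offsets: dict[int, int]
    fidelity: float

    def ranked_offsets(self) -> list[tuple[int, int]]:
        """Offsets by descending read count (secondary/tertiary isomiRs)."""
        return sorted(self.start_offsets.items(), key=lambda kv: (-kv[1], kv[0]))


def arm_usage(locus_id: str, reads_5p: int, reads_3p: int,
              dominance_ratio: float = 2.0) -> ArmUsageProfile:
    """Call arm dominance: an arm dominates when it has >= ``dominance_ratio``
    times the reads of the other arm; otherwise the locus is codominant."""
    total = reads_5p + reads_3p
    if total == 0:
        raise ValueError(f"locus {locus_id}: zero reads on both arms")
    if reads_5p >= dominance_ratio * max(reads_3p, 0) and reads_5p > reads_3p:
        dominant = "5p"
    elif reads_3p >= dominance_ratio * max(reads_5p, 0) and reads_3p > reads_5p:
        dominant = "3p"
    else:
        dominant = "codominant"
    return ArmUsageProfile(locus_id, reads_5p, reads_3p, dominant,
                           reads_5p / total)


def arm_usage_from_locus(locus: HairpinLocus,
                         dominance_ratio: float = 2.0) -> ArmUsageProfile:
    """Arm usage of a called locus (mature/star counts mapped onto 5p/3p)."""
    if locus.mature_arm == "5p":
        r5, r3 = locus.total_mature, locus.total_star
    else:
        r5, r3 = locus.total_star, locus.total_mature
    return arm_usage(locus.id, r5, r3, dominance_ratio)


def detect_arm_switch(profile_a: ArmUsageProfile,
                      profile_b: ArmUsageProfile) -> str:
    """'switch' when both datasets are dominant on opposite arms, 'stable'
    when dominant on the same arm, 'indeterminate' when either is
    codominant. Symmetric in its arguments."""
    if profile_a.locus_id != profile_b.locus_id:
        raise ValueError(
            f"mismatched family ids: {profile_a.locus_id} vs {profile_b.locus_id}")
    if "codominant" in (profile_a.dominant, profile_b.dominant):
        return "indeterminate"
    return "stable" if profile_a.dominant == profile_b.dominant else "switch"


def isomir_profile(locus_id: str, species: str,
                   offset_counts: dict[int, int],
                   window: int = 2) -> IsomirProfile:
    """5'-start spectrum relative to the annotated 5' end.

    Only offsets within ±``window`` count as isomiRs; reads outside are
    locus reads but not isomiRs and are dropped from the spectrum. Fidelity
    is the modal-offset fraction of in-window reads."""
    spectrum = {int(o): int(c) for o, c in offset_counts.items()
                if abs(o) <= window and c > 0}
    total = sum(spectrum.values())
    if total == 0:
        raise ValueError(f"locus {locus_id}: no reads within ±{window} nt "
                         f"of the annotated 5' end")
    modal = max(spectrum.values())
    return IsomirProfile(locus_id, species, spectrum, modal / total)


def isomir_from_reads(locus_id: str, species: str, annotated5: int,
                      read_starts: list[int], window: int = 2) -> IsomirProfile:
    """Convenience wrapper: build the offset spectrum from raw 5'-start
    positions (same strand-oriented coordinate system as ``annotated5``)."""
    counts: dict[int, int] = {}
    for s in read_starts:
        off = s - annotated5
        counts[off] = counts.get(off, 0) + 1
    return isomir_profile(locus_id, species, counts, window)


def fidelity_contrast(mature_profiles: list[IsomirProfile],
                      star_profiles: list[IsomirProfile]
                      ) -> tuple[pd.DataFrame, float]:
    """Per-locus paired (mature fidelity, star fidelity) table plus a
    two-sided sign-test p-value for mature > star. Ties are dropped from the
    test, as usual for a sign test."""
    star_by_id = {p.locus_id: p for p in star_profiles}
    rows = []
    for mp in mature_profiles:
        sp = star_by_id.get(mp.locus_id)
        if sp is None:
            continue
        rows.append({"locus_id": mp.locus_id,
                     "mature_fidelity": mp.fidelity,
                     "star_fidelity": sp.fidelity})
    table = pd.DataFrame(rows, columns=["locus_id", "mature_fidelity",
                                        "star_fidelity"])
    wins = int((table["mature_fidelity"] > table["star_fidelity"]).sum())
    losses = int((table["mature_fidelity"] < table["star_fidelity"]).sum())
    n = wins + losses
    p = 1.0 if n == 0 else stats.binomtest(wins, n, 0.5).pvalue
    return table, float(p)
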