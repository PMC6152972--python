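"""End-to-end pipeline orchestration.

Validates a YAML configuration carrying every stage threshold (defaults are
the analysis defaults: 18-30 nt length window, >=10 mature / >=1 star
reads, 35 nt loop space, 5 nt bulge, 90 nt homology flank, word size 7,
seed length 7, ΔG cutoff -20 kcal/mol, p < 0.05, 10 kb cluster gap,
dominance ratio 2) and runs the stages from simulated reads to report
tables, writing a manifest of output checksums so identical config + seed
yields identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, discovery, preprocess, profiles, regulation
from . import synthetic_data as sd
from .seqcore import GenomeIndex, interval_to_gff3, rna_to_dna, write_fasta

logger = logging.getLogger("mirnaforge")


@dataclass
class PipelineConfig:
    min_len: int = 18
    max_len: int = 30
    adapter: str | None = None
    min_overlap: int = 4
    min_mature: int = 10
    min_star: int = 1
    max_space: int = 35
    max_bulge: int = 5
    max_hits: int = 5
    flank: int = 90
    word: int = 7
    seed_len: int = 7
    dg_cutoff: float = -20.0
    p_cutoff: float = 0.05
    max_gap: int = 10_000
    dominance_ratio: float = 2.0
    rng_seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def sim_config(self) -> sd.SimConfig:
        return sd.SimConfig(rng_seed=self.rng_seed, **self.simulate)


_BOUNDS = {
    "min_len": (1, 50), "max_len": (1, 100), "min_overlap": (1, 30),
    "min_mature": (0, 10**6), "min_star": (0, 10**6),
    "max_space": (0, 1000), "max_bulge": (0, 100), "max_hits": (1, 1000),
    "flank": (0, 1000), "word": (4, 20), "seed_len": (7, 8),
    "max_gap": (1, 10**7), "dominance_ratio": (1.0, 100.0),
}
_PAPER_DEFAULTS = {"max_bulge": 5, "max_space": 35, "min_mature": 10,
                   "min_star": 1, "min_len": 18, "max_len": 30}


def validate_config(raw_text: str) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML config; collects all errors rather than
    failing on the first. An empty file yields the defaults (with a logged
    warning); values beyond the standard analysis defaults are accepted with
    a note."""
    errors: list[str] = []
    try:
        data = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as exc:
        return None, [f"invalid YAML: {exc}"]
    if not isinstance(data, dict):
        return None, ["config must be a mapping"]
    if not data:
        logger.warning("empty config: using defaults")
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for key in data:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    values = {}
    for key, value in data.items():
        if key not in known or key == "simulate":
            continue
        expected = known[key].type
        if key == "adapter":
            if value is not None and not isinstance(value, str):
                errors.append(f"{key}: expected a string, got {value!r}")
                continue
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            errors.append(f"{key}: expected a number, got {value!r}")
            continue
        if key in _BOUNDS and isinstance(value, (int, float)):
            lo, hi = _BOUNDS[key]
            if not lo <= value <= hi:
                errors.append(f"{key}: {value} outside documented bounds "
                              f"[{lo}, {hi}]")
                continue
        if key in _PAPER_DEFAULTS and value != _PAPER_DEFAULTS[key]:
            logger.warning("%s=%s differs from the standard analysis "
                           "default %s", key, value, _PAPER_DEFAULTS[key])
        values[key] = value
    if "simulate" in data:
        if not isinstance(data["simulate"], dict):
            errors.append("simulate: expected a mapping of SimConfig fields")
        else:
            sim_fields = {f.name for f in dataclasses.fields(sd.SimConfig)}
            bad = set(data["simulate"]) - sim_fields
            if bad:
                errors.append(f"simulate: unknown keys {sorted(bad)}")
            else:
                values["simulate"] = data["simulate"]
    min_len = values.get("min_len", 18)
    max_len = values.get("max_len", 30)
    if min_len > max_len:
        errors.append(f"min_len ({min_len}) exceeds max_len ({max_len})")
    if errors:
        return None, errors
    cfg = PipelineConfig(**values)
    logger.info("config: %s", dataclasses.asdict(cfg))
    return cfg, []


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a simulated dataset and write all report tables.

    Returns the manifest (relative path -> sha256). Stage outputs live in
    ``<outdir>/NN_<stage>/``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(handler)
    try:
        return _run_all(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage_dir(out: Path, n: int, name: str) -> Path:
    d = out / f"{n:02d}_{name}"
    d.mkdir(exist_ok=True)
    return d


def _run_all(cfg: PipelineConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.rng_seed)
    sim = cfg.sim_config()

    # 01 simulate
    d = _stage_dir(out, 1, "simulate")
    genome, truth = sd.generate_genome(sim, rng)
    refs = sd.make_reference_sets(rng)
    reads = sd.simulate_reads(genome, truth, sim, rng, references=refs)
    write_fasta({"chr1": genome}, d / "genome.fa")
    for cls, records in refs.items():
        write_fasta(records, d / f"{cls}.fa")
    for lib, seqs in reads.libraries.items():
        sd.write_fastq(seqs, d / f"{lib}.fastq")
    truth.to_frame().to_csv(d / "truth_loci.tsv", sep="\t", index=False)
    _truth_gff3(truth, d / "truth_loci.gff3")
    logger.info("simulate: %d loci, %d libraries", len(truth),
                len(reads.libraries))

    # 02 preprocess
    d = _stage_dir(out, 2, "preprocess")
    tags, stats = preprocess.run_preprocess(
        reads.libraries, adapter=cfg.adapter, min_overlap=cfg.min_overlap,
        references=refs, min_len=cfg.min_len, max_len=cfg.max_len)
    clean = preprocess.clean_tags(tags)
    removed = pd.Series([t.annotation for t in tags]).value_counts()
    logger.info("preprocess: %d tags, removed per class: %s", len(tags),
                removed.to_dict())
    with open(d / "tags.fa", "w") as fh:
        for i, t in enumerate(clean):
            fh.write(f">tag{i}_x{t.total}\n{t.sequence}\n")
    pd.DataFrame(
        [{"sequence": t.sequence, "annotation": t.annotation, **t.counts}
         for t in tags]).to_csv(d / "tags.tsv", sep="\t", index=False)

    # 03 discover
    d = _stage_dir(out, 3, "discover")
    index = GenomeIndex({"chr1": genome}, k=cfg.min_len)
    params = discovery.DiscoveryParams(
        min_mature_reads=cfg.min_mature, min_star_reads=cfg.min_star,
        max_space=cfg.max_space, max_bulge=cfg.max_bulge,
        max_hits=cfg.max_hits)
    loci = discovery.call_loci(clean, index, params)
    accepted = [l for l in loci if l.accepted]
    reasons = pd.Series([l.status for l in loci]).value_counts()
    logger.info("discover: %s", reasons.to_dict())
    _loci_gff3(accepted, d / "loci.gff3")
    write_fasta({l.id: rna_to_dna(l.mature_seq) for l in accepted},
                d / "mature.fa")
    counts = pd.DataFrame(
        [{"id": l.id, **{f"mature_{k}": v for k, v in l.mature_reads.items()},
          **{f"star_{k}": v for k, v in l.star_reads.items()}}
         for l in accepted]).fillna(0)
    counts.to_csv(d / "counts.tsv", sep="\t", index=False)
    spectrum, mode = discovery.length_spectrum(loci)
    bias = discovery.first_nt_bias(loci)
    pd.DataFrame({"length": list(spectrum), "fraction": list(spectrum.values())}
                 ).to_csv(d / "length_spectrum.tsv", sep="\t", index=False)
    logger.info("discover: modal length %s, 5' U fraction %.3f", mode,
                bias.get("U", 0.0))

    # 04 profiles
    d = _stage_dir(out, 4, "profiles")
    usage = [profiles.arm_usage_from_locus(l, cfg.dominance_ratio)
             for l in accepted]
    pd.DataFrame([dataclasses.asdict(u) for u in usage]).to_csv(
        d / "arm_usage.tsv", sep="\t", index=False)
    mature_p, star_p = _isomir_profiles(accepted, clean, index)
    contrast, sign_p = profiles.fidelity_contrast(mature_p, star_p)
    contrast.to_csv(d / "fidelity.tsv", sep="\t", index=False)
    (d / "fidelity_sign_test.txt").write_text(f"p={sign_p}\n")

    # 05 homologs
    d = _stage_dir(out, 5, "homologs")
    sister_names = ("sisterA", "sisterB")
    hits_per_genome = {}
    for name in sister_names:
        sister = sd.make_sister_genome(genome, truth,
                                       sim.homolog_mutation_rate, rng)
        sidx = GenomeIndex({"chr1": sister}, k=cfg.word)
        hp = comparative.HomologParams(word=cfg.word, flank=cfg.flank,
                                       max_space=cfg.max_space,
                                       max_bulge=cfg.max_bulge)
        hits_per_genome[name] = {
            l.id: comparative.homolog_search(l.id, l.mature_seq, name, sidx, hp)
            for l in accepted}
    classes, fractions = comparative.classify_conservation(
        [l.id for l in accepted], hits_per_genome)
    pd.DataFrame([{"id": k, "class": v} for k, v in classes.items()]).to_csv(
        d / "conservation.tsv", sep="\t", index=False)
    logger.info("homologs: %s", fractions)

    # 06 clusters
    d = _stage_dir(out, 6, "clusters")
    rows = [(l.id, "wbph_sim", l.chrom, l.start, l.end, l.mature_seq)
            for l in accepted]
    clusters = comparative.find_clusters(rows, max_gap=cfg.max_gap)
    pd.DataFrame([{"cluster": c.cluster_id, "chrom": c.chrom,
                   "members": ",".join(c.members),
                   "gaps": ",".join(map(str, c.gaps))} for c in clusters]
                 ).to_csv(d / "clusters.tsv", sep="\t", index=False)

    # 07 targets
    d = _stage_dir(out, 7, "targets")
    mirnas = {l.id: l.mature_seq for l in accepted}
    utrs, site_truth = sd.simulate_transcriptome(
        mirnas, seed=cfg.rng_seed + 7)
    pairs, summary = regulation.consensus_targets(
        mirnas, utrs, seed_len=cfg.seed_len, dg_cutoff=cfg.dg_cutoff)
    pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
        d / "targets.tsv", sep="\t", index=False)
    summary.to_csv(d / "targets_per_mirna.tsv", sep="\t", index=False)

    # 08 diffexp
    d = _stage_dir(out, 8, "diffexp")
    matrix = pd.DataFrame(
        {lib: [l.mature_reads.get(lib, 0) for l in accepted]
         for lib in reads.libraries},
        index=[l.id for l in accepted])
    de = regulation.de_test(matrix, reads.conditions, p_cutoff=cfg.p_cutoff)
    de.to_csv(d / "diffexp.tsv", sep="\t")
    matrix.to_csv(d / "count_matrix.tsv", sep="\t")
    pd.Series(reads.conditions).to_csv(d / "conditions.tsv", sep="\t",
                                       header=["condition"])
    logger.info("diffexp: %s", de["biased"].value_counts().to_dict())

    # 09 enrich
    d = _stage_dir(out, 9, "enrich")
    universe = set(utrs)
    term_rng = np.random.default_rng(cfg.rng_seed + 9)
    terms = [f"TERM:{i:04d}" for i in range(10)]
    term_map = {g: {terms[term_rng.integers(0, len(terms))]}
                for g in sorted(universe)}
    biased_ids = set(de.index[de["biased"] != "none"])
    gene_set = {p.gene_id for p in pairs
                if p.consensus and p.mirna_id in biased_ids}
    enrich = regulation.fisher_enrichment(gene_set, universe, term_map)
    enrich.to_csv(d / "enrichment.tsv", sep="\t", index=False)

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            manifest[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _truth_gff3(truth: sd.TruthTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in truth:
            s, e = interval_to_gff3(rec.start, rec.end)
            fh.write(f"{rec.chrom}\tmirnaforge_sim\tpre_miRNA\t{s}\t{e}\t.\t"
                     f"{rec.strand}\t.\tID={rec.locus_id}\n")


def _loci_gff3(loci, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            s, e = interval_to_gff3(l.start, l.end)
            fh.write(f"{l.chrom}\tmirnaforge\tpre_miRNA\t{s}\t{e}\t.\t"
                     f"{l.strand}\t.\tID={l.id}\n")
            ms, me = l.mature_genomic()
            s, e = interval_to_gff3(ms, me)
            fh.write(f"{l.chrom}\tmirnaforge\tmiRNA\t{s}\t{e}\t.\t"
                     f"{l.strand}\t.\tID={l.id}_mature;Parent={l.id}\n")


def _isomir_profiles(accepted, clean_tags, index):
    """Offset spectra for mature and star species of each accepted locus."""
    from .seqcore import map_exact

    mature_p, star_p = [], []
    for locus in accepted:
        m5_local = locus.mature[0]
        s5_local = locus.star[0] if locus.star else None
        m_offsets: dict[int, int] = {}
        s_offsets: dict[int, int] = {}
        for tag in clean_tags:
            for chrom, (s, e), strand in map_exact(tag.sequence, index):
                if chrom != locus.chrom or strand != locus.strand:
                    continue
                if not (locus.start <= s and e <= locus.end):
                    continue
                p5 = s if strand == "+" else e
                local = (p5 - locus.start) if strand == "+" \
                    else (locus.end - p5)
                for ref5, dest in ((m5_local, m_offsets),
                                   (s5_local, s_offsets)):
                    if ref5 is not None and abs(local - ref5) <= 2:
                        dest[local - ref5] = dest.get(local - ref5, 0) \
                            + tag.total
        try:
            mature_p.append(profiles.isomir_profile(locus.id, "mature",
                                                    m_offsets))
            star_p.append(profiles.isomir_profile(locus.id, "star",
                                                  s_offsets))
        except ValueError:
            continue  # no in-window reads for one species
    return mature_p, star_p
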