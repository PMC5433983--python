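"""End-to-end drivers: simulate -> genotype -> statistics.

A :class:`PipelineConfig` names every rate, threshold and permutation count
with the study defaults (clustering branch cutoff 0.1, 20% read-fraction
rule, 110 / 3,024 / 100,000 permutations, 500 bootstrap replicates,
10-codon windows) and one master seed.  The master seed expands into
per-stage seeds through a fixed counter scheme, so each stage is
independently reproducible and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import amova, divstats, fileio, genotyper, selection, synthgen
from .catalog import AlleleCatalog, pairwise_differences

#: fixed stage indices for seed expansion
_STAGES = ("alleles", "population", "reads", "duplicates", "hwe", "ewens",
           "phi_st", "amova", "ztest", "scan_a", "scan_b")


def stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the master seed by counter."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(master), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SiteSpec:
    site: str
    river: str
    position: str           # upstream | downstream
    n_individuals: int = 16
    freqs: list[float] | None = None
    inbreeding_f: float = 0.0


def _default_sites() -> list[SiteSpec]:
    return [SiteSpec(s, r, p) for s, r, p in
            [("BOW1", "Bow", "upstream"), ("BOW7", "Bow", "downstream"),
             ("OLD1", "Oldman", "upstream"), ("OLD8", "Oldman", "downstream"),
             ("MILK1", "Milk", "upstream"), ("MILK2", "Milk", "downstream")]]


@dataclass
class PipelineConfig:
    seed: int = 1
    # simulation
    n_alleles: int = 8
    exon_len: int = 207
    intron_len: int = 29
    n_segregating: int = 16
    sub_rate: float = 0.002
    hp_indel_rate: float = 0.002
    allele_balance: float = 0.5
    depth: int | None = 500          # None -> log-uniform over [101, 14027]
    duplicate_fraction: float = 0.27
    sites: list[SiteSpec] = field(default_factory=_default_sites)
    # genotyper thresholds
    min_branch: float = 0.1
    min_fraction: float = 0.2
    min_support: int = 2
    allow_singletons: bool = False
    min_depth: int = 20
    # statistics
    phi_permutations: int = 110
    amova_permutations: int = 3024
    mantel_permutations: int = 100_000
    hwe_chain_steps: int = 100_000
    hwe_dememorization: int = 1_000
    ewens_simulations: int = 1_000
    bootstrap_replicates: int = 500
    window_codons: int = 10
    scan_permutations: int = 200
    scan_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must lie in (0, 1)")
        if self.min_branch <= 0:
            raise ValueError("min_branch must be positive")
        if self.min_support < 1:
            raise ValueError("min_support must be at least 1")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sites" in d:
            d["sites"] = [SiteSpec(**s) for s in d["sites"]]
        return cls(**d)

    @property
    def digest(self) -> str:
        return fileio.config_digest(json.dumps(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# simulation stage
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    catalog: AlleleCatalog
    truths: list[synthgen.TruthRecord]
    readsets: list[synthgen.SampleReadSet]
    replicate_pairs: list[tuple[str, str]]


def simulate(config: PipelineConfig) -> SimulatedDataset:
    catalog = synthgen.gen_allele_pool(
        config.n_alleles, config.exon_len, config.intron_len,
        config.n_segregating, seed=stage_seed(config.seed, "alleles"))
    rng = np.random.Generator(np.random.PCG64(stage_seed(config.seed, "reads")))
    truths: list[synthgen.TruthRecord] = []
    readsets: list[synthgen.SampleReadSet] = []
    for si, spec in enumerate(config.sites):
        freqs = spec.freqs
        if freqs is None:
            # broken-stick style frequencies: common alleles plus rare tail
            raw = np.sort(rng.dirichlet(np.full(config.n_alleles, 0.8)))[::-1]
            freqs = (raw / raw.sum()).tolist()
        pop = synthgen.gen_population(
            catalog, freqs, spec.n_individuals, spec.inbreeding_f,
            seed=stage_seed(config.seed, "population") + si,
            site_code=spec.site)
        truths.extend(pop)
        for t in pop:
            depth = config.depth if config.depth is not None \
                else synthgen.draw_depth(rng)
            readsets.append(synthgen.gen_reads(
                t, catalog, depth, config.sub_rate, config.hp_indel_rate,
                config.allele_balance, seed=int(rng.integers(2 ** 31))))
    rep_sets, rep_truths = synthgen.make_duplicates(
        readsets, truths, catalog, config.duplicate_fraction,
        config.sub_rate, config.hp_indel_rate, config.allele_balance,
        seed=stage_seed(config.seed, "duplicates"))
    pairs = [(r.replicate_of, r.individual_id) for r in rep_sets]
    return SimulatedDataset(catalog, truths + rep_truths,
                            readsets + rep_sets, pairs)


# ---------------------------------------------------------------------------
# genotyping stage
# ---------------------------------------------------------------------------

def genotype_readsets(readsets: Sequence[synthgen.SampleReadSet],
                      config: PipelineConfig,
                      site_by_individual: dict[str, str] | None = None,
                      ) -> tuple[AlleleCatalog, genotyper.GenotypeTable]:
    putative = [genotyper.cluster_within_sample(rs, config.min_branch)
                for rs in readsets]
    catalog = genotyper.build_consensus_alleles(
        putative, config.min_support, config.allow_singletons,
        exon_span=(0, config.exon_len))
    rows = []
    for rs in readsets:
        site = (site_by_individual or {}).get(rs.individual_id)
        rows.append(genotyper.assign_genotypes(
            rs, catalog, config.min_fraction, config.min_depth, site))
    return catalog, genotyper.GenotypeTable(rows)


def genotype_recovery(table: genotyper.GenotypeTable,
                      called_catalog: AlleleCatalog,
                      truths: Sequence[synthgen.TruthRecord],
                      true_catalog: AlleleCatalog) -> float:
    """Fraction of samples whose called allele *sequences* match the truth.

    Called and true catalogs label alleles independently, so genotypes are
    compared at the sequence level.
    """
    true_seq = {a: s for a, s in true_catalog.alleles}
    called_seq = {a: s for a, s in called_catalog.alleles}
    truth_by_id = {t.individual_id: t for t in truths}
    n = hit = 0
    for row in table:
        t = truth_by_id.get(row.individual_id)
        if t is None:
            continue
        n += 1
        want = {true_seq[a] for a in t.true_alleles}
        got = {called_seq[a] for a in row.called_alleles}
        hit += row.flag == "ok" and got == want
    if n == 0:
        raise ValueError("no genotyped samples overlap the truth records")
    return hit / n


# ---------------------------------------------------------------------------
# statistics stages
# ---------------------------------------------------------------------------

def diversity_report(table: divstats.AlleleCountTable,
                     catalog: AlleleCatalog,
                     genotypes_by_site: dict[str, list[tuple[str, str]]] | None = None,
                     ) -> pd.DataFrame:
    rows = []
    for site in table.sites:
        counts = table.counts(site)
        if counts.sum() < 2:
            continue
        genos = (genotypes_by_site or {}).get(site)
        s = divstats.diversity_summary(site, catalog, counts, genos)
        rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def amova_records(table: genotyper.GenotypeTable,
                  catalog: AlleleCatalog,
                  site_meta: pd.DataFrame,
                  exclude: set[str] = frozenset()) -> list[amova.DiploidRecord]:
    river_of = dict(zip(site_meta["site"], site_meta["river"]))
    index = {a: i for i, a in enumerate(catalog.ids)}
    recs = []
    for row in table:
        if row.flag != "ok" or row.individual_id in exclude:
            continue
        if row.replicate_of is not None or not row.site_code:
            continue
        alleles = list(row.called_alleles)
        if len(alleles) == 1:
            alleles = alleles * 2
        recs.append(amova.DiploidRecord(
            row.individual_id, row.site_code, river_of[row.site_code],
            index[alleles[0]], index[alleles[1]]))
    return recs


def selection_report(catalog: AlleleCatalog,
                     table: divstats.AlleleCountTable,
                     config: PipelineConfig) -> pd.DataFrame:
    """Per-site Nei-Gojobori dN/dS and codon Z-test on the exon alignment,
    weighted by allele copy counts."""
    exon = catalog.exon_codon_sequences()
    rows = []
    for site in table.sites:
        counts = table.counts(site)
        present = counts > 0
        if present.sum() < 2:
            continue
        aln = selection.CodonAlignment(
            tuple(s for s, keep in zip(exon, present) if keep))
        w = counts[present].astype(float)
        ng = selection.nei_gojobori(aln, w)
        z, p = selection.codon_z_test(aln, w, config.bootstrap_replicates,
                                      seed=stage_seed(config.seed, "ztest"))
        rows.append({"site": site, "syn_sites": ng.syn_sites,
                     "nonsyn_sites": ng.nonsyn_sites, "pS": ng.pS,
                     "pN": ng.pN, "dS": ng.dS, "dN": ng.dN,
                     "dN_dS": ng.ratio, "Z": z, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate, genotype and analyse one synthetic data set.

    Writes the catalog FASTA, truth and genotype TSVs, the repeatability
    report, the allele-count table, diversity / AMOVA / pairwise Phi_ST /
    selection TSVs, the NJ allele tree, and a run log.  Returns the main
    results in memory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest
    log: list[str] = [f"config digest {digest}", f"master seed {config.seed}"]

    sim = simulate(config)
    sim.catalog.to_fasta(outdir / "true_catalog.fasta")
    synthgen.write_truth_tsv(sim.truths, outdir / "truth.tsv")
    site_of = {t.individual_id: t.site_code for t in sim.truths}

    called_catalog, genotypes = genotype_readsets(sim.readsets, config, site_of)
    called_catalog.to_fasta(outdir / "called_catalog.fasta")
    fileio.write_genotype_table(genotypes, outdir / "genotypes.tsv", digest)

    rep = genotyper.estimate_repeatability(genotypes, sim.replicate_pairs)
    exclude = {a for a, _ in rep.discordant}
    (outdir / "repeatability.txt").write_text(
        f"replicate pairs: {rep.n_pairs}\n"
        f"discordant: {len(rep.discordant)}\n"
        f"repeatability: {rep.percent:.1f}%\n"
        f"excluded individuals: {sorted(exclude)}\n")
    log.append(f"repeatability {rep.percent:.1f}% over {rep.n_pairs} pairs")

    site_meta = pd.DataFrame([{"site": s.site, "river": s.river,
                               "position": s.position} for s in config.sites])
    primary = genotyper.GenotypeTable(
        [r for r in genotypes
         if r.replicate_of is None and r.individual_id not in exclude])
    counts = fileio.counts_from_genotypes(primary, called_catalog, site_meta)
    fileio.write_counts_table(counts, outdir / "allele_counts.tsv", digest)

    genos_by_site: dict[str, list[tuple[str, str]]] = {}
    for row in primary:
        if row.flag != "ok":
            continue
        a = list(row.called_alleles)
        if len(a) == 1:
            a = a * 2
        genos_by_site.setdefault(row.site_code, []).append((a[0], a[1]))

    div = diversity_report(counts, called_catalog, genos_by_site)
    fileio.write_tsv(div, outdir / "diversity.tsv", digest)

    # per-site equilibrium tests on the called genotypes
    eq_rows = []
    for site, genos in sorted(genos_by_site.items()):
        if len(genos) < 2:
            continue
        hwe_p = divstats.hwe_exact_test(
            genos, config.hwe_chain_steps, config.hwe_dememorization,
            seed=stage_seed(config.seed, "hwe"))
        site_counts = counts.counts(site)
        if (site_counts > 0).sum() >= 2:
            ew_f, ew_p = divstats.ewens_watterson_test(
                site_counts, config.ewens_simulations,
                seed=stage_seed(config.seed, "ewens"))
        else:
            ew_f, ew_p = float("nan"), float("nan")
        eq_rows.append({"site": site, "hwe_p": hwe_p,
                        "ew_F_obs": ew_f, "ew_p": ew_p})
    fileio.write_tsv(pd.DataFrame(eq_rows), outdir / "equilibrium.tsv", digest)

    recs = amova_records(genotypes, called_catalog, site_meta, exclude)
    diffs = pairwise_differences(called_catalog)
    am = amova.hierarchical_amova(recs, diffs, config.amova_permutations,
                                  seed=stage_seed(config.seed, "amova"))
    fileio.write_tsv(am.to_dataframe(), outdir / "amova.tsv", digest)

    # pairwise Phi_ST matrix between sites
    by_site: dict[str, list[tuple[int, int]]] = {}
    for r in recs:
        by_site.setdefault(r.site, []).append((r.a1, r.a2))
    site_list = sorted(by_site)
    phi = np.zeros((len(site_list),) * 2)
    phi_p = np.ones((len(site_list),) * 2)
    for i in range(len(site_list)):
        for j in range(i + 1, len(site_list)):
            phi[i, j], phi_p[i, j] = amova.phi_st(
                by_site[site_list[i]], by_site[site_list[j]], diffs,
                config.phi_permutations,
                seed=stage_seed(config.seed, "phi_st"))
            phi[j, i], phi_p[j, i] = phi[i, j], phi_p[i, j]
    fileio.write_distance_matrix(site_list, phi, outdir / "phi_st.tsv", digest)
    fileio.write_distance_matrix(site_list, phi_p, outdir / "phi_st_p.tsv",
                                 digest)

    sel = selection_report(called_catalog, counts, config)
    fileio.write_tsv(sel, outdir / "selection.tsv", digest)

    # NJ tree over the alleles actually called somewhere (spurious
    # recurrent-error catalog entries never attract 20% of reads and may
    # carry indels, so they are left out of the alignment-based tree)
    pooled = counts.pooled(list(counts.sites)) if counts.sites else []
    tree_ids = [a for a, c in zip(called_catalog.ids, pooled) if c > 0]
    tree_seqs = [called_catalog.sequence(a) for a in tree_ids]
    if len(tree_ids) >= 3 and len({len(s) for s in tree_seqs}) == 1:
        jc = np.zeros((len(tree_ids),) * 2)
        for i in range(len(tree_seqs)):
            for j in range(i + 1, len(tree_seqs)):
                jc[i, j] = jc[j, i] = selection.jc_distance(
                    tree_seqs[i], tree_seqs[j])
        fileio.write_newick(selection.nj_tree(tree_ids, jc),
                            outdir / "alleles.nwk")

    config.to_yaml(outdir / "config.yaml")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return {"catalog": called_catalog, "genotypes": genotypes,
            "repeatability": rep, "counts": counts, "diversity": div,
            "amova": am, "selection": sel, "truths": sim.truths}
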