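"""End-to-end orchestration of the selection scan on synthetic inputs.

``run_pipeline`` chains the stages — sequence simulation, ortholog
inference, codon QC filtering, branch-model rates, branch-site scan,
population simulation, SNP tagging, and the F_ST outlier scan — into a
run directory of TSV tables, every one stamped with the config hash,
seed, and stage name so a run is fully reproducible and auditable.
Outputs contain no timestamps: two runs with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .alignment import CodonAlignment
from .codon_ml import SiteClassMix, fit_branch_site
from .codon_filter import FilterThresholds, filter_orthologs, write_filter_reports
from .fst_outlier import (
    McmcSettings,
    allele_counts_from_genotypes,
    bayescan_scan,
    hwe_exact,
    transect_consistency,
    wc_fst,
)
from .orthology import best_reciprocal_hits, translated_hit_table, write_ortholog_pairs
from .rate_tests import binomial_rate_test, bootstrap_branch_rates, concatenate
from .simulate import (
    IslandModelParams,
    ReadSimParams,
    SeqSimParams,
    simulate_allele_counts,
    simulate_codon_alignment,
    simulate_genotypes,
    simulate_read_counts,
)
from .snp_tagging import call_snps, select_tag_snps, write_site_counts, write_tag_snps
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_DEFAULT_TREE = (
    "(outgroup:0.45,(low_rana:0.08,high_rana:0.08 #1):0.2,"
    "(low_bufo:0.05,high_bufo:0.05):0.2);"
)


@dataclass
class PipelineConfig:
    """All thresholds, sizes, and seeds of one pipeline run.

    Thresholds default to the analysis settings of the altitudinal
    amphibian scan: BRH e-value 1e-10, minimum alignment 200 nt,
    synonymous-saturation cap dS = 3, PSG p < 0.05, outlier q < 0.05,
    rare-allele coverage > 20.
    """

    seed: int = 1
    out_dir: str = "pipeline_run"
    # orthology / filtering
    e_value: float = 1e-10
    min_len: int = 200
    ds_cap: float = 3.0
    # selection tests
    p_psg: float = 0.05
    q_outlier: float = 0.05
    n_bootstrap: int = 1000
    # SNP calling
    min_rare_coverage: int = 20
    mean_coverage: float = 250.0
    error_rate: float = 0.001
    # synthetic sequence panel
    n_genes: int = 10
    n_codons: int = 200
    n_psg_genes: int = 2
    #: append one 66-codon (198 nt) gene to exercise the length filter
    plant_short_gene: bool = False
    omega0: float = 0.2
    omega2: float = 8.0
    kappa: float = 2.0
    tree: str = _DEFAULT_TREE
    # synthetic population panel
    n_loci: int = 60
    n_pops: int = 5
    n_individuals: int = 20
    beta: float = -1.0
    n_outlier_loci: int = 3
    alpha_planted: float = 3.5
    # MCMC (scaled down from the BayeScan-equivalent defaults for desk runs)
    mcmc_burn_in: int = 5000
    mcmc_samples: int = 2000
    mcmc_thinning: int = 1
    mcmc_pilots: int = 5
    mcmc_pilot_length: int = 500
    transects: tuple = ((1, 2, 3), (4, 5))

    def config_hash(self) -> str:
        # out_dir is excluded: where a run lands must not change what it
        # computes, and identical analyses should share a hash
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are errors (fail fast)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "transects" in raw:
        raw["transects"] = tuple(tuple(t) for t in raw["transects"])
    return PipelineConfig(**raw)


def _header(config: PipelineConfig, stage: str) -> str:
    return (
        f"altisel {__version__} | stage={stage} | "
        f"config={config.config_hash()} | seed={config.seed}"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(config, stage)}\n")
        df.to_csv(fh, sep="\t", index=False)


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-data pipeline and write a run directory.

    Stages: simulate-seq -> orthologs -> filter -> scan-bs -> rate-test
    -> simulate-pop -> call-snps -> outlier -> report. Any stage error
    halts the run with the stage name; outputs of completed stages are
    preserved. Returns the summary dictionary (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    stage = "setup"
    try:
        tree = Phylogeny.from_newick(config.tree)
        foreground = sorted(tree.foreground)

        # ---- simulate-seq ------------------------------------------------
        stage = "simulate-seq"
        genes, truth_rows = _simulate_gene_panel(config, tree)
        seq_dir = out / "alignments"
        seq_dir.mkdir(exist_ok=True)
        for aln in genes:
            aln.to_fasta(seq_dir / f"{aln.gene_id}.fasta")
        _write_tsv(pd.DataFrame(truth_rows), out / "gene_truth.tsv", config, stage)

        # ---- orthologs ---------------------------------------------------
        stage = "orthologs"
        taxa_pair = [t for t in tree.taxa if t != tree.taxa[0]][:1]
        set_a = {f"{a.gene_id}|a": a.sequences[0] for a in genes}
        set_b = {
            f"{a.gene_id}|b": a.sequences[a.taxon_ids.index(taxa_pair[0])]
            for a in genes
        }
        hits_ab = translated_hit_table(set_a, set_b)
        hits_ba = translated_hit_table(set_b, set_a)
        pairs = best_reciprocal_hits(hits_ab, hits_ba, config.e_value)
        write_ortholog_pairs(
            pairs, out / "orthologs.tsv", header_comment=_header(config, stage)
        )
        summary["n_ortholog_pairs"] = len(pairs)

        # ---- filter ------------------------------------------------------
        stage = "filter"
        thresholds = FilterThresholds(
            min_length_nt=config.min_len, ds_cap=config.ds_cap
        )
        retained, reports = filter_orthologs(genes, thresholds)
        write_filter_reports(
            reports, out / "filter_reports.tsv", header_comment=_header(config, stage)
        )
        summary["n_genes_input"] = len(genes)
        summary["n_genes_retained"] = len(retained)

        # ---- scan-bs -----------------------------------------------------
        stage = "scan-bs"
        lrt_rows = []
        for aln in retained:
            res = fit_branch_site(aln, tree, p_threshold=config.p_psg)
            lrt_rows.append(
                {
                    "gene_id": aln.gene_id,
                    "lnl_null": round(res.lrt.lnl_null, 6),
                    "lnl_alt": round(res.lrt.lnl_alt, 6),
                    "statistic": round(res.lrt.statistic, 6),
                    "p_value": res.lrt.p_value,
                    "is_psg": int(res.lrt.is_psg),
                }
            )
        lrt_df = pd.DataFrame(lrt_rows)
        _write_tsv(lrt_df, out / "branch_site_lrt.tsv", config, stage)
        psgs = sorted(lrt_df.loc[lrt_df.is_psg == 1, "gene_id"])
        summary["n_psg"] = len(psgs)
        summary["psg_genes"] = psgs

        # ---- rate-test ---------------------------------------------------
        stage = "rate-test"
        concat = concatenate(retained)
        partition = {b: b for b in tree.branches}
        boot = bootstrap_branch_rates(
            concat,
            tree,
            partition,
            n_rep=config.n_bootstrap,
            seed=config.seed,
        )
        omega_df = pd.DataFrame(boot.omega)
        _write_tsv(omega_df, out / "bootstrap_omega.tsv", config, stage)
        summary["branch_omega"] = {
            b: round(float(boot.point_estimate.omega_map[b]), 4)
            for b in tree.branches
        }
        if foreground:
            fg = foreground[0]
            sibling = _sibling_leaf(tree, fg)
            if sibling is not None:
                summary["rate_test_p"] = binomial_rate_test(
                    boot.omega[fg], boot.omega[sibling]
                )

        # ---- simulate-pop ------------------------------------------------
        stage = "simulate-pop"
        alpha = np.zeros(config.n_loci)
        alpha[: config.n_outlier_loci] = config.alpha_planted
        pop_params = IslandModelParams(
            n_pops=config.n_pops,
            n_loci=config.n_loci,
            beta=config.beta,
            alpha=alpha,
            sample_sizes=2 * config.n_individuals,
            seed=config.seed,
        )
        counts, pop_truth = simulate_allele_counts(pop_params)
        genotypes = simulate_genotypes(
            pop_truth["pop_freqs"], config.n_individuals, seed=config.seed
        )
        counts = allele_counts_from_genotypes(genotypes)
        counts.to_tsv(out / "allele_counts.tsv", header_comment=_header(config, stage))

        # ---- call-snps ---------------------------------------------------
        stage = "call-snps"
        pooled = pop_truth["pop_freqs"].mean(axis=1)
        # three candidate sites per nutrient-metabolism gene, so tag-SNP
        # selection (<= 2 per gene) has something to rank
        read_sites = []
        for g in range(0, len(pooled), 3):
            chunk = simulate_read_counts(
                pooled[g : g + 3],
                ReadSimParams(
                    mean_coverage=config.mean_coverage,
                    error_rate=config.error_rate,
                    seed=config.seed + g,
                ),
                gene_id=f"tagged_gene{g // 3:03d}",
            )
            read_sites.extend(chunk)
        write_site_counts(
            read_sites, out / "site_counts.tsv", header_comment=_header(config, stage)
        )
        snps = call_snps(read_sites, config.min_rare_coverage)
        tags = select_tag_snps(snps)
        write_tag_snps(tags, out / "tag_snps.tsv", header_comment=_header(config, stage))
        summary["n_snps_called"] = len(snps)
        summary["n_tag_snps"] = len(tags)

        # ---- hwe + outlier -----------------------------------------------
        stage = "outlier"
        hwe_rows = []
        for i, locus in enumerate(genotypes.locus_ids):
            for pop in genotypes.population_names:
                n_aa, n_het, n_bb = genotypes.genotype_counts(i, pop)
                hwe_rows.append(
                    {
                        "locus_id": locus,
                        "pop": pop,
                        "p_hwe": hwe_exact(n_aa, n_het, n_bb),
                    }
                )
        _write_tsv(pd.DataFrame(hwe_rows), out / "hwe.tsv", config, stage)

        settings = McmcSettings(
            n_iter=config.mcmc_burn_in + config.mcmc_samples * config.mcmc_thinning,
            burn_in=config.mcmc_burn_in,
            thinning=config.mcmc_thinning,
            n_pilot=config.mcmc_pilots,
            pilot_length=config.mcmc_pilot_length,
            seed=config.seed,
        )
        analyses = {"global": counts}
        pop_names = counts.populations
        for t, pops in enumerate(config.transects, start=1):
            analyses[f"transect{t}"] = counts.subset_populations(
                [pop_names[i - 1] for i in pops]
            )
        results = {}
        for name, table in analyses.items():
            scan = bayescan_scan(table, settings)
            fst = wc_fst(table)
            sub = out / name
            sub.mkdir(exist_ok=True)
            df = scan.to_frame()
            df["wc_fst"] = [
                fst["per_locus_fst"][table.locus_ids.index(l)]
                for l in df["locus_id"]
            ]
            _write_tsv(df, sub / "outliers.tsv", config, f"{stage}:{name}")
            results[name] = scan
            summary[f"outliers_{name}"] = sorted(
                r.locus_id for r in scan.results if r.selection_class != "neutral"
            )
        consistent = transect_consistency(
            results["global"].results,
            [results[k].results for k in results if k != "global"],
        )
        _write_tsv(consistent, out / "consistent_outliers.tsv", config, stage)
        summary["consistent_outliers"] = list(consistent["locus_id"])

        # ---- report ------------------------------------------------------
        stage = "report"
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
    except Exception as exc:  # halt with the stage name, keep partial outputs
        raise StageFailure(stage, exc) from exc
    return summary


def _simulate_gene_panel(config: PipelineConfig, tree: Phylogeny):
    """Simulated ortholog panel: mostly clean genes, a few planted PSGs."""
    genes = []
    rows = []
    n_total = config.n_genes + int(config.plant_short_gene)
    for g in range(n_total):
        short = config.plant_short_gene and g == n_total - 1
        planted = g < config.n_psg_genes
        omega2 = config.omega2 if planted else 1.0
        mix = SiteClassMix(0.65, 0.25, config.omega0, omega2)
        params = SeqSimParams(
            tree=tree,
            kappa=config.kappa,
            site_mix=mix,
            n_codons=66 if short else config.n_codons,  # 66 codons = 198 nt
            seed=config.seed * 10_000 + g,
        )
        aln, _ = simulate_codon_alignment(params)
        aln.gene_id = f"gene{g:03d}"
        genes.append(aln)
        rows.append(
            {"gene_id": aln.gene_id, "planted_psg": int(planted), "omega2": omega2}
        )
    return genes, rows


def _sibling_leaf(tree: Phylogeny, branch: str) -> str | None:
    node = tree.nodes_by_name[branch]
    if node.parent is None:
        return None
    for sib in node.parent.children:
        if sib is not node and sib.is_leaf:
            return sib.name
    return None
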