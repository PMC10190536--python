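"""End-to-end orchestration over a directory layout.

``run_all`` executes simulate -> ingest -> DES calling -> patterns ->
enrichment -> prognosis -> triplet screen -> motif-window export, writing
every result as TSV/FASTA plus a JSON manifest that records the seed,
thresholds and input checksums, so a run can be reproduced exactly from
the manifest alone. All randomness flows from the single config seed;
re-running with the same config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import editing_core as ec
from . import enrichment as en
from . import io_formats as io
from . import mirna as mi
from . import prognosis as pr
from . import synthetic as syn

log = logging.getLogger(__name__)

INPUT_FILES = {
    "editing": "editing_matrix.tsv",
    "response": "response.tsv",
    "annotation": "annotation.tsv",
    "utr_fasta": "utr_sequences.fasta",
    "mirna_fasta": "mirna_sequences.fasta",
    "utr_sites": "utr_sites.tsv",
    "gene_expr": "gene_expression.tsv",
    "mirna_expr": "mirna_expression.tsv",
    "adar_expr": "adar_expression.tsv",
    "survival": "survival.tsv",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds, mode switches and simulation settings for one run."""

    outdir: str = "editscape_results"
    seed: int = 0
    alpha: float = 0.05
    min_diff: float = 0.05
    min_per_group: int = 3
    z_cut: float = 0.8
    flank: int = 20
    wilcoxon_mode: str = "auto"
    under_edited_rule: bool = True
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    n_mirnas: int = 4
    n_gain: int = 2
    n_loss: int = 2
    utr_length: int = 300
    n_utr_genes: int = 8
    correlation_strength: float = 0.9
    indir: str | None = None  # read pre-existing inputs instead of simulating

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_diff", "min_per_group", "z_cut", "flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_yaml(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Inputs:
    profile: io.EditingProfile
    response: pd.DataFrame
    annotation: pd.DataFrame
    utrs: dict[str, str]  # gene -> RNA sequence
    mirnas: dict[str, str]
    utr_sites: pd.DataFrame  # site_id, gene_id, utr_pos
    gene_expr: pd.DataFrame
    mirna_expr: pd.DataFrame
    adar_expr: pd.DataFrame
    survival: pd.DataFrame


# ---------------------------------------------------------------------------
# simulate stage


def simulate_inputs(config: PipelineConfig, indir: Path) -> None:
    """Generate every pipeline input with known ground truth into ``indir``.

    The tabular editing profile, response labels, annotation, UTR and
    miRNA sequences, expression tables, ADAR expression and survival
    table are all derived from the single config seed. A handful of
    planted over-editing DESs are relocated onto the synthetic 3'-UTRs
    so the rewiring truth and the editing truth name the same sites.
    Truth tables are written alongside the inputs for reference.
    """
    indir.mkdir(parents=True, exist_ok=True)
    sim_cfg = syn.SimConfig(seed=config.seed, **config.simulate)
    profile, response, truth = syn.simulate_editing_profile(sim_cfg)

    mirnas = syn.simulate_mirnas(config.n_mirnas, seed=config.seed + 1)
    utrs, utr_sites, triplet_truth = syn.simulate_utr_rewiring(
        n_genes=config.n_utr_genes,
        mirnas=mirnas,
        n_gain=config.n_gain,
        n_loss=config.n_loss,
        utr_length=config.utr_length,
        seed=config.seed + 2,
    )

    # graft the planted UTR editing sites onto planted over-editing DESs so
    # the triplet sites are genuine DESs in the editing matrix
    over_des = truth.sites[(truth.sites["is_des"]) & (truth.sites["planted_diff"] > 0)]
    n_events = len(utr_sites)
    if len(over_des) < n_events:
        raise ValueError(
            "not enough planted over-editing DESs to host the UTR rewiring sites"
        )
    rename = dict(zip(list(over_des.index[:n_events]), utr_sites["site_id"]))
    profile.levels = profile.levels.rename(index=rename)
    truth.sites = truth.sites.rename(index=rename)
    gene_of_site = dict(zip(utr_sites["site_id"], utr_sites["gene_id"]))
    for site_id, gene in gene_of_site.items():
        truth.sites.loc[site_id, ["region", "gene_id"]] = ["3'-UTR", gene]
    truth.triplets = triplet_truth

    labels = pd.Series(
        ["resistant"] * sim_cfg.n_resistant + ["sensitive"] * sim_cfg.n_sensitive,
        index=profile.sample_ids,
    )
    gene_expr, mirna_expr = syn.simulate_expression_for_triplets(
        triplet_truth,
        labels,
        correlation_strength=config.correlation_strength,
        seed=config.seed + 3,
        decoy_genes=sorted(set(utrs) - set(triplet_truth["gene_id"])),
        decoy_mirnas=sorted(set(mirnas) - set(triplet_truth["mirna_id"])),
    )

    oel = ec.compute_oel(profile).overall
    adar = syn.simulate_adar_expression(oel, sim_cfg.adar_r2_target, config.seed + 4)
    adar_expr = pd.DataFrame({s: [adar[s]] for s in adar.index}, index=["ADAR1"])

    # resistance drives outcome: resistant samples carry the elevated hazard,
    # so over-edited DESs (high in resistant samples) are risk factors and
    # under-edited DESs protective, as the prognosis stage expects
    hazard_groups = labels.map({"resistant": "over", "sensitive": "under"})
    survival = syn.simulate_survival(
        hazard_groups, sim_cfg.survival_hr, sim_cfg.censoring_rate, config.seed + 5
    )

    io.write_editing_matrix(profile, indir / INPUT_FILES["editing"])
    io.write_response(response, indir / INPUT_FILES["response"])
    io.write_annotation(syn.truth_to_annotation(truth), indir / INPUT_FILES["annotation"])
    io.write_fasta({g: mi.to_dna(s) for g, s in utrs.items()}, indir / INPUT_FILES["utr_fasta"])
    io.write_fasta({m: mi.to_dna(s) for m, s in mirnas.items()}, indir / INPUT_FILES["mirna_fasta"])
    utr_sites.to_csv(indir / INPUT_FILES["utr_sites"], sep="\t", index=False)
    io.write_expression(gene_expr, indir / INPUT_FILES["gene_expr"])
    io.write_expression(mirna_expr, indir / INPUT_FILES["mirna_expr"])
    io.write_expression(adar_expr, indir / INPUT_FILES["adar_expr"])
    io.write_survival(survival, indir / INPUT_FILES["survival"])
    truth.sites.to_csv(indir / "truth_sites.tsv", sep="\t")
    truth.triplets.to_csv(indir / "truth_triplets.tsv", sep="\t", index=False)


def load_inputs(indir: Path) -> Inputs:
    """Read and validate every input from a directory layout."""
    for key, fname in INPUT_FILES.items():
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing input file {fname!r} in {indir}")
    return Inputs(
        profile=io.read_editing_matrix(indir / INPUT_FILES["editing"]),
        response=io.read_response(indir / INPUT_FILES["response"]),
        annotation=io.read_annotation(indir / INPUT_FILES["annotation"]),
        utrs={k: mi.to_rna(v) for k, v in io.read_fasta(indir / INPUT_FILES["utr_fasta"]).items()},
        mirnas={k: mi.to_rna(v) for k, v in io.read_fasta(indir / INPUT_FILES["mirna_fasta"]).items()},
        utr_sites=pd.read_csv(indir / INPUT_FILES["utr_sites"], sep="\t"),
        gene_expr=io.read_expression(indir / INPUT_FILES["gene_expr"]),
        mirna_expr=io.read_expression(indir / INPUT_FILES["mirna_expr"]),
        adar_expr=io.read_expression(indir / INPUT_FILES["adar_expr"]),
        survival=io.read_survival(indir / INPUT_FILES["survival"]),
    )


# ---------------------------------------------------------------------------
# analysis stages


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Any stage failure raises :class:`StageError` naming the stage; the
    partial output directory is retained with a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "FAILED").unlink(missing_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "inputs": {},
        "counts": {},
    }
    try:
        result = _run_stages(config, outdir, manifest)
    except StageError:
        (outdir / "FAILED").write_text("see log for the failed stage\n")
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return result


def _run_stages(config: PipelineConfig, outdir: Path, manifest: dict) -> dict:
    indir = Path(config.indir) if config.indir else outdir / "inputs"

    if config.indir is None:
        try:
            simulate_inputs(config, indir)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("simulate", exc) from exc
        manifest["stages"].append("simulate")

    try:
        data = load_inputs(indir)
    except Exception as exc:
        raise StageError("ingest", exc) from exc
    manifest["stages"].append("ingest")
    for key, fname in INPUT_FILES.items():
        manifest["inputs"][fname] = _sha256(indir / fname)

    try:
        labeled = io.label_tumor_samples(data.response)
        conditions = io.build_conditions(labeled, config.min_per_group)
        if not conditions:
            raise ValueError("no condition with enough samples in both groups")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("conditions", exc) from exc
    manifest["counts"]["n_conditions"] = len(conditions)

    des_tables: dict[str, pd.DataFrame] = {}
    informative: dict[str, list[str]] = {}
    adar_lfc: dict[str, float] = {}

    try:
        oel = ec.compute_oel(data.profile, data.annotation)
        oel.overall.rename("oel").to_csv(outdir / "oel.tsv", sep="\t")
        if oel.by_region is not None:
            oel.by_region.to_csv(outdir / "oel_by_region.tsv", sep="\t")
        adar_series = data.adar_expr.loc["ADAR1"]
        reg = ec.regress_oel_on_expression(oel.overall, adar_series)
        pd.DataFrame(
            [dataclasses.asdict(reg)]
        ).to_csv(outdir / "adar_regression.tsv", sep="\t", index=False)
        manifest["counts"]["adar_r2"] = reg.r2
    except Exception as exc:
        raise StageError("oel", exc) from exc
    manifest["stages"].append("oel")

    try:
        for cond in conditions:
            sites = ec.find_informative_sites(data.profile, cond, config.min_per_group)
            des, full = ec.call_des(
                data.profile, cond,
                alpha=config.alpha, min_diff=config.min_diff,
                min_per_group=config.min_per_group, mode=config.wilcoxon_mode,
                sites=sites,
            )
            informative[cond.name] = sites
            des_tables[cond.name] = des
            full.to_csv(outdir / f"des_full_{cond.name}.tsv", sep="\t")
            des.to_csv(outdir / f"des_{cond.name}.tsv", sep="\t")
            adar_lfc[cond.name] = ec.log2_fold_change(adar_series, cond)
            manifest["counts"][f"n_informative_{cond.name}"] = len(sites)
            manifest["counts"][f"n_des_{cond.name}"] = len(des)
    except Exception as exc:
        raise StageError("des", exc) from exc
    manifest["stages"].append("des")

    try:
        patterns = ec.summarize_patterns(des_tables, adar_lfc)
        patterns.table.to_csv(outdir / "patterns.tsv", sep="\t")
        mm = ec.meet_min_matrix(
            {c: set(t.index) for c, t in des_tables.items() if len(t)}
        )
        mm.to_csv(outdir / "meet_min_des.tsv", sep="\t")
    except Exception as exc:
        raise StageError("patterns", exc) from exc
    manifest["stages"].append("patterns")

    try:
        region = en.integrative_region_enrichment(
            {c: set(t.index) for c, t in des_tables.items()},
            informative,
            data.annotation,
        )
        region.to_csv(outdir / "region_enrichment.tsv", sep="\t")
        for cond in conditions:
            gene = en.gene_enrichment(
                list(des_tables[cond.name].index), informative[cond.name], data.annotation
            )
            gene.to_csv(outdir / f"gene_enrichment_{cond.name}.tsv", sep="\t")
        per_cond, rollup = en.per_gene_summary(des_tables, data.annotation)
        per_cond.to_csv(outdir / "per_gene_summary.tsv", sep="\t", index=False)
        rollup.to_csv(outdir / "per_gene_rollup.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("enrich", exc) from exc
    manifest["stages"].append("enrich")

    try:
        all_des = sorted(set().union(*(set(t.index) for t in des_tables.values())))
        surv_results = pr.site_survival_scan(data.profile.levels, data.survival, all_des)
        surv_results.to_csv(outdir / "survival_results.tsv", sep="\t")
        des_union = pd.concat([t for t in des_tables.values()])
        des_union = des_union[~des_union.index.duplicated(keep="first")]
        flags, prop = pr.consistency_with_resistance(
            surv_results, des_union, alpha=config.alpha
        )
        flags.to_csv(outdir / "consistency.tsv", sep="\t")
        manifest["counts"]["n_prognostic_des"] = int(
            (surv_results["logrank_p"] < config.alpha).sum()
        )
        manifest["counts"]["consistency_fraction"] = None if pd.isna(prop) else prop
    except Exception as exc:
        raise StageError("prognosis", exc) from exc
    manifest["stages"].append("prognosis")

    try:
        events: list[mi.RewiringEvent] = []
        for gene, grp in data.utr_sites.groupby("gene_id"):
            positions = dict(zip(grp["site_id"], grp["utr_pos"].astype(int)))
            events.extend(
                mi.classify_rewiring(data.utrs[gene], positions, data.mirnas, gene)
            )
        pd.DataFrame(
            [
                (e.site_id, e.gene_id, e.mirna_id, e.utr_pos, e.kind)
                for e in events
            ],
            columns=["site_id", "gene_id", "mirna_id", "utr_pos", "kind"],
        ).to_csv(outdir / "rewiring.tsv", sep="\t", index=False)
        triplets: list[mi.Triplet] = []
        for cond in conditions:
            des = des_tables[cond.name]
            cond_events = [e for e in events if e.site_id in des.index]
            triplets.extend(
                mi.screen_triplets(
                    cond_events, des, data.gene_expr, data.mirna_expr, cond,
                    alpha=config.alpha, under_edited_rule=config.under_edited_rule,
                )
            )
        mi.triplets_to_frame(triplets).to_csv(
            outdir / "triplets.tsv", sep="\t", index=False
        )
        manifest["counts"]["n_rewiring_events"] = len(events)
        manifest["counts"]["n_triplets"] = len(triplets)
    except Exception as exc:
        raise StageError("triplets", exc) from exc
    manifest["stages"].append("triplets")

    try:
        site_to_contig = {
            row["site_id"]: (row["gene_id"], int(row["utr_pos"]))
            for _, row in data.utr_sites.iterrows()
            if any(row["site_id"] in t.index for t in des_tables.values())
        }
        windows = mi.extract_windows(site_to_contig, data.utrs, flank=config.flank)
        io.write_fasta(
            {k: mi.to_dna(v) for k, v in windows.items()},
            outdir / "motif_windows.fasta",
        )
    except Exception as exc:
        raise StageError("export-motifs", exc) from exc
    manifest["stages"].append("export-motifs")

    return manifest
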