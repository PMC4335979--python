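"""Declarative pipeline orchestration: simulate -> homologs -> align ->
tree -> reconcile -> motif -> rates.

A single master seed deterministically derives one sub-seed per stage, so
one integer reproduces every artifact byte-for-byte.  Each run writes its
artifacts plus ``manifest.json`` recording parameters, per-stage seeds and
artifact SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import homology_search, motif, msa, phylo, rates, reconcile, synthetic_data
from .io_formats import read_fasta, write_fasta, write_newick

#: consensus instance of the TM7 transporter signature planted into
#: simulated family roots so the motif stage has something to find
MOTIF_INSTANCE = "NVVSHGTQDLLLT"
DEFAULT_MOTIF = "NXX(S/T)HX(S/T)QDXXXT"

STAGES = ("simulate", "homologs", "align", "tree", "reconcile", "motif", "rates")


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-serializable."""

    stages: List[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # simulate
    n_species: int = 6
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    subst_rate: float = 0.2
    seq_length: int = 300
    n_decoys_per_species: int = 20
    plant_motif: bool = True
    # homologs
    evalue_cutoff: float = 1e-10
    proteome_dir: Optional[str] = None
    seed_file: Optional[str] = None
    # align
    max_gap_fraction: float = 0.5
    min_conserved_fraction: float = 0.5
    min_block_length: int = 3
    # tree
    tree_method: str = "nj"  # nj | bionj
    correction: str = "p"    # p | poisson | gamma
    gamma_alpha: float = 1.0
    bootstrap_replicates: int = 100
    outgroup: Optional[str] = None
    # motif
    motif_pattern: str = DEFAULT_MOTIF
    max_mismatches: int = 1
    # rates
    reference_strain: str = "reference"
    breakpoint_h: float = 22.0
    sig_figs: int = 2
    rates_file: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        on = set(self.stages)
        if "homologs" in on and "simulate" not in on:
            if not (self.proteome_dir and self.seed_file):
                raise ValueError(
                    "homologs stage needs the simulate stage or both "
                    "proteome_dir and seed_file")
        for stage, needs in (("align", "homologs"), ("tree", "align"),
                             ("reconcile", "simulate")):
            if stage in on and needs not in on:
                raise ValueError(f"{stage} stage needs the {needs} stage enabled")
        if "motif" in on and "simulate" not in on and "homologs" not in on:
            raise ValueError("motif stage needs simulate or homologs enabled")
        if self.tree_method not in ("nj", "bionj"):
            raise ValueError(f"unknown tree method {self.tree_method!r}")


def stage_seed(master: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    on = set(config.stages)
    manifest: dict = {"config": asdict(config), "stage_seeds": {},
                      "artifacts": {}, "stages_run": [], "results": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path.relative_to(out)),
                                       "sha256": _sha256(path)}

    truth = None
    proteomes = None
    family = None
    alignment = None
    inferred = None

    if "simulate" in on:
        s = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = s
        sim = synthetic_data.SimulationConfig(
            n_species=config.n_species, dup_rate=config.dup_rate,
            loss_rate=config.loss_rate, subst_rate=config.subst_rate,
            seq_length=config.seq_length,
            n_decoys_per_species=config.n_decoys_per_species, seed=s)
        stree = synthetic_data.simulate_species_tree(config.n_species, s)
        truth = synthetic_data.simulate_gene_family(stree, sim, seed=s + 1)
        root_seq = None
        if config.plant_motif:
            base = "".join(np.random.default_rng(s + 2).choice(
                list("ACDEFGHIKLMNPQRSTVWY"), size=config.seq_length))
            mid = config.seq_length // 2
            root_seq = (base[:mid] + MOTIF_INSTANCE +
                        base[mid + len(MOTIF_INSTANCE):])[:config.seq_length]
        proteomes = synthetic_data.evolve_sequences(
            truth.gene_tree, sim, root_seq=root_seq, seed=s + 3,
            species=truth.species_tree.leaf_names())
        (out / "proteomes").mkdir(exist_ok=True)
        for sp, records in proteomes.items():
            path = out / "proteomes" / f"{sp}.faa"
            write_fasta(records, path)
            record(f"proteome_{sp}", path)
        path = out / "species_tree.nwk"
        path.write_text(write_newick(truth.species_tree) + "\n")
        record("species_tree", path)
        if truth.gene_tree is not None:
            path = out / "gene_tree_true.nwk"
            path.write_text(write_newick(truth.gene_tree) + "\n")
            record("gene_tree_true", path)
        path = out / "events_true.tsv"
        with open(path, "w") as fh:
            fh.write("event_type\tspecies_branch\ttime\n")
            for etype, branch, t in truth.events:
                fh.write(f"{etype}\t{branch}\t{t:.6f}\n")
        record("events_true", path)
        manifest["results"]["simulate"] = {
            "n_duplications": truth.n_duplications,
            "n_losses": truth.n_losses,
            "n_surviving_genes": len(truth.surviving_leaves()),
            "extinct": truth.extinct,
        }
        manifest["stages_run"].append("simulate")

    if "homologs" in on:
        s = stage_seed(config.seed, "homologs")
        manifest["stage_seeds"]["homologs"] = s
        if proteomes is None:
            proteomes = {}
            for path in sorted(Path(config.proteome_dir).glob("*.faa")):
                proteomes[path.stem] = read_fasta(path, species=path.stem)
            seed_ids = set(Path(config.seed_file).read_text().split())
            seed_species = next(sp for sp, recs in proteomes.items()
                                if seed_ids & {r.id for r in recs})
        else:
            # seed with the species carrying the most surviving copies
            fam_counts = {
                sp: sum(1 for r in recs if r.description == "family")
                for sp, recs in proteomes.items()}
            seed_species = max(sorted(fam_counts), key=lambda sp: fam_counts[sp])
            seed_ids = {r.id for r in proteomes[seed_species]
                        if r.description == "family"}
            if not seed_ids:
                raise RuntimeError("simulated family went extinct; nothing to seed")
        others = {sp: recs for sp, recs in proteomes.items() if sp != seed_species}
        family = homology_search.reciprocal_screen(
            seed_ids, proteomes[seed_species], others,
            cutoff=config.evalue_cutoff)
        path = out / "family.tsv"
        with open(path, "w") as fh:
            fh.write("species\tgene_id\tforward_evalue\treciprocal_rank\n")
            for sp in sorted(family.members):
                for gid in sorted(family.members[sp]):
                    provs = family.provenance.get((sp, gid))
                    ev = f"{provs[0].forward.evalue:.3g}" if provs else "seed"
                    fh.write(f"{sp}\t{gid}\t{ev}\t1\n")
        record("family", path)
        path = out / "rejects.tsv"
        with open(path, "w") as fh:
            fh.write("species\tgene_id\treason\n")
            for rej in family.rejects:
                fh.write(f"{rej.forward.subject_species}\t"
                         f"{rej.forward.subject_id}\t{rej.reason}\n")
        record("rejects", path)
        manifest["results"]["homologs"] = {
            "n_members": len(family.all_member_ids()),
            "n_species": len(family.members),
            "n_rejects": len(family.rejects),
        }
        manifest["stages_run"].append("homologs")

    if "align" in on:
        member_records = []
        for sp in sorted(family.members):
            pool = {r.id: r for r in proteomes[sp]}
            for gid in sorted(family.members[sp]):
                member_records.append(pool[gid])
        alignment = msa.progressive_align(member_records)
        cfg = msa.BlockFilterConfig(config.max_gap_fraction,
                                    config.min_conserved_fraction,
                                    config.min_block_length)
        alignment, kept = msa.filter_blocks(alignment, cfg)
        path = out / "family_aligned.faa"
        with open(path, "w") as fh:
            for rid, row in alignment.rows:
                fh.write(f">{rid}\n{row}\n")
        record("alignment", path)
        path = out / "kept_columns.tsv"
        path.write_text("column\n" + "".join(f"{c}\n" for c in kept))
        record("kept_columns", path)
        manifest["results"]["align"] = {
            "n_rows": len(alignment.rows), "n_columns": alignment.n_columns,
            "n_kept_columns": len(kept)}
        manifest["stages_run"].append("align")

    if "tree" in on:
        s = stage_seed(config.seed, "tree")
        manifest["stage_seeds"]["tree"] = s
        gamma = phylo.GammaConfig(config.gamma_alpha)
        boot = phylo.bootstrap_support(
            alignment, builder=config.tree_method,
            n_replicates=config.bootstrap_replicates, seed=s,
            correction=config.correction, gamma_cfg=gamma)
        inferred = boot.main_tree
        if config.outgroup:
            inferred = phylo.root_with_outgroup(inferred, config.outgroup)
        path = out / "gene_tree_inferred.nwk"
        path.write_text(write_newick(inferred) + "\n")
        record("gene_tree_inferred", path)
        result = {"n_replicates": boot.n_replicates,
                  "n_failed_replicates": boot.n_failed}
        if truth is not None and truth.gene_tree is not None and \
                len(truth.gene_tree.leaves()) >= 4 and \
                set(truth.gene_tree.leaf_names()) == set(inferred.leaf_names()):
            result["rf_to_true_gene_tree"] = phylo.robinson_foulds(
                inferred, truth.gene_tree)
        manifest["results"]["tree"] = result
        manifest["stages_run"].append("tree")

    if "reconcile" in on:
        if truth.gene_tree is None or truth.gene_tree.is_leaf():
            manifest["results"]["reconcile"] = {"skipped": "family too small"}
        else:
            rec = reconcile.lca_reconcile(truth.gene_tree, truth.species_tree)
            report = reconcile.scenario_report(rec)
            path = out / "reconciliation.tsv"
            report.to_csv(path, sep="\t", index=False)
            record("reconciliation", path)
            manifest["results"]["reconcile"] = {
                "n_duplications": rec.n_duplications,
                "n_losses": rec.n_losses,
                "true_duplications": truth.n_duplications,
                "true_losses": truth.n_losses,
            }
        manifest["stages_run"].append("reconcile")

    if "motif" in on:
        pattern = motif.parse_pattern(config.motif_pattern)
        rows = []
        for sp in sorted(proteomes):
            pool = {r.id: r for r in proteomes[sp]}
            ids = (sorted(family.members.get(sp, ())) if family is not None
                   else sorted(pool))
            for gid in ids:
                for m in motif.scan(pool[gid], pattern):
                    rows.append((gid, m.start, m.end, m.matched, 0, ""))
                for start, mism in motif.diagnose(pool[gid], pattern,
                                                  config.max_mismatches):
                    detail = ";".join(f"{k}:{exp}>{obs}" for k, exp, obs in mism)
                    rows.append((gid, start, start + len(pattern) - 1,
                                 pool[gid].residues[start - 1:start - 1 + len(pattern)],
                                 len(mism), detail))
        path = out / "motifs.tsv"
        with open(path, "w") as fh:
            fh.write("seq_id\tstart\tend\tmatched\tn_mismatches\tmismatch_detail\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
        record("motifs", path)
        manifest["results"]["motif"] = {
            "n_exact": sum(1 for r in rows if r[4] == 0),
            "n_near_miss": sum(1 for r in rows if r[4] > 0)}
        manifest["stages_run"].append("motif")

    if "rates" in on:
        s = stage_seed(config.seed, "rates")
        manifest["stage_seeds"]["rates"] = s
        if config.rates_file:
            import pandas as pd
            df = pd.read_csv(config.rates_file, sep="\t")
            series = [
                rates.TimeSeries(sub, strain,
                                 list(zip(g["time_h"], g["concentration_gL"])))
                for (strain, sub), g in df.groupby(["strain", "substrate"])]
        else:
            # synthetic panel: reference plus two mutants on two substrates
            panel = {("reference", "fumarate"): 0.22, ("reference", "malate"): 0.24,
                     ("mutantA", "fumarate"): 0.24, ("mutantA", "malate"): 0.27,
                     ("mutantB", "fumarate"): 0.16, ("mutantB", "malate"): 0.12}
            series = []
            times = list(np.linspace(0.0, 40.0, 12))
            for k, ((strain, sub), rate) in enumerate(sorted(panel.items())):
                tr = synthetic_data.ConsumptionTruth(
                    substrate=sub, c0=10.0, true_rate=rate, noise_sd=0.05,
                    times=times, strain=strain)
                series.append(synthetic_data.simulate_consumption_series(tr, s + k))
        fits = {(ts.strain, ts.substrate): rates.fit_rate(ts) for ts in series}
        ref = (config.reference_strain if config.rates_file
               else "reference")
        table = rates.rate_table(fits, ref, config.sig_figs)
        path = out / "rates.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.4g")
        record("rates", path)
        manifest["results"]["rates"] = {"n_fits": len(fits)}
        manifest["stages_run"].append("rates")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
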